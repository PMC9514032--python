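"""Curated transcription/translation gene catalog and cassette categorization.

The catalog is the matching authority: every downstream count operates on
canonical gene names resolved through it.  Resolution is case-insensitive and
tiered — exact canonical name, then synonym, then COG id, then
function-keyword substring of the product — with the first matching tier
winning; an ambiguous multi-entry hit within one tier is treated as no-match
(logged), never guessed.

A cassette is classified into exactly one of four categories by the resolved
roles of its genes: ``transcription_only``, ``translation_only``, ``both``
(at least one gene of each role — the transcription–translation coupling
candidates) or ``none``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import TextIO

from .model import Cassette, Corpus, DataError, GeneRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("transcription", "translation")
CASSETTE_CATEGORIES = ("transcription_only", "translation_only", "both", "none")


@dataclass
class CatalogEntry:
    canonical_gene: str
    category: str
    synonyms: set[str] = field(default_factory=set)
    function_keywords: set[str] = field(default_factory=set)
    cog_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.canonical_gene:
            raise DataError("catalog entry with empty canonical_gene")
        if self.category not in CATEGORIES:
            raise DataError(
                f"{self.canonical_gene}: unknown category {self.category!r}"
            )


class CuratedCatalog:
    """Validated catalog with case-insensitive lookup indexes."""

    def __init__(self, entries: list[CatalogEntry]):
        self.entries: dict[str, CatalogEntry] = {}
        self._by_name: dict[str, list[str]] = {}
        self._by_cog: dict[str, list[str]] = {}
        for e in entries:
            if e.canonical_gene in self.entries:
                raise DataError(f"duplicate catalog entry {e.canonical_gene}")
            self.entries[e.canonical_gene] = e
        for e in entries:
            for name in {e.canonical_gene, *e.synonyms}:
                key = name.lower()
                owners = self._by_name.setdefault(key, [])
                if owners and owners != [e.canonical_gene]:
                    raise DataError(
                        f"name {name!r} claimed by entries "
                        f"{owners[0]} and {e.canonical_gene}"
                    )
                if e.canonical_gene not in owners:
                    owners.append(e.canonical_gene)
            for cog in e.cog_ids:
                self._by_cog.setdefault(cog.lower(), []).append(e.canonical_gene)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical_gene: str) -> bool:
        return canonical_gene in self.entries

    @property
    def canonical_genes(self) -> list[str]:
        return sorted(self.entries)

    def category_of(self, canonical_gene: str) -> str:
        return self.entries[canonical_gene].category

    def resolve_name(self, name: str) -> str | None:
        """Resolve a bare gene name or synonym to a canonical gene."""
        owners = self._by_name.get(name.lower(), [])
        return owners[0] if len(owners) == 1 else None

    def resolve_cog(self, cog: str) -> str | None:
        owners = sorted(set(self._by_cog.get(cog.lower(), [])))
        return owners[0] if len(owners) == 1 else None

    def resolve_keyword(self, product: str) -> str | None:
        """Resolve a product description by keyword substring (unambiguous only)."""
        hits = self._keyword_hits(product)
        return hits[0] if len(hits) == 1 else None

    def _keyword_hits(self, product: str) -> list[str]:
        # longest matched keyword wins, so "...protein L17" is not shadowed by
        # the "...protein L1" keyword of a sibling entry; remaining ties are
        # genuinely ambiguous
        text = product.lower()
        best: dict[str, int] = {}
        for e in self.entries.values():
            matched = [len(kw) for kw in e.function_keywords if kw and kw.lower() in text]
            if matched:
                best[e.canonical_gene] = max(matched)
        if not best:
            return []
        top = max(best.values())
        return sorted(g for g, length in best.items() if length == top)


def load_catalog(source: TextIO) -> CuratedCatalog:
    """Load a catalog TSV (canonical_gene, category, synonyms,
    function_keywords, cog_ids)."""
    entries: list[CatalogEntry] = []
    header: list[str] | None = None
    expected = ["canonical_gene", "category", "synonyms", "function_keywords", "cog_ids"]
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != expected:
                raise DataError(
                    f"catalog TSV: expected header {expected}, got {header}"
                )
            continue
        fields += [""] * (len(expected) - len(fields))
        row = dict(zip(expected, fields))
        entries.append(
            CatalogEntry(
                canonical_gene=row["canonical_gene"],
                category=row["category"],
                synonyms={s for s in row["synonyms"].split(";") if s},
                function_keywords={s for s in row["function_keywords"].split(";") if s},
                cog_ids={s for s in row["cog_ids"].split(";") if s},
            )
        )
    return CuratedCatalog(entries)


def load_default_catalog() -> CuratedCatalog:
    """Load the catalog seed shipped with the package."""
    ref = resources.files("cassettemine.data").joinpath("default_catalog.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_catalog(fh)


def resolve_gene(
    record: GeneRecord, catalog: CuratedCatalog
) -> tuple[str, str] | None:
    """Resolve one annotated gene to ``(canonical_gene, category)`` or None.

    Tier precedence: exact canonical name > synonym > COG id > keyword
    substring of the product.  Record-side synonyms participate in the name
    tiers so that dropout of ``gene_name`` degrades gracefully.
    """
    names = [record.gene_name] if record.gene_name else []
    # tier 1: exact canonical name
    canon_lc = {e.canonical_gene.lower(): e.canonical_gene for e in catalog.entries.values()}
    t1 = sorted({canon_lc[n.lower()] for n in names if n.lower() in canon_lc})
    if len(t1) == 1:
        return t1[0], catalog.category_of(t1[0])
    # tier 2: synonyms (the record's own name or listed synonyms vs catalog names)
    t2 = sorted(
        {
            c
            for n in names + list(record.synonyms)
            for c in [catalog.resolve_name(n)]
            if c is not None
        }
    )
    if len(t2) == 1:
        return t2[0], catalog.category_of(t2[0])
    if len(t2) > 1:
        logger.warning("ambiguous synonym hit for %s: %s", record.locus_tag, t2)
        return None
    # tier 3: COG ids
    t3 = sorted({c for cog in record.cog_ids for c in [catalog.resolve_cog(cog)] if c})
    if len(t3) == 1:
        return t3[0], catalog.category_of(t3[0])
    if len(t3) > 1:
        logger.warning("ambiguous COG hit for %s: %s", record.locus_tag, t3)
        return None
    # tier 4: function keywords
    t4 = catalog._keyword_hits(record.product) if record.product else []
    if len(t4) == 1:
        return t4[0], catalog.category_of(t4[0])
    if len(t4) > 1:
        logger.warning("ambiguous keyword hit for %s: %s", record.locus_tag, t4)
    return None


def resolve_all(record: GeneRecord, catalog: CuratedCatalog) -> set[str]:
    """All canonical genes a record matches at any tier (used for hybrid/fused
    loci where one record carries evidence for two genes)."""
    hits: set[str] = set()
    for n in ([record.gene_name] if record.gene_name else []) + list(record.synonyms):
        c = catalog.resolve_name(n)
        if c:
            hits.add(c)
    for cog in record.cog_ids:
        c = catalog.resolve_cog(cog)
        if c:
            hits.add(c)
    if record.product:
        hits.update(catalog._keyword_hits(record.product))
    return hits


def classify_cassette(cassette: Cassette, catalog: CuratedCatalog) -> str:
    """Assign one of the four cassette categories."""
    roles = {
        cat
        for g in cassette.genes
        for res in [resolve_gene(g, catalog)]
        if res is not None
        for cat in [res[1]]
    }
    has_tx = "transcription" in roles
    has_tl = "translation" in roles
    if has_tx and has_tl:
        return "both"
    if has_tx:
        return "transcription_only"
    if has_tl:
        return "translation_only"
    return "none"


@dataclass
class CorpusClassification:
    """Per-cassette categories, per-genome tallies and the ``both``-genome set."""

    categories: dict[tuple[str, str], str]
    tallies: dict[str, Counter]
    both_genomes: set[str]

    def total(self) -> Counter:
        out: Counter = Counter()
        for t in self.tallies.values():
            out.update(t)
        return out


def classify_corpus(corpus: Corpus, catalog: CuratedCatalog) -> CorpusClassification:
    """Classify every cassette; the ``both``-genome set (genomes possessing at
    least one cassette mixing transcription and translation genes) is the
    denominator for all downstream ranking."""
    categories: dict[tuple[str, str], str] = {}
    tallies: dict[str, Counter] = {}
    both: set[str] = set()
    for gid in corpus.genome_ids:
        tally: Counter = Counter({c: 0 for c in CASSETTE_CATEGORIES})
        for cas in corpus.cassettes.get(gid, []):
            cat = classify_cassette(cas, catalog)
            categories[(gid, cas.cassette_id)] = cat
            tally[cat] += 1
        tallies[gid] = tally
        if tally["both"] > 0:
            both.add(gid)
    return CorpusClassification(categories=categories, tallies=tallies, both_genomes=both)
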