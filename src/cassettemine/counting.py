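"""Cassette matching rules, genome counting and partner discovery.

A query cassette (an ordered tuple of canonical genes, e.g. ``rplK-nusG``)
matches an observed cassette under one of three rules:

* ``exact`` — the observed canonical gene set equals the query and the
  observed order equals the query's written order;
* ``reordered`` — same gene set, any other order;
* ``subset`` — every query gene occurs in the cassette, plus extra genes
  (order irrelevant).

Matching operates on canonical gene sets after synonym resolution;
unresolved genes in an observed cassette are transparent, and duplicate
canonical genes collapse to a set.  A genome counts once however many of its
cassettes match; the per-genome rule reported is the strongest present
(exact > reordered > subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import CuratedCatalog, resolve_gene
from .model import Cassette, Corpus, DataError

RULE_ORDER = {"exact": 0, "reordered": 1, "subset": 2}


@dataclass(frozen=True)
class CassetteQuery:
    """Ordered, duplicate-free tuple of canonical genes (size >= 2)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DataError("query needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"duplicate genes in query {self.genes}")

    @classmethod
    def parse(cls, text: str) -> "CassetteQuery":
        return cls(tuple(g for g in text.replace(",", "-").split("-") if g))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __str__(self) -> str:
        return "-".join(self.genes)


@dataclass
class MatchReport:
    query: CassetteQuery
    matched: dict[str, list[tuple[str, str]]]  # genome -> [(cassette_id, rule)]

    @property
    def genome_count(self) -> int:
        return len(self.matched)

    def strongest_rule(self, genome_id: str) -> str:
        rules = [r for _, r in self.matched[genome_id]]
        return min(rules, key=lambda r: RULE_ORDER[r])

    @property
    def rule_tallies(self) -> dict[str, int]:
        """Genomes by strongest matching rule."""
        out = {"exact": 0, "reordered": 0, "subset": 0}
        for gid in self.matched:
            out[self.strongest_rule(gid)] += 1
        return out


def _canonical_order(cassette: Cassette, catalog: CuratedCatalog) -> list[str]:
    """Resolved canonical genes in coordinate order; unresolved genes dropped,
    repeats collapsed to the first occurrence."""
    seen: list[str] = []
    for g in cassette.genes:
        res = resolve_gene(g, catalog)
        if res is not None and res[0] not in seen:
            seen.append(res[0])
    return seen


def matches(
    query: CassetteQuery, cassette: Cassette, catalog: CuratedCatalog
) -> str | None:
    """Return the matching rule (``exact``/``reordered``/``subset``) or None."""
    order = _canonical_order(cassette, catalog)
    s = set(order)
    q = set(query.genes)
    if not q.issubset(s):
        return None
    if s == q:
        return "exact" if tuple(order) == query.genes else "reordered"
    return "subset"


def count_genomes(
    query: CassetteQuery, corpus: Corpus, catalog: CuratedCatalog
) -> MatchReport:
    """Count genomes containing the query cassette under rules (i)-(iii)."""
    matched: dict[str, list[tuple[str, str]]] = {}
    for gid in corpus.genome_ids:
        hits = []
        for cas in corpus.cassettes.get(gid, []):
            rule = matches(query, cas, catalog)
            if rule is not None:
                hits.append((cas.cassette_id, rule))
        if hits:
            matched[gid] = hits
    return MatchReport(query=query, matched=matched)


def cooccurring_partners(
    query: CassetteQuery,
    corpus: Corpus,
    catalog: CuratedCatalog,
    min_fraction: float = 0.5,
    report: MatchReport | None = None,
) -> list[tuple[str, float]]:
    """Non-query canonical genes riding along in matching cassettes.

    For each partner gene, the fraction of matched genomes in which some
    matching cassette also carries the partner; partners above
    ``min_fraction`` (strict) are returned sorted by fraction descending,
    ties lexicographic.
    """
    rep = report or count_genomes(query, corpus, catalog)
    if rep.genome_count == 0:
        return []
    partner_genomes: dict[str, set[str]] = {}
    for gid, hits in rep.matched.items():
        by_id = {c.cassette_id: c for c in corpus.cassettes.get(gid, [])}
        for cid, _rule in hits:
            for gene in _canonical_order(by_id[cid], catalog):
                if gene not in query.gene_set:
                    partner_genomes.setdefault(gene, set()).add(gid)
    out = [
        (gene, len(gids) / rep.genome_count)
        for gene, gids in partner_genomes.items()
    ]
    out = [(g, f) for g, f in out if f > min_fraction]
    out.sort(key=lambda gf: (-gf[1], gf[0]))
    return out


def independence_fraction(
    query: CassetteQuery,
    corpus: Corpus,
    catalog: CuratedCatalog,
    report: MatchReport | None = None,
) -> float | None:
    """Fraction of matched genomes where the query occurs as a standalone
    cassette (gene set exactly equal, no extra genes); None if no matches."""
    rep = report or count_genomes(query, corpus, catalog)
    if rep.genome_count == 0:
        return None
    standalone = sum(
        1
        for gid, hits in rep.matched.items()
        if any(rule in ("exact", "reordered") for _, rule in hits)
    )
    return standalone / rep.genome_count
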