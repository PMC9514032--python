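"""Three-way genome-occurrence ranking and taxonomic distribution summaries.

Genes of transcription–translation (``both``) cassettes are counted along
three axes — canonical gene name, product function string and COG id — at
genome-level presence (a key counts once per genome however many cassettes
contain it).  Top lists use a strict genome-count cutoff (default > 300
genomes) and a consensus set keeps the genes recurring across the axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import CorpusClassification, CuratedCatalog, classify_corpus, resolve_gene
from .model import Corpus, DataError, Taxon

AXES = ("gene", "function", "cog")


@dataclass
class FrequencyTable:
    """Genome-occurrence counts along one axis.

    Keys are canonicalized: genes via the catalog, functions as lower-cased
    product strings, COG ids verbatim.  ``denominator`` is the number of
    genomes considered (the ``both``-genome set for the default restriction).
    """

    axis: str
    counts: dict[str, int]
    denominator: int


@dataclass
class RankingConfig:
    top_n: int = 20
    min_genomes: int = 300
    restrict_to_category: str = "both"

    def __post_init__(self) -> None:
        if self.top_n < 1 or self.min_genomes < 0:
            raise DataError("top_n must be >= 1 and min_genomes >= 0")


def build_frequency_table(
    corpus: Corpus,
    axis: str,
    catalog: CuratedCatalog,
    config: RankingConfig = RankingConfig(),
    classification: CorpusClassification | None = None,
) -> FrequencyTable:
    """Count genome-level occurrence of keys within cassettes of the
    configured category."""
    if axis not in AXES:
        raise DataError(f"unknown ranking axis {axis!r}")
    cls = classification or classify_corpus(corpus, catalog)
    counts: dict[str, int] = {}
    denominator = 0
    for gid in corpus.genome_ids:
        keys: set[str] = set()
        in_category = False
        for cas in corpus.cassettes.get(gid, []):
            if cls.categories[(gid, cas.cassette_id)] != config.restrict_to_category:
                continue
            in_category = True
            for g in cas.genes:
                if axis == "gene":
                    res = resolve_gene(g, catalog)
                    if res is not None:
                        keys.add(res[0])
                elif axis == "function":
                    if g.product:
                        keys.add(g.product.lower())
                else:
                    keys.update(g.cog_ids)
        if in_category:
            denominator += 1
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    return FrequencyTable(axis=axis, counts=counts, denominator=denominator)


def top_ranked(
    table: FrequencyTable, config: RankingConfig = RankingConfig()
) -> list[tuple[str, int]]:
    """Keys with count strictly above ``min_genomes``, sorted by count
    descending (ties lexicographic ascending), truncated to ``top_n``."""
    eligible = [(k, c) for k, c in table.counts.items() if c > config.min_genomes]
    eligible.sort(key=lambda kc: (-kc[1], kc[0]))
    return eligible[: config.top_n]


def _canonicalize_keys(
    keys: list[str], axis: str, catalog: CuratedCatalog
) -> set[str]:
    out: set[str] = set()
    for k in keys:
        if axis == "gene":
            c = catalog.resolve_name(k)
        elif axis == "cog":
            c = catalog.resolve_cog(k)
        else:
            c = catalog.resolve_keyword(k)
        if c is not None:
            out.add(c)
    return out


def consensus_genes(
    gene_list: list[str],
    function_list: list[str],
    cog_list: list[str],
    catalog: CuratedCatalog,
    min_rankings: int = 2,
) -> set[str]:
    """Canonical genes present in at least ``min_rankings`` of the three
    top-ranked lists, after synonym unification (e.g. yhbC = rimP)."""
    sets = [
        _canonicalize_keys(gene_list, "gene", catalog),
        _canonicalize_keys(function_list, "function", catalog),
        _canonicalize_keys(cog_list, "cog", catalog),
    ]
    votes: dict[str, int] = {}
    for s in sets:
        for g in s:
            votes[g] = votes.get(g, 0) + 1
    return {g for g, v in votes.items() if v >= min_rankings}


def summarize_taxa(
    genome_ids: list[str],
    taxonomy_map: dict[str, Taxon],
    group_by: str = "genus",
) -> dict[str, tuple[float, float]]:
    """Group genomes by genus, phylum or free-text label.

    Returns ``group -> (count, fraction)``; fractions sum to 1 including the
    ``unclassified`` group.  A genome carrying several labels contributes
    1/|labels| to each so the unit-mass invariant holds.
    """
    if group_by not in ("genus", "phylum", "label"):
        raise DataError(f"unknown group_by {group_by!r}")
    weights: dict[str, float] = {}
    for gid in genome_ids:
        taxon = taxonomy_map.get(gid)
        if taxon is None:
            weights["unclassified"] = weights.get("unclassified", 0.0) + 1.0
            continue
        if group_by == "label":
            labels = sorted(taxon.labels) or ["unclassified"]
            for lab in labels:
                weights[lab] = weights.get(lab, 0.0) + 1.0 / len(labels)
        else:
            group = getattr(taxon, group_by) or "unclassified"
            weights[group] = weights.get(group, 0.0) + 1.0
    n = len(genome_ids)
    return {g: (w, w / n if n else 0.0) for g, w in sorted(weights.items())}
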