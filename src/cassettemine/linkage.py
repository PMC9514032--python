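"""Corpus-internal gene-linkage network and candidate-cassette extraction.

Three evidence channels, each a fraction over the genomes that contain both
genes of a pair:

* **fusion** — the genes occur as one hybrid locus or are adjacent in a
  cassette with no intergenic sequence (D_I <= 0);
* **neighborhood** — the genes are consecutive members of one cassette;
* **co-occurrence** — both genes sit in one cassette, intervening genes
  allowed.

Scores live in [0, 1]; an edge is *confident* in a channel when its score is
strictly greater than the threshold (default 0.7).  Connected components of
confident edges (per channel) become candidate cassettes, and a k = 2
k-means bipartition of the combined-score matrix separates the
transcription- from the translation-dominated cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .catalog import CuratedCatalog, resolve_all, resolve_gene
from .counting import CassetteQuery, count_genomes
from .model import Cassette, Corpus, DataError
from .operon_features import intergenic_distance

CHANNELS = ("fusion", "neighborhood", "cooccurrence")

EXACT_BIPARTITION_LIMIT = 15  # exhaustive 2-partition search up to this many nodes


def _presence_and_cassette_maps(corpus: Corpus, catalog: CuratedCatalog):
    """Per genome: set of canonical genes present, and per cassette the
    resolved gene sequence (with records kept for distance checks)."""
    presence: dict[str, set[str]] = {}
    resolved_cassettes: dict[str, list[tuple[Cassette, list[str | None]]]] = {}
    for gid in corpus.genome_ids:
        genes: set[str] = set()
        for g in corpus.genomes[gid].genes:
            res = resolve_gene(g, catalog)
            if res is not None:
                genes.add(res[0])
        presence[gid] = genes
        rc = []
        for cas in corpus.cassettes.get(gid, []):
            seq = [
                (resolve_gene(g, catalog) or (None,))[0] for g in cas.genes
            ]
            rc.append((cas, seq))
        resolved_cassettes[gid] = rc
    return presence, resolved_cassettes


class _ChannelCounter:
    """Shared scan computing all three channel numerators in one pass."""

    def __init__(self, corpus: Corpus, catalog: CuratedCatalog):
        self.corpus = corpus
        self.catalog = catalog
        self.presence, self.resolved = _presence_and_cassette_maps(corpus, catalog)

    def score(self, gene_a: str, gene_b: str) -> dict[str, float]:
        pair = {gene_a, gene_b}
        n_both = 0
        hits = {c: 0 for c in CHANNELS}
        for gid in self.corpus.genome_ids:
            if not pair.issubset(self.presence[gid]):
                continue
            n_both += 1
            fused = nbr = cooc = False
            # hybrid locus carrying evidence for both genes
            for g in self.corpus.genomes[gid].genes:
                if pair.issubset(resolve_all(g, self.catalog)):
                    fused = True
                    break
            for cas, seq in self.resolved[gid]:
                in_cas = pair.issubset({s for s in seq if s})
                if in_cas:
                    cooc = True
                for i in range(len(seq) - 1):
                    if {seq[i], seq[i + 1]} == pair:
                        nbr = True
                        if intergenic_distance(cas.genes[i], cas.genes[i + 1]) <= 0:
                            fused = True
            hits["fusion"] += fused
            hits["neighborhood"] += nbr
            hits["cooccurrence"] += cooc
        if n_both == 0:
            return {c: 0.0 for c in CHANNELS}
        return {c: hits[c] / n_both for c in CHANNELS}


def fusion_score(
    gene_a: str, gene_b: str, corpus: Corpus, catalog: CuratedCatalog
) -> float:
    return _ChannelCounter(corpus, catalog).score(gene_a, gene_b)["fusion"]


def neighborhood_score(
    gene_a: str, gene_b: str, corpus: Corpus, catalog: CuratedCatalog
) -> float:
    return _ChannelCounter(corpus, catalog).score(gene_a, gene_b)["neighborhood"]


def cooccurrence_score(
    gene_a: str, gene_b: str, corpus: Corpus, catalog: CuratedCatalog
) -> float:
    return _ChannelCounter(corpus, catalog).score(gene_a, gene_b)["cooccurrence"]


def build_linkage_graph(
    gene_set: set[str],
    corpus: Corpus,
    catalog: CuratedCatalog,
    threshold: float = 0.7,
) -> nx.Graph:
    """All pairwise channel scores over ``gene_set`` as a networkx graph.

    Edge attributes: the three channel scores, ``combined`` (max over
    channels) and ``confident_channels`` (channels with score strictly
    above the threshold).
    """
    if len(gene_set) < 2:
        raise DataError("linkage graph needs at least 2 genes")
    counter = _ChannelCounter(corpus, catalog)
    graph = nx.Graph(threshold=threshold)
    graph.add_nodes_from(sorted(gene_set))
    for a, b in combinations(sorted(gene_set), 2):
        scores = counter.score(a, b)
        confident = [c for c in CHANNELS if scores[c] > threshold]
        graph.add_edge(
            a,
            b,
            **scores,
            combined=max(scores.values()),
            confident_channels=confident,
        )
    return graph


@dataclass
class CandidateCassette:
    genes: frozenset[str]
    channel: str
    genome_count: int
    frequency: float


def extract_candidates(
    graph: nx.Graph,
    corpus: Corpus,
    catalog: CuratedCatalog,
    denominator: int | None = None,
) -> list[CandidateCassette]:
    """Connected components (size >= 2) of confident edges, per channel,
    with genome counts by the cassette-matching rules.

    ``denominator`` (default: number of corpus genomes) converts counts to
    frequencies; pass the ``both``-genome set size for ranking-consistent
    frequencies.
    """
    denom = denominator if denominator is not None else len(corpus.genomes)
    out: list[CandidateCassette] = []
    for channel in CHANNELS:
        sub = nx.Graph()
        sub.add_nodes_from(graph.nodes)
        for a, b, data in graph.edges(data=True):
            if channel in data["confident_channels"]:
                sub.add_edge(a, b)
        for comp in nx.connected_components(sub):
            if len(comp) < 2:
                continue
            query = CassetteQuery(tuple(sorted(comp)))
            report = count_genomes(query, corpus, catalog)
            out.append(
                CandidateCassette(
                    genes=frozenset(comp),
                    channel=channel,
                    genome_count=report.genome_count,
                    frequency=report.genome_count / denom if denom else 0.0,
                )
            )
    out.sort(key=lambda c: (-c.genome_count, c.channel, sorted(c.genes)))
    return out


def combined_matrix(graph: nx.Graph, combine: str = "max") -> tuple[list[str], np.ndarray]:
    """Symmetric combined-score matrix over sorted nodes."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)))
    for a, b, data in graph.edges(data=True):
        scores = [data[c] for c in CHANNELS]
        val = max(scores) if combine == "max" else float(np.mean(scores))
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = val
    return nodes, mat


def _wcss(mat: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        rows = mat[labels == lab]
        total += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return total


def bipartition(
    graph: nx.Graph,
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
    combine: str = "max",
) -> tuple[list[str], list[str]]:
    """k = 2 clustering of genes by their combined-score matrix rows.

    Small instances (<= 15 nodes) are solved exactly by enumerating all
    2-partitions and minimizing the within-cluster sum of squares; larger
    instances use restarted k-means (deterministic given seed).  The cluster
    containing the lexicographically smallest gene is returned first; equal
    objectives break ties toward the enumeration order, which realizes the
    lexicographic smallest-gene assignment.
    """
    nodes, mat = combined_matrix(graph, combine=combine)
    n = len(nodes)
    if n < k:
        raise DataError(f"bipartition needs >= {k} nodes, got {n}")
    if k != 2:
        labels = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit_predict(mat)
    elif n <= EXACT_BIPARTITION_LIMIT:
        best_labels: np.ndarray | None = None
        best = np.inf
        # node 0 fixed to cluster 0 halves the search space
        for mask in range(1, 2 ** (n - 1)):
            labels = np.zeros(n, dtype=int)
            for j in range(1, n):
                labels[j] = (mask >> (j - 1)) & 1
            w = _wcss(mat, labels)
            if w < best - 1e-12:
                best = w
                best_labels = labels
        labels = best_labels
    else:
        labels = KMeans(n_clusters=2, n_init=restarts, random_state=seed).fit_predict(mat)
    first = [nodes[i] for i in range(n) if labels[i] == labels[0]]
    second = [nodes[i] for i in range(n) if labels[i] != labels[0]]
    return sorted(first), sorted(second)
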