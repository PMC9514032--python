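"""Linkage channels, confident-edge graphs, candidates and bipartition."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cassettemine.counting import CassetteQuery, count_genomes
from cassettemine.linkage import (
    CHANNELS,
    bipartition,
    build_linkage_graph,
    combined_matrix,
    cooccurrence_score,
    extract_candidates,
    fusion_score,
    neighborhood_score,
)
from cassettemine.model import DataError
from cassettemine.simulate import PlantedQuery, SimulationConfig, simulate_corpus

from conftest import build_corpus


class TestChannelScores:
    def test_always_adjacent_scores_one(self, catalog):
        corpus = build_corpus({f"G{i}": [["rplK", "nusG"]] for i in range(4)})
        assert neighborhood_score("rplK", "nusG", corpus, catalog) == 1.0
        assert cooccurrence_score("rplK", "nusG", corpus, catalog) == 1.0

    def test_never_coresident_scores_zero(self, catalog):
        corpus = build_corpus({"G1": [["rplK"]], "G2": [["nusG"]]})
        for fn in (fusion_score, neighborhood_score, cooccurrence_score):
            assert fn("rplK", "nusG", corpus, catalog) == 0.0

    def test_planted_fraction_fusion(self, catalog):
        # fused (overlapping, D_I <= 0) in 3 of 4 co-resident genomes
        spec = {f"G{i}": [["rplK", "nusG"]] for i in range(4)}
        gaps = {"G0": -10, "G1": -10, "G2": 0, "G3": 50}
        corpus = build_corpus(spec, gaps=gaps)
        assert fusion_score("rplK", "nusG", corpus, catalog) == 0.75

    def test_planted_fraction_neighborhood(self, catalog):
        # consecutive in 2 of 4 genomes containing both
        spec = {
            "G0": [["rplK", "nusG"]],
            "G1": [["rplK", "nusG"]],
            "G2": [["rplK", "rplA", "nusG"]],
            "G3": [["rplK"], ["nusG"]],
        }
        corpus = build_corpus(spec)
        assert neighborhood_score("rplK", "nusG", corpus, catalog) == 0.5
        assert cooccurrence_score("rplK", "nusG", corpus, catalog) == 0.75

    def test_symmetry(self, catalog, planted_corpus):
        corpus, _ = planted_corpus
        for fn in (fusion_score, neighborhood_score, cooccurrence_score):
            assert fn("rplK", "nusG", corpus, catalog) == fn(
                "nusG", "rplK", corpus, catalog
            )

    def test_channel_nesting_on_single_copy_corpus(self, catalog):
        """fusion <= neighborhood <= cooccurrence for every pair."""
        corpus, _ = simulate_corpus(
            SimulationConfig(
                n_genomes=30,
                seed=21,
                planted=[PlantedQuery(CassetteQuery(("rplK", "nusG")), 8, 4, 6)],
                genes_per_genome=(25, 35),
            ),
            catalog,
        )
        genes = ["rplK", "nusG", "rplA", "secE", "rbfA", "truB"]
        graph = build_linkage_graph(set(genes), corpus, catalog)
        for a, b, data in graph.edges(data=True):
            assert data["fusion"] <= data["neighborhood"] <= data["cooccurrence"]


class TestLinkageGraph:
    def test_too_small_gene_set_rejected(self, catalog):
        corpus = build_corpus({"G1": [["rplK"]]})
        with pytest.raises(DataError):
            build_linkage_graph({"rplK"}, corpus, catalog)

    def test_exact_threshold_is_not_confident(self, catalog):
        # adjacency in exactly 7 of 10 co-resident genomes -> score 0.70
        spec = {f"G{i}": [["rplK", "nusG"]] for i in range(7)}
        spec.update({f"G{i}": [["rplK"], ["nusG"]] for i in range(7, 10)})
        corpus = build_corpus(spec)
        graph = build_linkage_graph({"rplK", "nusG"}, corpus, catalog, threshold=0.7)
        data = graph.edges["nusG", "rplK"]
        assert data["neighborhood"] == pytest.approx(0.7)
        assert "neighborhood" not in data["confident_channels"]

    def test_impossible_threshold_gives_no_confident_edges(self, catalog, planted_corpus):
        corpus, _ = planted_corpus
        graph = build_linkage_graph({"rplK", "nusG"}, corpus, catalog, threshold=1.01)
        assert all(
            not data["confident_channels"] for _, _, data in graph.edges(data=True)
        )


class TestExtractCandidates:
    @pytest.fixture()
    def two_clique_corpus(self, catalog):
        # two disjoint always-adjacent cliques
        spec = {
            f"G{i}": [["rplK", "nusG"], ["nusA", "infB"]] for i in range(10)
        }
        return build_corpus(spec)

    def test_two_planted_cliques_found_per_channel(self, two_clique_corpus, catalog):
        graph = build_linkage_graph(
            {"rplK", "nusG", "nusA", "infB"}, two_clique_corpus, catalog
        )
        candidates = extract_candidates(graph, two_clique_corpus, catalog)
        by_channel = {}
        for c in candidates:
            by_channel.setdefault(c.channel, set()).add(c.genes)
        expected = {frozenset({"rplK", "nusG"}), frozenset({"nusA", "infB"})}
        assert by_channel["neighborhood"] == expected
        assert by_channel["cooccurrence"] == expected

    def test_genome_counts_match_counting_module(self, two_clique_corpus, catalog):
        graph = build_linkage_graph(
            {"rplK", "nusG", "nusA", "infB"}, two_clique_corpus, catalog
        )
        for c in extract_candidates(graph, two_clique_corpus, catalog):
            report = count_genomes(
                CassetteQuery(tuple(sorted(c.genes))), two_clique_corpus, catalog
            )
            assert c.genome_count == report.genome_count

    def test_empty_confident_edges_empty_list(self, catalog):
        corpus = build_corpus({"G1": [["rplK"], ["nusG"]]})
        graph = build_linkage_graph({"rplK", "nusG"}, corpus, catalog)
        assert extract_candidates(graph, corpus, catalog) == []


def _random_score_graph(rng, n):
    graph = nx.Graph(threshold=0.7)
    names = [f"g{i:02d}" for i in range(n)]
    graph.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        scores = {c: float(rng.random()) for c in CHANNELS}
        graph.add_edge(a, b, **scores, combined=max(scores.values()),
                       confident_channels=[])
    return graph


def _brute_force_wcss_optimum(mat):
    """Independent exhaustive search over all 2-partitions."""
    n = mat.shape[0]
    best = np.inf
    for assignment in itertools.product([0, 1], repeat=n - 1):
        labels = np.array([0, *assignment])
        if labels.sum() in (0, n):
            continue
        total = 0.0
        for lab in (0, 1):
            rows = mat[labels == lab]
            total += ((rows - rows.mean(axis=0)) ** 2).sum()
        best = min(best, total)
    return best


class TestBipartition:
    def test_two_planted_blocks_recovered(self):
        graph = nx.Graph(threshold=0.7)
        block1, block2 = ["a", "b", "c"], ["x", "y", "z"]
        graph.add_nodes_from(block1 + block2)
        for a, b in itertools.combinations(block1 + block2, 2):
            within = (a in block1) == (b in block1)
            s = 0.9 if within else 0.05
            graph.add_edge(a, b, fusion=s, neighborhood=s, cooccurrence=s,
                           combined=s, confident_channels=[])
        left, right = bipartition(graph, seed=0)
        assert {tuple(left), tuple(right)} == {tuple(block1), tuple(block2)}

    def test_matches_brute_force_optimum(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 6, 8, 10):
            graph = _random_score_graph(rng, n)
            _, mat = combined_matrix(graph)
            left, right = bipartition(graph, seed=1)
            nodes = sorted(graph.nodes)
            labels = np.array([0 if v in left else 1 for v in nodes])
            wcss = 0.0
            for lab in (0, 1):
                rows = mat[labels == lab]
                wcss += ((rows - rows.mean(axis=0)) ** 2).sum()
            assert wcss == pytest.approx(_brute_force_wcss_optimum(mat))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        graph = _random_score_graph(rng, 18)  # above the exact-search limit
        assert bipartition(graph, seed=4) == bipartition(graph, seed=4)

    def test_fewer_nodes_than_clusters_rejected(self):
        graph = nx.Graph()
        graph.add_node("only")
        with pytest.raises(DataError):
            bipartition(graph)
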