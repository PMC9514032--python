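"""Pair features, the logistic operon-pair classifier and operon chaining."""

import io
import math

import numpy as np
import pytest

from cassettemine.model import DataError, GeneRecord, GenomeAnnotation
from cassettemine.operon_features import (
    AdjacentPairFeatures,
    FeatureConfig,
    OperonPairClassifier,
    conservation_from_counts,
    intergenic_distance,
    length_ratio_score,
    motif_frequencies,
    phylogenetic_profile,
    predict_operons,
    profile_distance,
    reverse_complement,
    train_pair_classifier,
    within_cutoffs,
)
from cassettemine.simulate import SimulationConfig, simulate_corpus

from conftest import build_corpus


def _gene(start, end, strand="+", genome="G1", tag="t1"):
    return GeneRecord(genome, tag, "", [], "", [], start, end, strand)


class TestIntergenicDistance:
    @pytest.mark.parametrize(
        "up_end,down_start,expected",
        [(1000, 1001, 0), (200, 151, -50), (100, 351, 250)],
    )
    def test_worked_values(self, up_end, down_start, expected):
        up = _gene(1, up_end, tag="a")
        down = _gene(down_start, down_start + 500, tag="b")
        assert intergenic_distance(up, down) == expected

    def test_translation_invariance(self):
        up, down = _gene(100, 400, tag="a"), _gene(450, 900, tag="b")
        shifted_up = _gene(100 + 5000, 400 + 5000, tag="a")
        shifted_down = _gene(450 + 5000, 900 + 5000, tag="b")
        assert intergenic_distance(up, down) == intergenic_distance(
            shifted_up, shifted_down
        )

    def test_cross_genome_error(self):
        with pytest.raises(DataError):
            intergenic_distance(_gene(1, 10, genome="G1"), _gene(20, 30, genome="G2"))

    @pytest.mark.parametrize("d,inside", [(-50, True), (0, True), (250, True),
                                          (-51, False), (251, False)])
    def test_cutoffs_inclusive(self, d, inside):
        assert within_cutoffs(d) is inside


class TestProfileDistance:
    def test_identical_profiles_zero(self):
        p = np.array([1, 0, 1, 1])
        assert profile_distance(p, p) == 0.0

    def test_complementary_half_frequency(self):
        p1 = np.array([1, 1, 0, 0])
        p2 = np.array([0, 0, 1, 1])
        # Hamming fraction 1, both entropies 1 bit -> distance ~ 1
        assert profile_distance(p1, p2) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p1 = rng.integers(0, 2, 12)
            p2 = rng.integers(0, 2, 12)
            d12 = profile_distance(p1, p2)
            assert d12 == profile_distance(p2, p1)
            assert d12 >= 0.0

    def test_length_mismatch_error(self):
        with pytest.raises(DataError):
            profile_distance(np.ones(3), np.ones(4))

    def test_planted_presence_recovered(self, planted_corpus, catalog):
        corpus, manifest = planted_corpus
        profile = phylogenetic_profile("rpoA", corpus, catalog)
        planted = manifest.genomes_with("rpoA-rplQ-rpsD-rpsK-rpsM")
        expected = np.array(
            [1 if gid in planted else 0 for gid in corpus.genome_ids], dtype=np.int8
        )
        assert (profile == expected).all()


class TestConservation:
    def test_smoothed_arithmetic(self):
        assert conservation_from_counts(8, 8) == pytest.approx(-math.log(9 / 10))
        assert conservation_from_counts(0, 8) == pytest.approx(-math.log(1 / 10))
        assert conservation_from_counts(0, 0) == pytest.approx(-math.log(1 / 2))

    def test_strictly_decreasing_in_adjacency(self):
        for n_both in range(21):
            scores = [conservation_from_counts(a, n_both) for a in range(n_both + 1)]
            assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))


class TestLengthRatio:
    def test_formula(self):
        assert length_ratio_score(_gene(1, 300, tag="a"), _gene(400, 699, tag="b")) == 0.0
        up, down = _gene(1, 600, tag="a"), _gene(700, 999, tag="b")
        assert length_ratio_score(up, down) == pytest.approx(math.log(2))
        assert length_ratio_score(down, up) == pytest.approx(-math.log(2))


class TestMotifFrequencies:
    def _genome(self, sequence, genes):
        return GenomeAnnotation(genome_id="G1", genes=genes, sequence=sequence)

    def test_absent_motif_zero(self):
        seq = "C" * 100 + "ATGAAATAG" + "C" * 20
        gene = _gene(101, 109)
        genome = self._genome(seq, [gene])
        config = FeatureConfig(motifs=["TATAAT"])
        freqs, truncated = motif_frequencies(genome, gene, config)
        assert freqs[0] == 0.0 and not truncated

    def test_single_occurrence_normalization(self):
        window = "TATAAT" + "C" * 94
        seq = window + "ATGAAATAG"
        gene = _gene(101, 109)
        genome = self._genome(seq, [gene])
        freqs, _ = motif_frequencies(genome, gene, FeatureConfig(motifs=["TATAAT"]))
        assert freqs[0] == pytest.approx(1 / 95)

    def test_minus_strand_window_is_reverse_complement(self):
        motif = "TATAAT"
        downstream_window = reverse_complement(motif) + "G" * 94
        seq = "C" * 50 + downstream_window  # gene ends at 50; window 3' of end
        gene = _gene(11, 50, strand="-")
        genome = self._genome(seq, [gene])
        freqs, _ = motif_frequencies(genome, gene, FeatureConfig(motifs=[motif]))
        assert freqs[0] == pytest.approx(1 / 95)

    def test_overlapping_occurrences_counted(self):
        window = "AAAAA" + "C" * 95
        seq = window + "ATG"
        gene = _gene(101, 103)
        genome = self._genome(seq, [gene])
        freqs, _ = motif_frequencies(genome, gene, FeatureConfig(motifs=["AA"]))
        assert freqs[0] == pytest.approx(4 / 99)

    def test_truncation_flagged_at_contig_edge(self):
        gene = _gene(31, 60)
        genome = self._genome("A" * 60, [gene])
        freqs, truncated = motif_frequencies(genome, gene, FeatureConfig(motifs=["AA"]))
        assert truncated
        assert 0.0 <= freqs[0] <= 1.0

    def test_missing_sequence_error(self):
        gene = _gene(1, 30)
        genome = GenomeAnnotation(genome_id="G1", genes=[gene])
        with pytest.raises(DataError):
            motif_frequencies(genome, gene, FeatureConfig(motifs=["AA"]))


def _synthetic_pairs(rng, n=500):
    pairs = []
    for d in rng.normal(20, 10, n):
        pairs.append(AdjacentPairFeatures(int(round(d)), 0, 0, 0, label="operon_pair"))
    for d in rng.normal(300, 60, n):
        pairs.append(AdjacentPairFeatures(int(round(d)), 0, 0, 0, label="boundary_pair"))
    return pairs


class TestPairClassifier:
    def test_single_class_rejected(self):
        pairs = [AdjacentPairFeatures(10, 0, 0, 0, label="operon_pair")] * 5
        with pytest.raises(DataError):
            train_pair_classifier(pairs)

    def test_held_out_accuracy(self):
        rng = np.random.default_rng(1)
        clf = train_pair_classifier(_synthetic_pairs(rng, 500), seed=1)
        held_out = _synthetic_pairs(rng, 200)
        X = np.vstack([p.to_vector() for p in held_out])
        y = np.array([1 if p.label == "operon_pair" else 0 for p in held_out])
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_duplicated_training_set_identical_weights(self):
        rng = np.random.default_rng(2)
        pairs = _synthetic_pairs(rng, 100)
        w1 = train_pair_classifier(pairs, seed=3).weights_
        w2 = train_pair_classifier(pairs, seed=3).weights_
        assert (w1 == w2).all()

    def test_zero_weights_give_half_probability(self):
        clf = OperonPairClassifier(feature_order=["d_i"])
        buf = io.StringIO("feature\tmean\tscale\tweight\nd_i\t0.0\t1.0\t0.0\n__intercept__\t0.0\t1.0\t0.0\n")
        clf = OperonPairClassifier.from_tsv(buf)
        assert clf.operon_probability([[123.0]])[0] == pytest.approx(0.5)

    def test_tsv_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(4)
        clf = train_pair_classifier(_synthetic_pairs(rng, 200), seed=1)
        buf = io.StringIO()
        clf.to_tsv(buf)
        buf.seek(0)
        clone = OperonPairClassifier.from_tsv(buf)
        X = np.vstack([p.to_vector() for p in _synthetic_pairs(rng, 50)])
        assert np.allclose(clf.predict_proba(X), clone.predict_proba(X))

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone

        clf = OperonPairClassifier(C=2.0)
        params = clf.get_params()
        assert params["C"] == 2.0
        clone(clf)  # must be re-constructible from get_params


@pytest.fixture(scope="module")
def trained_classifier():
    rng = np.random.default_rng(1)
    return train_pair_classifier(_synthetic_pairs(rng, 500), seed=1)


class TestPredictOperons:
    def test_far_apart_genes_become_singletons(self, trained_classifier):
        corpus = build_corpus({"G1": [["a"], ["b"], ["c"]]})
        genome = corpus.genomes["G1"]
        out = predict_operons(genome, trained_classifier)
        assert [c.locus_tags for c in out] == [[g.locus_tag] for g in genome.genes]

    def test_three_gene_chain(self, trained_classifier):
        corpus = build_corpus({"G1": [["a", "b", "c"]]}, intra_gap=20)
        genome = corpus.genomes["G1"]
        out = predict_operons(genome, trained_classifier)
        assert len(out) == 1 and len(out[0].genes) == 3

    def test_output_partitions_gene_list(self, trained_classifier, catalog):
        corpus, _ = simulate_corpus(
            SimulationConfig(n_genomes=3, seed=9, genes_per_genome=(30, 40)), catalog
        )
        for gid in corpus.genome_ids:
            genome = corpus.genomes[gid]
            out = predict_operons(genome, trained_classifier)
            tags = [t for c in out for t in c.locus_tags]
            assert tags == [g.locus_tag for g in genome.genes]

    def test_boundary_recovery_on_planted_operons(self, trained_classifier, catalog):
        """Well-separated intra/boundary gap distributions let the classifier
        recover planted operon boundaries."""
        corpus, manifest = simulate_corpus(
            SimulationConfig(n_genomes=10, seed=13, genes_per_genome=(40, 60)), catalog
        )
        recovered = total = 0
        for gid in corpus.genome_ids:
            truth = {tuple(tags) for _, tags in manifest.operons[gid]}
            pred = {
                tuple(c.locus_tags)
                for c in predict_operons(corpus.genomes[gid], trained_classifier)
            }
            total += len(truth)
            recovered += len(truth & pred)
        assert recovered / total >= 0.90


class TestProfileDistanceProperties:
    from hypothesis import given, settings, strategies as st

    profiles = st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=16)

    @given(profiles, profiles)
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_nonnegative_zero_iff_identical(self, bits1, bits2):
        n = min(len(bits1), len(bits2))
        p1, p2 = np.array(bits1[:n]), np.array(bits2[:n])
        d = profile_distance(p1, p2)
        assert d == profile_distance(p2, p1)
        assert d >= 0.0
        if (p1 == p2).all():
            assert d == 0.0
        else:
            assert d > 0.0
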