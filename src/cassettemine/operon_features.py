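"""Adjacent-gene-pair features and a logistic operon-pair classifier.

Operon membership of an adjacent gene pair is predicted from five feature
groups:

1. **intergenic distance** ``D_I = downstream_start - (upstream_end + 1)``,
   with -50 and 250 nt as lower/upper plausibility cutoffs (negative values
   mean overlapping genes);
2. **neighborhood conservation** — a smoothed negative log-likelihood of the
   pair being adjacent across genomes that contain both genes (smaller =
   more conserved);
3. **functional relatedness** — a phylogenetic-profile distance combining
   the normalized Hamming distance with the profiles' Shannon entropies
   (smaller = more related);
4. **length ratio** — natural log of upstream/downstream gene lengths;
5. **motif frequencies** — normalized occurrence counts of configured IUPAC
   DNA motifs in the 100 nt upstream of the downstream gene's translational
   start, on the coding strand.

"Upstream/downstream" follows coordinate order; only the motif window is
strand-aware.  The classifier is a standardized logistic regression exposed
as a scikit-learn estimator so it composes with sklearn model selection.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .catalog import CuratedCatalog, resolve_gene
from .model import Cassette, Corpus, DataError, GeneRecord, GenomeAnnotation

BASE_FEATURES = ("d_i", "conservation", "phylo_distance", "length_ratio")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class FeatureConfig:
    """Tunables of the pair feature model (distances in nt)."""

    d_i_min: int = -50
    d_i_max: int = 250
    upstream_window: int = 100
    motifs: list[str] = field(default_factory=list)
    pseudocount: float = 1.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.d_i_min >= self.d_i_max:
            raise DataError("d_i_min must be < d_i_max")
        if self.upstream_window < 1:
            raise DataError("upstream_window must be >= 1")

    @property
    def feature_order(self) -> list[str]:
        return list(BASE_FEATURES) + [f"motif_{m}" for m in self.motifs]


@dataclass
class AdjacentPairFeatures:
    d_i: int
    conservation: float
    phylo_distance: float
    length_ratio: float
    motif_freqs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label: str = "unknown"  # operon_pair | boundary_pair | unknown

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.d_i, self.conservation, self.phylo_distance, self.length_ratio],
                np.asarray(self.motif_freqs, dtype=float),
            ]
        )


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """``D_I = downstream_start - (upstream_end + 1)``; negative on overlap."""
    if upstream.genome_id != downstream.genome_id:
        raise DataError(
            f"intergenic distance across genomes: {upstream.genome_id} vs "
            f"{downstream.genome_id}"
        )
    return downstream.start - (upstream.end + 1)


def within_cutoffs(d_i: int, config: FeatureConfig = FeatureConfig()) -> bool:
    return config.d_i_min <= d_i <= config.d_i_max


def phylogenetic_profile(
    canonical_gene: str, corpus: Corpus, catalog: CuratedCatalog
) -> np.ndarray:
    """Presence/absence bit vector of a gene over sorted genome ids."""
    present = _presence_map(corpus, catalog)
    return np.array(
        [1 if canonical_gene in present[gid] else 0 for gid in corpus.genome_ids],
        dtype=np.int8,
    )


def _presence_map(corpus: Corpus, catalog: CuratedCatalog) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gid in corpus.genome_ids:
        genes: set[str] = set()
        for g in corpus.genomes[gid].genes:
            res = resolve_gene(g, catalog)
            if res is not None:
                genes.add(res[0])
        out[gid] = genes
    return out


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def profile_distance(
    p1: np.ndarray, p2: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> float:
    """Phylogenetic-profile distance: normalized Hamming distance divided by
    the mean binary Shannon entropy of the two profiles (plus epsilon).

    Identical profiles give 0; dissimilar, information-rich profiles give
    values near 1.  Smaller = more functionally related.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape or p1.size == 0:
        raise DataError("profiles must be equal-length and non-empty")
    h = float(np.mean(p1 != p2))
    if h == 0.0:
        return 0.0
    entropy = (_binary_entropy(float(p1.mean())) + _binary_entropy(float(p2.mean()))) / 2
    return h / (config.epsilon + entropy)


def neighborhood_conservation(
    gene_a: str,
    gene_b: str,
    corpus: Corpus,
    catalog: CuratedCatalog,
) -> float:
    """Laplace-smoothed negative log-likelihood of adjacency:
    ``s = -ln((n_adj + 1) / (n_both + 2))`` where ``n_adj`` counts genomes in
    which the two genes are adjacent within one cassette and ``n_both``
    genomes containing both.  Strictly decreasing in ``n_adj``."""
    present = _presence_map(corpus, catalog)
    n_both = 0
    n_adj = 0
    for gid in corpus.genome_ids:
        if gene_a not in present[gid] or gene_b not in present[gid]:
            continue
        n_both += 1
        if _adjacent_in_any_cassette(gene_a, gene_b, corpus.cassettes.get(gid, []), catalog):
            n_adj += 1
    return conservation_from_counts(n_adj, n_both)


def conservation_from_counts(n_adj: int, n_both: int) -> float:
    if not 0 <= n_adj <= n_both:
        raise DataError(f"need 0 <= n_adj <= n_both, got {n_adj}, {n_both}")
    return -math.log((n_adj + 1) / (n_both + 2))


def _resolved_sequence(cassette: Cassette, catalog: CuratedCatalog) -> list[str]:
    out = []
    for g in cassette.genes:
        res = resolve_gene(g, catalog)
        out.append(res[0] if res is not None else "")
    return out


def _adjacent_in_any_cassette(
    gene_a: str, gene_b: str, cassettes: list[Cassette], catalog: CuratedCatalog
) -> bool:
    for cas in cassettes:
        seq = _resolved_sequence(cas, catalog)
        for x, y in zip(seq, seq[1:]):
            if {x, y} == {gene_a, gene_b}:
                return True
    return False


def length_ratio_score(upstream: GeneRecord, downstream: GeneRecord) -> float:
    """Natural log of the upstream/downstream gene length ratio."""
    return math.log(upstream.length / downstream.length)


def _motif_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[c] for c in motif.upper())
    except KeyError as exc:
        raise DataError(f"motif {motif!r}: invalid IUPAC symbol {exc}") from None
    return re.compile(f"(?={body})")  # lookahead => overlapping matches counted


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def motif_frequencies(
    genome: GenomeAnnotation,
    downstream: GeneRecord,
    config: FeatureConfig,
) -> tuple[np.ndarray, bool]:
    """Normalized motif counts in the window upstream of the translational
    start of ``downstream``, on the coding strand.

    Returns ``(vector, truncated)``; the window is truncated (flagged) at
    contig edges.  Each count is normalized by the number of possible motif
    placements in the window, so entries lie in [0, 1].
    """
    if genome.sequence is None:
        raise DataError(f"{genome.genome_id}: motif features require a sequence")
    w = config.upstream_window
    seq = genome.sequence
    if downstream.strand == "+":
        lo = max(0, downstream.start - 1 - w)
        window = seq[lo : downstream.start - 1].upper()
        truncated = downstream.start - 1 - lo < w
    else:
        hi = min(len(seq), downstream.end + w)
        window = reverse_complement(seq[downstream.end : hi])
        truncated = hi - downstream.end < w
    freqs = np.zeros(len(config.motifs))
    for i, motif in enumerate(config.motifs):
        placements = len(window) - len(motif) + 1
        if placements <= 0:
            continue
        freqs[i] = len(_motif_regex(motif).findall(window)) / placements
    return freqs, truncated


def pair_features(
    upstream: GeneRecord,
    downstream: GeneRecord,
    config: FeatureConfig,
    genome: GenomeAnnotation | None = None,
    corpus: Corpus | None = None,
    catalog: CuratedCatalog | None = None,
    profiles: dict[str, np.ndarray] | None = None,
    label: str = "unknown",
) -> AdjacentPairFeatures:
    """Compute the full feature set for one adjacent pair.

    Corpus-level features (conservation, profile distance) require a corpus
    and catalog; they default to 0 when those are unavailable (single-genome
    prediction), which the standardization step absorbs.
    """
    conservation = 0.0
    phylo = 0.0
    if corpus is not None and catalog is not None:
        ra = resolve_gene(upstream, catalog)
        rb = resolve_gene(downstream, catalog)
        if ra is not None and rb is not None:
            conservation = neighborhood_conservation(ra[0], rb[0], corpus, catalog)
            if profiles is not None:
                pa, pb = profiles.get(ra[0]), profiles.get(rb[0])
            else:
                pa = phylogenetic_profile(ra[0], corpus, catalog)
                pb = phylogenetic_profile(rb[0], corpus, catalog)
            if pa is not None and pb is not None:
                phylo = profile_distance(pa, pb, config)
    if config.motifs and genome is not None and genome.sequence is not None:
        motif_vec, _ = motif_frequencies(genome, downstream, config)
    else:
        motif_vec = np.zeros(len(config.motifs))
    return AdjacentPairFeatures(
        d_i=intergenic_distance(upstream, downstream),
        conservation=conservation,
        phylo_distance=phylo,
        length_ratio=length_ratio_score(upstream, downstream),
        motif_freqs=motif_vec,
        label=label,
    )


class OperonPairClassifier(BaseEstimator, ClassifierMixin):
    """Standardized logistic regression over adjacent-pair features.

    Follows the scikit-learn estimator contract: :meth:`fit` on an
    ``(n_pairs, n_features)`` matrix with binary labels (1 = same operon),
    then :meth:`predict_proba`/:meth:`predict`.  Feature means and scales
    are stored with the model so serialized classifiers reproduce
    predictions exactly.
    """

    def __init__(
        self,
        feature_order: Sequence[str] = BASE_FEATURES,
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.feature_order = feature_order
        self.C = C
        self.random_state = random_state

    def fit(self, X, y) -> "OperonPairClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != len(self.feature_order):
            raise DataError(
                f"X must be (n, {len(self.feature_order)}); got {X.shape}"
            )
        if len(np.unique(y)) < 2:
            raise DataError("training data must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        self.lr_ = LogisticRegression(
            C=self.C, random_state=self.random_state, max_iter=1000
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.lr_.classes_
        self.means_ = self.scaler_.mean_
        self.scales_ = self.scaler_.scale_
        self.weights_ = self.lr_.coef_[0]
        self.intercept_ = float(self.lr_.intercept_[0])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "lr_")
        return self.lr_.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "lr_")
        return self.lr_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def operon_probability(self, X) -> np.ndarray:
        """Probability of the positive (same-operon) class."""
        proba = self.predict_proba(X)
        pos = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos]

    def to_tsv(self, dest: TextIO) -> None:
        check_is_fitted(self, "lr_")
        dest.write("feature\tmean\tscale\tweight\n")
        for name, m, s, w in zip(self.feature_order, self.means_, self.scales_, self.weights_):
            dest.write(f"{name}\t{float(m)!r}\t{float(s)!r}\t{float(w)!r}\n")
        dest.write(f"__intercept__\t0.0\t1.0\t{float(self.intercept_)!r}\n")

    @classmethod
    def from_tsv(cls, source: TextIO) -> "OperonPairClassifier":
        header = source.readline()
        if not header.startswith("feature"):
            raise DataError("classifier TSV: missing header")
        names, means, scales, weights = [], [], [], []
        intercept = 0.0
        for line in source:
            name, m, s, w = line.rstrip("\n").split("\t")
            if name == "__intercept__":
                intercept = float(w)
            else:
                names.append(name)
                means.append(float(m))
                scales.append(float(s))
                weights.append(float(w))
        clf = cls(feature_order=names)
        clf.scaler_ = StandardScaler()
        clf.scaler_.mean_ = np.array(means)
        clf.scaler_.scale_ = np.array(scales)
        clf.scaler_.var_ = clf.scaler_.scale_ ** 2
        clf.scaler_.n_features_in_ = len(names)
        clf.lr_ = LogisticRegression()
        clf.lr_.classes_ = np.array([0, 1])
        clf.lr_.coef_ = np.array([weights])
        clf.lr_.intercept_ = np.array([intercept])
        clf.lr_.n_features_in_ = len(names)
        clf.classes_ = clf.lr_.classes_
        clf.means_ = clf.scaler_.mean_
        clf.scales_ = clf.scaler_.scale_
        clf.weights_ = np.array(weights)
        clf.intercept_ = intercept
        return clf


def train_pair_classifier(
    pairs: list[AdjacentPairFeatures],
    seed: int = 0,
    config: FeatureConfig = FeatureConfig(),
) -> OperonPairClassifier:
    """Fit the logistic pair model on labeled pairs (deterministic given
    seed and data)."""
    labeled = [p for p in pairs if p.label in ("operon_pair", "boundary_pair")]
    if not labeled:
        raise DataError("no labeled pairs")
    X = np.vstack([p.to_vector() for p in labeled])
    y = np.array([1 if p.label == "operon_pair" else 0 for p in labeled])
    clf = OperonPairClassifier(feature_order=config.feature_order, random_state=seed)
    return clf.fit(X, y)


def predict_operons(
    genome: GenomeAnnotation,
    classifier: OperonPairClassifier,
    config: FeatureConfig = FeatureConfig(),
    threshold: float = 0.5,
    corpus: Corpus | None = None,
    catalog: CuratedCatalog | None = None,
) -> list[Cassette]:
    """Chain predicted in-operon adjacent pairs into cassettes.

    Adjacent same-strand pairs with operon probability above ``threshold``
    AND intergenic distance within the cutoffs are linked; maximal chains
    become cassettes and unlinked genes become single-gene cassettes.  The
    output partitions the gene list.
    """
    genes = sorted(genome.genes, key=lambda g: (g.start, g.end))
    cassettes: list[Cassette] = []
    current: list[GeneRecord] = []

    profiles: dict[str, np.ndarray] | None = None
    if corpus is not None and catalog is not None:
        profiles = {
            g: phylogenetic_profile(g, corpus, catalog) for g in catalog.canonical_genes
        }

    def flush() -> None:
        if current:
            cid = f"{genome.genome_id}_pred{len(cassettes) + 1:05d}"
            cassettes.append(
                Cassette(genome_id=genome.genome_id, cassette_id=cid, genes=list(current))
            )
            current.clear()

    if not genes:
        return []
    current.append(genes[0])
    for up, down in zip(genes, genes[1:]):
        linked = False
        if up.strand == down.strand:
            feats = pair_features(
                up, down, config, genome=genome, corpus=corpus,
                catalog=catalog, profiles=profiles,
            )
            if within_cutoffs(feats.d_i, config):
                prob = float(classifier.operon_probability(feats.to_vector()[None, :])[0])
                linked = prob > threshold
        if not linked:
            flush()
        current.append(down)
    flush()
    return cassettes
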