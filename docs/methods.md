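# Methods

This note documents the models, parameter choices and limitations of
`cassettemine` in the package's own terms: what each stage computes, which
knobs matter, what the synthetic corpus does and does not emulate, and
where genuinely open design choices were settled.

## Units and conventions

Coordinates are 1-based inclusive nucleotides (GenBank/GFF3 convention).
Gene order within a cassette is ascending start coordinate, regardless of
strand; "upstream/downstream" in all pair features means coordinate order,
with one exception — the motif window is strand-aware because it anchors on
the *translational start site* of the downstream gene. A genome is the unit
of analysis; multi-replicon organisms are expected to be concatenated under
one `genome_id` by the caller.

## Curated catalog and resolution

The catalog maps canonical gene names to a binary role (transcription or
translation machinery), with synonyms, product keywords and COG ids as
alternative evidence routes. The shipped seed covers the high-frequency
coupling genes (RNA polymerase subunits, NusA/NusG/Mfd, ribosomal proteins,
IF-1/IF-2, SecE/SecY, RimP with synonym *yhbC*, YlxR); it is a documented,
extensible seed, not an exhaustive gene inventory. Dual-role coupling
factors (NusA, NusG) are filed under transcription: a cassette mixing them
with ribosomal genes is classified *both* by composition, which is the
property of interest, so no per-gene dual label is needed.

Resolution is case-insensitive and tiered: exact canonical name, then
synonym, then COG id, then keyword substring of the product. Within the
keyword tier the **longest matched keyword wins** before ambiguity is
declared; plain substring matching would let "50S ribosomal protein L1"
shadow the L11/L15/L17/L18 products, which is a lexical artifact rather
than real ambiguity. Remaining multi-entry ties resolve to no-match (with
a logged warning) rather than a guess. Resolution is deterministic and
independent of catalog row order.

## Cassette categories and ranking

Each cassette is assigned exactly one of four categories from the resolved
roles of its genes (transcription-only / translation-only / both / none);
the four tallies partition the corpus cassette count. Genomes owning at
least one *both* cassette form the denominator of all downstream ranking.

Frequency tables count **genome-level presence**: a key (canonical gene,
lower-cased product string, or verbatim COG id) counts once per genome if
it occurs in at least one cassette of the configured category. Top lists
keep keys with count strictly greater than `min_genomes` (default 300 —
the strict reading of a ">300 genomes" cutoff), sorted by count descending
with lexicographic tie-breaks (ties need a rule; alphabetical is auditable).
The consensus set keeps genes appearing in at least `min_rankings`
(default 2) of the three canonicalized axis lists, after synonym
unification; it is monotone in `min_rankings` by construction. Function
keys are exact lower-cased product strings — no fuzzy matching — so counts
remain auditable.

## Linkage network

Three evidence channels are computed corpus-internally as fractions over
the genomes containing both genes of a pair:

* **fusion** — a single hybrid locus resolving to both genes, or adjacency
  within a cassette with no intergenic sequence (D_I ≤ 0);
* **neighborhood** — consecutive membership in one cassette;
* **co-occurrence** — joint membership in one cassette, intervening genes
  allowed.

On single-copy corpora these nest: fusion ≤ neighborhood ≤ co-occurrence.
An edge is *confident* in a channel iff its score is **strictly** greater
than the threshold (default 0.7). The threshold is applied per channel;
the combined score (default max over channels, mean available) is used
only for the k = 2 clustering. Candidate cassettes are connected
components (size ≥ 2) of confident edges per channel, with genome counts
delegated to the matching rules below.

The bipartition minimizes within-cluster sum of squares over rows of the
combined-score matrix. Instances up to 15 nodes are solved exactly by
enumerating all 2-partitions (the consensus gene set is small, so the
exact solver is the common path and is provably optimal); larger instances
fall back to restarted k-means seeded for determinism. Equal objectives
resolve to the first partition in enumeration order with the
lexicographically smallest gene fixed to cluster one.

## Cassette matching and counting

A query is an ordered, duplicate-free gene tuple (size ≥ 2). Matching
operates on canonical gene sets after synonym resolution; unresolved genes
in an observed cassette are transparent and duplicate canonicals collapse
to a set. Rules: *exact* (equal set, observed coordinate order equals the
query's written order), *reordered* (equal set, any other order — a
reversed cassette is "a different order" and counts here), *subset*
(query strictly inside a larger cassette). A genome counts once however
many of its cassettes match; the reported per-genome rule is the strongest
present (exact > reordered > subset) — a reporting convention only, counts
are rule-agnostic. Partner discovery reports non-query genes present in
matching cassettes in more than `min_fraction` (default 0.5) of matched
genomes; the independence fraction is the share of matched genomes where
the cassette occurs with no extra genes.

## Operon-pair model

For corpora lacking operon tables, adjacent same-strand pairs are
classified in/not-in the same operon by standardized logistic regression
over five feature groups. Only the intergenic distance is fully forced by
its definition (`D_I = downstream_start − (upstream_end + 1)`, cutoffs
−50 and 250 nt); the remaining features needed concrete formulas, chosen
here and exposed in `FeatureConfig`:

* **neighborhood conservation** `s = −ln((n_adj + 1) / (n_both + 2))` —
  a Laplace-smoothed negative log-likelihood of adjacency, strictly
  decreasing in `n_adj`, finite at `n_both = 0`;
* **profile distance** `d = h / (ε + (H(p₁) + H(p₂)) / 2)` with `h` the
  normalized Hamming distance between presence/absence profiles and `H`
  the binary Shannon entropy (bits) of a profile's mean presence — zero
  for identical profiles, ≈1 for complementary half-frequency profiles;
* **length ratio** `ln(L_up / L_down)`;
* **motif frequencies** — overlap-counted IUPAC motif occurrences in the
  100 nt window 5′ of the downstream gene's translational start on the
  coding strand, each normalized by the number of possible placements
  (window − motif + 1), so entries lie in [0, 1]; windows truncated at
  contig edges are flagged.

Features are z-scored before the fit and the standardization is stored
with the model (plain-TSV serialization reproduces predictions exactly).
Pairs with predicted operon probability > 0.5 **and** D_I within the
cutoffs are chained; maximal chains become cassettes, singletons included,
so the output partitions the gene list. The 0.5 threshold and the
standardization are artifact conventions, configurable. The corpus-level
features default to 0 for single-genome prediction; the decision-tree
variant of operon prediction and motif discovery are out of scope (the
motif list is an input).

## Enrichment

The over-representation p-value is the hypergeometric upper tail computed
in log-space via `gammaln`; it agrees with exhaustive draw enumeration to
1e−12 for small universes and with `scipy.stats.hypergeom.sf` generally.
BH adjustment is the step-up procedure `q₍ᵢ₎ = min(1, min_{j≥i} p₍ⱼ₎·m/j)`
returned in input order; "α ≤ 0.05" is read inclusively. The background
universe defaults to the catalog genes observed in the corpus and is
configurable; term→gene maps are plain inputs, never fetched, and no
ontology-graph propagation is attempted.

## Synthetic corpus

The simulator emits the exact dialects the readers consume, plus a
manifest recording every planted truth; a verifier re-derives each claim
from the emitted corpus. Study conditions (defaults): 200 genomes of
60–100 genes in 1–5-gene operons; operon-internal gaps ~ N(20, 15) nt
truncated to [−50, 250]; boundary gaps ~ N(300, 80) nt truncated to
≥ 251 nt so the cutoff band separates the classes (artifact defaults
chosen to respect the −50/250 band, not measured values); decoy pool of
200 unresolvable genes; 10% synonym usage; no annotation dropout; genus
proportions realized exactly by largest-remainder apportionment with a
fixed genus→phylum/label table. Planted cassettes occupy genome slots
sampled without replacement per query: exact plants in written order,
reordered plants under a non-identity permutation, subset plants embedded
with 1–3 partner genes from a configured pool (which is what makes
partner discovery testable). Gene lengths ~ N(900, 300) clipped to
[150, 3000] nt.

What passing tests therefore show: the machinery — resolution, category
partition, counting rules, linkage fractions, rankings — is correct on
corpora whose statistical structure matches these assumptions. What they
do not show: robustness to real annotation noise (inconsistent product
strings, split/merged loci, paralogs, multi-replicon assemblies,
horizontally transferred duplicates), to operon-caller errors, or to real
taxonomic correlation structure; simulated genomes carry no compositional
realism (GC content, codon usage). Published genome tallies from any
particular operon-database snapshot are inherently snapshot-dependent and
are not reproduction targets.

## Numerical and degenerate-input choices

All fractions are exact rational arithmetic in floating point (no
iterative estimation), so equality assertions against planted truths are
legitimate. Empty corpora yield empty tables with denominator 0; a query
with no matches reports an undefined independence fraction as a no-value;
conservation at `n_both = 0` returns −ln(1/2) by smoothing rather than an
error. The pipeline excludes the output directory from its configuration
hash so identical analyses stamp identical hashes wherever they are
written; rerunning with one seed is byte-identical end to end.

## Known limitations

* The catalog seed is small by design; corpus genes outside it are
  invisible to ranking and linkage (decoys by construction in synthetic
  corpora, potentially real genes in user corpora).
* Keyword resolution is substring-based; products phrased differently from
  the catalog keywords fall through to no-match.
* Channel nesting can break on corpora with multi-copy genes (a fused
  paralog pair elsewhere in the genome), which is why the invariant is
  stated for single-copy corpora.
* The k-means fallback above 15 nodes is a heuristic; only the exact
  enumeration path carries an optimality guarantee.
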