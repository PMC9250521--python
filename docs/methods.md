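# Methods

## The natural-vector representation

A CDS `S = s_1 … s_N` over {A, C, G, T} is summarised per nucleotide `k` by

* the count `n_k`,
* the mean 1-based position `mu_k = (Σ_i i·[s_i = k]) / n_k`,
* the second normalized central moment
  `D2_k = Σ_i (i − mu_k)²·[s_i = k] / (n_k · N)`,

giving the classic 12-dimensional natural vector
`(n_A, n_C, n_G, n_T, mu_A, …, D2_T)`.  The NVDT extension appends the 16
overlapping dinucleotide counts and the 64 overlapping trinucleotide
counts (lexicographic, A < C < G < T), for 92 features per sequence.  The
trinucleotide block makes the vector sensitive to codon-scale
composition, the biological signal (codon-usage bias) that motivates
using gene rather than protein sequence.  Variants NV (12), NVD (28),
NVT (76) and NVDT (92) are selectable everywhere for ablation.

Conventions that the defining sums leave open:

* positions are 1-based, so `mu("ACGT") = (1, 2, 3, 4)`;
* an absent nucleotide contributes `mu_k = D2_k = 0` rather than dropping
  entries — the vector stays fixed-length and finite;
* k-mer features are raw counts, not frequencies (`--kmer-normalize`
  divides by the window count `N − k + 1` for sensitivity analysis;
  downstream Z-scoring removes the scale either way);
* higher central moments (j ≥ 3) are deliberately not computed: the
  second moment is known to be sufficient for stable classification in
  this representation and higher moments add noise-dominated dimensions.

Non-ACGT characters (admitted only under the `mask` validation policy)
match no nucleotide: they count toward `N` but toward no `n_k`, and any
k-mer window touching one is skipped.  The count-conservation identities
(`Σ n_k = N`, `Σ dinuc = N − 1`, `Σ trinuc = N − 2`) therefore hold
exactly only for pure-ACGT sequences; published-style runs should use
`strict` or `drop`.

## Pair encoding and standardization

Two per-protein vectors A, B combine under five schemes: `Cod1 = |A−B|`,
`Cod2 = A+B`, `Cod3 = (|A−B|, A+B)`, `Cod4 = A∘B`, `Cod5 = (A, B)`
(default).  Cod5 is order-sensitive, so pairs are canonicalised to
lexicographic id order before encoding; an optional training-only
augmentation adds both orders.  Order-invariance of the trained
classifier is an empirical property checked by tests, not a theorem for
RBF kernels.

Pair features are Z-scored with training-set statistics only:
`d' = (d − μ)/σ` with the population (1/n) standard deviation.  σ = 0
columns (possible for rare k-mers in small sets) transform to 0 and are
flagged.  Test matrices are always transformed with the fitted training
state — the leakage guard is asserted by instrumented tests.

## Classifiers and evaluation

* SVM: RBF kernel; `c ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}` and
  `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` searched by stratified 3-fold
  cross-validated accuracy (the classic LIBSVM-style grid; the original
  grid ranges are not published, so these are this package's defaults).
* RF: tree count searched over {50, 100, 150, 200}; √d feature sampling;
  minimum leaf 1.

Deployed predictions threshold a positive-class probability at 0.5 (ties
to positive).  For the SVM the probability is Platt-calibrated
(`CalibratedClassifierCV`, single sigmoid on cross-validated decision
values).  One numerical subtlety drove the selection design: grid corners
with tiny `c` and large `γ` can reach perfect inner-CV accuracy through
margins of order 1e-22 — the raw decision sign classifies, but any
squashed score collapses to a constant in float64 and calibration
degenerates.  Tied grid winners are therefore tried in rank order and the
first whose calibrated training accuracy backs up its cross-validated
score is kept; if none of the top ten does, the top-ranked calibrated
model is used.  The whole procedure is deterministic given the seed.

Metrics: accuracy, precision, sensitivity, specificity, MCC and F1 from
the confusion counts, plus trapezoidal ROC AUC.  Zero-denominator ratios
report 0 with a flag (stable CSV output).  k-fold results are reported as
mean ± sample (n−1) standard deviation across folds.

## Dataset construction

Mirrors standard interaction-corpus practice: CDS under 3×50 nt (50
amino acids) are removed; an optional greedy redundancy filter drops
sequences over 40% identity to an already-kept one.  The identity
function is pluggable — the built-in default (global alignment, match 1,
mismatch 0, no gap penalty, identities/alignment-length) is an explicit
stand-in suitable for small inputs; production users should inject a
CD-HIT-style callback.  Negatives are sampled uniformly without
replacement from non-positive unordered pairs (self-pairs excluded),
balanced 1:1 with positives by default, optionally restricted to pairs
annotated to disjoint subcellular compartments.  The labeled set splits
5:1 (test fraction 1/6, rounded, stratified by default, at least one
test pair per class).  k-fold partitioning is a seeded shuffle with
round-robin assignment using a running counter across classes, which
bounds overall fold-size differences by one even when every class count
has a remainder (per-class stratified splitters only bound the per-class
difference).

## The synthetic benchmark

The generator is a validation construct, not a biological simulator.  It
plants exactly the signal the trinucleotide block measures: latent
codon-usage profiles drawn from a symmetric Dirichlet over the 64 codons
(concentration 0.5 — distinctly biased profiles, qualitatively like real
codon-usage tables), and sequences sampled codon-by-codon from
`effect·profile + (1−effect)·uniform`.  Interacting pairs share one
profile; non-interacting pairs draw two **distinct** profiles.  A
literal independent draw would let negatives collide on a profile with
probability 1/n_profiles, capping attainable accuracy at 75% for two
profiles — incompatible with a "full-strength" planted signal, so
distinctness is part of the design.  At `effect = 0` both classes are
exchangeable regardless.  Sequences start with ATG and contain no
in-frame stop (stop probability reassigned to the other codons).
Defaults: 300 pairs per class, 900 nt (300 codons), effect 1, two
profiles.

What passing tests show — and do not show: recovery of the planted
signal demonstrates that the feature math, encoding, standardization and
model selection compose correctly end-to-end, with a null control
(effect 0 → AUC ≈ 0.5) and a monotone dose-response in `effect`.  Real
interactomes carry homology structure, length variation, compositional
confounders and label noise that the generator deliberately omits, so
synthetic accuracy says nothing quantitative about accuracy on curated
corpora.

Under Cod5 the synthetic task is XOR-like (positives are
(p₀,p₀)/(p₁,p₁), negatives (p₀,p₁)), which RBF-SVMs solve reliably at
the default scale but only marginally below roughly 100 pairs per class
at 300 nt — small-sample runs may sit near chance without indicating a
defect.

## Network prediction

Candidate networks are undirected graphs with role-annotated nodes
(`core`/`satellite`, taken from input annotation, never inferred).
Edge prediction is pointwise application of the trained classifier to
each edge's encoded pair; per-network accuracy is correct/total.
`augment_and_retrain` moves a seeded uniform fraction of each core
protein's edges — with their curated labels — into the training set and
re-scores the remainder, emulating incremental experimental evidence;
moved edges never re-enter the evaluated set.  Graphs export to Pajek
`.net` (1-based contiguous vertices; an edge value of 1/2/0 encodes
correct/false/unscored).  To avoid leakage, network edges are never
implicitly added to training — callers supply explicit train and
evaluate manifests.

## Problem sizes used by the shipped checks

The acceptance script and end-to-end tests run the generator at its
defaults (300 pairs/class, 900 nt) for the strong-signal and null-signal
checks, and at 100 pairs/class, 450 nt with 3-fold CV for the
five-point effect sweep — sizes chosen as the smallest at which the
Cod5 task is comfortably inside the reliable regime described above.

## Known limitations

* The default pairwise-identity function is a naive stand-in; the
  redundancy filter's greedy order-dependence is intentional and
  documented.
* Calibrated probabilities are only as good as the inner CV allows; on
  very small training sets (tens of pairs) calibration can be
  uninformative even when the underlying margin classifies.
* No reading-frame or start/stop validation is enforced on real input
  beyond a length-multiple-of-3 warning.
* Cross-species transfer is supported only as generic
  train-on-one/predict-on-another plumbing.
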