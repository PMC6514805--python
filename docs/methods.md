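# Methods

## Model overview

`acpmeta` classifies peptides (5–50 standard residues) as anticancer (ACP) or
not by stacking: seven encoding-specific RBF-SVM base models each emit a
calibrated probability, and a second-level RBF-SVM over those seven
probabilities makes the final call. The design assumption is that the
descriptors capture complementary views of the sequence — bulk composition
(AAC, DPC), sequence order (QSO, CTF), terminal position-specific residues
(NC5), and physicochemical profiles (AAIF, CTD) — so a low-dimensional
probability-space combiner can outperform any single view without the
dimensionality cost of concatenating raw features.

## Descriptors and embedded tables

Canonical residue order is alphabetical (`ACDEFGHIKLMNPQRSTVWY`) everywhere;
every encoder is a pure function with a fixed output dimension.

**QSO (100-dim).** Two 20×20 distance matrices, each contributing 20
composition terms and `nlag = 30` coupling terms with weight `w = 0.1`:
`x_a = f_a / (1 + w Σ τ_d)` and `x_{20+d} = w τ_d / (1 + w Σ τ_d)`, with
`τ_d = Σ_i d(r_i, r_{i+d})²` and `τ_d ≡ 0` for lags reaching past the
sequence, so peptides as short as 5 residues are encodable. The 2 × (20+30)
layout is the only parameterization consistent with the 100-dimension
contract. One matrix is the Grantham chemical distance, rebuilt exactly from
its defining side-chain properties (composition, polarity, volume;
α = 1.833, β = 0.1018, γ = 0.000399, mean over pairs normalized to 100, then
rescaled to [0,1]). The second is a *synthetic* Schneider–Wrede-like matrix:
the published matrix is not redistributable here, so a surrogate with the same
role is derived from standardized Kyte–Doolittle hydropathy, Hopp–Woods
hydrophilicity and residue mass (Euclidean distance, rescaled to [0,1]). It
preserves symmetry, the zero diagonal and a chemically sensible neighbourhood
structure; coupling terms computed from it are therefore physicochemically
meaningful but not numerically identical to Schneider–Wrede-based ones.

**CTF (343-dim).** The Shen et al. seven classes by dipole/side-chain volume
({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}); raw ordered
class-triad counts (they sum to L−2) are min–max normalized over the 343
cells; a degenerate all-equal count vector maps to all zeros.

**NC5 (200-dim).** One-hot blocks for N-terminal positions 1–5 then
C-terminal positions L−4…L. For 5 ≤ L < 10 the windows deliberately overlap.

**AAIF (160-dim).** Eight curated AAindex scales (LIFS790101, CEDJ970104,
MIYS990104, NAKH920108, TSAJ990101, MAXF760101, BIOV880101, BLAM930101),
embedded as packaged constants. The per-feature definition — standardized
scale value × residue frequency — is one defensible reading of a
"scale × residue" profile; positional averaging was the alternative and was
rejected because it collapses the 160-dimension contract to 8. Each scale is
standardized across the 20 residues before weighting, so the absolute units
(and any last-digit transcription noise in the embedded constants) do not
affect the feature geometry.

**CTD (147-dim).** Seven three-class partitions (hydrophobicity, van der
Waals volume, polarity, polarizability, charge, secondary structure, solvent
accessibility; Dubchak convention). Composition is the class fraction;
transition counts unordered adjacent class pairs (1↔2, 1↔3, 2↔3) over L−1;
distribution reports the position (percent of L) of the 1st, 25th-, 50th-,
75th-percentile and last occurrence per class, with ceiling occurrence
indices and five zeros for an absent class, so values are 0 or in (0, 100].

Minimum-length violations (DPC < 2, CTF < 3, NC5 < 5, CTD < 2) raise errors
rather than zero-padding; the dataset rule L ≥ 5 makes them unreachable in
normal use. A checksum over all tables is recorded with every trained model
and verified at load time.

## Feature selection

F-scores follow the Chen & Lin ratio of between-class to within-class
scatter. Constant features score 0; a feature with zero pooled within-class
variance but distinct class means separates the classes perfectly and is
ranked ahead of all finite scores (a large finite sentinel keeps sorting
well-defined). Ties keep original column order (stable sort).

The forward search is prefix-only — features enter strictly in ranked order,
no floating or backtracking — and scores each prefix by mean stratified
k-fold CV accuracy of an RBF-SVM held at C = 1, γ = 1/m (re-tuning the grid
at every prefix is supported in principle by re-running the search with tuned
parameters, but the default keeps the search O(D) SVM fits per fold). The
shortest prefix attaining the maximum accuracy wins (parsimony tie-break).
Fold assignment is stratified and derived from a required seed, so the trace
is exactly reproducible.

## SVM training

The tuning grid interprets the canonical search space multiplicatively:
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} (exponent step 2, 11 values) and γ ∈ {2⁻¹⁵, …, 2¹⁵}
(exponent step 1, 31 values). All 341 pairs are scored on identical folds;
ties resolve to the smaller C then smaller γ, making the result independent
of enumeration order. Features are standardized to zero mean/unit variance
inside the training pipeline, so CV folds and held-out data are transformed
with training-fold statistics only.

Probabilities come from Platt sigmoid calibration fitted on an internal
unshuffled 5-fold split (`CalibratedClassifierCV(..., ensemble=False)`), the
same construction scikit-learn uses for probabilistic SVMs; nothing in the
pipeline is stochastic, so a fixed fold seed makes training bit-reproducible.

Repeated cross-validation re-partitions the data per repeat (fold seed =
base seed + repeat index) under one set of hyperparameters, pools each
repeat's held-out predictions, and reports SN/SP/ACC/MCC/AUC mean ± SD.

## Stacking

Meta-training features are produced out-of-fold: per CV fold, a clone of each
base pipeline (fixed selected features and hyperparameters) is refitted on
the fold-training rows and scores the held-out rows, so no training peptide
is scored by a base model that saw it. An in-fold variant
(`out_of_fold=False`) exists for comparison; with strong signal the two are
near-indistinguishable, with weak signal the in-fold variant optimistically
compresses base probabilities toward the labels. The meta grid search
defaults to a coarse 4×4 sub-grid — the meta space is only 7-dimensional and
flat around its optimum, so the full 341-point grid buys nothing. The
decision rule is probability ≥ 0.5 (boundary counted positive, configurable).

## Evaluation

ACC is `(TP+TN)/total` — the universally used form; MCC uses the standard
product-of-margins denominator and is reported as *undefined* (with a
warning), never silently zeroed, when a margin vanishes. The AUC is the
empirical Mann–Whitney area with half-credit ties (verified against all-pairs
counting). Correlated AUCs on one test set are compared with DeLong's
nonparametric two-tailed test (structural components from midranks, normal
approximation); Hanley–McNeil was the alternative and DeLong was preferred as
the standard for paired empirical ROC curves. Degenerate zero-variance
comparisons return p = 1 for equal AUCs, and p is clamped to (0, 1].

## Redundancy filtering

Dataset assembly supports a greedy longest-first clustering at a global
alignment identity threshold (identity = matched positions / shorter length).
This approximates CD-HIT's behaviour but not its word-filter heuristics or
exact cluster membership; visiting order ties keep input order. It is meant
for fixture construction and modest datasets, not for CD-HIT-scale corpora.

## Synthetic data

The generator emulates balanced two-class benchmarks: residues drawn i.i.d.
from `(1−effect)·uniform + effect·bias` (positives) and the alphabet-reversed
bias (negatives), lengths uniform on [5, 50]. The default bias enriches
K, R, L, F, W — the cationic/hydrophobic signature of membranolytic ACPs —
and the reversed bias lands on small/neutral residues, so `effect` smoothly
interpolates between identical classes (effect = 0) and strongly divergent
compositions (effect = 1). An optional terminal-motif mode plants a fixed
3-mer at the N-terminus of positives, giving position-specific encoders
(NC5) signal that composition encoders cannot see.

What the generator does **not** emulate: positional autocorrelation,
secondary-structure propensity, homology clusters, length–class association,
or class imbalance. Passing tests therefore demonstrate correctness and
calibration of the machinery, not field performance on curated ACP
benchmarks.

## Verification problem sizes

The acceptance script and test suite exercise the pipeline at desk scale,
chosen as the package's own verification conditions: dimension contracts on
random valid peptides; oracle equivalence (F-score, MCC, AUC) on 1,000 random
instances each; forward-search parameter recovery with 5 informative features
(standardized class shift 1.0 — moderate and complementary, so each feature
contributes accuracy and the parsimony tie-break does not truncate the set)
among 95 noise features, 100 samples, 10 seeds; stacking dominance at the
benchmark training size (266 peptides per class, effect = 1, 100 per class
held out; base models at default hyperparameters on full feature sets — the
structural claim under test is the stacking inequality, not tuning); null
calibration at effect = 0 (train 100/100, test 150/150, 10 seeds; every base
model and the stack must stay within 0.5 ± 0.1); and byte-identical
prediction TSVs across two same-seed runs.

## Known limitations

- The synthetic-matrix surrogate for Schneider–Wrede means QSO values are not
  comparable across implementations that embed the published matrix.
- The embedded AAindex constants are transcribed package constants; AAIF
  standardization makes the features robust to last-digit deviations, but
  exact cross-implementation equality is not guaranteed.
- The greedy redundancy filter is O(n²) alignments and not CD-HIT-compatible.
- Probability calibration quality degrades below ~10 training peptides per
  class (the internal calibration split runs out of data).
- The full per-encoding grid search over 341 points with 10×10 CV is
  expensive by construction; the coarse grid and `select/tune` switches are
  the supported desk-scale path.
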