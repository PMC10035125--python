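# Methods

## Scope and model

`subloc` predicts the subcellular localization of an mRNA transcript from
its sequence alone. The multi-class problem is decomposed one-vs-rest
(OvR): for each location a binary classifier separates that location's
transcripts from a sample of all the others, and an unknown transcript is
assigned to `argmax` over the per-location scores. Scores are the
underlying model's positive-class probability; no cross-model calibration
is attempted, which is the usual caveat of OvR argmax assignment.

All encoders operate on the DNA alphabet. RNA input is accepted and U is
mapped to T during sanitization. Ambiguous IUPAC codes are kept at I/O
level; encoders skip any counting window that touches one (a `strict`
policy rejects such sequences outright). Coordinates are 0-based with
half-open windows.

## Feature encoders

**k-mer (1360).** For each k in {2, 3, 4, 5}, the count of each of the 4^k
words divided by the transcript length L, blocks concatenated in ascending
k with words in alphabetical order. The divisor is deliberately L, not the
window count L − k + 1, so each block sums to (L − k + 1)/L; this is the
descriptor's conventional printed form. k = 1 is available via the `ks`
parameter but excluded from the default battery, whose printed width
(16 + 64 + 256 + 1024) implies k ≥ 2.

**PseKNC (1370).** Type-I (parallel-correlation) pseudo k-tuple nucleotide
composition. Correlation factors θ_j (j = 1..λ) are the mean over positions
i of Θ(D_i, D_{i+j}), where D_i is the dinucleotide starting at i and Θ is
the mean squared difference of standardized property values between the two
dinucleotides. The frequency blocks (window-count normalized, per k) are
scaled by 1/(1 + w·Σθ) and the λ factors by w/(1 + w·Σθ), appended after
all k blocks, giving Σ4^k + λ = 1370 at the defaults k ∈ {2..5}, λ = 10.
The variant, weight and property set are conventions where the descriptor's
definition is underdetermined: type I, w = 0.1, and the six helical
parameters (Twist, Tilt, Roll, Shift, Slide, Rise), all configurable
through `PseKNCConfig`. With w = 0 the descriptor degenerates to plain
normalized frequencies, which the tests exploit.

**PseEIIP (64).** Component xyz = (EIIP_x + EIIP_y + EIIP_z) · f_xyz with
the EIIP nucleotide energies A 0.1260, C 0.1340, G 0.0806, T 0.1335 and
f the window-count-normalized trinucleotide frequency. The per-position
EIIP indicator sequence is exposed separately (`eiip_indicator`).

**DPCP (2368) / TPCP (768).** For every property p and word w (di- or
trinucleotide), component = value(p, w) · f_w, property-major, words
alphabetical. Frequencies are window-count normalized. Property values are
used raw by default (standardization is available upstream but the
descriptor's printed definition multiplies raw values), matching the
148 × 16 and 12 × 64 dimensions.

**Z-curve (48 + 144).** For each two-base prefix XY, with p(XYN) the
normalized trinucleotide frequency: x contrasts purines vs pyrimidines,
y amino vs keto, z weak vs strong hydrogen bonding. The identity
x + y + z = 4·p(XYA) − Σ_N p(XYN) and the bound |axis| ≤ Σ_N p(XYN) ≤ 1
hold exactly under window-count normalization and are asserted in tests.
The phase-specific variant repeats this per codon phase k ∈ {1, 2, 3}
(windows starting at positions ≡ k − 1 mod 3, counted from the first base
of the transcript — no reading-frame annotation is attempted), normalized
within phase. Minimum usable lengths follow from the window sizes: 5 nt
for the full battery (largest k-mer and one window per phase).

### Normalization split

Two normalizations coexist by design: the k-mer block divides by L (its
printed form), every other frequency divides by the valid-window count so
that frequencies of one word length sum to exactly 1 — which the Z-curve
bounds and the "normalized frequency" in the property-weighted descriptors
require. Encoders are pure and deterministic; identical input yields
bit-identical output.

## Property tables

The EIIP constants are code-level data. The di-/trinucleotide property
tables ship as TSV package data with recorded SHA-256 checksums and are
**synthetic stand-ins**: the canonical 148-property dinucleotide compendium
is distributed as supplementary material of its sources and is not
redistributed here, so the bundled file preserves the layout (148
properties × 16 dinucleotides, first six rows named for the conventional
helical parameters) with deterministic pseudo-random values at realistic
scales. The trinucleotide table uses the twelve conventional property
names; "Trinucleotide GC content" and the molecular-weight rows are
computed exactly from the word, the other nine rows are synthetic. Every
numeric claim the tests make about these tables is therefore structural
(shape, names, completeness, standardization moments), never a
physicochemical value; a user TSV restores published values without code
changes. PseKNC standardizes its property rows to mean 0 / population SD 1;
zero-variance rows are rejected by name.

## Dataset construction

Positives for a location are all its transcripts; negatives are drawn
uniformly without replacement from the pooled other locations (an optional
stratified mode draws evenly per location). The negative count is
round-half-up(|positives| · neg/pos); a short pool is exhausted and
flagged rather than an error. Default ratios: 1:1 everywhere except ExR
(1:2) and mitochondria (1:3); locations beyond the core five default to
1:1. The holdout split is stratified with ceil(fraction · n) test members
per class; CV folds are stratified k-fold. Every sampling step takes an
explicit integer seed through `numpy.random.default_rng`.

## Synthetic corpus generator

The generator emulates a curated localization corpus: per location, i.i.d.
bases from a 4-vector composition, lengths uniform in a range (a clipped
lognormal option exists for more realistic length skew), and an optional
planted trinucleotide motif carried by a fraction `rate` of the location's
sequences (carriers receive max(1, L // 60) copies overwritten at random
positions). The default five-location study corpus uses 200 sequences per
location, lengths 120–400 nt, one base biased to 0.40 per location
(mitochondria: A/G at 0.34 each) and one distinct motif per location at
carrier rate 0.8.

What it does *not* emulate: homology/redundancy structure (real corpora
are clustered to remove near-duplicates), UTR/CDS architecture, true
localization signals (zipcodes), length–class correlations, or multi-label
localization. Passing the end-to-end recovery test therefore shows that
the pipeline is wired correctly and can recover strong compositional
signal — not that comparable accuracy is attainable on curated transcript
databases.

## Models and training

Candidate algorithms: DT, GNB, RBF-kernel SVC, RF, XGB and LGBM (the two
gradient-boosting families bracket the ensemble methods that dominate this
task). SVC and GNB see standardized features via a scaler stored with the
scorer; tree ensembles train on raw features. Hyperparameter tuning is an
exhaustive grid by stratified-CV accuracy with ties broken toward the first
grid cell. The default location → feature-group mapping feeds k-mer +
PseKNC to cytoplasm, nucleus and ER, and physicochemical + Z-curve to ExR
and mitochondria; other locations get all four groups. The mapping is
enforced structurally: each scorer's stored schema contains only its
groups' columns, and bundle loading verifies schema hashes.

Argmax ties are broken by a fixed priority — cytoplasm, nucleus, ER, ExR,
mitochondria (descending corpus size), then further locations
alphabetically — with a tie flag in the output. The priority is recorded
in the serialized bundle.

## Feature attribution

`rank_features` orders features by mean absolute additive attribution.
XGBoost and LightGBM use their built-in TreeSHAP contributions (additive on
the margin scale, bias term reported as base value). sklearn trees and
forests use decision-path attribution: the change in positive-class
fraction between a node and the child a sample descends into is credited
to the node's split feature, so base + Σ credits reconstructs the leaf
probability exactly (the additivity contract, asserted at 1e-6). Non-tree
models fall back to a label-free score-permutation importance (mean
|score shift| when one column is shuffled), recorded in the result's
`method` tag.

## Evaluation

Six metrics from the binary confusion counts: Sn = tp/(tp+fn),
Sp = tn/(fp+tn), Acc = (tp+tn)/n, Pre = tp/(tp+fp), F1 = harmonic mean of
Pre and Sn, MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)). Any
zero denominator yields 0 for that metric plus a `degenerate` flag instead
of an exception. Reports carry values on [0, 1] and format as two-decimal
percentages at the edge. The CV harness asserts that the holdout partition
is disjoint from every fold's fit set.

### The label-shuffled control

The end-to-end null control permutes corpus labels and expects CV MCC near
zero. One subtlety: with a few strongly clustered classes, a *single*
permutation can be imbalanced across clusters, which makes the binary
positives and negatives genuinely distinguishable and biases that
permutation's MCC away from zero. The control therefore averages the mean
CV MCC over three independent permutations — an estimate of the
permutation-null mean, which is zero by symmetry — and checks
|mean| < 0.15.

## Numerical choices and problem sizes

Encoders use exact integer counting before a single division, so oracle
comparisons against naive sliding-window counters hold to < 1e-12.
Standardization uses population SD. Negative-count rounding is
half-up. The test suite and the acceptance script run the end-to-end
pipeline at 200 sequences per location (1000 transcripts, full 6122-wide
battery), which exercises every component at realistic width while keeping
a full run in the low minutes on one CPU.

## Known limitations

Single-label assignment only (multi-localized transcripts are out of
scope); no secondary-structure or annotation-derived features; bundled
property values are placeholders pending a user-supplied compendium;
OvR scores from differently calibrated models are compared by raw argmax;
synthetic benchmarks bound what the shipped tests can claim about curated
data.
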