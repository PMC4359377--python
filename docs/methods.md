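# Methods

This note records the models implemented by the package, the assumptions
behind them, the parameter choices that matter, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken where
the design was genuinely open.

## Readthrough propensity regression

**Model.**  Basal readthrough of a stop codon is approximated as a linear
function of its indicator-encoded sequence context.  The context window
is fixed at −6..+9 with the stop at +1..+3; the stop is a single 3-way
categorical position (TAA/TAG/TGA), never three nucleotide positions.
The full encoding is 12 positions × 4 bases + 3 stop entries = 51 binary
dimensions, unit-normalised (division by √13 ≈ 3.6 for the full window).
Weights solve w = (XᵀX + k·I)⁻¹Xᵀy with **no intercept**; any constant
component of the response must be absorbed by the indicator blocks
themselves (each block contributes a constant 1/√p to every feature
vector).  This choice follows the model whose published weights are
bundled; its consequences are discussed under *Feature selection* below.

**Identifiability.**  Every encoded context activates exactly one entry
per block, so the columns of X are exactly collinear: adding a constant
c_j to all entries of block j and subtracting matching constants
elsewhere leaves all predictions unchanged.  Raw weights are therefore
identifiable only up to per-block shifts; the minimum-norm solution
selected by the ridge limit k → 0 is the representative in which all
block sums are equal.  Anything that claims to "recover" weights — the
synthetic generators, the parameter-recovery tests — works with this
representative.

**Regularisation.**  k is selected by leave-one-out CV (sum of squared
held-out errors) over the 21-point grid 10^i, i = −3, −2.7, …, 3, ties
resolved toward the smallest k (strongest regularisation).  The bundled
models use k = 10^0.3 ≈ 1.995.  loo-CV is computed with the exact ridge
hat-matrix identity, e_i/(1 − H_ii); a naive refit-n-times oracle backs
this in the tests.  The linear system is solved with a symmetric
positive-definite solve, never an explicit inverse.

**Scoring.**  Predicted readthrough for a context is the sum of matched
raw weights divided by √(active positions); dividing further by the
Euclidean norm of the weight stack gives the dimensionless RTP score.
RTP is invariant to uniform rescaling of weights (hence to the unit of
the training response — percent vs fraction affects predicted values,
not rankings; bundled fixtures store percent).  The bundled models'
recomputed norms are 0.00879 (`LINiter`) and 0.00631 (`LINfs3`),
matching their published roundings 0.0088/0.0063, and the combined
shortcut divisors are 0.0317 and 0.0126.  RTP can be negative; the scan
stage rescales it to [0, 1] before forming product scores.

## Feature selection

Backward elimination starts from all 12 context positions, removes the
position with the smallest sum of squared coefficients (the stop is
never a candidate), refits with k re-selected by loo-CV at every step,
and repeats until only the stop remains — 12 removal steps plus the
initial record.  Importance ties are broken by removing the position
farthest from the stop, upstream before downstream, so that proximal
downstream positions survive longest; the rule is explicit and tested.
The per-step "regression error" is the loo-CV SSE (the only error the
procedure defines).  The global minimum of the error trace names the
best reduced model; interior steps smaller than both neighbours are
reported as local minima.  The consensus motif of a reduced model is the
argmax-weight base per retained position (ties: lexicographically first,
flagged ambiguous).

**A caveat discovered during validation.**  On synthetic data with
signal planted only at {stop, +4..+6}, the planted positions survive the
elimination longest and are contained in the global-minimum model in
essentially every random draw — but in roughly half of draws the global
minimum also retains one or two chance positions.  This is not a solver
or grid artifact (it persists at the fine-grid optimum of k and under a
naive refit oracle): with no intercept and a non-negative response, an
extra indicator block lets ridge represent the constant component of y
at lower weight-norm cost, and the resulting reduction in shrinkage bias
can outweigh the block's variance penalty.  The effect is scale-free in
noise level and sample size.  Consumers of elimination traces should
read shallow minima accordingly: the retained-positions set is reliable
as a superset of the signal, and the elimination *order* is the sharper
signal of position relevance.

## PTS1 classification

C-terminal peptides are encoded as binary indicators over the last 15
residues (20 amino acids × 15 positions = 300 dimensions); shorter
peptides leave leading blocks empty and the undefined residue `X` (used
for the recoded stop of a readthrough extension) contributes nothing.
Peptide vectors are *not* unit-normalised: window occupancy varies and
carries information.  The classifier is ridge regression against ±1
labels (the same closed form as the context model); k defaults to 1 and
can be selected by CV squared error over the standard grid.  Raw scores
are mapped to posteriors by a two-parameter logistic σ(αs + β) fitted by
maximum likelihood to held-out scores from an internal stratified 5-fold
CV, with α constrained positive so the posterior is strictly increasing;
final weights are refitted on all data.  Evaluation is by stratified
k-fold CV with pooled held-out scores: trapezoidal auROC and the area
under the precision/recall curve.  No class reweighting is applied —
plain least squares — and the CV report carries the class balance so
imbalance is visible.

The PTS1 scoring window of a scanned transcript is the last 15 residues
of protein-plus-extension: when the extension is shorter than 15
residues the window deliberately dips into the annotated protein.

## Transcriptome scanning

Records are a CDS (including its stop) plus ≤300 nt downstream, sense
strand, 1-based codon coordinates, +4 = first nucleotide after the stop.
Filtering removes, in order of check: records with any non-ACGT
character ("undetermined"), CDS length not a codon multiple ("frame"),
missing/terminal non-stop codon ("stop"), and proteins under 15 aa
("short"); filtering is total and logged, never an exception.  Records
with identical 3′ termini — key: last 45 CDS nt + up to 303 nt
downstream — collapse to one representative (lexicographically smallest
id, a determinism choice; the aggregation map is preserved).  The
extension runs from +4 to the next in-frame stop (exclusive) within
300 nt; its translation is prefixed with `X` for the recoded stop.
Transcripts with no in-frame downstream stop stay in the ranking with
PTS1 posterior 0 (hence product 0) rather than being dropped.

Ranking multiplies RTP⁺ — RTP min-max scaled to [0, 1] *over the scanned
set*, so ranks depend on the input universe — by the PTS1 posterior of
the extended C-terminus; ties break by id.  The half-max rank (first
rank below 50% of the top product) summarises how sharply the score
distribution drops.

## Reporter statistics

Readthrough of a construct is luminescence/fluorescence (x₂/x₁) with
first-order propagation σ_y² = σ_x1²(∂y/∂x₁)² + σ_x2²(∂y/∂x₂)², blank
subtraction applied to the means first, normalised to percent of the
no-stop control (ratio-of-ratios propagation), and combined across
replicates by inverse-variance weighting: x_m = Σxᵢwᵢ/Σwᵢ,
σ_xm = (Σwᵢ)^−½ with wᵢ = 1/σᵢ².  Zero-σ replicates are rejected (their
weight is undefined) rather than given infinite weight.  Induction
factors (e.g. by aminoglycosides) are ratios of estimates with the same
propagation.  First-order propagation is accurate to a few percent for
coefficients of variation up to ~10%, verified against 10⁵-draw
Monte-Carlo sampling; beyond that, ratio distributions grow skewed and
the linearisation under-reports spread.

## Synthetic data

The generators provide the statistical structure each stage assumes,
with all randomness a pure function of the seed:

* **Context sets** — contexts uniform per position (stop uniform over
  three), response y = w_planted·x + Gaussian noise, truncated at 0
  because readthrough cannot be negative (the truncation count is
  recorded; with the default non-negative planted weights it is rare).
  Planted weights are drawn in the identifiable equal-block-sum form
  (see above).  Default sizes in tests: 80–120 contexts, noise SD 0.005–
  0.05 against a planted signal SD of ~0.12 — chosen as a plausible
  measurement-noise-to-signal regime for reporter assays.
* **Peptide sets** — positives end in a motif tripeptide (default SKL,
  SRL, ARL, AKL); negatives avoid the motifs *and* the wider canonical
  neighbourhood (terminal L/M with a basic residue at −2 or S/A/C at −3),
  since upstream-of-tripeptide similarity is part of the real signal.
  The corpus-scale default, 200 positives vs 1800 negatives, mirrors the
  shape of a real PTS1 training corpus (tens of seed proteins expanded
  by orthologs, against thousands of negatives).
* **Toy transcriptomes** — uniform-codon decoys (30–80 codons plus stop,
  300 nt downstream) that never carry the UGA-CUA stop motif or a
  PTS1-like extension terminus, plus planted candidates defaulting to
  the LDHB arrangement: UGA stop, CUA G at +4..+7, an 18-nt extension
  encoding six residues ending in SRL.

What the generators do **not** emulate: real nucleotide composition and
codon-usage bias around human stop codons, the actual readthrough-value
distribution of nonsense-mutation training sets, homology structure in
peptide corpora (synthetic examples are i.i.d., so CV is not inflated by
relatives straddling folds), and transcript-isoform redundancy beyond
exact 3′-terminus duplication.  Passing tests therefore demonstrate that
the algorithms are implemented correctly and recover planted structure —
not that the bundled models' accuracy on real transcriptomes is
reproduced.  Published data-dependent figures (loo-CV error minima,
Pearson correlations of 0.34/0.41, auROC 0.996/auPRC 0.863, genome-wide
motif and transcript counts, specific posterior percentages) depend on
external corpora that are not bundled and are documented as such, not
asserted.

## Problem sizes

Test and acceptance runs use: ridge/loo oracles at n ≤ 20 instances,
parameter recovery at n = 80–120, feature-selection traces at n = 120
(a full trace is 13 model fits × 21 grid points of loo-CV), PTS1 CV at
n = 2000 peptides, the end-to-end scan at 501 transcripts, and 10⁵
Monte-Carlo draws for propagation checks.  The whole suite runs in a few
seconds on one CPU.
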