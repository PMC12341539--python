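# Methods

This note documents the models, numerical choices and limitations behind
`prejump`. The pipeline ranks candidate determinants of trampoline
pre-jump height from a small athlete cohort; because the original raw
data were never deposited, the package pairs the analysis stages with a
moment-matched synthetic-cohort generator calibrated to the published
summary statistics.

## Synthetic cohorts

**Moment specification.** A `MomentSpec` holds, per indicator, the target
mean, SD and Pearson correlation with the criterion (pre-jump height, in
metres), plus the criterion's own mean and SD. The built-in calibration
(`prejump.calibration`) stores the published values at printed precision:
criterion 3.13 ± 0.36 m, height 152.66 ± 9.98 cm, and so on for all 16
representative indicators, with criterion correlations from 0.875 down to
−0.631. One published unit label is internally inconsistent (standing long
jump is labelled metres with a printed value of 212.75, clearly
centimetres); the numbers are stored verbatim since correlations are
scale-free and no downstream quantity mixes that indicator's units.

**Correlation completion.** Only indicator–criterion correlations are
published. The full (m+1)×(m+1) correlation matrix is completed by the
rank-one rule r_ij = r_i·r_j — the exact structure implied by a single
latent ability factor that the criterion measures without error. This is
a modeling choice, not a published fact; it is the most parsimonious
completion consistent with the data available. The completed matrix is
provably positive definite whenever all |r_i| < 1 (for the calibrated
17×17 matrix the smallest eigenvalue is ≈ 0.047). As a safety net for
other fill strategies, eigenvalues are clipped at 1e-6, the matrix
reconstructed and rescaled to unit diagonal — simpler than a full
nearest-correlation iteration and sufficient at this dimension.

**Exact matching.** `generate_exact` draws an n×m standard-normal matrix,
centers the columns, whitens against the empirical covariance (Cholesky
solve), re-imposes the completed correlation via its Cholesky factor, then
scales by the target SDs and shifts by the target means. Sample means,
SDs (n−1 divisor, matching the published mean ± SD convention) and all
sample correlations then equal the targets to roundoff, for every seed.
This requires n ≥ m+2 so the centered draw has full column rank with
margin; with 17 variables the minimum is n = 19, so the original cohort
size of 16 cannot be exactly matched — paper-scale runs use
`generate_sampled`, which draws i.i.d. rows from the implied multivariate
normal and matches moments only in expectation. Seeds are mandatory
arguments throughout; both generators are pure functions of
(spec, n, seed).

**What the generator does and does not emulate.** Cohorts are Gaussian
with the published first and second moments. Real athlete data are
bounded, partly discrete (questionnaire scores, repetition counts),
possibly skewed, and carry indicator–indicator correlations that are not
rank-one. Tests passing on synthetic cohorts therefore certify the
*pipeline arithmetic* (moments in → statistics out), not distributional
robustness on real data. Grey relational grades in particular depend on
the full sample paths, not just moments, so grades computed on synthetic
cohorts are internally consistent but are not estimates of the published
grade values.

## Expert screening

Items are retained when the rater mean strictly exceeds 3.5 (on the 1–5
scale) and, under the default consensus rule, the across-rater SD (n−1
divisor) is at most 1.0. The source procedure requires "consensus" without
defining it; an SD cap is the common Delphi-style operationalization and
is exposed in configuration (`consensus_rule="none"` disables it) rather
than hidden. Retention is monotone in any rater's score when no consensus
rule is applied (property-tested).

## Factor reduction

Per indicator block the stages run in fixed order: Pearson correlation
matrix → KMO → Bartlett → PCA extraction → varimax → representative
selection. The block is *refused* (a diagnostic-failure result, never a
silent continuation) when KMO ≤ 0.5 or Bartlett p ≥ 0.05.

- **KMO** uses the anti-image formulation: with A = R⁻¹, the partial
  correlation is q_ij = −a_ij/√(a_ii a_jj) and
  KMO = Σr²/(Σr² + Σq²) over off-diagonal entries. Tests verify this
  against an independent pairwise Schur-complement computation of the
  partial correlations. A singular matrix raises (condition number gate at
  1e12); an identity matrix is a 0/0 form and raises a degenerate-KMO
  error.
- **Bartlett** is the standard determinant test,
  χ² = −(n−1−(2p+5)/6)·ln det R on p(p−1)/2 degrees of freedom.
- **Extraction** is PCA on the correlation matrix (no iterated
  communalities), retaining eigenvalues *strictly* greater than 1.
  Eigenvalue ties are broken by a stable sort on original position;
  eigenvector signs are fixed so each column's largest-magnitude loading
  is positive.
- **Varimax** is the classic SVD iteration with Kaiser row normalization
  on by default (rows scaled to unit communality during rotation, the
  SPSS convention), tol 1e-9, max_iter 1000. Non-convergence returns the
  best rotation found with a warning rather than raising: the objective is
  monotone under the iteration and the tight tolerance can require more
  than 1000 steps on problems with slow linear convergence, where the
  returned rotation is already at the optimum to ~1e-12. Tests pin the
  2-component solution to a 0.001-radian grid search and to an
  independent GPA-based rotation (statsmodels); orthogonality of the
  rotation and preservation of row communalities are property-tested.
- **Representatives.** Each indicator is assigned to the component
  carrying its largest absolute loading; within a component the
  highest-loading assigned indicator represents it, provided
  |loading| > 0.4, otherwise the component is flagged with no
  representative. Assignment-then-selection makes the "other indicators"
  lists a partition of the block.

Small cohorts with many indicators give near-singular correlation
matrices; the module gates on invertibility and synthetic tests use
n ≥ 5× the indicator count (recommended, not enforced).

## Grey relational analysis

Sequences are normalized by dividing by their own mean (undefined, and
refused, when the mean is ≤ 0 — values entering GRA must be on positive
scales). Deng's coefficient uses Δmin and Δmax taken **globally** over all
inspected sequences and positions, per the ∀i ∀k definition; a
consequence worth flagging is that an indicator's grade depends on which
other indicators share the table. The degenerate case Δmax = 0 (all
sequences identical after normalization) defines every coefficient as 1.
The grade is the plain mean of a sequence's coefficients; classification
uses strict grade > 0.9 for strong, grade < 0.8 for weak, and the closed
interval [0.8, 0.9] for moderate (so exactly 0.9 is moderate). Ranks
break ties by input order.

No sign alignment of negatively oriented indicators (e.g. state anxiety)
is applied by default: the published analysis reports a high grade for
state anxiety alongside a negative Pearson correlation, implying none was
applied there either. An opt-in `direction_alignment` flag reflects
negatively correlated sequences about twice their mean (x → 2·mean − x),
which flips the trend while keeping the mean positive so normalization
stays defined.

Pearson correlations and their two-sided t-based p-values come from
`scipy.stats.pearsonr`; the significance flag uses α = 0.05.

## Pipeline and reproducibility

`run_pipeline` executes screen → load/synthesize → (optional) per-block
reduction → GRA, writing CSV reports and a `manifest.json` (config echo,
seed, package versions) from which a run regenerates byte-identically.
Factor reduction is optional because the calibrated 16-indicator runs
feed representatives directly; threshold comparisons are logged at INFO
level to support audit trails.

## Problem sizes

Default analyses use n = 40 synthetic athletes for exact-moment runs (the
smallest round size comfortably above the n ≥ 19 feasibility bound for 17
variables), n = 16 for paper-scale sampled runs, n = 200–500 for factor-
recovery simulations, and n = 100 000 for law-of-large-numbers checks of
the sampled generator; these sizes give the tests their stated precision
at negligible cost.

## Known limitations

- The rank-one correlation completion understates indicator–indicator
  dependence within blocks; factor reduction on calibrated synthetic
  cohorts consequently tends toward a single dominant component rather
  than the published multi-factor block structure.
- Published grade values cannot be recomputed without the raw data; they
  are embedded only as classification inputs and reference points.
- GRA grades have no sampling-uncertainty quantification here (no
  bootstrap); only Pearson correlations carry p-values.
- Mean normalization presumes positive-valued indicators; indicators on
  scales with non-positive means must be re-expressed before analysis.
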