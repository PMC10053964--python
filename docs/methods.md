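# Methods

## Model

A clock is an intercept plus linear and quadratic terms in percent
methylation, `DNAmAge = β0 + Σ β_i m_i + Σ γ_j m_j²`, evaluated with
`m` on the 0–100 percent scale (the published coefficient tables
multiply percentages, never fractions, so the I/O layer warns on
fraction-looking files instead of rescaling). Quadratic terms are
independent predictors: a CpG may carry a `γ` with no `β` (the blood
model's ASPA CpG1 and ELOVL2 CpG4 do exactly that), and no polynomial
hierarchy is imposed. Inputs are validated to [0, 100] at I/O time and
never clipped or winsorized at evaluation time.

Built-in coefficient sets are stored as decimal strings and converted
once, so the published precision survives JSON round-trips on any
platform. The only built-in missing-data policy besides failing loudly
is per-site median imputation within the evaluated matrix: no published
imputation rule exists, and the median is the least structured choice.

## The 31-CpG panel

The default panel enumerates the CpGs of the six assay amplicons by
counting the degenerate C/G positions in each pyrosequencing
sequence-to-analyze: ELOVL2 7, FHL2 12, PDE4C 5, ITGA2B 3, ASPA 2,
EDARADD 2 — 31 sites total, covering every site used by either built-in
clock. Genomic coordinates are not bundled (the panel addresses CpGs by
gene + 1-based amplicon ordinal, hg38 assumed when user-supplied
coordinates are attached).

## DeltaAge and the normality band

DeltaAge is the plain difference DNAmAge − chronological age; no
residual-based acceleration measure is offered. The band half-width is
the *raw* MAD — median of absolute deviations from the median, with no
1.4826 consistency factor — because the published half-widths (2.78
blood, 3.46 heart) are used directly on the year scale. Centering is
configurable (the publication does not state it; with DeltaAge medians
near zero both forms nearly coincide) and defaults to the classical
centered form. The band boundary is inclusive (|Δ| = h is "normal") so
class counts are exactly reproducible. The paired comparison of
chronological and predicted age is the classic two-sided paired t-test;
a zero-variance deviation vector reports p = 1 (identical predictions
are maximal evidence of no difference, and the t statistic is 0/0).

## Clock construction

Defaults are the study conditions: test fraction 0.35 drawn only from
samples with ≥ 90% observed CpGs, screening and pruning thresholds
0.10, "30-cross-validation" read as 30-fold CV, and RFE scored with 30
folds × 10 repeats. Decisions the procedure description left open:

- **Screening** fits each site's linear and quadratic term in separate
  single-term models; either may enter candidacy independently
  (consistent with quadratic-only terms in the final published models).
  Pairwise deletion per site; a constant predictor records p = 1.
- **Stepwise** is AIC-guided bidirectional search from the null model
  (no entry/exit criterion is published; AIC needs no extra threshold
  and is deterministic). It refuses when complete samples ≤ candidate
  terms rather than fitting an underdetermined model.
- **Lasso** standardizes candidates internally, picks λ minimizing
  30-fold CV squared error over a log grid (default 30 points,
  10⁻³–10¹; λ-min, not 1-SE), and "selects" nonzero coefficients.
- **RFE** ranks terms once by recursively dropping the smallest
  absolute standardized OLS coefficient, then scores every subset size
  — including the intercept-only model, which makes the single-candidate
  rule (keep it only if it beats the empty model) fall out naturally —
  by repeated-CV RMSE; ties go to the smaller model.
- **Combination** is OLS on the union of the three selections
  (complete cases on the union's sites), backward-pruned one term at a
  time by largest p while any p > 0.10. A perfect fit (all p
  undefined) prunes nothing. An empty union yields a constant model
  predicting the mean age, flagged in the report.
- The trained clock's half-width is the centered MAD of training-set
  deviations; test-set deviations are summarized separately in the
  report (test samples are evaluated with median imputation so a
  stray missing value does not void the summary).

All randomness (split, CV folds, bootstrap) flows from one recorded
seed; identical data + config + seed give identical models and reports.

The neural-network baseline is deliberately minimal: one hidden layer,
width tuned over {1, 2, 4, 8, 16} by out-of-bag MAD across 25 bootstrap
resamples, min–max-scaled inputs, LBFGS optimization; width 0 is
allowed in the grid and collapses to a linear model. Published NN
details are too sparse to mirror more closely.

## Cohort statistics

- Pearson chi-squared without continuity correction throughout
  (uncorrected statistics match the reproducible count arithmetic).
- Post hoc scheme: per-class one-vs-rest 2×2 chi-squared tests with
  Benjamini–Hochberg adjustment across the classes. The publication
  names a post hoc procedure without detailing it; one-vs-rest matches
  the per-class p-value structure of the reported tables.
- Stratified analysis uses the generalized 2×J×K
  Cochran–Mantel–Haenszel statistic (sum of observed-minus-expected
  vectors with pooled multivariate-hypergeometric covariance,
  df = J − 1), hand-implemented because the installed statsmodels
  stratified tables cover only 2×2×K. For a single stratum it equals
  (N−1)/N times the Pearson statistic, which the tests exploit as an
  oracle identity.
- Multinomial odds ratios come from a maximum-likelihood multinomial
  logit of class on a group indicator (reference class "normal",
  reference group AVR, which reproduces the published cardiac OR 0.47);
  on a saturated 2×J table the MLE equals the closed-form count
  cross-ratio, kept as an independent oracle in the tests. ORs with a
  zero cell in the cross-ratio are reported non-estimable.
- Ratio tables keep full precision internally; the display rounding is
  two significant figures, which reproduces the published mixed one-
  and two-decimal renderings (1.7 and 0.25 in the same table).
- Continuous echo-parameter comparisons are pairwise Welch
  (unequal-variance) t-tests across class × group cells with BH
  adjustment — the publication shows only significance stars, so the
  test choice is an explicit package decision.

## Synthetic cohorts

The generator emulates targeted-panel methylation aging data: per-site
quadratic-in-age mean trajectories with Gaussian noise, clipped to
[0, 100] with clipping counted and reported; ages from a truncated
normal (66.5 ± 9.7 on [40, 90], the surgical cohort's age law); group
sizes defaulting to the study's 94 AVR / 289 CABG; per-group binary
risk factors at roughly the published prevalences. Group effects enter
through an *effective age* t* = t + δ(group, tissue) rather than
additive prediction noise, so clock evaluation and clock training see
one coherent signal.

`blood_clock_consistent_spec` solves (by nonlinear least squares on an
age grid, verified to < 0.05 y before use; in practice the residual is
~1e-8 y) linear trajectories for the 12 blood-clock CpGs such that the
built-in blood clock maps the generated methylation back to
chronological age. The requested output noise is injected as one common
per-site methylation noise level scaled through the clock's gradient at
the mid-cohort trajectory values (delta method), so the clock-scale
error sd equals `noise_sd` to first order; every clock site is
individually noisy, which is what makes consensus selection recover the
full site set rather than a minimal perfect predictor. The remaining 19
panel sites are age-independent noise. The default two-tissue spec
instead spreads per-site age correlations over roughly |r| 0.2–0.8,
echoing the heterogeneous correlations of real panels.

What the generator does *not* emulate: bisulfite-conversion chemistry,
read-level pyrosequencing signal, cell-type composition shifts,
between-site correlated noise, and batch effects. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not clinical performance on real cohorts; in
particular the published fitted MADs, R² values and group DeltaAge
means depend on the patient data and are not reproducible here.

## Problem sizes and numerical choices

Tests and the acceptance checks run at desk scale: parameter recovery
uses n = 400 with the full 30-fold × 10-repeat CV; screening
calibration uses 2000 Monte-Carlo replicates at n = 60; group-effect
detection uses 200 replicates at the study's cardiac group sizes
(68/224). Tolerances: clock evaluation against the term-loop oracle at
1e-9 years; statistic oracles at 1e-6–1e-10; stochastic checks use
seeded generators with bands wide enough for Monte-Carlo error.
Degenerate inputs are rejected loudly (zero margins, empty strata,
sub-minimal cells, non-positive half-widths) rather than propagated as
NaN.

## Known limitations

- The default panel's per-gene CpG ordinals follow the assay sequences;
  users with genomic coordinates should attach them to a custom panel.
- Coefficients of the two reference clocks cited alongside the built-in
  models are not bundled; they can be supplied as clock JSON.
- The stepwise/Lasso/RFE consensus is one reasonable reading of a
  procedure whose published description is incomplete; alternative
  readings (p-value stepwise, 1-SE Lasso) would select slightly
  different unions on noisy data.
- `ConsensusClockRegressor` requires site-labelled input (DataFrame or
  MethylationMatrix) — a bare array has no CpG identities from which to
  build a clock.
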