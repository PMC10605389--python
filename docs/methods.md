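# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Signature-regression deconvolution

**Model.** A bulk tumor expression profile is treated as a convex mixture
of reference cell-type profiles: *m ≈ S f*, with *m* the per-gene linear
TPM vector, *S* the signature matrix (genes × cell types, LM22 role:
547 × 22 with seven T-cell subsets) and *f* ≥ 0, Σ*f* = 1 the cell-type
proportions. Inputs must be on the **linear TPM scale**; `log2(TPM + 1)`
files are accepted as an encoding and inverted (`2^v − 1`) before
deconvolution, since the regression model is defined on linear mixtures.

**Fitting.** Genes are intersected with the signature (at least 50% of
signature genes must be present). The mixture vector is z-scored over the
shared genes; the signature is standardized **as a whole matrix** (one mean
and sd over all entries). Whole-matrix standardization is an affine map,
so a convex mixture of columns stays a convex mixture with the *same*
weights — per-column scaling would silently reweight each cell type by the
inverse of its column sd. A linear ν-SVR of the standardized mixture on
the standardized columns is fitted for each ν ∈ {0.25, 0.5, 0.75}
(C = 1); the fit with the lowest reconstruction RMSE is selected, negative
coefficients are truncated at zero and the remainder renormalized to sum
to one. An all-non-positive coefficient vector or a zero-variance mixture
is an explicit error, never silent zeros.

Numerical settings: libsvm tolerance 1e-3 with an iteration cap of 5000
per fit. On noiseless, well-conditioned mixtures the solver converges well
before the cap (fraction MAE ~3e-6 vs the generating truth and vs a
non-negative least-squares oracle on the same standardized, centered
system); under multiplicative log-normal noise with sd 0.3 the cap costs a
little polish (CD8 recovery r ≈ 0.96–0.98 instead of ≈ 0.97–0.98) while
keeping a 522-sample cohort under about a minute on one CPU. Rare libsvm
numerical failures at a single ν (possible on pathological shuffled
mixtures) drop that ν from the grid rather than aborting the sample.

**Significance.** An optional permutation test shuffles the mixture values
across genes, re-runs the ν-grid selection, and records the selected-fit
correlation; `p = (1 + #{null ≥ observed}) / (n + 1)` (add-one estimator,
so p is never zero; default 100 permutations, minimum 10). The correlation
is taken from the selected fit *before* truncation so the null statistic is
defined even for degenerate shuffles. Quantile normalization — the classic
microarray-era default — is not applied: the expected input is RNA-seq TPM.

**Densities.** CD3 (pan-T) is the summed fraction of the declared T-cell
subsets; CD8 is the declared CD8 subset's fraction. Which subsets
constitute "CD3" is a declaration on the signature, not an inference; with
the LM22-style naming all seven T-cell columns are declared and
`T cells CD8` is the CD8 subset, so 0 ≤ CD8 ≤ CD3 ≤ 1 holds by
construction. These are *relative* immune fractions standing in for the
immunohistochemical cell densities of the original immunoscore — only
their cohort percentiles enter the score, so any monotone rescaling of the
densities leaves the immunoscore unchanged.

## Cross-validated percentile immunoscore

A patient's score is the mean of the mid-rank empirical percentiles of
their CD3 and CD8 densities among a training population:
`pct(q) = 100 · (#{t < q} + ½·#{t = q}) / n`. The mid-rank convention
handles ties symmetrically (an all-tied cohort scores exactly 50) and
makes the score of the strictly largest patient strictly dominant.

To avoid using each patient's own density in defining their percentile
function, scoring is cross-validated: 20 iterations of 5-fold partitioning
(folds shuffled from a seeded generator, stratified by the event indicator
when available so every training split contains both outcome classes);
per iteration a patient is scored against the union of the other four
folds, and the final score is the mean of the 20 held-out scores. The
per-iteration matrix is retained, because the cut-off machinery and the
C-index are evaluated per iteration.

**Cut-offs.** Two dichotomizations into low (0) vs intermediate–high (1):

- *Fixed percentile* (default 25): the threshold is that percentile of the
  cohort's final scores; a score exactly at the threshold is
  intermediate–high ("low" is the strict lower tail).
- *Youden-optimized*: per CV iteration, the cut-off c maximizing
  J(c) = sensitivity + specificity − 1, with death (event indicator,
  censoring ignored) as the positive class and `score < c` as the positive
  test. Candidates are the midpoints of consecutive distinct scores; the
  maximizer is located with the exact integer numerator
  `tp·n_neg − fp·n_pos`, so ties in J are well-defined and break toward
  the smallest cut-off. Each iteration's cut-off is re-expressed as the
  mid-rank percentile of that iteration's score distribution, and the
  resolved cut-off is the mean over iterations.

Using the raw event indicator as the Youden label is a deliberate
simplification (it conflates early deaths with deaths at any follow-up
length); a time-horizon label would need a horizon the analysis does not
otherwise define. When outcome labels are generated deterministically from
a threshold on the true combined percentile, the resolved cut-off lands
within ±5 of the generating threshold, with a small (~2–3 point) downward
bias inherent to the smallest-tie rule combined with fold noise.

## Survival statistics

- **Kaplan–Meier** curves (product-limit at event times, Greenwood
  variance, 95% bands via the exponential-Greenwood log(−log) transform,
  clamped to [0, 1]) and the **two-group log-rank** chi-square
  (observed-minus-expected over hypergeometric variance, df = 1) are
  computed through lifelines behind this module's interface; both are
  verified against hand-computed oracles in the test suite. The reported
  median is the smallest event time with S ≤ 0.5.
- **Harrell's C-index** is implemented directly because its pair
  conventions matter here: a pair is comparable when the earlier time is
  an observed death (or the times are tied with exactly one death); it is
  concordant when the longer-surviving patient carries the *higher* score
  (protective orientation — the immunoscore is favorable); tied scores
  count ½. By default the binary category enters the C-index (it is the
  stratification evaluated throughout), computed per CV iteration by
  thresholding that iteration's scores and summarized as
  mean ± 1.96·sd/√k over the k iterations; the continuous per-iteration
  score is available via a flag.
- **Cox regression** for the binary category maximizes the Breslow partial
  likelihood by Newton–Raphson (steps damped to |Δβ| ≤ 2) until the score
  function is below 1e-8; for a binary covariate the information reduces
  to Σ d·(μ − μ²) with μ the risk-set covariate mean, so no linear algebra
  is needed. A group with no events makes the likelihood monotone; the
  estimate is then flagged rather than iterated to divergence. Estimates
  match lifelines on tie-free data to ~1e-4 (solver tolerances). Survival
  times of exactly zero are shifted to 1e-6 with a warning.

## Synthetic cohorts

The generator produces everything a run needs with known ground truth:

- **Signature**: log-normal background (log-mean 1, log-sd 0.6) with a
  dedicated block of ⌊genes/types⌋ marker genes per cell type up-regulated
  30-fold; needs ≥ 2 markers per type. This keeps the standardized matrix
  well-conditioned (condition number < 100, asserted in tests).
- **Fractions**: Dirichlet with unit concentration per type (mean CD3 over
  7 of 22 subsets ≈ 0.32, sd ≈ 0.10 — a wide, realistic infiltration
  range).
- **Expression**: signature · fractions with i.i.d. multiplicative
  log-normal noise (default sd 0.3 on the log scale).
- **Survival**: exponential with per-patient hazard
  `h·exp(β·(cd3 − mean cd3))`, baseline `h = ln2/10.5` per month (median
  time-to-death 10.5 months at the cohort mean) and β = −5 per unit CD3
  fraction by default (≈ −0.5 per CD3 sd: a clearly protective, but not
  overwhelming, effect). Censoring is independent and administrative: with
  probability 0.47 a record is censored at a uniform fraction of its event
  time, giving ≈ 53% observed events. Cancer-type labels are dealt
  round-robin over four names, so 522 patients split 131/131/130/130.
- **Determinism**: one root seed spawns independent child generators for
  signature, fractions, noise, survival and censoring, so runs are bitwise
  reproducible and one condition can change without disturbing the others.

What the simulation does **not** emulate: count-level RNA-seq noise
(negative-binomial per read), batch effects, tumor purity (the simulated
mixture is purely immune, so fractions are on the same scale as the
signature's population), gene-signature mismatch between reference and
tumor context, and informative censoring. Passing the synthetic
benchmarks therefore demonstrates that the *machinery* is correct and that
the statistical chain recovers known effects at realistic sizes — not that
the imputation is accurate on any particular real cohort.

## Pipeline and problem sizes

The orchestrated run inner-joins expression and survival tables on patient
id (dropped ids are logged), deconvolves once, and evaluates every
requested cut-off; the stratified report repeats scoring, cut-off
resolution and all statistics independently within each cancer-type
stratum (deconvolution is per-sample, hence identical either way, and is
reused). Strata smaller than the fold count, or with no events or a single
category, are skipped with a logged reason. All randomness descends from
one root seed.

The shipped benchmarks use 50 noiseless and 200 noisy samples for
deconvolution recovery, 1000 random instances for each exact-oracle check,
cohorts of 1000 for coverage, the study-scale 522 for cut-off recovery and
the end-to-end runs, 500 per group for Cox recovery, and 5000 for the
Kaplan–Meier closed-form check — sizes at which each property is sharply
testable on a single CPU.
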