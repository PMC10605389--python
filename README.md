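# immunoscore

A tested, reusable pipeline for computing a **transcriptomics-based T-cell
immunoscore** and quantifying how well it stratifies overall survival in
cancer patients treated with immune checkpoint inhibitors (ICIs).

The immunoscore concept summarizes the density of CD3+ (pan-T) and CD8+
(cytotoxic) tumor-infiltrating T cells into a single prognostic number.
When only bulk tumor RNA-seq is available — no immunohistochemistry — those
densities can be *imputed* by deconvolving the bulk expression profile into
immune-cell fractions against a leukocyte signature matrix (the LM22 role:
547 genes × 22 hematopoietic cell types, seven of them T-cell subsets).
This package implements that whole chain for computational oncologists and
biomarker researchers:

1. **Deconvolution** — a mixture *m* (linear TPM) is regressed on the
   signature matrix *S* with linear ν-support-vector regression over
   ν ∈ {0.25, 0.5, 0.75}; the lowest-RMSE fit is kept, negative
   coefficients are truncated and the rest renormalized, giving cell-type
   fractions *f* ≥ 0, Σ*f* = 1 (the published CIBERSORT core; an optional
   gene-shuffling permutation test calibrates fit significance).
2. **Densities** — CD3 = Σ fractions of the declared T-cell subsets,
   CD8 = fraction of the CD8 subset.
3. **Immunoscore** — for each patient, the mean of the mid-rank empirical
   percentiles of CD3 and CD8 among a training population. To avoid
   over-fitting, percentile functions are estimated on 4 of 5 folds and
   applied to the held-out fold, over 20 random fold assignments; the final
   score is the average of the 20 held-out scores.
4. **Cut-offs** — patients are dichotomized into *low* (0) vs
   *intermediate–high* (1) at the 25th percentile, or at a data-driven
   cut-off maximizing Youden's J = sensitivity + specificity − 1 (computed
   per CV iteration on the percentile scale and averaged).
5. **Survival statistics** — Kaplan–Meier curves with exponential-Greenwood
   95% bands, the two-group log-rank test, a univariate Cox hazard ratio
   (Breslow ties, Newton–Raphson), and Harrell's concordance index averaged
   over the CV iterations with a normal-approximation 95% CI.

Because matched real-world cohorts with both transcriptomes and outcomes
are rarely shareable, the package ships a first-class synthetic-data module
that generates cohorts with known ground truth (Dirichlet cell fractions,
log-normal expression noise, exponential survival whose hazard falls with
CD3 abundance, independent right-censoring), so every stage is testable
end-to-end offline.

## Worked example

```sh
immunoscore simulate --n-patients 200 --seed 42 --out demo
cat > demo/config.yaml <<EOF
expression_path: demo/expression.tsv
signature_path: demo/signature.tsv
survival_path: demo/survival.tsv
output_dir: demo/out
seed: 1
EOF
immunoscore run-all --config demo/config.yaml
```

which prints (whole cohort first, then one row per cancer-type stratum):

```
      cohort  percentile_cutoff  n_low  pct_low  avg_c_index  c_index_ci_lower  c_index_ci_upper  log_rank_p  cox_hr    cox_p
whole_cohort              25.00     50     25.0       0.6049            0.6027            0.6071    0.000026  0.4057 0.000046
whole_cohort              79.08    158     79.0       0.5304            0.5286            0.5323    0.073008  0.6153 0.075712
```

Reading the first row: at the fixed 25th-percentile cut-off, 50 of 200
simulated patients (25.0%) fall in the low-immunoscore category; the
CV-averaged Harrell C-index of the binary category is 0.605 (95% CI
0.603–0.607); the log-rank test separates the two survival curves at
p ≈ 2.6 × 10⁻⁵; and the Cox hazard ratio of intermediate–high vs low is
0.41 — the high-immunoscore group dies at less than half the rate, as
expected for a cohort simulated with a protective CD3 effect. The second
row is the Youden-optimized cut-off resolved on this cohort (79.1st
percentile). `demo/out/` additionally holds the cell-fraction table, the
per-patient scores, per-category Kaplan–Meier exports and JSON reports.

The same analysis is available programmatically:

```python
from immunoscore import (SyntheticConfig, simulate_cohort, deconvolve_cohort,
                         impute_t_cell_densities, cv_immunoscore)

cohort = simulate_cohort(SyntheticConfig(n_patients=200, seed=42))
fractions = deconvolve_cohort(cohort.expression, cohort.signature, seed=1)
densities = impute_t_cell_densities(fractions, cohort.signature)
scores = cv_immunoscore(densities)
```

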