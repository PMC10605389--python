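"""End-to-end orchestration: deconvolve, score, cut, and report survival.

A run loads the expression, signature and survival tables, inner-joins them
on patient id (warning about any dropped ids), deconvolves the cohort into
immune-cell fractions, derives CD3/CD8 densities, computes the
cross-validated percentile immunoscore, resolves each requested cut-off
(fixed percentile and/or Youden-averaged), and reports per cut-off the
low-category count, Kaplan-Meier exports, the log-rank test, the Cox hazard
ratio and the CV-averaged Harrell C-index with its 95% CI.  A stratified
run repeats the scoring and statistics independently within each
cancer-type stratum, including stratum-specific Youden cut-offs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deconvolution import (TCellDensities, deconvolve_cohort,
                            impute_t_cell_densities)
from .expression_io import (read_expression_matrix, read_signature_matrix,
                            to_linear_tpm)
from .scoring import (CVScheme, CutoffSpec, categorize, cv_immunoscore,
                      cv_youden_cutoff, YOUDEN)
from .survival_stats import (SurvivalRecord, cox_binary_hr, harrell_c,
                             kaplan_meier, logrank_test, summarize_c)

logger = logging.getLogger("immunoscore")

# Default LM22-style T-cell declarations (match synthetic_data's naming).
DEFAULT_T_CELL_TYPES = (
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
)
DEFAULT_CD8_TYPE = "T cells CD8"


@dataclass
class PipelineConfig:
    """File paths, declarations and knobs for a full run."""

    expression_path: str
    signature_path: str
    survival_path: str
    output_dir: str = "immunoscore_out"
    t_cell_types: tuple = DEFAULT_T_CELL_TYPES
    cd8_type: str = DEFAULT_CD8_TYPE
    cv: CVScheme = field(default_factory=CVScheme)
    cutoffs: list = field(default_factory=lambda: [
        CutoffSpec(method="fixed_percentile", percentile=25.0),
        CutoffSpec(method="youden"),
    ])
    nu_grid: tuple = (0.25, 0.50, 0.75)
    n_permutations: int = 0
    seed: int = 0
    use_continuous_score_for_c: bool = False
    delimiter: str = "\t"
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.cutoffs:
            raise ValueError("at least one cut-off specification is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cv" in raw:
            raw["cv"] = CVScheme(**raw["cv"])
        if "cutoffs" in raw:
            raw["cutoffs"] = [CutoffSpec(**c) for c in raw["cutoffs"]]
        for key in ("t_cell_types", "nu_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortReport:
    """Table-shaped summary of one cohort (or one stratum)."""

    name: str
    n_patients: int
    n_events: int
    cutoff_reports: list

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "cutoffs": self.cutoff_reports,
        }

    def summary_table(self) -> pd.DataFrame:
        """Rows shaped like the published per-cut-off summary tables."""
        rows = []
        for c in self.cutoff_reports:
            cs = c["concordance"]
            rows.append({
                "cohort": self.name,
                "percentile_cutoff": round(c["percentile"], 2),
                "n_low": c["n_low"],
                "pct_low": round(c["pct_low"], 1),
                "avg_c_index": round(cs["mean_c"], 4),
                "c_index_ci_lower": round(cs["ci_lower"], 4),
                "c_index_ci_upper": round(cs["ci_upper"], 4),
                "log_rank_p": c["logrank"]["p_value"],
                "cox_hr": round(c["cox"]["hazard_ratio"], 4),
                "cox_p": c["cox"]["p_value"],
            })
        return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig):
    expr = to_linear_tpm(read_expression_matrix(config.expression_path, config.delimiter))
    sig = read_signature_matrix(config.signature_path, config.t_cell_types,
                                config.cd8_type, config.delimiter)
    surv = pd.read_csv(config.survival_path, sep=config.delimiter, dtype={"patient_id": str})
    surv = surv.set_index("patient_id")
    return expr, sig, surv


def _join_cohort(expr, surv):
    expr_ids = list(expr.sample_ids)
    shared = [pid for pid in expr_ids if pid in surv.index]
    dropped = sorted((set(expr_ids) | set(surv.index)) - set(shared))
    if dropped:
        logger.warning("dropping %d patient(s) absent from one input: %s",
                       len(dropped), ", ".join(dropped[:10]))
    if not shared:
        raise ValueError("no patients shared between expression and survival inputs")
    return shared


def _survival_records(surv: pd.DataFrame, ids):
    return [SurvivalRecord(pid, surv.loc[pid, "time_months"], surv.loc[pid, "event"])
            for pid in ids]


def _iteration_categories(per_iter_scores: np.ndarray, percentile: float) -> np.ndarray:
    """Binary category per patient within each CV iteration's score column."""
    cats = np.empty_like(per_iter_scores, dtype=int)
    for it in range(per_iter_scores.shape[1]):
        thr = np.percentile(per_iter_scores[:, it], percentile)
        cats[:, it] = (per_iter_scores[:, it] >= thr).astype(int)
    return cats


def _evaluate_cutoff(cutoff: CutoffSpec, score_result, densities, records,
                     events, scheme: CVScheme, use_continuous: bool,
                     outdir: Path | None, tag: str) -> dict:
    if cutoff.method == YOUDEN and cutoff.resolved_percentile is None:
        cutoff = cv_youden_cutoff(densities, events, scheme)
    pct = cutoff.effective_percentile
    result = categorize(score_result, cutoff)
    category = result.category
    n_low = int((category == 0).sum())

    lr = logrank_test(records, category) if 0 < n_low < len(category) else None
    cox = cox_binary_hr(records, category) if 0 < n_low < len(category) else None

    per_iter = score_result.per_iteration_scores
    if use_continuous:
        c_values = [harrell_c(records, per_iter[:, it]) for it in range(per_iter.shape[1])]
    else:
        cats = _iteration_categories(per_iter, pct)
        c_values = [harrell_c(records, cats[:, it]) for it in range(cats.shape[1])]
    conc = summarize_c(c_values)

    km_paths = {}
    if outdir is not None:
        for g, label in ((0, "low"), (1, "intermediate_high")):
            idx = np.flatnonzero(category == g)
            if idx.size == 0:
                continue
            curve = kaplan_meier([records[i] for i in idx])
            p = outdir / f"km_{tag}_{label}.tsv"
            curve.to_frame().to_csv(p, sep="\t", index=False)
            km_paths[label] = str(p)

    return {
        "method": cutoff.method,
        "percentile": float(pct),
        "n_low": n_low,
        "pct_low": 100.0 * n_low / len(category),
        "logrank": (None if lr is None
                    else {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}),
        "cox": (None if cox is None else {
            "hazard_ratio": cox.hazard_ratio, "log_hazard_ratio": cox.log_hazard_ratio,
            "ci_lower": cox.ci_lower, "ci_upper": cox.ci_upper,
            "p_value": cox.p_value, "monotone": cox.monotone,
        }),
        "concordance": {
            "mean_c": conc.mean_c, "ci_lower": conc.ci_lower,
            "ci_upper": conc.ci_upper,
            "per_iteration_c": [float(v) for v in conc.per_iteration_c],
        },
        "km_exports": km_paths,
        "categories": {str(pid): int(c) for pid, c in zip(result.patient_ids, category)},
    }


def _analyze(name: str, densities: TCellDensities, records, events,
             config: PipelineConfig, outdir: Path | None) -> CohortReport:
    scheme = CVScheme(config.cv.n_iterations, config.cv.n_folds,
                      config.cv.seed, config.cv.stratify_on_event)
    score_result = cv_immunoscore(densities, scheme, events=events)
    reports = []
    for i, cutoff in enumerate(config.cutoffs):
        tag = f"{name}_{cutoff.method}_{i}"
        reports.append(_evaluate_cutoff(
            cutoff, score_result, densities, records, events, scheme,
            config.use_continuous_score_for_c, outdir, tag,
        ))
    if outdir is not None:
        score_result.to_frame(wide_iterations=False).to_csv(
            outdir / f"scores_{name}.tsv", sep="\t")
    return CohortReport(
        name=name, n_patients=len(records),
        n_events=int(sum(r.event for r in records)), cutoff_reports=reports,
    )


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> CohortReport:
    """Execute the whole-cohort analysis; deterministic given config.seed."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    outdir = Path(config.output_dir) if write_outputs else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    expr, sig, surv = _load_inputs(config)
    ids = _join_cohort(expr, surv)
    expr_frame = expr.to_frame()[ids]
    logger.info("joined cohort: %d patients", len(ids))

    t1 = time.time()
    from .expression_io import ExpressionMatrix
    expr_joined = ExpressionMatrix(expr.gene_ids, ids, expr_frame.to_numpy(), "linear")
    fractions = deconvolve_cohort(
        expr_joined, sig, nu_grid=config.nu_grid,
        n_permutations=config.n_permutations, seed=config.seed,
    )
    logger.info("deconvolution: %d samples in %.1fs", len(ids), time.time() - t1)
    densities = impute_t_cell_densities(fractions, sig)

    records = _survival_records(surv, ids)
    events = np.array([r.event for r in records])
    report = _analyze("whole_cohort", densities, records, events, config, outdir)
    logger.info("pipeline finished in %.1fs", time.time() - t0)

    if outdir is not None:
        fractions.write_tsv(outdir / "cell_fractions.tsv")
        densities.to_frame().to_csv(outdir / "densities.tsv", sep="\t")
        with open(outdir / "report_whole_cohort.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        report.summary_table().to_csv(outdir / "summary_whole_cohort.tsv",
                                      sep="\t", index=False)
    return report


def stratified_report(config: PipelineConfig, strata=None,
                      write_outputs: bool = True) -> dict:
    """Repeat the analysis independently within each cancer-type stratum.

    Deconvolution is per-sample and therefore identical whether run per
    stratum or once; it is run once and subset.  Scoring, cut-off
    resolution (including stratum-specific Youden percentiles) and all
    survival statistics are recomputed within each stratum.  Strata with
    fewer patients than folds, no events, or a single category are skipped
    with a logged reason.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir) if write_outputs else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    expr, sig, surv = _load_inputs(config)
    ids = _join_cohort(expr, surv)
    if strata is None:
        if "cancer_type" not in surv.columns:
            raise ValueError("no strata given and no cancer_type column in survival table")
        strata = {pid: surv.loc[pid, "cancer_type"] for pid in ids}
    else:
        strata = {pid: strata[pid] for pid in ids}

    from .expression_io import ExpressionMatrix
    expr_frame = expr.to_frame()[ids]
    expr_joined = ExpressionMatrix(expr.gene_ids, ids, expr_frame.to_numpy(), "linear")
    fractions = deconvolve_cohort(expr_joined, sig, nu_grid=config.nu_grid, seed=config.seed)
    densities = impute_t_cell_densities(fractions, sig)
    dens_frame = densities.to_frame()

    reports = {}
    for name in sorted(set(strata.values())):
        sub_ids = [pid for pid in ids if strata[pid] == name]
        records = _survival_records(surv, sub_ids)
        events = np.array([r.event for r in records])
        if len(sub_ids) < config.cv.n_folds:
            logger.warning("stratum %s skipped: %d patients < %d folds",
                           name, len(sub_ids), config.cv.n_folds)
            continue
        if events.sum() == 0:
            logger.warning("stratum %s skipped: no events", name)
            continue
        sub_dens = TCellDensities(
            sub_ids, dens_frame.loc[sub_ids, "cd3"].to_numpy(),
            dens_frame.loc[sub_ids, "cd8"].to_numpy(),
        )
        try:
            reports[name] = _analyze(name, sub_dens, records, events, config, outdir)
        except ValueError as exc:
            logger.warning("stratum %s skipped: %s", name, exc)

    if outdir is not None:
        combined = {k: r.to_dict() for k, r in reports.items()}
        with open(outdir / "report_strata.json", "w") as fh:
            json.dump(combined, fh, indent=2, sort_keys=True)
        if reports:
            pd.concat([r.summary_table() for r in reports.values()]).to_csv(
                outdir / "summary_strata.tsv", sep="\t", index=False)
    return reports
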