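"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the data shapes the analysis consumes: an LM22-like
signature matrix (547 genes x 22 immune cell types, 7 of them T-cell
subsets), Dirichlet-distributed true cell fractions, bulk mixtures with
multiplicative log-normal noise, and exponential survival whose hazard
falls log-linearly with the patient's CD3+ T-cell abundance, under
independent administrative right-censoring.  Cancer-type labels are dealt
round-robin so strata are near-equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deconvolution import CellFractions, TCellDensities
from .expression_io import (ExpressionMatrix, SignatureMatrix,
                            write_expression_matrix, write_signature_matrix)
from .survival_stats import SurvivalRecord

# LM22-style naming: the seven T-cell subsets first, CD8 leading.
_LM22_LIKE_TYPES = [
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
]

_CANCER_TYPES_4 = ["melanoma", "head_and_neck", "nsclc", "rcc"]


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated ICI-treated cohort.

    Defaults mirror the analysis setting: a 547 x 22 signature with 7 T-cell
    subsets, four near-equal cancer strata, a baseline hazard giving a
    median time-to-death of 10.5 months, a protective CD3 effect
    (negative log-hazard per unit CD3 fraction), and a censoring fraction
    close to the cohort's observed 47% non-event rate.
    """

    n_genes: int = 547
    n_cell_types: int = 22
    n_t_cell_types: int = 7
    n_patients: int = 200
    dirichlet_concentration: np.ndarray | None = None  # default: all ones
    noise_sd: float = 0.3
    baseline_hazard: float = float(np.log(2) / 10.5)  # events/month
    log_hr_per_unit_cd3: float = -5.0
    censoring_rate: float = 0.47
    n_cancer_types: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_cell_types", "n_t_cell_types",
                     "n_patients", "n_cancer_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.dirichlet_concentration is not None:
            conc = np.asarray(self.dirichlet_concentration, dtype=float)
            if conc.shape != (self.n_cell_types,) or np.any(conc <= 0):
                raise ValueError("dirichlet_concentration needs one positive value per cell type")
            self.dirichlet_concentration = conc


@dataclass
class SyntheticCohort:
    """Everything a full pipeline run needs, plus the generating truth."""

    signature: SignatureMatrix
    true_fractions: CellFractions
    expression: ExpressionMatrix
    survival: list
    cancer_type: list
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def true_densities(self) -> TCellDensities:
        import pandas as pd
        frame = pd.DataFrame(self.true_fractions.fractions,
                             columns=self.true_fractions.cell_types)
        cd3 = frame[list(self.signature.t_cell_types)].sum(axis=1).to_numpy()
        cd8 = frame[self.signature.cd8_type].to_numpy()
        return TCellDensities(list(self.true_fractions.sample_ids), cd3, cd8)


def _type_names(n_cell_types: int, n_t_cell_types: int):
    if n_cell_types == len(_LM22_LIKE_TYPES) and n_t_cell_types == 7:
        return list(_LM22_LIKE_TYPES)
    t = [f"T_{i + 1}" for i in range(n_t_cell_types)]
    other = [f"CellType_{i + 1}" for i in range(n_cell_types - n_t_cell_types)]
    return t + other


def make_signature(n_genes: int = 547, n_cell_types: int = 22,
                   n_t_cell_types: int = 7, seed: int = 0,
                   marker_fold: float = 30.0) -> SignatureMatrix:
    """Draw a well-conditioned synthetic signature matrix.

    Each cell type receives a dedicated block of marker genes up-regulated
    by ``marker_fold`` over a shared log-normal background, so the
    standardized matrix keeps a condition number far below 100.  The first
    ``n_t_cell_types`` columns are declared T-cell subsets, the first of
    them as the CD8 subset.
    """
    if n_t_cell_types >= n_cell_types:
        raise ValueError("n_t_cell_types must be smaller than n_cell_types")
    if n_genes < 2 * n_cell_types:
        raise ValueError(
            f"need at least {2 * n_cell_types} genes to allocate 2 markers "
            f"per cell type, got {n_genes}"
        )
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=1.0, sigma=0.6, size=(n_genes, n_cell_types))
    markers_per_type = n_genes // n_cell_types
    for k in range(n_cell_types):
        rows = slice(k * markers_per_type, (k + 1) * markers_per_type)
        base[rows, k] *= marker_fold
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    types = _type_names(n_cell_types, n_t_cell_types)
    return SignatureMatrix(
        gene_ids=genes, cell_types=types, values=base,
        t_cell_types=tuple(types[:n_t_cell_types]), cd8_type=types[0],
    )


def _cancer_labels(n_patients: int, n_cancer_types: int):
    names = (_CANCER_TYPES_4 if n_cancer_types == 4
             else [f"cancer_{i + 1}" for i in range(n_cancer_types)])
    return [names[i % n_cancer_types] for i in range(n_patients)]


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Simulate a cohort under the generating model described above.

    Deterministic given ``config.seed``: independent child generators are
    spawned for the signature, fractions, expression noise, survival times
    and censoring so changing one condition leaves the other draws intact.
    """
    root = np.random.SeedSequence(config.seed)
    s_sig, s_frac, s_noise, s_surv, s_cens = root.spawn(5)

    signature = make_signature(
        config.n_genes, config.n_cell_types, config.n_t_cell_types,
        seed=s_sig,
    )
    rng_frac = np.random.default_rng(s_frac)
    conc = (config.dirichlet_concentration
            if config.dirichlet_concentration is not None
            else np.ones(config.n_cell_types))
    fractions = rng_frac.dirichlet(conc, size=config.n_patients)
    patient_ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]

    clean = signature.values @ fractions.T  # genes x patients
    rng_noise = np.random.default_rng(s_noise)
    if config.noise_sd > 0:
        noise = rng_noise.lognormal(mean=0.0, sigma=config.noise_sd, size=clean.shape)
        expr_values = clean * noise
    else:
        expr_values = clean
    expression = ExpressionMatrix(
        gene_ids=list(signature.gene_ids), sample_ids=patient_ids,
        values=expr_values, scale_tag="linear",
    )

    cd3 = fractions[:, :config.n_t_cell_types].sum(axis=1)
    hazard = config.baseline_hazard * np.exp(
        config.log_hr_per_unit_cd3 * (cd3 - cd3.mean())
    )
    rng_surv = np.random.default_rng(s_surv)
    event_times = rng_surv.exponential(1.0 / hazard)
    rng_cens = np.random.default_rng(s_cens)
    censored = rng_cens.random(config.n_patients) < config.censoring_rate
    frac_observed = rng_cens.uniform(size=config.n_patients)
    times = np.where(censored, event_times * frac_observed, event_times)
    times = np.maximum(times, 1e-9)
    survival = [
        SurvivalRecord(pid, t, 0 if c else 1)
        for pid, t, c in zip(patient_ids, times, censored)
    ]

    true_fracs = CellFractions(
        sample_ids=patient_ids, cell_types=list(signature.cell_types),
        fractions=fractions,
        fit_rmse=np.zeros(config.n_patients),
        fit_corr=np.ones(config.n_patients),
    )
    return SyntheticCohort(
        signature=signature, true_fractions=true_fracs, expression=expression,
        survival=survival,
        cancer_type=_cancer_labels(config.n_patients, config.n_cancer_types),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write all cohort artifacts in the TSV dialects the pipeline reads."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "signature": outdir / "signature.tsv",
        "survival": outdir / "survival.tsv",
        "true_fractions": outdir / "true_fractions.tsv",
    }
    write_expression_matrix(cohort.expression, paths["expression"])
    write_signature_matrix(cohort.signature, paths["signature"])
    surv = pd.DataFrame({
        "patient_id": [r.patient_id for r in cohort.survival],
        "time_months": [r.time for r in cohort.survival],
        "event": [r.event for r in cohort.survival],
        "cancer_type": cohort.cancer_type,
    })
    surv.to_csv(paths["survival"], sep="\t", index=False)
    cohort.true_fractions.to_frame().to_csv(paths["true_fractions"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
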