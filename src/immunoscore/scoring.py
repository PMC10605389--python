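"""Cross-validated percentile immunoscore and cut-off selection.

The immunoscore of a patient is the mean of the empirical percentiles of
their CD3+ and CD8+ T-cell densities among a training population.  To avoid
over-fitting, the percentile functions are defined on four of five folds and
evaluated on the held-out fold, repeated for 20 random fold assignments; a
patient's final score is the average of their 20 held-out scores.

Patients are dichotomized into low (0) versus intermediate-high (1) at
either a fixed percentile cut-off (default 25th) or a data-driven cut-off
maximizing Youden's J statistic, averaged over the cross-validation
iterations on the percentile scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

FIXED_PERCENTILE = "fixed_percentile"
YOUDEN = "youden"


@dataclass
class CVScheme:
    """Repeated k-fold scheme for the percentile functions.

    ``stratify_on_event`` keeps both outcome classes represented in every
    training split when an event indicator is supplied.
    """

    n_iterations: int = 20
    n_folds: int = 5
    seed: int = 0
    stratify_on_event: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class CutoffSpec:
    """How the low / intermediate-high boundary is chosen.

    ``method`` is ``fixed_percentile`` (use ``percentile`` directly, default
    25) or ``youden`` (``resolved_percentile`` filled in by
    :func:`cv_youden_cutoff`).
    """

    method: str = FIXED_PERCENTILE
    percentile: float = 25.0
    resolved_percentile: float | None = None

    def __post_init__(self):
        if self.method not in (FIXED_PERCENTILE, YOUDEN):
            raise ValueError(f"unknown cut-off method {self.method!r}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie strictly inside (0, 100)")
        if self.resolved_percentile is not None and not 0 < self.resolved_percentile < 100:
            raise ValueError("resolved_percentile must lie strictly inside (0, 100)")

    @property
    def effective_percentile(self) -> float:
        if self.method == YOUDEN:
            if self.resolved_percentile is None:
                raise ValueError("youden cut-off not resolved yet")
            return self.resolved_percentile
        return self.percentile


@dataclass
class ImmunoscoreResult:
    """Per-patient immunoscore: CV-averaged score in [0, 100] plus category."""

    patient_ids: list
    score: np.ndarray
    per_iteration_scores: np.ndarray
    category: np.ndarray | None = None
    cutoff_used: CutoffSpec | None = None

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        self.per_iteration_scores = np.asarray(self.per_iteration_scores, dtype=float)
        n = len(self.patient_ids)
        if self.per_iteration_scores.shape[0] != n or self.score.shape != (n,):
            raise ValueError("score shapes do not match patient_ids")
        if not np.allclose(self.score, self.per_iteration_scores.mean(axis=1), atol=1e-9):
            raise ValueError("score must equal the row mean of per_iteration_scores")
        if np.any(self.score < 0) or np.any(self.score > 100):
            raise ValueError("scores must lie in [0, 100]")
        if self.category is not None:
            self.category = np.asarray(self.category, dtype=int)
            if not np.isin(self.category, (0, 1)).all():
                raise ValueError("category must be 0 or 1")

    def to_frame(self, wide_iterations: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame({"score": self.score}, index=self.patient_ids)
        if self.category is not None:
            frame["category"] = self.category
        if wide_iterations:
            for i in range(self.per_iteration_scores.shape[1]):
                frame[f"iter_{i + 1}"] = self.per_iteration_scores[:, i]
        frame.index.name = "patient_id"
        return frame


def empirical_percentile(training_values, query) -> float | np.ndarray:
    """Mid-rank empirical percentile of ``query`` among ``training_values``.

    Returns ``100 * (#{t < q} + 0.5 * #{t == q}) / n``; ties contribute half
    a count, so a query equal to every training value scores 50.  ``query``
    may be a scalar or an array.
    """
    t = np.sort(np.asarray(training_values, dtype=float))
    if t.size == 0:
        raise ValueError("training set must be non-empty")
    q = np.asarray(query, dtype=float)
    below = np.searchsorted(t, q, side="left")
    at = np.searchsorted(t, q, side="right") - below
    pct = 100.0 * (below + 0.5 * at) / t.size
    return float(pct) if np.isscalar(query) or q.ndim == 0 else pct


def pair_percentile_score(cd3_percentile, cd8_percentile):
    """Mean of the CD3 and CD8 percentiles (both must lie in [0, 100])."""
    p3 = np.asarray(cd3_percentile, dtype=float)
    p8 = np.asarray(cd8_percentile, dtype=float)
    if np.any(p3 < 0) or np.any(p3 > 100) or np.any(p8 < 0) or np.any(p8 > 100):
        raise ValueError("percentiles must lie in [0, 100]")
    out = (p3 + p8) / 2.0
    return float(out) if out.ndim == 0 else out


def _fold_assignments(n: int, scheme: CVScheme, events=None) -> np.ndarray:
    """(n_iterations, n) fold labels, deterministic given the scheme seed.

    With stratification, each outcome class is permuted separately and dealt
    round-robin so every fold holds a near-proportional share of each class.
    """
    if n < scheme.n_folds:
        raise ValueError(f"need at least {scheme.n_folds} patients, got {n}")
    root = np.random.SeedSequence(scheme.seed)
    folds = np.empty((scheme.n_iterations, n), dtype=int)
    for it, child in enumerate(root.spawn(scheme.n_iterations)):
        rng = np.random.default_rng(child)
        if scheme.stratify_on_event and events is not None:
            ev = np.asarray(events, dtype=int)
            labels = np.empty(n, dtype=int)
            offset = rng.integers(scheme.n_folds)
            for cls in np.unique(ev):
                idx = np.flatnonzero(ev == cls)
                idx = rng.permutation(idx)
                labels[idx] = (np.arange(idx.size) + offset) % scheme.n_folds
                offset += idx.size
            folds[it] = labels
        else:
            perm = rng.permutation(n)
            labels = np.empty(n, dtype=int)
            labels[perm] = np.arange(n) % scheme.n_folds
            folds[it] = labels
    return folds


def _iteration_scores(cd3: np.ndarray, cd8: np.ndarray, folds: np.ndarray) -> np.ndarray:
    """Held-out percentile scores, one column per CV iteration."""
    n_iter, n = folds.shape
    scores = np.empty((n, n_iter))
    for it in range(n_iter):
        for f in np.unique(folds[it]):
            test = folds[it] == f
            train = ~test
            p3 = empirical_percentile(cd3[train], cd3[test])
            p8 = empirical_percentile(cd8[train], cd8[test])
            scores[test, it] = pair_percentile_score(p3, p8)
    return scores


class CVPercentileImmunoscore(BaseEstimator):
    """Cross-validated percentile immunoscore as a scikit-learn estimator.

    ``fit`` takes a :class:`~immunoscore.deconvolution.TCellDensities` (or a
    DataFrame with ``cd3``/``cd8`` columns) and an optional event indicator
    ``y`` used for fold stratification; fitted attributes hold the
    per-iteration and averaged scores.

    Parameters mirror :class:`CVScheme`.
    """

    def __init__(self, n_iterations=20, n_folds=5, random_state=0, stratify_on_event=True):
        self.n_iterations = n_iterations
        self.n_folds = n_folds
        self.random_state = random_state
        self.stratify_on_event = stratify_on_event

    def _scheme(self) -> CVScheme:
        return CVScheme(self.n_iterations, self.n_folds, self.random_state,
                        self.stratify_on_event)

    def fit(self, X, y=None):
        cd3, cd8, ids = _densities_arrays(X)
        scheme = self._scheme()
        folds = _fold_assignments(len(ids), scheme, events=y)
        self.per_iteration_scores_ = _iteration_scores(cd3, cd8, folds)
        self.scores_ = self.per_iteration_scores_.mean(axis=1)
        self.patient_ids_ = ids
        self.folds_ = folds
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).scores_

    def result_(self) -> ImmunoscoreResult:
        return ImmunoscoreResult(
            patient_ids=self.patient_ids_, score=self.scores_,
            per_iteration_scores=self.per_iteration_scores_,
        )


def _densities_arrays(densities):
    if hasattr(densities, "cd3") and hasattr(densities, "cd8"):
        return (np.asarray(densities.cd3, float), np.asarray(densities.cd8, float),
                list(densities.sample_ids))
    frame = pd.DataFrame(densities)
    return (frame["cd3"].to_numpy(float), frame["cd8"].to_numpy(float),
            list(frame.index))


def cv_immunoscore(densities, scheme: CVScheme = CVScheme(), events=None) -> ImmunoscoreResult:
    """Compute CV-averaged percentile immunoscores (category left unset)."""
    est = CVPercentileImmunoscore(
        n_iterations=scheme.n_iterations, n_folds=scheme.n_folds,
        random_state=scheme.seed, stratify_on_event=scheme.stratify_on_event,
    ).fit(densities, y=events)
    return est.result_()


def youden_cutoff(scores, labels, candidates=None):
    """Cut-off maximizing Youden's J for a protective score.

    Label 1 (death) is the positive class and ``score < c`` the positive
    test, so ``J(c) = sensitivity + specificity - 1``.  Candidates default
    to midpoints between consecutive distinct sorted scores; ties in J break
    toward the smallest cut-off.  Returns ``(cutoff, J)``.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if candidates is None:
        distinct = np.unique(s)
        if distinct.size < 2:
            raise ValueError("all scores identical: no candidate cut-offs")
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.sort(np.asarray(candidates, dtype=float))
    # sensitivity(c) = P(score < c | death); specificity(c) = P(score >= c | alive)
    # J = tp/n_pos - fp/n_neg has the exact integer numerator
    # tp*n_neg - fp*n_pos over the constant denominator n_pos*n_neg, so the
    # maximizer (and its ties) is found in integer arithmetic.
    pos_sorted = np.sort(s[lab == 1])
    neg_sorted = np.sort(s[lab == 0])
    tp = np.searchsorted(pos_sorted, candidates, side="left").astype(np.int64)
    fp = np.searchsorted(neg_sorted, candidates, side="left").astype(np.int64)
    numerator = tp * n_neg - fp * n_pos
    best = int(np.argmax(numerator))  # argmax takes the first (smallest) maximizer
    return float(candidates[best]), float(numerator[best] / (n_pos * n_neg))


def cv_youden_cutoff(densities, survival_labels, scheme: CVScheme = CVScheme()) -> CutoffSpec:
    """Average per-iteration Youden cut-offs on the percentile scale.

    For each CV iteration, the Youden-optimal cut-off is located on that
    iteration's score distribution and re-expressed as the mid-rank
    percentile of that distribution; the resolved cut-off is the mean over
    iterations.
    """
    cd3, cd8, ids = _densities_arrays(densities)
    lab = np.asarray(survival_labels, dtype=int)
    if lab.shape != (len(ids),):
        raise ValueError("survival_labels length must match densities")
    if lab.min() == lab.max():
        raise ValueError("both outcome classes must be present")
    folds = _fold_assignments(len(ids), scheme, events=lab)
    scores = _iteration_scores(cd3, cd8, folds)
    pcts = np.empty(scheme.n_iterations)
    for it in range(scheme.n_iterations):
        cut, _ = youden_cutoff(scores[:, it], lab)
        pcts[it] = empirical_percentile(scores[:, it], cut)
    return CutoffSpec(method=YOUDEN, resolved_percentile=float(pcts.mean()))


def categorize(result: ImmunoscoreResult, cutoff: CutoffSpec,
               reference_scores=None) -> ImmunoscoreResult:
    """Assign low (0) versus intermediate-high (1) categories.

    The threshold is the cut-off percentile of ``reference_scores`` (the
    cohort's own final scores by default); a score exactly at the threshold
    is intermediate-high, since "low" is the strict lower tail.
    """
    ref = np.asarray(
        result.score if reference_scores is None else reference_scores, dtype=float
    )
    threshold = float(np.percentile(ref, cutoff.effective_percentile))
    category = (result.score >= threshold).astype(int)
    return replace(result, category=category, cutoff_used=cutoff)
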