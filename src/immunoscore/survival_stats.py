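"""Survival estimation and comparison between immunoscore categories.

Kaplan-Meier curves (Greenwood variance, log(-log) 95% bands) and the
two-group log-rank test are delegated to lifelines.  Harrell's concordance
index is computed here with the orientation fixed so that a higher
(protective) score paired with longer survival counts as concordant, and
the univariate binary-covariate Cox model is fitted by Newton iteration on
the Breslow partial likelihood, giving a closed-form-checkable gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class SurvivalRecord:
    """One patient's follow-up from first ICI exposure.

    ``time`` is months to death (``event=1``) or to censoring (``event=0``,
    alive or lost to follow-up).  A time of exactly zero is shifted to 1e-6
    with a warning; negative times are invalid.
    """

    patient_id: str
    time: float
    event: int

    def __post_init__(self):
        self.time = float(self.time)
        self.event = int(self.event)
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.time == 0:
            warnings.warn(f"patient {self.patient_id!r}: time 0 shifted to 1e-6")
            self.time = 1e-6
        if self.time < 0:
            raise ValueError(f"patient {self.patient_id!r}: negative time")


def records_to_arrays(records):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def records_from_frame(frame: pd.DataFrame, time_col="time_months", event_col="event"):
    return [
        SurvivalRecord(str(i), row[time_col], row[event_col])
        for i, row in frame.iterrows()
    ]


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood-based 95% bands."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        for name in ("event_times", "survival", "ci_lower", "ci_upper", "n_at_risk"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(self.ci_lower > self.survival + 1e-9) or np.any(self.ci_upper < self.survival - 1e-9):
            raise ValueError("confidence band must bracket the estimate")

    @property
    def median(self) -> float:
        """Smallest event time with survival <= 0.5 (inf if never reached)."""
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_at_risk": self.n_at_risk.astype(int),
        })


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("log-rank statistic must be non-negative")


@dataclass
class ConcordanceSummary:
    """Mean C-index over CV iterations with a normal-approximation 95% CI."""

    per_iteration_c: np.ndarray
    mean_c: float
    ci_lower: float
    ci_upper: float


@dataclass
class CoxResult:
    """Univariate Cox fit for a binary group indicator (Breslow ties)."""

    log_hazard_ratio: float
    hazard_ratio: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    converged: bool = True
    monotone: bool = False


def kaplan_meier(records) -> KMCurve:
    """Kaplan-Meier estimate at the observed event times.

    The 95% band uses the exponential-Greenwood (log(-log)) transform, which
    stays inside [0, 1].
    """
    if not len(records):
        raise ValueError("need at least one record")
    t, e = records_to_arrays(records)
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        # all censored: survival identically 1 at each observed time
        times = np.unique(t)
        ones = np.ones_like(times)
        at_risk = np.array([(t >= u).sum() for u in times], dtype=float)
        return KMCurve(times, ones, ones, ones, at_risk)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(event_times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(event_times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=float)
    return KMCurve(event_times, surv, np.minimum(lo, surv), np.maximum(hi, surv), at_risk)


def logrank_test(records, group_labels) -> LogRankResult:
    """Two-group log-rank chi-square test (df = 1)."""
    t, e = records_to_arrays(records)
    g = np.asarray(group_labels, dtype=int)
    if g.shape != t.shape:
        raise ValueError("group_labels length must match records")
    if np.unique(g).size < 2:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(t[g == 0], t[g == 1], event_observed_A=e[g == 0],
                      event_observed_B=e[g == 1])
    return LogRankResult(statistic=float(res.test_statistic), df=1,
                         p_value=float(res.p_value))


def harrell_c(records, scores, tol: float = 0.0) -> float:
    """Harrell's concordance index for a protective score.

    A pair is comparable when the earlier time is an observed death (or the
    two times are tied with exactly one death).  A pair is concordant when
    the longer-surviving patient carries the HIGHER score; tied scores add
    half a count.  Returns concordant weight / comparable pairs.
    """
    t, e = records_to_arrays(records)
    s = np.asarray(scores, dtype=float)
    if s.shape != t.shape:
        raise ValueError("scores length must match records")
    # pair (i, j): i the earlier, uncensored death
    ti = t[:, None]
    tj = t[None, :]
    ei = e[:, None].astype(bool)
    ej = e[None, :].astype(bool)
    comparable = (ti < tj) & ei
    comparable |= (ti == tj) & ei & ~ej  # death vs same-time censored survivor
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    si = s[:, None]
    sj = s[None, :]
    concordant = (sj > si) & comparable
    tied = (np.abs(sj - si) <= tol) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def summarize_c(per_iteration_c) -> ConcordanceSummary:
    """Mean and normal-approximation 95% CI over CV-iteration C-indices."""
    c = np.asarray(per_iteration_c, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two iteration values")
    mean = float(c.mean())
    half = 1.96 * float(c.std(ddof=1)) / np.sqrt(c.size)
    return ConcordanceSummary(per_iteration_c=c, mean_c=mean,
                              ci_lower=mean - half, ci_upper=mean + half)


def _cox_grad_hess(beta: float, t, e, x):
    """Breslow partial-likelihood score and information for binary x."""
    order = np.argsort(-t, kind="stable")  # decreasing time
    t, e, x = t[order], e[order], x[order]
    w = np.exp(beta * x)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)  # x binary: S2 == S1
    grad = 0.0
    hess = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set = all with time >= t[i] = indices 0..j-1 in this ordering
        d = e[i:j].sum()
        if d > 0:
            mu = s1[j - 1] / s0[j - 1]
            grad += (x[i:j] * e[i:j]).sum() - d * mu
            hess += d * (mu - mu**2)
        i = j
    return grad, hess


def cox_binary_hr(records, group_labels, max_iter: int = 100,
                  grad_tol: float = 1e-8) -> CoxResult:
    """Univariate Cox hazard ratio for a binary group indicator.

    Newton-Raphson on the Breslow partial likelihood until the score
    function falls below ``grad_tol``.  If one group has no events the
    likelihood is monotone; the result is flagged rather than iterated to
    divergence.
    """
    t, e = records_to_arrays(records)
    x = np.asarray(group_labels, dtype=float)
    if x.shape != t.shape:
        raise ValueError("group_labels length must match records")
    if np.unique(x).size < 2:
        raise ValueError("both groups must be present")
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("group_labels must be binary 0/1")
    if e.sum() == 0:
        raise ValueError("no events in data")
    monotone = e[x == 1].sum() == 0 or e[x == 0].sum() == 0
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        grad, hess = _cox_grad_hess(beta, t, e, x)
        if abs(grad) < grad_tol:
            converged = True
            break
        if hess <= 0:
            break
        step = grad / hess
        beta += np.clip(step, -2.0, 2.0)  # damp early overshoot
        if monotone and abs(beta) > 20:
            break
    if not converged and not monotone:
        raise RuntimeError(f"Cox Newton iteration failed to converge in {max_iter} steps")
    _, hess = _cox_grad_hess(beta, t, e, x)
    se = float(1.0 / np.sqrt(hess)) if hess > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    if np.isfinite(se):
        with np.errstate(over="ignore"):  # flagged monotone fits have huge CIs
            lo, hi = float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))
    else:
        lo, hi = 0.0, float("inf")
    return CoxResult(
        log_hazard_ratio=float(beta), hazard_ratio=float(np.exp(beta)), se=se,
        ci_lower=lo, ci_upper=hi,
        p_value=p, converged=converged, monotone=bool(monotone),
    )
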