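"""Risk stratification by ROI involvement and its statistical validation.

Kaplan-Meier curves, two-group log-rank, univariate Cox hazard ratio
(Efron ties), fixed-horizon survival ROC with bootstrap CI, and the simple
cohort-characteristic tests (Pearson chi-square without continuity
correction, Welch/Student t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .core import GridMismatchError, LesionMask
from .vlsm import ROIMask

__all__ = [
    "RiskAssignment",
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "TimeROCResult",
    "assign_risk_groups",
    "km_estimate",
    "logrank_test",
    "cox_hazard_ratio",
    "roc_at_horizon",
    "pearson_chi2",
    "two_sample_ttest",
]


@dataclass
class RiskAssignment:
    """Per-patient high/low risk labels from ROI overlap (>= 1 voxel = high)."""

    table: pd.DataFrame  # patient_id, risk_group, overlapping_rois, columns n_overlap_<label>

    @property
    def risk_group(self) -> np.ndarray:
        return self.table["risk_group"].to_numpy()


@dataclass
class KMCurve:
    times: np.ndarray  # event-time grid (starts at 0)
    survival: np.ndarray  # S(t) estimates
    at_risk: np.ndarray  # number at risk entering each time
    censor_times: np.ndarray  # times of censored observations


@dataclass
class LogRankResult:
    statistic: float  # chi-square, df=1
    p_value: float
    observed: tuple[float, float]  # events per group (a, b)
    expected: tuple[float, float]


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    coef_se: float
    p_value: float
    reference_group: str
    orientation: str
    monotone_likelihood: bool = False

    @property
    def reciprocal(self) -> float:
        return 1.0 / self.hazard_ratio


@dataclass
class TimeROCResult:
    horizon: float
    auc: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int
    n_excluded_censored: int


# ---------------------------------------------------------------------------
# risk assignment


def assign_risk_groups(masks: Sequence[LesionMask], rois: Sequence[ROIMask]) -> RiskAssignment:
    """High-risk iff the lesion shares >= 1 voxel with any ROI; else low-risk."""
    if not rois:
        warnings.warn("no ROIs supplied: every patient is assigned low risk", stacklevel=2)
    rows = []
    for m in masks:
        counts = {}
        hit_labels = []
        for roi in rois:
            if not m.grid.matches(roi.grid):
                raise GridMismatchError(
                    f"patient {m.patient_id!r} mask and ROI {roi.label!r} grids differ"
                )
            c = int(np.logical_and(m.voxels, roi.mask).sum())
            counts[f"n_overlap_{roi.label}"] = c
            if c >= 1:
                hit_labels.append(roi.label)
        rows.append(
            {
                "patient_id": m.patient_id,
                "risk_group": "high" if hit_labels else "low",
                "overlapping_rois": ",".join(hit_labels),
                **counts,
            }
        )
    return RiskAssignment(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# survival statistics


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate (events precede censorings at ties)."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    table = kmf.event_table
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        censor_times=np.sort(t[e == 0]),
    )


def _observed_expected(ta, ea, tb, eb) -> tuple[tuple[float, float], tuple[float, float]]:
    """Observed and expected event counts per group over pooled event times."""
    pooled = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    oa = ob = exa = exb = 0.0
    for u in pooled:
        na = float(np.sum(ta >= u))
        nb = float(np.sum(tb >= u))
        da = float(np.sum((ta == u) & (ea == 1)))
        db = float(np.sum((tb == u) & (eb == 1)))
        d = da + db
        n = na + nb
        if n == 0:
            continue
        oa += da
        ob += db
        exa += d * na / n
        exb += d * nb / n
    return (oa, ob), (exa, exb)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (df=1) with per-group observed/expected counts."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group: log-rank p set to 1", stacklevel=2)
        return LogRankResult(statistic=0.0, p_value=1.0, observed=(0.0, 0.0), expected=(0.0, 0.0))
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    obs, exp = _observed_expected(ta, ea, tb, eb)
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        observed=obs,
        expected=exp,
    )


def cox_hazard_ratio(times, events, group_indicator, indicator_label: str = "low") -> CoxResult:
    """Univariate proportional-hazards HR for ``group_indicator`` (Efron ties).

    The hazard ratio is ``exp(coef)`` for indicator=1 vs indicator=0; pass
    the low-risk indicator to get the protective (< 1) orientation. Complete
    separation of event times (monotone likelihood) is flagged and the CI
    reported as unbounded.
    """
    t, e = _check_surv(times, events)
    g = np.asarray(group_indicator, dtype=int)
    if len(set(g.tolist())) < 2:
        raise ValueError("group indicator is constant: no contrast to estimate")
    for val in (0, 1):
        if e[g == val].sum() < 1:
            raise ValueError(f"group {val} has no events: hazard ratio not estimable")
    df = pd.DataFrame({"time": t, "event": e, "group": g})
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
    se = float(cph.standard_errors_["group"])
    coef = float(cph.params_["group"])
    monotone = any("convergence" in str(w.message).lower() for w in caught) or se > 50
    lo, hi = np.exp(coef - 1.959963984540054 * se), np.exp(coef + 1.959963984540054 * se)
    if monotone:
        lo, hi = 0.0, np.inf
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        coef_se=se,
        p_value=float(cph.summary.loc["group", "p"]),
        reference_group=f"{indicator_label}=0",
        orientation=f"hazard of {indicator_label}=1 relative to {indicator_label}=0",
        monotone_likelihood=bool(monotone),
    )


# ---------------------------------------------------------------------------
# fixed-horizon ROC


def _pairwise_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """P(case score > control score) + 0.5 * P(tie), via midranks."""
    n1, n0 = case_scores.size, control_scores.size
    ranks = stats.rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_at_horizon(
    marker,
    times,
    events,
    horizon: float,
    n_boot: int = 2000,
    seed: int | None = None,
) -> TimeROCResult:
    """AUC of a risk marker for death-by-horizon status.

    Cases died by the horizon; controls were followed beyond it; patients
    censored before the horizon are excluded. CI is a seeded percentile
    bootstrap over the included patients.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    t, e = _check_surv(times, events)
    m = np.asarray(marker, dtype=float)
    if m.shape != t.shape:
        raise ValueError("marker length does not match survival data")
    case = (t <= horizon) & (e == 1)
    control = t > horizon
    excluded = (t <= horizon) & (e == 0)
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"horizon {horizon}: need at least one case and one control "
            f"({int(case.sum())} cases, {int(control.sum())} controls after exclusions)"
        )
    auc = _pairwise_auc(m[case], m[control])

    rng = np.random.default_rng(seed)
    included = np.nonzero(case | control)[0]
    is_case = case[included]
    scores = m[included]
    boots = np.empty(n_boot)
    b = 0
    while b < n_boot:
        pick = rng.integers(0, included.size, size=included.size)
        c = is_case[pick]
        if c.all() or not c.any():
            continue  # degenerate resample: redraw
        boots[b] = _pairwise_auc(scores[pick][c], scores[pick][~c])
        b += 1
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return TimeROCResult(
        horizon=float(horizon),
        auc=auc,
        ci_lower=float(min(lo, auc)),
        ci_upper=float(max(hi, auc)),
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
        n_excluded_censored=int(excluded.sum()),
    )


# ---------------------------------------------------------------------------
# cohort-characteristic tests


def plot_km(curves: dict[str, KMCurve], path, title: str | None = None) -> None:
    """Step-plot KM curves per group to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, NO continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def two_sample_ttest(x, y, equal_variance: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    return float(res.statistic), float(res.pvalue)
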