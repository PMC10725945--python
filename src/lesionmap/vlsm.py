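"""Mass-univariate lesion-symptom mapping with permutation + FDR inference.

At every analyzed voxel the binary lesion indicator across patients is
regressed (OLS) on a design of [intercept, outcome, covariates]; the t
statistic of the outcome coefficient is the map statistic. The adverse
direction is fixed: ``t_adv = -t`` so that voxels whose lesioning co-occurs
with a LOWER outcome (worse function, shorter survival) score positive.
Significance combines a per-voxel one-sided permutation threshold with
Benjamini-Hochberg FDR on the permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import LesionStack, ReferenceGrid

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "StatMap",
    "PermutationNull",
    "ROIMask",
    "build_design",
    "voxel_inclusion",
    "default_min_lesion_count",
    "fit_voxelwise_glm",
    "permutation_null",
    "bh_fdr",
    "extract_roi",
    "run_vlsm",
]

OUTCOME_COLUMNS = {"kps": "kps", "os": "time"}
COVARIATE_COLUMNS = {"age": "age", "sex": "sex", "volume": "tumor_volume_cm3"}


@dataclass(frozen=True)
class DesignSpec:
    """Analysis settings for one lesion-symptom map."""

    outcome: Literal["kps", "os"]
    covariates: tuple[str, ...] = ("age", "sex", "volume")
    min_lesion_count: int | None = None  # None -> max(5, ceil(0.05 * n))
    alpha: float = 0.05
    n_permutations: int = 500
    seed: int = 0
    threshold_rule: Literal["pervoxel", "max", "none"] = "pervoxel"
    permutation_scheme: Literal["simple", "freedman_lane"] = "simple"
    log_time: bool = False  # use log(OS) as the outcome column

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be 'kps' or 'os', got {self.outcome!r}")
        unknown = [c for c in self.covariates if c not in COVARIATE_COLUMNS]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}; allowed: {sorted(COVARIATE_COLUMNS)}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError(
                "n_permutations must be >= 100: fewer permutations cannot resolve "
                "p-values finely enough for alpha=0.05 with FDR correction"
            )
        if self.min_lesion_count is not None and self.min_lesion_count < 1:
            raise ValueError("min_lesion_count must be >= 1")


@dataclass
class DesignMatrix:
    """Patient x regressor matrix: [intercept, outcome, covariates...]."""

    values: np.ndarray  # (n, p) float
    columns: list[str]
    outcome_index: int = 1

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class StatMap:
    """Voxelwise GLM results on the reference grid (NaN outside analyzed)."""

    grid: ReferenceGrid
    t: np.ndarray  # 3-D, t of the outcome coefficient
    beta: np.ndarray  # 3-D, outcome coefficient
    analyzed: np.ndarray  # 3-D uint8
    df: int

    @property
    def t_adv(self) -> np.ndarray:
        """Adverse-direction statistic: positive where lesions track worse outcome."""
        return -self.t

    def flat(self, volume: np.ndarray) -> np.ndarray:
        """Values of a 3-D map at analyzed voxels, C-order."""
        return volume.reshape(-1)[self.analyzed.reshape(-1).astype(bool)]


@dataclass
class PermutationNull:
    """Per-voxel permutation summaries for analyzed voxels (C-order)."""

    threshold: np.ndarray  # 95th percentile of the adverse-direction null
    pvalues: np.ndarray  # add-one one-sided permutation p
    max_stat: np.ndarray  # per-permutation max over voxels (for max-stat rule)
    n_permutations: int
    seed: int
    scheme: str


@dataclass
class ROIMask:
    """Significant-voxel mask with provenance."""

    mask: np.ndarray  # 3-D uint8
    grid: ReferenceGrid
    label: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# design


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"column {name!r} is constant: design would be rank deficient")
    return (x - x.mean()) / sd


def build_design(clinical: pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """Build [intercept, outcome, covariates] with z-scored continuous columns.

    Sex is coded male=1 / female=0. Raises on missing values, constant
    columns, or a rank-deficient result.
    """
    n = len(clinical)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]

    out_col = OUTCOME_COLUMNS[spec.outcome]
    needed = [out_col] + [COVARIATE_COLUMNS[c] for c in spec.covariates]
    for col in needed:
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
        vals = clinical[col]
        if vals.isna().any():
            bad = clinical.loc[vals.isna(), "patient_id"].tolist()
            raise ValueError(f"missing values in {col!r} for patients: {bad}")

    y = clinical[out_col].to_numpy(dtype=float)
    if spec.outcome == "os" and spec.log_time:
        y = np.log(y)
    cols.append(_standardize(y, spec.outcome))
    names.append(spec.outcome)

    for cov in spec.covariates:
        if cov == "sex":
            vals = (clinical["sex"] == "male").to_numpy(dtype=float)
            if vals.std() == 0:
                raise ValueError("column 'sex' is constant: design would be rank deficient")
            cols.append(vals)
        else:
            cols.append(_standardize(clinical[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float), cov))
        names.append(cov)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")
    return DesignMatrix(values=X, columns=names, outcome_index=1)


def default_min_lesion_count(n_patients: int) -> int:
    return max(5, int(np.ceil(0.05 * n_patients)))


def voxel_inclusion(stack: LesionStack, min_lesion_count: int) -> np.ndarray:
    """Analyzed-voxel mask: lesion count in [k, n - k] (3-D uint8).

    Symmetric exclusion removes voxels that are (nearly) constant in either
    direction, which would make the voxelwise fit degenerate.
    """
    counts = stack.lesion_counts()
    n = stack.n_patients
    ok = (counts >= min_lesion_count) & (counts <= n - min_lesion_count)
    if not ok.any():
        warnings.warn(
            f"no voxel passes the inclusion filter (k={min_lesion_count}, n={n})", stacklevel=2
        )
    return ok.reshape(stack.grid.shape).astype(np.uint8)


# ---------------------------------------------------------------------------
# fitting


def _ols_outcome_t(X: np.ndarray, Y: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of every column of Y on X; return (beta_j, t_j) for design column j.

    Y is (n, V); a voxel with a perfect fit (zero residual) gets t = NaN.
    """
    n, p = X.shape
    XtXinv = np.linalg.inv(X.T @ X)
    coef = XtXinv @ (X.T @ Y)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - p
    sigma2 = rss / df
    var_j = sigma2 * XtXinv[j, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[j] / np.sqrt(var_j)
    t[~np.isfinite(t)] = np.nan
    return coef[j], t


def fit_voxelwise_glm(stack: LesionStack, design: DesignMatrix, analyzed: np.ndarray) -> StatMap:
    """Fit the lesion indicator on the design at every analyzed voxel."""
    if design.n != stack.n_patients:
        raise ValueError("design rows do not match stack rows")
    flat = analyzed.reshape(-1).astype(bool)
    if not flat.any():
        raise ValueError("analyzed mask is empty")
    Y = stack.data[:, flat].astype(float)
    beta_v, t_v = _ols_outcome_t(design.values, Y, design.outcome_index)
    n_bad = int(np.isnan(t_v).sum())
    if n_bad:
        warnings.warn(f"{n_bad} analyzed voxels produced a degenerate fit (t=NaN)", stacklevel=2)

    shape = stack.grid.shape
    t3 = np.full(shape, np.nan)
    b3 = np.full(shape, np.nan)
    t3.reshape(-1)[flat] = t_v
    b3.reshape(-1)[flat] = beta_v
    return StatMap(
        grid=stack.grid,
        t=t3,
        beta=b3,
        analyzed=analyzed.astype(np.uint8),
        df=design.n - design.p,
    )


def permutation_null(
    stack: LesionStack,
    design: DesignMatrix,
    analyzed: np.ndarray,
    spec: DesignSpec,
    statmap: StatMap | None = None,
) -> PermutationNull:
    """Build the one-sided permutation null of the adverse-direction statistic.

    Simple scheme: the outcome column is permuted across patients, covariates
    and lesion data fixed. Freedman-Lane scheme: lesion indicators are
    replaced by reduced-model fits plus permuted reduced-model residuals.
    Per voxel the null is summarized by its 95th percentile and an add-one
    p-value ``(1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if statmap is None:
        statmap = fit_voxelwise_glm(stack, design, analyzed)
    flat = analyzed.reshape(-1).astype(bool)
    Y = stack.data[:, flat].astype(float)
    X = design.values
    j = design.outcome_index
    n, _ = X.shape
    V = Y.shape[1]
    t_obs = -statmap.t.reshape(-1)[flat]

    rng = np.random.default_rng(spec.seed)
    n_perm = spec.n_permutations
    perm_t = np.empty((n_perm, V), dtype=np.float32)

    if spec.permutation_scheme == "simple":
        Xp = X.copy()
        for r in range(n_perm):
            idx = rng.permutation(n)
            Xp[:, j] = X[idx, j]
            _, t = _ols_outcome_t(Xp, Y, j)
            perm_t[r] = -t
    elif spec.permutation_scheme == "freedman_lane":
        keep = [k for k in range(X.shape[1]) if k != j]
        Z = X[:, keep]
        Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        fitted = Hz @ Y
        resid = Y - fitted
        for r in range(n_perm):
            idx = rng.permutation(n)
            Yp = fitted + resid[idx]
            _, t = _ols_outcome_t(X, Yp, j)
            perm_t[r] = -t
    else:  # pragma: no cover
        raise ValueError(f"unknown permutation scheme {spec.permutation_scheme!r}")

    perm_t = np.nan_to_num(perm_t, nan=-np.inf)
    threshold = np.quantile(perm_t, 0.95, axis=0)
    t_cmp = np.where(np.isnan(t_obs), -np.inf, t_obs)
    exceed = (perm_t >= t_cmp[None, :]).sum(axis=0)
    pvalues = (1.0 + exceed) / (n_perm + 1.0)
    max_stat = perm_t.max(axis=1)
    return PermutationNull(
        threshold=threshold,
        pvalues=pvalues,
        max_stat=max_stat,
        n_permutations=n_perm,
        seed=spec.seed,
        scheme=spec.permutation_scheme,
    )


# ---------------------------------------------------------------------------
# inference


def bh_fdr(pvalues: Sequence[float], alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values).

    Rejects hypotheses 1..k for the largest k with p_(k) <= k*alpha/m;
    adjusted p-values are the usual monotone step-up transform.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= crit)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    return reject, adjusted


def extract_roi(
    statmap: StatMap,
    null: PermutationNull,
    spec: DesignSpec,
    label: str = "custom",
) -> ROIMask:
    """Threshold the map into an ROI: permutation threshold AND FDR rejection.

    A voxel enters the ROI iff its adverse-direction t exceeds the voxel's
    95th-percentile permutation threshold (or the max-statistic threshold /
    no threshold, per ``spec.threshold_rule``) and its permutation p-value
    survives BH-FDR at ``spec.alpha``. An empty ROI is a legitimate outcome.
    """
    flat = statmap.analyzed.reshape(-1).astype(bool)
    t_adv = -statmap.t.reshape(-1)[flat]
    t_cmp = np.where(np.isnan(t_adv), -np.inf, t_adv)

    if spec.threshold_rule == "pervoxel":
        above = t_cmp > null.threshold
    elif spec.threshold_rule == "max":
        above = t_cmp > np.quantile(null.max_stat, 0.95)
    elif spec.threshold_rule == "none":
        above = np.ones(t_cmp.size, dtype=bool)
    else:  # pragma: no cover
        raise ValueError(f"unknown threshold rule {spec.threshold_rule!r}")

    reject, _ = bh_fdr(null.pvalues, spec.alpha)
    sel = above & reject
    roi = np.zeros(statmap.grid.n_voxels, dtype=np.uint8)
    roi[np.nonzero(flat)[0][sel]] = 1
    return ROIMask(
        mask=roi.reshape(statmap.grid.shape),
        grid=statmap.grid,
        label=label,
        provenance={
            "outcome": spec.outcome,
            "covariates": list(spec.covariates),
            "alpha": spec.alpha,
            "n_permutations": null.n_permutations,
            "seed": null.seed,
            "threshold_rule": spec.threshold_rule,
            "permutation_scheme": null.scheme,
            "n_analyzed": int(flat.sum()),
            "n_roi": int(sel.sum()),
        },
    )


def run_vlsm(
    stack: LesionStack,
    clinical: pd.DataFrame,
    spec: DesignSpec,
    label: str = "custom",
) -> tuple[StatMap, PermutationNull, ROIMask]:
    """Full single-outcome analysis: design, inclusion, fit, null, ROI.

    An empty analyzed set (no voxel passes the inclusion filter) is a no-op:
    the returned statistic map and ROI are empty, with a warning already
    emitted by :func:`voxel_inclusion`.
    """
    design = build_design(clinical, spec)
    k = spec.min_lesion_count or default_min_lesion_count(stack.n_patients)
    analyzed = voxel_inclusion(stack, k)
    if not analyzed.any():
        shape = stack.grid.shape
        statmap = StatMap(
            grid=stack.grid,
            t=np.full(shape, np.nan),
            beta=np.full(shape, np.nan),
            analyzed=np.zeros(shape, dtype=np.uint8),
            df=design.n - design.p,
        )
        null = PermutationNull(
            threshold=np.zeros(0),
            pvalues=np.zeros(0),
            max_stat=np.zeros(spec.n_permutations),
            n_permutations=spec.n_permutations,
            seed=spec.seed,
            scheme=spec.permutation_scheme,
        )
        return statmap, null, extract_roi(statmap, null, spec, label=label)
    statmap = fit_voxelwise_glm(stack, design, analyzed)
    null = permutation_null(stack, design, analyzed, spec, statmap=statmap)
    roi = extract_roi(statmap, null, spec, label=label)
    return statmap, null, roi
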