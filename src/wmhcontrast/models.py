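"""Design matrices, linear and random-intercept model fits, descriptive tests.

Six model forms are supported, combining: the outcome (ordinal severity
entered as numeric 0/1/2, or log(volume+1) of total/regional WMH), the
two-group contrast (reference-coded indicator), the covariate set (base =
age + sex + education + diagnosis; vascular adds diabetes + hypertension +
BMI), a subject random intercept for longitudinal data, and optionally a
time-from-baseline trend with a group x time interaction (with age fixed at
its baseline value).

The random-intercept fit is restricted maximum likelihood, profiled down to
a one-dimensional search over the variance ratio lambda =
sigma_subject^2 / sigma_resid^2: for fixed lambda the GLS problem is solved
in closed form through the per-subject shrinkage transform
y_ij - theta_i * ybar_i with theta_i = 1 - 1/sqrt(1 + n_i * lambda).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import log1p_volume

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_ols",
    "fit_random_intercept",
    "welch_t",
    "chi_square",
    "harmonize_vascular_columns",
]

DAYS_PER_YEAR = 365.25

OUTCOME_COLUMNS = {
    "severity": "wmh_severity",
    "log_total": "wmh_total_mm3",
    "log_frontal": "wmh_frontal_mm3",
    "log_parietal": "wmh_parietal_mm3",
    "log_temporal": "wmh_temporal_mm3",
    "log_occipital": "wmh_occipital_mm3",
}

BASE_COVARIATES = ("age", "sex", "education", "diagnosis")
VASCULAR_COVARIATES = ("diabetes", "hypertension", "bmi")


class DesignError(ValueError):
    """Raised when a usable design matrix cannot be built."""


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient; names the columns."""


class ConvergenceError(RuntimeError):
    """REML search failed; carries the profile trace in ``trace``."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model forms.

    ``contrast`` is (target_group, reference_group); the reported group
    coefficient is the target-vs-reference offset. ``interaction`` implies
    ``longitudinal``.
    """

    outcome: Literal[
        "severity", "log_total", "log_frontal", "log_parietal",
        "log_temporal", "log_occipital",
    ]
    contrast: tuple[str, str]
    covariates: Literal["base", "vascular"] = "base"
    longitudinal: bool = False
    interaction: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.covariates not in ("base", "vascular"):
            raise ValueError(f"unknown covariate set {self.covariates!r}")
        if self.interaction and not self.longitudinal:
            raise ValueError("interaction models must be longitudinal")

    @property
    def formula(self) -> str:
        """Human-readable formula echoed in output metadata."""
        terms = ["Group"]
        terms += ["AgeBaseline" if self.interaction else "Age"]
        terms += ["Sex", "Education", "Diagnosis"]
        if self.covariates == "vascular":
            terms += ["Diabetes", "Hypertension", "BMI"]
        if self.interaction:
            terms += ["TimeFromBaseline", "Group:TimeFromBaseline"]
        rhs = " + ".join(terms)
        if self.longitudinal:
            rhs += " + (1|ID)"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitResult:
    """Coefficients and inference from one model fit.

    ``dof`` is the residual degrees of freedom convention used for p-values
    (t distribution for OLS; ``dof_method`` = "normal" means z-based
    p-values, the convention for the mixed model). Variance components are
    populated only for random-intercept fits.
    """

    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    dof: float
    dof_method: str
    n_obs: int
    n_subjects: int
    sigma2_resid: float
    sigma2_subject: float | None = None
    exact_fit: bool = False
    boundary: bool = False
    formula: str = ""
    n_dropped: int = 0

    def coef(self, name: str) -> tuple[float, float, float, float]:
        """(estimate, se, t, p) for a named coefficient."""
        i = self.names.index(name)
        return (
            float(self.estimates[i]),
            float(self.se[i]),
            float(self.tstats[i]),
            float(self.pvalues[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "t": self.tstats,
                "p": self.pvalues,
            },
            index=self.names,
        )


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, int]:
    """Build (response, design frame, subject ids, n_dropped) for a spec.

    Restricts to the two contrast groups, drops incomplete cases on all
    model variables (count returned), codes the group indicator with the
    reference group at 0, diagnosis dummies against NC, sex male=1, time in
    years, and log outcomes as natural log(volume mm^3 + 1). Baseline-only
    specs keep only time-0 rows.
    """
    target, reference = spec.contrast
    present = set(cohort["group"].unique())
    missing_groups = {target, reference} - present
    if missing_groups:
        raise DesignError(f"contrast groups absent from cohort: {missing_groups}")
    sub = cohort[cohort["group"].isin([target, reference])].copy()
    if not spec.longitudinal:
        t = pd.to_numeric(sub["time_from_baseline_days"], errors="coerce")
        sub = sub[t == 0]

    cols = ["age", "sex", "education", "diagnosis"]
    if spec.covariates == "vascular":
        cols += ["diabetes", "hypertension", "bmi"]
    outcome_col = OUTCOME_COLUMNS[spec.outcome]
    if outcome_col not in sub.columns:
        raise DesignError(f"outcome column {outcome_col!r} absent")
    model_cols = cols + [outcome_col, "time_from_baseline_days", "id"]
    n0 = len(sub)
    sub = sub.dropna(subset=[c for c in model_cols if c in sub.columns])
    n_dropped = n0 - len(sub)
    if len(sub) == 0:
        raise DesignError("zero complete cases after filtering")

    if spec.outcome == "severity":
        y = sub[outcome_col].to_numpy(dtype=float)
    else:
        y = log1p_volume(sub[outcome_col])

    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X["group"] = (sub["group"] == target).astype(float)
    if spec.interaction:
        # Baseline age: age at each participant's earliest visit.
        t = pd.to_numeric(sub["time_from_baseline_days"], errors="coerce")
        base_age = (
            sub.assign(_t=t)
            .sort_values(["id", "_t"], kind="mergesort")
            .drop_duplicates("id")
            .set_index("id")["age"]
        )
        X["age"] = sub["id"].map(base_age).to_numpy(dtype=float)
    else:
        X["age"] = sub["age"].to_numpy(dtype=float)
    X["sex"] = sub["sex"].to_numpy(dtype=float)
    X["education"] = sub["education"].to_numpy(dtype=float)
    X["dx_mci"] = (sub["diagnosis"] == "MCI").astype(float)
    X["dx_ad"] = (sub["diagnosis"] == "AD").astype(float)
    if spec.covariates == "vascular":
        X["diabetes"] = sub["diabetes"].to_numpy(dtype=float)
        X["hypertension"] = sub["hypertension"].to_numpy(dtype=float)
        X["bmi"] = sub["bmi"].to_numpy(dtype=float)
    if spec.interaction:
        years = (
            pd.to_numeric(sub["time_from_baseline_days"], errors="coerce")
            / DAYS_PER_YEAR
        )
        X["time_years"] = years.to_numpy(dtype=float)
        X["group_x_time"] = X["group"] * X["time_years"]

    constant = [
        c for c in X.columns if c != "const" and np.ptp(X[c].to_numpy()) == 0.0
    ]
    if constant:
        raise DesignError(f"constant design columns after filtering: {constant}")
    ids = sub["id"].to_numpy()
    return y, X, ids, n_dropped


def _qr_solve(
    X: np.ndarray, y: np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(beta, Rinv, rss, logdet XtX) via QR; raises on rank deficiency."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = diag <= tol
    if bad.any():
        raise RankDeficientError(
            f"design rank deficient; collinear columns: {[names[i] for i in np.flatnonzero(bad)]}"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    Rinv = np.linalg.solve(R, np.eye(R.shape[0]))
    logdet = float(2.0 * np.sum(np.log(diag)))
    return beta, Rinv, rss, logdet


def fit_ols(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
    formula: str = "",
    n_dropped: int = 0,
) -> FitResult:
    """Ordinary least squares with classical SEs and t-based p-values.

    An exactly interpolating fit (zero residual sum of squares) is flagged
    via ``exact_fit``; its t-statistics are +/-inf rather than an error.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = list(names) if names is not None else [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    beta, Rinv, rss, _ = _qr_solve(Xm, y, names)
    dof = n - p
    sigma2 = rss / dof
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    exact = rss <= max(1e-12 * float(y @ y), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return FitResult(
        names=names,
        estimates=beta,
        se=se,
        tstats=t,
        pvalues=pvals,
        dof=float(dof),
        dof_method="t",
        n_obs=n,
        n_subjects=n,
        sigma2_resid=sigma2,
        exact_fit=bool(exact),
        formula=formula,
        n_dropped=n_dropped,
    )


def _reml_negloglik(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    names: Sequence[str],
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """-2 restricted log-likelihood (profiled over sigma^2) at ratio lam.

    Returns (criterion, beta, Rinv of the transformed design, rss_tilde).
    """
    n, p = X.shape
    theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)
    # Subject means, then shrink each observation toward its subject mean.
    ytil = y.copy()
    Xtil = X.copy()
    for s, c, th in zip(starts, counts, theta):
        sl = slice(s, s + c)
        ytil[sl] -= th * y[sl].mean()
        Xtil[sl] -= th * X[sl].mean(axis=0)
    beta, Rinv, rss, logdet = _qr_solve(Xtil, ytil, names)
    crit = (
        float(np.sum(np.log1p(counts * lam)))
        + logdet
        + (n - p) * np.log(max(rss, 1e-300))
    )
    return crit, beta, Rinv, rss


def fit_random_intercept(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    ids: np.ndarray,
    names: Sequence[str] | None = None,
    formula: str = "",
    n_dropped: int = 0,
    max_ratio: float = 1e6,
    grid_size: int = 41,
) -> FitResult:
    """Linear model with one random intercept per subject, fit by REML.

    The variance ratio lambda = sigma_subject^2 / sigma_resid^2 is profiled
    out with a log-scale grid scan refined by bounded scalar minimization;
    the boundary lambda = 0 (no subject variance, reduction to OLS/GLS) is
    admitted and flagged. Fixed-effect p-values use the normal
    approximation.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = list(names) if names is not None else [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    ids = np.asarray(ids)
    n, p = Xm.shape
    if not (len(y) == n == len(ids)):
        raise ValueError("y, X and ids must have matching lengths")

    order = np.argsort(ids, kind="stable")
    y = y[order]
    Xm = Xm[order]
    ids_sorted = ids[order]
    uniq, starts, counts = np.unique(ids_sorted, return_index=True, return_counts=True)
    n_subjects = len(uniq)
    if n_subjects < 2:
        raise DesignError("random-intercept fit needs >= 2 subjects")
    if counts.max() < 2:
        raise DesignError(
            "no subject has repeated visits; subject variance is not identifiable"
        )
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")

    trace: list[tuple[float, float]] = []

    def crit(lam: float) -> float:
        c = _reml_negloglik(lam, y, Xm, starts, counts, names)[0]
        trace.append((lam, c))
        return c

    # Log-spaced grid (plus the boundary) to bracket the minimum, then a
    # bounded refinement around the best grid point.
    grid = np.concatenate([[0.0], np.geomspace(1e-4, max_ratio, grid_size)])
    vals = np.array([crit(l) for l in grid])
    if not np.all(np.isfinite(vals)):
        raise ConvergenceError("non-finite REML criterion on grid", trace)
    k = int(np.argmin(vals))
    if k == 0:
        lam_hat = 0.0
    else:
        lo = grid[k - 1]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi <= lo:
            hi = lo * 10 + 1.0
        res = optimize.minimize_scalar(
            crit, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        if not res.success:
            raise ConvergenceError(f"REML refinement failed: {res.message}", trace)
        lam_hat = float(res.x)
        if crit(0.0) < res.fun:
            lam_hat = 0.0

    _, beta, Rinv, rss = _reml_negloglik(lam_hat, y, Xm, starts, counts, names)
    sigma2_e = rss / (n - p)
    sigma2_u = lam_hat * sigma2_e
    cov = sigma2_e * (Rinv @ Rinv.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(t))
    return FitResult(
        names=names,
        estimates=beta,
        se=se,
        tstats=t,
        pvalues=pvals,
        dof=float(n - p),
        dof_method="normal",
        n_obs=n,
        n_subjects=n_subjects,
        sigma2_resid=float(sigma2_e),
        sigma2_subject=float(sigma2_u),
        boundary=bool(lam_hat == 0.0),
        formula=formula,
        n_dropped=n_dropped,
    )


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for ``spec`` and dispatch to the right fitter."""
    y, X, ids, n_dropped = build_design(cohort, spec)
    if spec.longitudinal:
        return fit_random_intercept(
            y, X, ids, formula=spec.formula, n_dropped=n_dropped
        )
    return fit_ols(y, X, formula=spec.formula, n_dropped=n_dropped)


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, Welch-Satterthwaite dof, two-sided p); the statistic is
    positive when group 1 has the larger mean.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(dof), float(res.pvalue)


def chi_square(counts: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k contingency table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(chi2), int(dof), float(p)


_HTN_SOURCES = ("HYPERT", "HXHYPER", "HYPERTEN")
_DM_SOURCES = ("DIABET", "DIABETES")


def _merge_indicator(table: pd.DataFrame, sources: Sequence[str]) -> pd.Series:
    present = [c for c in sources if c in table.columns]
    if not present:
        raise ValueError(f"none of the source columns {sources} present")
    block = table[present].apply(pd.to_numeric, errors="coerce")
    any_pos = (block == 1).any(axis=1)
    all_zero = (block == 0).all(axis=1)
    out = pd.Series(np.nan, index=table.index, dtype=float)
    out[any_pos] = 1.0
    out[all_zero & ~any_pos] = 0.0
    return out


def harmonize_vascular_columns(raw: pd.DataFrame) -> pd.DataFrame:
    """Merge NACC-style vascular source columns into the analysis columns.

    Hypertension = 1 if any of HYPERT/HXHYPER/HYPERTEN equals 1, 0 if at
    least one equals 0 and none equals 1, missing otherwise; same rule for
    diabetes from DIABET/DIABETES. NACCBMI passes through as ``bmi`` with
    values outside the plausible 12-70 kg/m^2 range set to missing.
    """
    out = raw.copy()
    out["hypertension"] = _merge_indicator(raw, _HTN_SOURCES)
    out["diabetes"] = _merge_indicator(raw, _DM_SOURCES)
    if "NACCBMI" in raw.columns:
        bmi = pd.to_numeric(raw["NACCBMI"], errors="coerce")
        bmi[(bmi < 12) | (bmi > 70)] = np.nan
        out["bmi"] = bmi
    elif "bmi" not in out.columns:
        raise ValueError("no BMI source column (NACCBMI or bmi) present")
    return out
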