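"""Matched-bootstrap resampling pipeline.

The headline procedure: repeat (match a reference subsample to the target
group, fit the model, record the group coefficient and its t-statistic)
over many iterations, then summarize with the median effect size, median t,
and percentile confidence intervals of the t distribution at the 95% and
99.5% levels. Vascular-adjusted and unadjusted runs can share the
per-iteration matched subsamples so attenuation comparisons are not
confounded by resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import baseline_rows
from .matching import Matcher, MatchPlan, expand_to_visits
from .models import (
    ModelSpec,
    build_design,
    fit_ols,
    fit_random_intercept,
)

__all__ = [
    "ResampleSummary",
    "aggregate_iterations",
    "run_resampled_contrast",
    "compare_adjustment",
    "run_regional_panel",
    "iteration_seed",
]

#: Default iteration count of the matched bootstrap.
DEFAULT_ITERATIONS = 1000

#: CI level whose exclusion-of-zero flag drives significance classification.
CLASSIFICATION_LEVEL = 0.995


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Deterministic per-iteration seed from (master seed, iteration index).

    Only the pair determines the value, so partial reruns of any iteration
    subset are reproducible.
    """
    ss = np.random.SeedSequence((int(master_seed), int(iteration)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ResampleSummary:
    """Aggregated results of one resampled contrast.

    Percentile CIs are of the per-iteration t-statistics;
    ``excludes_zero_*`` flags are true iff both interval bounds share sign.
    Per-iteration effects/t/p are retained for audit.
    """

    model: str
    contrast: tuple[str, str]
    coefficient: str
    n_iterations: int
    n_failed: int
    master_seed: int
    effects: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    median_effect: float
    median_t: float
    median_p: float
    ci95: tuple[float, float]
    ci995: tuple[float, float]
    excludes_zero_95: bool
    excludes_zero_995: bool

    def __post_init__(self) -> None:
        lo95, hi95 = self.ci95
        lo995, hi995 = self.ci995
        if not (lo995 <= lo95 and hi95 <= hi995):
            raise ValueError("99.5% CI must contain the 95% CI")

    @property
    def significant(self) -> bool:
        """Classification flag at the package's conservative default level."""
        return self.excludes_zero_995

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "contrast": f"{self.contrast[0]} vs {self.contrast[1]}",
            "coefficient": self.coefficient,
            "n_iterations": self.n_iterations,
            "n_failed": self.n_failed,
            "median_effect": self.median_effect,
            "median_t": self.median_t,
            "median_p": self.median_p,
            "ci995_lower": self.ci995[0],
            "ci995_upper": self.ci995[1],
            "ci95_lower": self.ci95[0],
            "ci95_upper": self.ci95[1],
            "excludes_zero_995": self.excludes_zero_995,
            "excludes_zero_95": self.excludes_zero_95,
        }


def aggregate_iterations(
    effects: Sequence[float],
    tstats: Sequence[float],
    pvalues: Sequence[float],
    levels: tuple[float, float] = (0.95, 0.995),
    **meta,
) -> ResampleSummary:
    """Medians and percentile CIs over retained iterations.

    Quantiles use linear interpolation between order statistics; the CI at
    level L spans the (1-L)/2 and (1+L)/2 empirical quantiles of the
    t-statistics.
    """
    eff = np.asarray(effects, dtype=float)
    t = np.asarray(tstats, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if not (len(eff) == len(t) == len(p)):
        raise ValueError("effects, tstats and pvalues must have equal lengths")
    if len(t) == 0:
        raise ValueError("no successful iterations to aggregate")

    def ci(level: float) -> tuple[float, float]:
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(t, [alpha, 100.0 - alpha], method="linear")
        return float(lo), float(hi)

    ci_lo, ci_hi = sorted(levels)
    c95, c995 = ci(ci_lo), ci(ci_hi)
    meta.setdefault("model", "")
    meta.setdefault("contrast", ("target", "reference"))
    meta.setdefault("coefficient", "group")
    meta.setdefault("n_failed", 0)
    meta.setdefault("master_seed", 0)
    return ResampleSummary(
        n_iterations=len(t),
        effects=eff,
        tstats=t,
        pvalues=p,
        median_effect=float(np.median(eff)),
        median_t=float(np.median(t)),
        median_p=float(np.median(p)),
        ci95=c95,
        ci995=c995,
        excludes_zero_95=bool(c95[0] * c95[1] > 0),
        excludes_zero_995=bool(c995[0] * c995[1] > 0),
        **meta,
    )


def _fit_one(
    cohort: pd.DataFrame,
    baseline: pd.DataFrame,
    spec: ModelSpec,
    plan: MatchPlan,
) -> dict[str, tuple[float, float, float, float]]:
    """Fit ``spec`` on one matched subsample; returns per-coefficient stats."""
    if spec.longitudinal:
        ids_sel = pd.concat(
            [
                baseline.loc[plan.reference_indices, "id"],
                baseline.loc[plan.target_indices, "id"],
            ]
        )
        if plan.with_replacement:
            subsample = expand_to_visits(cohort, plan)
        else:
            subsample = cohort[cohort["id"].isin(set(ids_sel))]
    else:
        subsample = baseline.loc[
            list(plan.reference_indices) + list(plan.target_indices)
        ]
    y, X, ids, n_dropped = build_design(subsample, spec)
    if spec.longitudinal:
        fit = fit_random_intercept(y, X, ids, formula=spec.formula, n_dropped=n_dropped)
    else:
        fit = fit_ols(y, X, formula=spec.formula, n_dropped=n_dropped)
    out = {"group": fit.coef("group")}
    if spec.interaction:
        out["group_x_time"] = fit.coef("group_x_time")
    return out


def _build_plans(
    cohort: pd.DataFrame,
    contrast: tuple[str, str],
    n_iterations: int,
    master_seed: int,
    allow_replacement: bool,
    baseline: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[MatchPlan]]:
    """One matcher, ``n_iterations`` seeded draws; returns (baseline, plans)."""
    target, reference = contrast
    matcher = Matcher(
        cohort,
        reference_group=reference,
        target_group=target,
        allow_replacement=allow_replacement,
        baseline=baseline,
    )
    plans = [
        matcher.draw(iteration_seed(master_seed, i)) for i in range(n_iterations)
    ]
    return matcher.baseline, plans


def run_resampled_contrast(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_iterations: int = DEFAULT_ITERATIONS,
    master_seed: int = 0,
    allow_replacement: bool = False,
    plans: Sequence[MatchPlan] | None = None,
    max_failure_rate: float = 0.05,
    ci_levels: tuple[float, float] = (0.95, 0.995),
) -> ResampleSummary:
    """Run the matched bootstrap for one model spec.

    Iteration ``i`` uses the seed derived from (master_seed, i) to build a
    matched subsample, expands it to all visits for longitudinal specs,
    fits the model, and records the group coefficient and t. Iterations
    whose fit raises are excluded and counted; more than
    ``max_failure_rate`` failures aborts (systematic infeasibility).
    Interaction specs attach a companion summary of the group x time
    coefficient as ``.interaction``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if plans is None:
        baseline, plans = _build_plans(
            cohort, spec.contrast, n_iterations, master_seed, allow_replacement
        )
    else:
        baseline = baseline_rows(cohort)
    records: dict[str, list[tuple[float, float, float]]] = {}
    n_failed = 0
    for plan in plans:
        try:
            coefs = _fit_one(cohort, baseline, spec, plan)
        except Exception:
            n_failed += 1
            continue
        for name, (est, _se, t, p) in coefs.items():
            records.setdefault(name, []).append((est, t, p))
    if n_failed > max_failure_rate * len(plans):
        raise RuntimeError(
            f"{n_failed}/{len(plans)} iterations failed; "
            "matched resampling is systematically infeasible for this spec"
        )
    if not records:
        raise RuntimeError("all iterations failed")

    def summarize(name: str) -> ResampleSummary:
        arr = np.array(records[name])
        return aggregate_iterations(
            arr[:, 0],
            arr[:, 1],
            arr[:, 2],
            levels=ci_levels,
            model=spec.formula,
            contrast=spec.contrast,
            coefficient=name,
            n_failed=n_failed,
            master_seed=master_seed,
        )

    summary = summarize("group")
    if spec.interaction:
        summary.interaction = summarize("group_x_time")  # type: ignore[attr-defined]
    return summary


@dataclass
class AdjustmentComparison:
    """Paired unadjusted/vascular-adjusted summaries and their difference."""

    unadjusted: ResampleSummary
    adjusted: ResampleSummary
    delta_median_t: float
    delta_median_effect: float
    classification: str  # attenuated | unchanged | revealed

    def to_row(self) -> dict:
        return {
            "contrast": f"{self.unadjusted.contrast[0]} vs {self.unadjusted.contrast[1]}",
            "median_t_unadjusted": self.unadjusted.median_t,
            "median_t_adjusted": self.adjusted.median_t,
            "delta_median_t": self.delta_median_t,
            "delta_median_effect": self.delta_median_effect,
            "classification": self.classification,
        }


def classify_adjustment(
    unadjusted: ResampleSummary, adjusted: ResampleSummary
) -> str:
    """attenuated / revealed / unchanged by exclusion-flag flips.

    Uses the conservative 99.5% flags: "attenuated" when a non-null
    contrast becomes null after vascular adjustment, "revealed" when a null
    contrast becomes non-null (suppression), "unchanged" otherwise.
    """
    base_sig = unadjusted.significant
    adj_sig = adjusted.significant
    if base_sig and not adj_sig:
        return "attenuated"
    if not base_sig and adj_sig:
        return "revealed"
    return "unchanged"


def compare_adjustment(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_iterations: int = DEFAULT_ITERATIONS,
    master_seed: int = 0,
    allow_replacement: bool = False,
) -> AdjustmentComparison:
    """Run a contrast with and without vascular covariates on shared plans.

    ``spec`` must carry the base covariate set; the adjusted run swaps in
    diabetes + hypertension + BMI. Both runs reuse identical per-iteration
    matched subsamples (same derived seeds), so the difference in median t
    isolates covariate adjustment from resampling noise.
    """
    if spec.covariates != "base":
        raise ValueError("compare_adjustment expects a base-covariate spec")
    _, plans = _build_plans(
        cohort, spec.contrast, n_iterations, master_seed, allow_replacement
    )
    from dataclasses import replace

    unadj = run_resampled_contrast(
        cohort, spec, n_iterations, master_seed, plans=plans
    )
    adj = run_resampled_contrast(
        cohort,
        replace(spec, covariates="vascular"),
        n_iterations,
        master_seed,
        plans=plans,
    )
    return AdjustmentComparison(
        unadjusted=unadj,
        adjusted=adj,
        delta_median_t=adj.median_t - unadj.median_t,
        delta_median_effect=adj.median_effect - unadj.median_effect,
        classification=classify_adjustment(unadj, adj),
    )


REGIONAL_OUTCOMES = (
    "log_total",
    "log_frontal",
    "log_parietal",
    "log_temporal",
    "log_occipital",
)


def run_regional_panel(
    cohort: pd.DataFrame,
    contrast: tuple[str, str],
    n_iterations: int = DEFAULT_ITERATIONS,
    master_seed: int = 0,
    allow_replacement: bool = False,
) -> list[ResampleSummary]:
    """Baseline-only contrasts of total + four regional log volumes.

    Runs each outcome under both covariate sets (10 summaries). Within an
    iteration every outcome and covariate set shares the same matched
    subsample.
    """
    missing = [
        c
        for c in (
            "wmh_total_mm3",
            "wmh_frontal_mm3",
            "wmh_parietal_mm3",
            "wmh_temporal_mm3",
            "wmh_occipital_mm3",
        )
        if c not in cohort.columns
    ]
    if missing:
        raise ValueError(f"missing regional volume columns: {missing}")
    _, plans = _build_plans(
        cohort, contrast, n_iterations, master_seed, allow_replacement
    )
    summaries = []
    for covariates in ("base", "vascular"):
        for outcome in REGIONAL_OUTCOMES:
            spec = ModelSpec(
                outcome=outcome, contrast=contrast, covariates=covariates
            )
            summaries.append(
                run_resampled_contrast(
                    cohort, spec, n_iterations, master_seed, plans=plans
                )
            )
    return summaries
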