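"""Synthetic cohort generator.

Simulates participant-visit tables with the demographic, vascular, and
outcome structure the downstream contrast analysis assumes: per-group
marginals for age, sex, education, BMI, hypertension, diabetes and
diagnosis mix; a linear model for log-scale total white matter
hypointensity (WMH) volume with a subject random intercept; group-specific
annual progression slopes; regional volumes apportioned from the total; and
an ordinal low/moderate/extensive severity staging derived from log volume
by fixed cutpoints.

The generative outcome model is, on the log(volume + 1) scale,

    y_ij = b0 + b_group[g] + b_age*age + b_male*male + b_edu*edu
           + b_mci*MCI + b_ad*AD + b_htn*HTN + b_dm*DM + b_bmi*BMI
           + slope[g]*t_ij + u_i + e_ij,

with u_i ~ N(0, sigma_subject^2) shared across a participant's visits and
e_ij ~ N(0, sigma_resid^2) fresh per visit. This is exactly the structure
the fitting side assumes, so parameter-recovery tests are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SCHEMA_COLUMNS, baseline_rows

__all__ = [
    "GroupProfile",
    "OutcomeModelParams",
    "GeneratorConfig",
    "generate_baseline",
    "extend_longitudinal",
    "severity_from_volume",
    "summarize_cohort",
]

DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class GroupProfile:
    """Marginal distribution of one group's demographics and risk factors.

    Units: age and education in years, BMI in kg/m^2; ``male_frac``,
    ``htn_prev`` and ``dm_prev`` are proportions; ``dx_probs`` is the
    (NC, MCI, AD) diagnosis mix.
    """

    label: str
    n: int
    age_mean: float
    age_sd: float
    edu_mean: float
    edu_sd: float
    bmi_mean: float
    bmi_sd: float
    male_frac: float
    htn_prev: float
    dm_prev: float
    dx_probs: tuple[float, float, float]
    ethnicity: str = ""

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"profile {self.label!r}: n must be >= 1")
        for name in ("age_sd", "edu_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"profile {self.label!r}: {name} must be > 0")
        for name in ("male_frac", "htn_prev", "dm_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"profile {self.label!r}: {name} must be in [0,1]")
        probs = np.asarray(self.dx_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"profile {self.label!r}: dx_probs must be 3 non-negative "
                "probabilities summing to 1"
            )


@dataclass(frozen=True)
class OutcomeModelParams:
    """Coefficients of the generative log-WMH model.

    ``beta_group`` and ``slope_time_by_group`` map group labels to the
    direct group offset (log-mm^3) and annual change (log-mm^3 per year);
    labels not present default to 0. ``region_weights`` apportions total
    volume to frontal/parietal/temporal/occipital (log-regional =
    log(weight) + log-total + N(0, regional_noise_sd^2)).
    """

    intercept: float = 5.0
    beta_group: Mapping[str, float] = field(default_factory=dict)
    beta_age: float = 0.04
    beta_edu: float = -0.01
    beta_male: float = 0.10
    beta_dx_mci: float = 0.30
    beta_dx_ad: float = 0.50
    beta_htn: float = 0.25
    beta_dm: float = 0.20
    beta_bmi: float = 0.015
    slope_time_by_group: Mapping[str, float] = field(default_factory=dict)
    sigma_subject: float = 0.8
    sigma_resid: float = 0.6
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "frontal": 0.58,
            "parietal": 0.32,
            "temporal": 0.055,
            "occipital": 0.045,
            "total": 1.0,
        }
    )
    regional_noise_sd: float = 0.1

    def validate(self) -> None:
        if self.sigma_subject < 0:
            raise ConfigError("sigma_subject must be >= 0")
        if self.sigma_resid <= 0:
            raise ConfigError("sigma_resid must be > 0")
        if any(w < 0 for w in self.region_weights.values()):
            raise ConfigError("region_weights must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full simulation recipe: group profiles + outcome model + visit process.

    ``severity_thresholds`` are log(volume + 1) cutpoints for the ordinal
    low/moderate/extensive staging; ``n_visits_mean`` is the expected number
    of repeated assessments per participant (visit count is
    1 + Poisson(n_visits_mean - 1)); visit intervals are normal in days,
    floored at 1 day.
    """

    profiles: Sequence[GroupProfile]
    outcome: OutcomeModelParams = field(default_factory=OutcomeModelParams)
    n_visits_mean: float = 1.87
    visit_interval_mean: float = 455.0
    visit_interval_sd: float = 140.0
    severity_thresholds: tuple[float, float] = (8.53, 9.40)
    seed: int = 0

    def validate(self) -> None:
        if not self.profiles:
            raise ConfigError("profiles must be non-empty")
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ConfigError("profile labels must be unique")
        for p in self.profiles:
            p.validate()
        self.outcome.validate()
        if self.n_visits_mean < 1:
            raise ConfigError("n_visits_mean must be >= 1")
        if self.visit_interval_mean <= 0:
            raise ConfigError("visit_interval_mean must be > 0")
        if self.visit_interval_sd < 0:
            raise ConfigError("visit_interval_sd must be >= 0")
        lo, hi = self.severity_thresholds
        if not lo < hi:
            raise ConfigError("severity_thresholds must be strictly increasing")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def severity_from_volume(
    log_volume: float | np.ndarray, thresholds: Sequence[float]
) -> np.ndarray | int:
    """Stage log volume into ordinal severity 0 (low) / 1 (moderate) / 2 (extensive).

    The lower bound of each band is inclusive: a value exactly at a cutpoint
    falls in the higher band. Monotone non-decreasing in ``log_volume``.
    """
    lo, hi = float(thresholds[0]), float(thresholds[1])
    if not lo < hi:
        raise ConfigError("severity thresholds must be strictly increasing")
    arr = np.asarray(log_volume, dtype=float)
    sev = np.digitize(arr, [lo, hi], right=False)
    if np.isscalar(log_volume) or arr.ndim == 0:
        return int(sev)
    return sev


def _linear_predictor(
    table: pd.DataFrame, params: OutcomeModelParams
) -> np.ndarray:
    """Fixed-effects part of the log-WMH model, excluding time trends."""
    beta_g = np.array(
        [params.beta_group.get(g, 0.0) for g in table["group"]], dtype=float
    )
    dx = table["diagnosis"].to_numpy()
    lp = (
        params.intercept
        + beta_g
        + params.beta_age * table["age"].to_numpy(float)
        + params.beta_edu * table["education"].to_numpy(float)
        + params.beta_male * table["sex"].to_numpy(float)
        + params.beta_dx_mci * (dx == "MCI")
        + params.beta_dx_ad * (dx == "AD")
        + params.beta_htn * table["hypertension"].to_numpy(float)
        + params.beta_dm * table["diabetes"].to_numpy(float)
        + params.beta_bmi * table["bmi"].to_numpy(float)
    )
    return lp


def _outcome_columns(
    log_total: np.ndarray, params: OutcomeModelParams, thresholds, rng
) -> dict[str, np.ndarray]:
    """Severity + regional/total mm^3 volumes from log(total + 1) values."""
    out: dict[str, np.ndarray] = {}
    out["wmh_severity"] = severity_from_volume(log_total, thresholds)
    out["wmh_total_mm3"] = np.maximum(np.expm1(log_total), 0.0)
    for region in ("frontal", "parietal", "temporal", "occipital"):
        w = params.region_weights.get(region, 0.0)
        if w <= 0:
            log_reg = np.full_like(log_total, -np.inf)
        else:
            log_reg = (
                np.log(w)
                + log_total
                + rng.normal(0.0, params.regional_noise_sd, size=log_total.shape)
            )
        out[f"wmh_{region}_mm3"] = np.maximum(np.expm1(log_reg), 0.0)
    return out


def generate_baseline(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the baseline visit of every participant.

    One row per participant, ``time_from_baseline_days`` = 0. Demographics
    are drawn from the per-group profiles (education truncated at 0 years,
    BMI at 12 kg/m^2, age untruncated); the log-WMH outcome follows the
    generative model. The returned frame carries the latent
    ``subject_intercept`` column needed by :func:`extend_longitudinal`.
    Byte-identical output for identical config + seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = config.outcome
    frames = []
    for profile in config.profiles:
        n = profile.n
        age = rng.normal(profile.age_mean, profile.age_sd, n)
        edu = np.maximum(rng.normal(profile.edu_mean, profile.edu_sd, n), 0.0)
        bmi = np.maximum(rng.normal(profile.bmi_mean, profile.bmi_sd, n), 12.0)
        sex = (rng.random(n) < profile.male_frac).astype(int)
        htn = (rng.random(n) < profile.htn_prev).astype(int)
        dm = (rng.random(n) < profile.dm_prev).astype(int)
        dx = rng.choice(np.array(["NC", "MCI", "AD"]), size=n, p=profile.dx_probs)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{profile.label}_{i:05d}" for i in range(n)],
                    "group": profile.label,
                    "ethnicity": profile.ethnicity or profile.label,
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "diagnosis": dx,
                    "bmi": bmi,
                    "hypertension": htn,
                    "diabetes": dm,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["time_from_baseline_days"] = 0.0
    n_all = len(table)
    subject_intercept = rng.normal(0.0, params.sigma_subject, n_all)
    resid = rng.normal(0.0, params.sigma_resid, n_all)
    log_total = _linear_predictor(table, params) + subject_intercept + resid
    for col, vals in _outcome_columns(
        log_total, params, config.severity_thresholds, rng
    ).items():
        table[col] = vals
    table["subject_intercept"] = subject_intercept
    return table[SCHEMA_COLUMNS + ["subject_intercept"]]


def extend_longitudinal(
    baseline: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Append follow-up visits to a baseline table.

    Per participant the visit count is 1 + Poisson(n_visits_mean - 1);
    inter-visit intervals are normal(visit_interval_mean, visit_interval_sd)
    days floored at 1. Follow-up outcomes share the participant's latent
    subject intercept, add the group-specific annual slope (time in years =
    days / 365.25), and draw fresh residuals; age advances with elapsed
    time. Severity and regional volumes are recomputed per visit.
    """
    config.validate()
    if baseline["id"].duplicated().any():
        dupes = baseline.loc[baseline["id"].duplicated(), "id"].unique()[:5]
        raise ConfigError(f"duplicate participant ids in baseline: {list(dupes)}")
    if "subject_intercept" not in baseline.columns:
        raise ConfigError(
            "baseline table lacks the latent subject_intercept column; "
            "extend_longitudinal must be applied to freshly generated tables"
        )
    # Child stream so baseline draws are untouched: same config + seed still
    # yields identical longitudinal tables.
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    params = config.outcome
    n = len(baseline)
    n_extra = rng.poisson(max(config.n_visits_mean - 1.0, 0.0), size=n)
    frames = [baseline]
    lp0 = _linear_predictor(baseline, params)
    slopes = np.array(
        [params.slope_time_by_group.get(g, 0.0) for g in baseline["group"]],
        dtype=float,
    )
    for i in range(n):
        k = int(n_extra[i])
        if k == 0:
            continue
        intervals = np.maximum(
            rng.normal(config.visit_interval_mean, config.visit_interval_sd, k), 1.0
        )
        days = np.cumsum(intervals)
        years = days / DAYS_PER_YEAR
        resid = rng.normal(0.0, params.sigma_resid, k)
        log_total = (
            lp0[i]
            + slopes[i] * years
            + baseline["subject_intercept"].iloc[i]
            + resid
        )
        row = baseline.iloc[i]
        visit = pd.DataFrame(
            {
                "id": row["id"],
                "group": row["group"],
                "ethnicity": row["ethnicity"],
                "age": row["age"] + years,
                "sex": row["sex"],
                "education": row["education"],
                "diagnosis": row["diagnosis"],
                "bmi": row["bmi"],
                "hypertension": row["hypertension"],
                "diabetes": row["diabetes"],
                "time_from_baseline_days": days,
            }
        )
        for col, vals in _outcome_columns(
            log_total, params, config.severity_thresholds, rng
        ).items():
            visit[col] = vals
        visit["subject_intercept"] = row["subject_intercept"]
        frames.append(visit)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["id", "time_from_baseline_days"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def generate_cohort(config: GeneratorConfig, longitudinal: bool = True) -> pd.DataFrame:
    """Convenience: baseline table, optionally extended with follow-ups."""
    base = generate_baseline(config)
    if not longitudinal:
        return base
    return extend_longitudinal(base, config)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-group summary of baseline rows.

    Mean +/- SD for age, education, BMI; count and percentage for male sex,
    each diagnosis level, hypertension and diabetes. SD is reported as NaN
    for single-participant groups.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    needed = [
        "id",
        "group",
        "age",
        "sex",
        "education",
        "diagnosis",
        "bmi",
        "hypertension",
        "diabetes",
        "time_from_baseline_days",
    ]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"summarize_cohort: missing columns {missing}")
    base = baseline_rows(cohort)
    records = []
    for label, grp in base.groupby("group", sort=True):
        n = len(grp)
        rec: dict[str, object] = {"group": label, "n": n}
        for col in ("age", "education", "bmi"):
            vals = pd.to_numeric(grp[col], errors="coerce")
            rec[f"{col}_mean"] = float(vals.mean())
            rec[f"{col}_sd"] = float(vals.std(ddof=1)) if n > 1 else float("nan")
        for col, name in (
            ("sex", "male"),
            ("hypertension", "hypertension"),
            ("diabetes", "diabetes"),
        ):
            count = int(pd.to_numeric(grp[col], errors="coerce").fillna(0).sum())
            rec[f"{name}_n"] = count
            rec[f"{name}_pct"] = 100.0 * count / n
        for level in ("NC", "MCI", "AD"):
            count = int((grp["diagnosis"] == level).sum())
            rec[f"dx_{level.lower()}_n"] = count
            rec[f"dx_{level.lower()}_pct"] = 100.0 * count / n
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("group")
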