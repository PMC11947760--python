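"""Published cohort profiles and named simulation scenarios.

The group profiles encode the printed descriptive statistics of the NACC
clinical sample (visual WMH staging) and its volumetric MRI subset: per
racial/ethnic group, means and SDs of age, education and BMI, the male
fraction, hypertension/diabetes prevalence and the NC/MCI/AD diagnosis mix.
These published summary tables are the study conditions the synthetic
cohorts emulate.

Scenario builders return full :class:`~wmhcontrast.synthetic.GeneratorConfig`
objects for the three causal structures the pipeline is meant to detect:

* ``mediation_config`` — the Black–White pattern: a modest direct group
  effect plus a sizeable vascular-mediated contribution, so vascular
  adjustment attenuates the contrast.
* ``suppression_config`` — the Hispanic pattern: a negative direct effect
  exactly cancelled in expectation by the positive vascular-mediated path,
  so the contrast is null unadjusted and emerges after adjustment.
* ``null_config`` — two identical groups with no effect anywhere, for
  calibration checks.
"""

from __future__ import annotations

from .synthetic import GeneratorConfig, GroupProfile, OutcomeModelParams

__all__ = [
    "clinical_profile",
    "mri_profile",
    "clinical_config",
    "mediation_config",
    "suppression_config",
    "null_config",
    "regional_config",
]

# Clinical (visual-staging) sample: mean +/- SD for age/education/BMI,
# proportions for sex/hypertension/diabetes, NC/MCI/AD mix.
_CLINICAL = {
    "White": dict(
        n=7132, age=(71.36, 9.23), edu=(16.31, 2.67), bmi=(26.72, 5.00),
        male=0.47, htn=0.42, dm=0.09, dx=(0.54, 0.09, 0.37),
    ),
    "Black": dict(
        n=892, age=(72.26, 8.82), edu=(15.08, 2.81), bmi=(29.13, 6.04),
        male=0.27, htn=0.70, dm=0.27, dx=(0.6155, 0.1065, 0.2780),
    ),
    "Asian": dict(
        n=283, age=(71.27, 9.53), edu=(16.48, 3.13), bmi=(23.90, 3.73),
        male=0.41, htn=0.46, dm=0.18, dx=(0.59, 0.10, 0.31),
    ),
    "Hispanic": dict(
        n=661, age=(71.47, 8.66), edu=(13.61, 4.54), bmi=(28.09, 5.04),
        male=0.37, htn=0.59, dm=0.25, dx=(0.455, 0.197, 0.348),
    ),
    "non-Hispanic": dict(
        n=8307, age=(71.38, 9.19), edu=(16.18, 2.73), bmi=(26.89, 5.17),
        male=0.45, htn=0.45, dm=0.11, dx=(0.52, 0.10, 0.38),
    ),
}

# Volumetric MRI subset.
_MRI = {
    "White": dict(
        n=1876, age=(70.38, 9.06), edu=(15.93, 2.85), bmi=(26.77, 4.71),
        male=0.46, htn=0.42, dm=0.10, dx=(0.585, 0.094, 0.321),
    ),
    "Black": dict(
        n=260, age=(70.98, 9.12), edu=(14.53, 3.09), bmi=(29.73, 5.49),
        male=0.29, htn=0.70, dm=0.36, dx=(0.696, 0.142, 0.162),
    ),
    "Asian": dict(
        n=55, age=(74.80, 9.60), edu=(15.62, 3.03), bmi=(23.62, 2.95),
        male=0.35, htn=0.56, dm=0.25, dx=(0.545, 0.146, 0.309),
    ),
    "Hispanic": dict(
        n=207, age=(72.32, 7.76), edu=(11.25, 4.88), bmi=(28.93, 5.33),
        male=0.32, htn=0.62, dm=0.29, dx=(0.633, 0.082, 0.285),
    ),
    "non-Hispanic": dict(
        n=2191, age=(70.56, 9.11), edu=(15.76, 2.92), bmi=(27.04, 4.90),
        male=0.56, htn=0.45, dm=0.13, dx=(0.598, 0.101, 0.301),
    ),
}


def _profile(label: str, spec: dict, n: int | None, ethnicity: str = "") -> GroupProfile:
    probs = spec["dx"]
    s = sum(probs)
    probs = tuple(p / s for p in probs)
    return GroupProfile(
        label=label,
        n=int(n if n is not None else spec["n"]),
        age_mean=spec["age"][0], age_sd=spec["age"][1],
        edu_mean=spec["edu"][0], edu_sd=spec["edu"][1],
        bmi_mean=spec["bmi"][0], bmi_sd=spec["bmi"][1],
        male_frac=spec["male"], htn_prev=spec["htn"], dm_prev=spec["dm"],
        dx_probs=probs,
        ethnicity=ethnicity,
    )


def clinical_profile(label: str, n: int | None = None) -> GroupProfile:
    """Profile of one clinical-sample group; ``n`` overrides the group size."""
    return _profile(label, _CLINICAL[label], n)


def mri_profile(label: str, n: int | None = None) -> GroupProfile:
    """Profile of one MRI-subset group; ``n`` overrides the group size."""
    return _profile(label, _MRI[label], n)


def _default_outcome(**overrides) -> OutcomeModelParams:
    base = dict(
        beta_group={"Black": 0.05},
        slope_time_by_group={
            "White": 0.08, "Black": 0.10, "Asian": 0.04,
            "Hispanic": 0.08, "non-Hispanic": 0.08,
        },
    )
    base.update(overrides)
    return OutcomeModelParams(**base)


def clinical_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Full clinical-sample scenario: all four race groups at published sizes.

    ``scale`` < 1 shrinks every group proportionally (minimum 30/group) for
    quick runs.
    """
    labels = ["White", "Black", "Asian", "Hispanic"]
    profiles = [
        clinical_profile(lab, max(int(round(_CLINICAL[lab]["n"] * scale)), 30))
        for lab in labels
    ]
    return GeneratorConfig(profiles=profiles, outcome=_default_outcome(), seed=seed)


def mediation_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Black vs White full-mediation scenario at the published group sizes.

    No direct group effect; the entire contrast flows through the vascular
    paths (hypertension +0.25, diabetes +0.20, BMI +0.015/unit log-mm^3).
    With the prevalence gaps in the profiles the expected unadjusted
    contrast is ~0.14 on the log scale, so vascular adjustment attenuates
    it toward zero.
    """
    profiles = [
        clinical_profile("White", max(int(round(7132 * scale)), 30)),
        clinical_profile("Black", max(int(round(892 * scale)), 10)),
    ]
    outcome = _default_outcome(beta_group={})
    return GeneratorConfig(profiles=profiles, outcome=outcome, seed=seed)


def suppression_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Hispanic vs non-Hispanic suppression scenario.

    Vascular effects are strengthened (hypertension +0.8, diabetes +0.7,
    BMI +0.06/unit) and the direct ethnicity effect is set to exactly minus
    the expected mediated contribution computed from the profile prevalence
    gaps, so the unadjusted contrast is null by construction while the
    adjusted contrast is negative and clearly non-null.
    """
    his, non = _CLINICAL["Hispanic"], _CLINICAL["non-Hispanic"]
    b_htn, b_dm, b_bmi = 0.8, 0.7, 0.06
    mediated = (
        (his["htn"] - non["htn"]) * b_htn
        + (his["dm"] - non["dm"]) * b_dm
        + (his["bmi"][0] - non["bmi"][0]) * b_bmi
    )
    outcome = _default_outcome(
        beta_group={"Hispanic": -mediated},
        beta_htn=b_htn, beta_dm=b_dm, beta_bmi=b_bmi,
    )
    profiles = [
        clinical_profile("non-Hispanic", max(int(round(8307 * scale)), 40)),
        clinical_profile("Hispanic", max(int(round(661 * scale)), 10)),
    ]
    return GeneratorConfig(profiles=profiles, outcome=outcome, seed=seed)


def null_config(seed: int = 0, n_reference: int = 3600, n_target: int = 120) -> GeneratorConfig:
    """Two identical groups, no group effect anywhere, for calibration.

    The reference pool is 30x the target group: the percentile interval of
    the bootstrap t is conditional on the realized cohort, and its spread
    only approaches the cohort-level sampling spread of the group contrast
    when subsamples are drawn from a pool much larger than the target
    group. At 30:1 the two agree within ~4%, so exclusion-of-zero flags
    fire at close to their nominal rate under the null.
    """
    ref = _profile("A", _CLINICAL["White"], n_reference)
    tgt = _profile("B", _CLINICAL["White"], n_target)
    outcome = _default_outcome(beta_group={})
    return GeneratorConfig(profiles=[ref, tgt], outcome=outcome, seed=seed)


def regional_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Black vs White volumetric scenario at the MRI-subset group sizes."""
    profiles = [
        mri_profile("White", max(int(round(1876 * scale)), 30)),
        mri_profile("Black", max(int(round(260 * scale)), 10)),
    ]
    return GeneratorConfig(profiles=profiles, outcome=_default_outcome(), seed=seed)
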