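import pandas as pd
import pytest

from wmhcontrast import GeneratorConfig, GroupProfile, OutcomeModelParams
from wmhcontrast.synthetic import extend_longitudinal, generate_baseline


def two_group_config(
    n_a=900,
    n_b=250,
    beta_group=0.0,
    seed=0,
    sigma_subject=0.8,
    sigma_resid=0.6,
    **outcome_overrides,
):
    """Small two-group config with identical demographics unless overridden."""
    common = dict(
        age_mean=71.0, age_sd=9.0, edu_mean=16.0, edu_sd=2.7,
        bmi_mean=27.0, bmi_sd=5.0, male_frac=0.45,
        htn_prev=0.45, dm_prev=0.10, dx_probs=(0.55, 0.10, 0.35),
    )
    outcome = OutcomeModelParams(
        beta_group={"B": beta_group},
        sigma_subject=sigma_subject,
        sigma_resid=sigma_resid,
        **outcome_overrides,
    )
    return GeneratorConfig(
        profiles=[
            GroupProfile(label="A", n=n_a, **common),
            GroupProfile(label="B", n=n_b, **common),
        ],
        outcome=outcome,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Longitudinal two-group cohort, ~800 participants, fixed seed."""
    cfg = two_group_config(seed=42)
    return extend_longitudinal(generate_baseline(cfg), cfg)


@pytest.fixture(scope="session")
def small_baseline():
    cfg = two_group_config(seed=43)
    return generate_baseline(cfg)


@pytest.fixture()
def tiny_cohort():
    """Hand-sized cohort: 6 participants, deterministic values."""
    rows = []
    for i, (grp, age, edu, sex, dx) in enumerate(
        [
            ("A", 70.0, 16.0, 1, "NC"),
            ("A", 75.0, 14.0, 0, "AD"),
            ("A", 65.0, 18.0, 1, "MCI"),
            ("B", 71.0, 15.0, 1, "NC"),
            ("B", 74.0, 13.0, 0, "AD"),
            ("B", 66.0, 17.0, 1, "MCI"),
        ]
    ):
        rows.append(
            {
                "id": f"p{i}",
                "group": grp,
                "ethnicity": grp,
                "age": age,
                "sex": sex,
                "education": edu,
                "diagnosis": dx,
                "bmi": 26.0 + i,
                "hypertension": i % 2,
                "diabetes": int(i in (2, 4)),
                "time_from_baseline_days": 0.0,
                "wmh_severity": i % 3,
                "wmh_total_mm3": 1000.0 + 100 * i,
                "wmh_frontal_mm3": 500.0 + 50 * i,
                "wmh_parietal_mm3": 300.0 + 30 * i,
                "wmh_temporal_mm3": 50.0 + 5 * i,
                "wmh_occipital_mm3": 40.0 + 4 * i,
            }
        )
    return pd.DataFrame(rows)
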