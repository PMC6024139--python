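import numpy as np
import pandas as pd
import pytest

from anestheeg import (
    Group, Sex, SubjectMeta, power_trajectory, sample_cohort, synthesize_eeg,
)


@pytest.fixture(scope="session")
def nt_meta() -> SubjectMeta:
    return SubjectMeta("nt-fix", Group.NT, 10.0, Sex.MALE, False, 30.0)


@pytest.fixture(scope="session")
def clean_record(nt_meta):
    """One clean 600-s synthetic NT record plus its drug log (shared)."""
    return synthesize_eeg(nt_meta, 600.0, seed=11)


def cohort_frame(n_asd: int, n_nt: int, seed: int) -> pd.DataFrame:
    """Tidy covariate table for a sampled cohort (no EEG synthesis)."""
    subs = sample_cohort(n_asd, n_nt, seed=seed)
    return pd.DataFrame([
        {"subject_id": s.meta.subject_id, "group": s.meta.group.value,
         "age_years": s.meta.age, "sex": s.meta.sex.value,
         "infusion": s.infusion_rate, "bolus": s.propofol_bolus,
         "midazolam": s.midazolam, "fentanyl": s.fentanyl,
         "epilepsy": s.meta.epilepsy}
        for s in subs
    ])


def simulate_offset_response(
    df: pd.DataFrame, group_offset: float, sigma: float, seed: int,
    band: str = "slow", column: str = "slow_db",
) -> pd.DataFrame:
    """Band power = NT trajectory cubic + group offset (ASD) + N(0, sigma).

    The age trend is exactly cubic and the group effect a pure offset, so the
    regression model nests the truth and the group coefficient equals
    ``group_offset``.
    """
    rng = np.random.default_rng(seed)
    df = df.copy()
    base = np.array([power_trajectory(a, "NT", band) for a in df["age_years"]])
    offs = np.where(df["group"] == Group.ASD.value, group_offset, 0.0)
    df[column] = base + offs + rng.normal(0.0, sigma, len(df))
    return df
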