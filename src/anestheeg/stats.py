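"""Cohort descriptive tables and standardized mean differences (SMD).

Group baseline characteristics are compared with SMDs rather than p-values:
for continuous variables |m₁ − m₂| / sqrt((s₁² + s₂²)/2) with the unweighted
average of the two group variances; for binary variables the same formula on
the group proportions with Bernoulli variances p(1−p). An SMD above 0.2
(roughly 15% distributional non-overlap) is flagged notable.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

from .records import Group, Sex
from .synth import SyntheticSubject

NOTABLE_SMD = 0.2


@dataclass(frozen=True)
class SMDResult:
    variable: str
    smd: float
    group1: tuple[float, float]   # (mean, SD) or (count, denominator)
    group2: tuple[float, float]

    def __post_init__(self) -> None:
        if self.smd < 0:
            raise ValueError("SMD is nonnegative by definition")

    @property
    def notable(self) -> bool:
        return self.smd > NOTABLE_SMD


def smd_continuous(
    m1: float, s1: float, m2: float, s2: float, variable: str = ""
) -> SMDResult:
    """SMD for a continuous variable from group means and SDs."""
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    pooled = math.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0.0:
        if m1 == m2:
            raise ValueError("SMD undefined: both SDs zero")
        raise ValueError("SMD infinite: zero pooled SD with differing means")
    return SMDResult(variable, abs(m1 - m2) / pooled, (m1, s1), (m2, s2))


def smd_binary(
    k1: int, n1: int, k2: int, n2: int, variable: str = ""
) -> SMDResult:
    """SMD for a binary variable from group counts, using Bernoulli variances."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= k <= n with n >= 1 in each group")
    p1, p2 = k1 / n1, k2 / n2
    pooled = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if pooled == 0.0:
        if p1 == p2:
            raise ValueError("SMD undefined: both proportions degenerate")
        # p1, p2 in {0, 1} and different: complete separation
        return SMDResult(variable, math.inf, (k1, n1), (k2, n2))
    return SMDResult(variable, abs(p1 - p2) / pooled, (k1, n1), (k2, n2))


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Baseline-characteristics table with per-variable SMDs.

    One row per variable (age, male sex, infusion rate, propofol bolus,
    midazolam, fentanyl, epilepsy) with group means (SD) or counts (%), the
    SMD, and the notable flag. Requires ≥2 subjects per group so SDs exist.
    """
    groups = {}
    for g in (Group.ASD, Group.NT):
        sub = [s for s in subjects if s.meta.group is g]
        if not sub:
            raise ValueError(f"empty group {g.value}")
        if len(sub) < 2:
            raise ValueError(f"group {g.value} has n=1; SDs undefined")
        groups[g] = sub

    def cont(name, getter):
        stats = {}
        for g, sub in groups.items():
            vals = [getter(s) for s in sub]
            m = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            stats[g] = (m, sd)
        if stats[Group.ASD] == stats[Group.NT]:
            # identical (possibly degenerate) groups: no difference by definition
            smd, notable = 0.0, False
        else:
            r = smd_continuous(*stats[Group.ASD], *stats[Group.NT], variable=name)
            smd, notable = r.smd, r.notable
        return {"variable": name, "kind": "continuous",
                "asd": f"{stats[Group.ASD][0]:.2f} ({stats[Group.ASD][1]:.2f})",
                "nt": f"{stats[Group.NT][0]:.2f} ({stats[Group.NT][1]:.2f})",
                "smd": round(smd, 3), "notable": notable}

    def binary(name, pred):
        counts = {g: (sum(pred(s) for s in sub), len(sub))
                  for g, sub in groups.items()}
        p_asd = counts[Group.ASD][0] / counts[Group.ASD][1]
        p_nt = counts[Group.NT][0] / counts[Group.NT][1]
        if p_asd == p_nt and p_asd in (0.0, 1.0):
            # identical degenerate groups: no difference by definition
            smd, notable = 0.0, False
        else:
            r = smd_binary(*counts[Group.ASD], *counts[Group.NT], variable=name)
            smd, notable = r.smd, r.notable
        return {"variable": name, "kind": "binary",
                "asd": f"{counts[Group.ASD][0]} ({100 * p_asd:.1f})",
                "nt": f"{counts[Group.NT][0]} ({100 * p_nt:.1f})",
                "smd": round(smd, 3), "notable": notable}

    rows = [
        cont("age_years", lambda s: s.meta.age),
        binary("male_sex", lambda s: s.meta.sex is Sex.MALE),
        cont("propofol_infusion_mcg_kg_min", lambda s: s.infusion_rate),
        cont("propofol_bolus_mg_kg", lambda s: s.propofol_bolus),
        cont("midazolam_mg_kg", lambda s: s.midazolam),
        cont("fentanyl_mcg_kg", lambda s: s.fentanyl),
        binary("epilepsy", lambda s: s.meta.epilepsy),
    ]
    return pd.DataFrame(rows)
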