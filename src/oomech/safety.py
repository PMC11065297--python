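"""Measured-vs-control safety comparison.

Builds 2x2 contingency tables of (measured, control) x (outcome yes/no)
for fertilization, good day-3 (grade A) embryo and blastocyst formation,
and tests them with a Pearson chi-square (1 df).  Fertilization is
counted out of all injected oocytes; day-3 and blastocyst outcomes are
counted out of fertilized oocytes by default, with the all-oocyte
denominator available — both conventions are reported side by side by
:func:`safety_report` since neither is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

OUTCOMES = ("fertilized", "day3_grade_a", "blastocyst")

__all__ = ["ContingencyTable", "build_table", "chi_square", "safety_report",
           "OUTCOMES"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a,b,c,d for (measured, control) x (yes, no)."""

    a: int  # measured, outcome yes
    b: int  # measured, outcome no
    c: int  # control, outcome yes
    d: int  # control, outcome no
    outcome: str = ""
    clinic: str = "all"
    denominator: str = "all"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_table(cohort: pd.DataFrame, outcome: str, clinic: str = "all",
                denominator: str = "fertilized") -> ContingencyTable:
    """Contingency table for one outcome, optionally restricted to one
    clinic (e.g. the blastocyst-culture site for blastocyst outcomes).

    ``denominator`` controls the eligible set for day-3/blastocyst
    outcomes: "fertilized" (default) or "all" injected oocytes; the
    fertilization outcome always uses all oocytes.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; one of {OUTCOMES}")
    df = cohort if clinic == "all" else cohort[cohort["clinic_id"] == clinic]
    if outcome != "fertilized" and denominator == "fertilized":
        df = df[df["fertilized"].astype(bool)]
        den = "fertilized"
    else:
        den = "all"
    arms = set(df["arm"].unique())
    if not {"measured", "control"} <= arms:
        raise ValueError(f"cohort slice lacks an arm (has {sorted(arms)})")
    y = df[outcome].astype(bool)
    meas = df["arm"] == "measured"
    return ContingencyTable(
        a=int((meas & y).sum()), b=int((meas & ~y).sum()),
        c=int((~meas & y).sum()), d=int((~meas & ~y).sum()),
        outcome=outcome, clinic=clinic, denominator=den)


def chi_square(table: ContingencyTable, continuity_correction: bool = False):
    """Pearson chi-square on the 2x2 table; p from chi2 with 1 df.

    The uncorrected statistic equals n(ad-bc)^2 over the product of the
    four marginals; the Yates continuity correction is applied iff
    requested (off by default).
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: table not testable")
    stat, p, _, _ = chi2_contingency(arr, correction=continuity_correction)
    return float(stat), float(p)


def safety_report(cohort: pd.DataFrame, clinic: str = "all",
                  continuity_correction: bool = False) -> pd.DataFrame:
    """Per-outcome rates, chi-square statistics and p-values for the
    measured-vs-control comparison, under both denominator conventions
    where they differ."""
    rows = []
    for outcome in OUTCOMES:
        dens = ("all",) if outcome == "fertilized" else ("fertilized", "all")
        for den in dens:
            try:
                t = build_table(cohort, outcome, clinic=clinic, denominator=den)
                stat, p = chi_square(t, continuity_correction)
            except ValueError as e:
                rows.append({"outcome": outcome, "clinic": clinic,
                             "denominator": den, "error": str(e)})
                continue
            rows.append({
                "outcome": outcome, "clinic": clinic, "denominator": t.denominator,
                "measured_yes": t.a, "measured_no": t.b,
                "control_yes": t.c, "control_no": t.d,
                "measured_rate": t.a / (t.a + t.b) if t.a + t.b else float("nan"),
                "control_rate": t.c / (t.c + t.d) if t.c + t.d else float("nan"),
                "chi2": stat, "p_value": p,
                "continuity_correction": continuity_correction,
            })
    return pd.DataFrame(rows)
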