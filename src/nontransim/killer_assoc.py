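"""Killer-phenotype bookkeeping and genotype-phenotype association statistics.

Killer yeast phenotypes have two axes scored by halo assay: killing ability
(K) and immunity to the toxin (I), each graded full / weak / none.  This
module computes per-generation retention fractions across populations,
audits phenotype transitions for biologically forbidden events (immunity
loss before killing loss; any regain of a lost grade), and provides the
2x2 contingency chi-squared used to associate viral mutations with
phenotype loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GRADES = ("none", "weak", "full")
GRADE_ORDER = {g: i for i, g in enumerate(GRADES)}


def grade_value(grade: str) -> int:
    try:
        return GRADE_ORDER[grade]
    except KeyError:
        raise ValueError(f"unknown grade {grade!r}; expected one of {GRADES}")


@dataclass(frozen=True)
class KillerPhenotype:
    killing: str
    immunity: str

    def __post_init__(self):
        grade_value(self.killing)
        grade_value(self.immunity)


def phenotype_trajectory(
    records: pd.DataFrame, threshold: str = "full"
) -> pd.DataFrame:
    """Per-generation fraction of populations retaining killing / immunity.

    ``records`` has columns population, generation, killing, immunity with
    one row per (population, generation).  A population "retains" an axis
    when its grade is >= ``threshold``.  Missing observations are carried
    forward from the population's last observed generation; every
    population must be observed at generation 0.
    """
    req = {"population", "generation", "killing", "immunity"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    thr = grade_value(threshold)
    pops = records["population"].unique()
    gens = np.sort(records["generation"].unique())
    at_zero = set(records.loc[records["generation"] == gens.min(), "population"])
    if gens.min() != 0 or set(pops) - at_zero:
        missing = sorted(set(pops) - at_zero) if gens.min() == 0 else list(pops)
        raise ValueError(f"populations missing at generation 0: {missing}")
    # pivot then forward-fill each population's trajectory
    out = []
    for axis in ("killing", "immunity"):
        wide = records.pivot(index="generation", columns="population", values=axis)
        wide = wide.ffill()
        vals = wide.map(grade_value)
        out.append((vals >= thr).mean(axis=1))
    return pd.DataFrame(
        {"killing_retained": out[0], "immunity_retained": out[1]}
    ).reset_index()


@dataclass(frozen=True)
class TransitionViolation:
    population: object
    generation: int
    kind: str  # "immunity_lost_before_killing" | "grade_increase"
    detail: str


def transition_audit(records: pd.DataFrame) -> list[TransitionViolation]:
    """Flag forbidden phenotype transitions.

    (a) immunity below full while killing is still full at the same
    timepoint (immunity is never lost before killing ability); (b) any
    increase of either grade over time (lost function does not reappear).
    Simultaneous loss of both axes is legal.
    """
    violations: list[TransitionViolation] = []
    for pop, grp in records.sort_values("generation").groupby("population"):
        prev_k = prev_i = None
        for _, row in grp.iterrows():
            k, i = grade_value(row["killing"]), grade_value(row["immunity"])
            gen = int(row["generation"])
            if k == GRADE_ORDER["full"] and i < GRADE_ORDER["full"]:
                violations.append(
                    TransitionViolation(
                        pop, gen, "immunity_lost_before_killing",
                        f"killing=full while immunity={row['immunity']}",
                    )
                )
            if prev_k is not None:
                if k > prev_k:
                    violations.append(
                        TransitionViolation(
                            pop, gen, "grade_increase",
                            f"killing rose {GRADES[prev_k]}->{GRADES[k]}",
                        )
                    )
                if i > prev_i:
                    violations.append(
                        TransitionViolation(
                            pop, gen, "grade_increase",
                            f"immunity rose {GRADES[prev_i]}->{GRADES[i]}",
                        )
                    )
            prev_k, prev_i = k, i
    return violations


def contingency_chisq(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, optionally Yates-corrected.

    Returns (chi2, df, p).  All four marginals must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all row and column marginals must be > 0")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), int(df), float(p)


def chisq_sf(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(x, df))
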