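"""Replicate-level statistics for diffusion-coefficient data.

One-way ANOVA with the classical sums-of-squares decomposition, Tukey's
honestly-significant-difference pairwise comparison at a configurable
confidence level (default 95%), and the ordinary least-squares regression
of effective diffusivity against hydrodynamic radius.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .physchem import SoluteRecord

__all__ = [
    "GroupData",
    "AnovaResult",
    "RegressionResult",
    "one_way_anova",
    "tukey_hsd",
    "regress_d_vs_radius",
]


@dataclass
class GroupData:
    """Replicated measurements grouped by label (e.g. strain x solute)."""

    group_labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if len(self.group_labels) != len(self.values):
            raise ValueError("one label per group required")
        if len(self.values) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        if any(len(v) < 2 for v in self.values):
            raise ValueError("each group needs at least 2 replicates")

    @property
    def k(self) -> int:
        return len(self.values)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.values)


@dataclass
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    degenerate: bool = False  # all values identical
    infinite_f: bool = False  # zero within-variance, unequal means

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


@dataclass
class RegressionResult:
    """OLS line through (hydrodynamic radius, D_eff) points."""

    slope: float  # um^2/s per nm
    intercept: float  # um^2/s
    r2: float
    n: int
    region: str = ""


def one_way_anova(data: GroupData) -> AnovaResult:
    """One-way analysis of variance: F = MS_between / MS_within.

    Degenerate inputs are flagged rather than raised: identical values
    everywhere set ``degenerate``; zero within-group variance with unequal
    means sets ``infinite_f`` and reports F = inf, p = 0.
    """
    grand = np.mean(np.concatenate(data.values))
    ss_b = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values)
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in data.values)
    df_b = data.k - 1
    df_w = data.n_total - data.k

    if ss_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0, degenerate=True)
        return AnovaResult(
            float("inf"), df_b, df_w, 0.0, ss_b, 0.0, infinite_f=True
        )
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, float(ss_b), float(ss_w))


def tukey_hsd(data: GroupData, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparison via the studentized-range distribution.

    Balanced designs use the common group size; unbalanced designs fall
    back to the harmonic mean of the two group sizes (Tukey-Kramer).
    Returns one row per unordered pair with the mean difference, the q
    statistic, the critical q at ``alpha``, and a significance flag.
    """
    anova = one_way_anova(data)
    if anova.degenerate:
        ms_w = 0.0
    else:
        ms_w = anova.ss_within / anova.df_within
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, data.k, anova.df_within))

    rows = []
    for i, j in itertools.combinations(range(data.k), 2):
        vi, vj = data.values[i], data.values[j]
        n_h = 2.0 / (1.0 / len(vi) + 1.0 / len(vj))  # harmonic mean group size
        diff = float(vi.mean() - vj.mean())
        se = np.sqrt(ms_w / n_h)
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else float("inf"))
        rows.append(
            {
                "group1": data.group_labels[i],
                "group2": data.group_labels[j],
                "diff": diff,
                "se": float(se),
                "q": float(q),
                "q_crit": q_crit,
                "significant": bool(q > q_crit),
            }
        )
    return pd.DataFrame(rows)


def regress_d_vs_radius(
    solutes: list[SoluteRecord],
    d_values: np.ndarray,
    region: str = "",
) -> RegressionResult:
    """OLS regression of effective diffusivity on hydrodynamic radius.

    Used to test whether D_eff decreases linearly with solute size over a
    molecular-weight series, separately inside and outside colonies.
    """
    d_values = np.asarray(d_values, dtype=float)
    if len(solutes) != len(d_values):
        raise ValueError("one D value per solute required")
    if len(solutes) < 3:
        raise InsufficientDataError("regression needs at least 3 (radius, D) pairs")
    radii = np.array([s.hydrodynamic_radius for s in solutes])
    res = stats.linregress(radii, d_values)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(solutes),
        region=region,
    )
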