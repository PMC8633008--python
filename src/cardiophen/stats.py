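"""Group-comparison statistics: one-way ANOVA, Fisher's LSD, fold changes.

The study design compares a control arm (CTR) with treated arms on scalar
per-sample measurements. Inference is a one-way ANOVA (significance level
0.05) followed by the post hoc least-significant-difference (LSD) test:
unadjusted pairwise t comparisons that reuse the ANOVA residual mean
square, reported as mean differences with 95% confidence intervals. LSD is
applied unconditionally, with the omnibus p reported alongside. Also here:
fold-change arithmetic and reference-normalized protein ratio tables
(densitometry ratios referred to a reference band set at 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientReplicationError, UndefinedFoldError

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "LsdComparison",
    "one_way_anova",
    "lsd_posthoc",
    "fold_change",
    "ratio_table",
]

ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Labeled collections of scalar measurements for one metric."""

    groups: dict[str, np.ndarray]
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float).ravel() for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise InsufficientReplicationError("need at least 2 groups")
        for name, values in self.groups.items():
            if values.size < 2:
                raise InsufficientReplicationError(
                    f"group {name!r} has n={values.size} < 2"
                )

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, group_col: str = "group",
                  value_col: str = "value", **kwargs) -> "GroupedMeasurements":
        groups = {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}
        return cls(groups=groups, **kwargs)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    ms_within: float  # residual mean square (MSE)
    df_within: int
    ss_between: float
    df_between: int
    ss_total: float
    degenerate: bool = False  # zero within-group variance -> infinite F


@dataclass
class LsdComparison:
    pair: tuple[str, str]
    mean_difference: float  # mean(b) - mean(a)
    ci95: tuple[float, float]
    p_value: float
    fold_change: float  # mean(b) / mean(a)

    def to_row(self) -> dict:
        return {
            "group_a": self.pair[0],
            "group_b": self.pair[1],
            "mean_difference": self.mean_difference,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "fold_change": self.fold_change,
        }


def one_way_anova(data: GroupedMeasurements) -> AnovaResult:
    """Standard between/within sums-of-squares decomposition.

    The decomposition is written out (rather than delegated) because the
    LSD test reuses the residual mean square and residual df.
    """
    values = list(data.groups.values())
    all_values = np.concatenate(values)
    grand_mean = all_values.mean()
    k = len(values)
    n_total = all_values.size

    ss_between = sum(v.size * (v.mean() - grand_mean) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    ss_total = ((all_values - grand_mean) ** 2).sum()
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
        degenerate = True
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df_between, df_within))
        degenerate = False
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        ms_within=float(ms_within),
        df_within=int(df_within),
        ss_between=float(ss_between),
        df_between=int(df_between),
        ss_total=float(ss_total),
        degenerate=degenerate,
    )


def lsd_posthoc(data: GroupedMeasurements, alpha: float = ALPHA) -> list[LsdComparison]:
    """Fisher's LSD: unadjusted pairwise t tests on the pooled MSE.

    For each ordered pair (a, b): difference = mean(b) - mean(a), standard
    error sqrt(MSE * (1/n_a + 1/n_b)), CI at t(1 - alpha/2, df_residual),
    two-sided p from the t distribution. No multiplicity correction (LSD by
    definition).
    """
    anova = one_way_anova(data)
    names = list(data.groups)
    tcrit = float(sps.t.ppf(1 - alpha / 2, anova.df_within))
    out = []
    for a, b in itertools.combinations(names, 2):
        va, vb = data.groups[a], data.groups[b]
        diff = vb.mean() - va.mean()
        se = np.sqrt(anova.ms_within * (1 / va.size + 1 / vb.size))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            ci = (diff, diff)
        else:
            tstat = diff / se
            p = float(2 * sps.t.sf(abs(tstat), anova.df_within))
            ci = (diff - tcrit * se, diff + tcrit * se)
        fold = vb.mean() / va.mean() if va.mean() != 0 else np.nan
        out.append(
            LsdComparison(
                pair=(a, b),
                mean_difference=float(diff),
                ci95=(float(ci[0]), float(ci[1])),
                p_value=p,
                fold_change=float(fold),
            )
        )
    return out


def lsd_table(data: GroupedMeasurements, alpha: float = ALPHA) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in lsd_posthoc(data, alpha)])


def fold_change(data: GroupedMeasurements, reference_group: str) -> dict[str, float]:
    """Group mean divided by the reference group's mean."""
    ref = data.groups[reference_group].mean()
    if ref == 0:
        raise UndefinedFoldError("reference group mean is zero")
    return {name: float(v.mean() / ref) for name, v in data.groups.items()}


def ratio_table(
    band_intensities: pd.DataFrame, reference_protein: str
) -> pd.DataFrame:
    """Reference-normalized protein ratios (reference column set at 1).

    Rows are samples, columns proteins; each row is divided by its own
    reference-protein value, so ratios are invariant to any positive
    rescaling of a sample's intensities.
    """
    if reference_protein not in band_intensities.columns:
        raise KeyError(f"reference protein {reference_protein!r} not in table")
    ref = band_intensities[reference_protein]
    if (ref <= 0).any():
        raise UndefinedFoldError("reference intensity must be > 0 in every sample")
    return band_intensities.div(ref, axis=0)
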