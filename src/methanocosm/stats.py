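"""Supporting group statistics: one-way ANOVA, LSD post hoc, Hartley's
F-max variance screen, and a Pearson correlation matrix.

These are the routine tests run on microcosm summary quantities such as
per-bottle conversion efficiencies or coal heating values: a classical
between/within variance decomposition, Fisher's least significant
difference for pairwise follow-ups, the Hartley max/min variance ratio as
a cheap homoscedasticity screen, and Pearson correlations between measured
series (e.g. acetate concentration versus methane).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "LsdComparison",
    "one_way_anova",
    "lsd_posthoc",
    "hartley_fmax",
    "pearson_matrix",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Labelled groups of replicate measurements."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {k: np.asarray(v, dtype=float).ravel() for k, v in self.groups.items()}
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str, value_col: str) -> "GroupedMeasurements":
        return cls({str(g): sub[value_col].to_numpy(float) for g, sub in df.groupby(group_col)})

    def require(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        if len(self.groups) < min_groups:
            raise ValueError(f"need >= {min_groups} groups, got {len(self.groups)}")
        for name, v in self.groups.items():
            if len(v) < min_per_group:
                raise ValueError(f"group {name!r} has {len(v)} value(s); need >= {min_per_group}")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]


def one_way_anova(data: GroupedMeasurements, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Decomposes total sum of squares into between-group and within-group
    components; F = MSB/MSW with (k-1, N-k) degrees of freedom.
    """
    data.require()
    values = list(data.groups.values())
    grand = np.concatenate(values)
    grand_mean = grand.mean()
    ssb = sum(len(v) * (v.mean() - grand_mean) ** 2 for v in values)
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in values)
    dfb = len(values) - 1
    dfw = len(grand) - len(values)
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else float("inf")
    else:
        f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f_statistic=float(f), df_between=dfb, df_within=dfw, p_value=p,
        ms_within=float(msw),
        group_means={k: float(v.mean()) for k, v in data.groups.items()},
        group_sizes={k: len(v) for k, v in data.groups.items()},
    )


@dataclass(frozen=True)
class LsdComparison:
    group_a: str
    group_b: str
    mean_diff: float
    lsd: float
    significant: bool


def lsd_posthoc(data: GroupedMeasurements, alpha: float = 0.05) -> list[LsdComparison]:
    """Fisher's least-significant-difference pairwise comparisons.

    LSD_ij = t(1 - alpha/2, df_within) * sqrt(MSW * (1/n_i + 1/n_j)); a
    pair is flagged when |mean_i - mean_j| exceeds its LSD.
    """
    res = one_way_anova(data, alpha)
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, res.df_within))
    out = []
    for a, b in combinations(data.groups, 2):
        lsd = t_crit * np.sqrt(res.ms_within * (1.0 / res.group_sizes[a] + 1.0 / res.group_sizes[b]))
        diff = res.group_means[a] - res.group_means[b]
        out.append(
            LsdComparison(a, b, float(diff), float(lsd), bool(abs(diff) > lsd))
        )
    return out


def hartley_fmax(data: GroupedMeasurements, critical_value: float | None = 39.2) -> tuple[float, bool | None]:
    """Hartley's max/min variance ratio across groups.

    Returns ``(ratio, equal_variances)`` where the verdict compares the
    ratio against ``critical_value`` (None skips the verdict).  Critical
    values are table lookups that depend on the number of groups and the
    per-group degrees of freedom; the default 39.2 corresponds to four
    groups of four at alpha 0.05, so supply your own for other designs.
    """
    data.require()
    variances = {k: float(np.var(v, ddof=1)) for k, v in data.groups.items()}
    vmin = min(variances.values())
    vmax = max(variances.values())
    if vmin == 0.0:
        ratio = 1.0 if vmax == 0.0 else float("inf")
    else:
        ratio = vmax / vmin
    verdict = None if critical_value is None else bool(ratio <= critical_value)
    return ratio, verdict


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric columns of ``table``."""
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least two numeric columns to correlate")
    return numeric.corr(method="pearson")
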