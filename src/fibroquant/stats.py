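"""One-way ANOVA and Tukey(-Kramer) post-hoc comparisons.

Both stages run either from raw per-animal values or from printed summary
statistics (n, mean, sample SD), reconstructing the between- and within-group
sums of squares from the summaries.  Published "mean +/- SD" values are
treated as sample SDs (n - 1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyComparison",
    "StarCode",
    "summarize",
    "anova_oneway_summary",
    "anova_oneway_raw",
    "tukey_hsd",
    "stars",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if not math.isfinite(self.mean) or not math.isfinite(self.sd):
            raise ValueError(f"group {self.label!r}: mean/sd must be finite")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    k_groups: int
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    F: float
    p: float
    degenerate: bool = False  # ss_within == 0 with unequal means

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass(frozen=True)
class TukeyComparison:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    q: float
    p_adj: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class StarCode:
    code: str  # one of {"ns", "*", "**", "***"}


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and sample SD (n - 1 denominator) of >= 2 finite values."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("summarize needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("summarize requires finite values")
    return GroupSummary(label=label, n=int(arr.size),
                        mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def anova_oneway_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from (n, mean, sd) summaries.

    grand mean = sum(n_i m_i) / sum(n_i);
    SS_between = sum n_i (m_i - grand)^2;  SS_within = sum (n_i - 1) s_i^2.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = np.array([g.n for g in groups], dtype=np.float64)
    m = np.array([g.mean for g in groups], dtype=np.float64)
    s = np.array([g.sd for g in groups], dtype=np.float64)
    k = len(groups)
    big_n = n.sum()
    grand = float((n * m).sum() / big_n)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s ** 2).sum())
    dfb, dfw = k - 1, int(big_n) - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("ANOVA undefined: zero variance within and between groups")
        return AnovaResult(k_groups=k, df_between=dfb, df_within=dfw,
                           ss_between=ssb, ss_within=0.0,
                           F=math.inf, p=0.0, degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(k_groups=k, df_between=dfb, df_within=dfw,
                       ss_between=ssb, ss_within=ssw, F=float(F), p=p)


def anova_oneway_raw(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None) -> AnovaResult:
    """Textbook one-way ANOVA decomposition from raw values.

    Identical contract to :func:`anova_oneway_summary`; the two agree to
    floating-point accuracy on the same data.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    for a in arrs:
        if a.size < 2:
            raise ValueError("each group needs at least 2 values")
        if not np.all(np.isfinite(a)):
            raise ValueError("ANOVA requires finite values")
    k = len(arrs)
    big_n = sum(a.size for a in arrs)
    grand = sum(a.sum() for a in arrs) / big_n
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    dfb, dfw = k - 1, big_n - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("ANOVA undefined: zero variance within and between groups")
        return AnovaResult(k_groups=k, df_between=dfb, df_within=dfw,
                           ss_between=ssb, ss_within=0.0,
                           F=math.inf, p=0.0, degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(k_groups=k, df_between=dfb, df_within=dfw,
                       ss_between=ssb, ss_within=ssw, F=float(F), p=p)


def _as_summaries(groups) -> list[GroupSummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(summarize(g, label=f"g{i}"))
    return out


def tukey_hsd(groups: Sequence) -> list[TukeyComparison]:
    """All-pairs Tukey-Kramer comparisons using the pooled within-group MS.

    Accepts raw value lists or :class:`GroupSummary` records.  For pair
    (i, j): se = sqrt(MSw/2 * (1/n_i + 1/n_j)), q = |m_i - m_j| / se, and
    p_adj is the upper tail of the studentized range distribution with
    (k, df_within).
    """
    summaries = _as_summaries(groups)
    anova = anova_oneway_summary(summaries)
    k, dfw = anova.k_groups, anova.df_within
    out: list[TukeyComparison] = []
    for gi, gj in combinations(summaries, 2):
        diff = gi.mean - gj.mean
        if anova.degenerate:
            p_adj = 0.0 if diff != 0 else 1.0
            out.append(TukeyComparison(pair=(gi.label, gj.label),
                                       mean_diff=diff, se=0.0,
                                       q=math.inf if diff != 0 else 0.0,
                                       p_adj=p_adj,
                                       significant=p_adj < ALPHA,
                                       degenerate=True))
            continue
        se = math.sqrt(anova.ms_within / 2.0 * (1.0 / gi.n + 1.0 / gj.n))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, dfw))
        p_adj = min(max(p_adj, 0.0), 1.0)
        out.append(TukeyComparison(pair=(gi.label, gj.label),
                                   mean_diff=diff, se=se, q=q, p_adj=p_adj,
                                   significant=p_adj < ALPHA))
    return out


def stars(p: float) -> StarCode:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return StarCode("***")
    if p < 0.01:
        return StarCode("**")
    if p < 0.05:
        return StarCode("*")
    return StarCode("ns")
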