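"""Group-level inference for the three-group relaxation cohort.

One-way ANOVA across healthy / NMIBC / NMIBC-after-PDT, pairwise post hoc
comparisons (Tukey HSD by default, Bonferroni-adjusted t tests optionally),
a summary-statistics ANOVA that reconstructs F from per-group mean/SD/n
only, and a paired t test for the pre-/post-PDT tumour measurements.

Significance is reported at the three conventional thresholds 0.05, 0.01
and 0.001. Variance-homogeneity (Levene) diagnostics are reported but never
gate the analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALPHA_LEVELS",
    "GroupSummary",
    "PairwiseComparison",
    "AnovaResult",
    "PairedResult",
    "summarize",
    "one_way_anova",
    "anova_from_summary",
    "posthoc_pairwise",
    "paired_delta_test",
    "levene_test",
]

ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.group!r}: sd must be >= 0")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p_adjusted: float
    method: str
    #: alpha -> significant at that threshold
    significant: dict[float, bool] = field(default_factory=dict)


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "posthoc": [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "p_adjusted": c.p_adjusted,
                    "method": c.method,
                    "significant": {str(a): s for a, s in c.significant.items()},
                }
                for c in self.posthoc
            ],
        }


@dataclass
class PairedResult:
    mean_delta: float
    t_stat: float
    p_value: float
    n: int


def _as_groups(measurements: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(measurements) < 2:
        raise ValueError("need >= 2 groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in measurements.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n = {v.size} < 2")
    return groups


def summarize(measurements: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Per-group n, mean and sample SD (n - 1 denominator)."""
    groups = _as_groups(measurements)
    return [
        GroupSummary(g, int(v.size), float(v.mean()), float(np.std(v, ddof=1)))
        for g, v in groups.items()
    ]


def one_way_anova(measurements: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within with exact dfs."""
    groups = _as_groups(measurements)
    values = list(groups.values())
    k = len(values)
    n_total = sum(v.size for v in values)
    f_stat, p_value = sps.f_oneway(*values)
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p_value),
    )


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) alone.

    ``SS_between = sum n_i (m_i - grand_mean)^2`` with grand mean weighted
    by n; ``MS_within`` pools the per-group variances. Algebraically
    identical to :func:`one_way_anova` applied to the underlying raw data.
    With all SDs zero and unequal means, F is reported as ``+inf`` (p = 0).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 group summaries")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    sd = np.array([s.sd for s in summaries], dtype=float)
    k = len(summaries)
    n_total = int(n.sum())
    df_between = k - 1
    df_within = n_total - k

    grand = float((n * m).sum() / n.sum())
    ss_between = float((n * (m - grand) ** 2).sum())
    ms_between = ss_between / df_between
    ms_within = float(((n - 1) * sd**2).sum() / df_within)

    if ms_within == 0:
        if ss_between == 0:
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_stat=f_stat,
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
    )


def _flag(p: float) -> dict[float, bool]:
    return {a: bool(p < a) for a in ALPHA_LEVELS}


def posthoc_pairwise(
    measurements: Mapping[str, Sequence[float]],
    method: str = "tukey",
) -> list[PairwiseComparison]:
    """All unordered pairwise comparisons with multiplicity-adjusted p.

    ``tukey`` uses the studentized-range (Tukey HSD) adjustment; in that
    setting identical groups yield an adjusted p of 1. ``bonferroni``
    multiplies each pairwise two-sample t-test p by the number of pairs,
    capped at 1.
    """
    groups = _as_groups(measurements)
    labels = list(groups)
    pairs = list(itertools.combinations(range(len(labels)), 2))

    out: list[PairwiseComparison] = []
    if method == "tukey":
        res = sps.tukey_hsd(*groups.values())
        for i, j in pairs:
            p = float(res.pvalue[i, j])
            out.append(
                PairwiseComparison(labels[i], labels[j], p, "tukey", _flag(p))
            )
    elif method == "bonferroni":
        m = len(pairs)
        for i, j in pairs:
            _, p_raw = sps.ttest_ind(groups[labels[i]], groups[labels[j]])
            p = min(1.0, m * float(p_raw))
            out.append(
                PairwiseComparison(labels[i], labels[j], p, "bonferroni", _flag(p))
            )
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return out


def paired_delta_test(
    pre: Mapping[str, float], post: Mapping[str, float]
) -> PairedResult:
    """Paired t test on post - pre differences, matched by sample_id.

    Degenerate zero-variance differences are handled exactly: all-equal
    nonzero deltas give t = ±inf, p = 0; all-zero deltas give t = 0, p = 1.
    """
    if set(pre) != set(post):
        only_pre = sorted(set(pre) - set(post))
        only_post = sorted(set(post) - set(pre))
        raise ValueError(
            f"mismatched sample_ids: pre-only {only_pre}, post-only {only_post}"
        )
    ids = sorted(pre)
    if len(ids) < 2:
        raise ValueError("need >= 2 paired samples")
    delta = np.array([post[i] - pre[i] for i in ids], dtype=float)
    mean_delta = float(delta.mean())
    if np.ptp(delta) == 0:
        if mean_delta == 0:
            return PairedResult(0.0, 0.0, 1.0, len(ids))
        return PairedResult(
            mean_delta, math.copysign(math.inf, mean_delta), 0.0, len(ids)
        )
    t_stat, p_value = sps.ttest_1samp(delta, 0.0)
    return PairedResult(mean_delta, float(t_stat), float(p_value), len(ids))


def levene_test(measurements: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Levene variance-homogeneity diagnostic (statistic, p); reported only."""
    groups = _as_groups(measurements)
    stat, p = sps.levene(*groups.values())
    return float(stat), float(p)
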