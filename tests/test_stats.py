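"""Group inference: ANOVA, summary-stat ANOVA, post hoc, paired delta."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from relaxmap import (
    GroupSummary,
    anova_from_summary,
    levene_test,
    one_way_anova,
    paired_delta_test,
    posthoc_pairwise,
    summarize,
)


def test_anova_hand_computation():
    res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
    assert res.f_stat == pytest.approx(13.5)
    assert (res.df_between, res.df_within) == (1, 4)


def test_anova_equal_means_gives_zero_f():
    res = one_way_anova({"a": [1, 3], "b": [2, 2]})
    assert res.f_stat == pytest.approx(0.0, abs=1e-12)


def test_anova_translation_invariance():
    groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [2.0, 2.5, 9.0]}
    shifted = {g: [v + 100.0 for v in vals] for g, vals in groups.items()}
    assert one_way_anova(groups).f_stat == pytest.approx(
        one_way_anova(shifted).f_stat, rel=1e-10
    )


def test_anova_small_group_rejected():
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


def test_summary_anova_equal_means_zero():
    res = anova_from_summary(
        [GroupSummary("a", 10, 5.0, 1.0), GroupSummary("b", 10, 5.0, 3.0)]
    )
    assert res.f_stat == 0.0


def test_summary_anova_zero_variance_unequal_means_is_inf():
    res = anova_from_summary(
        [GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 0.0)]
    )
    assert math.isinf(res.f_stat) and res.p_value == 0.0


def test_summary_anova_three_group_reference_values():
    """Pooled-variance F from the three tissue-group summaries (n = 25 each)
    matches the hand-derived 187.81 for T1."""
    res = anova_from_summary(
        [
            GroupSummary("healthy", 25, 1351.7, 271.1),
            GroupSummary("NMIBC", 25, 727.7, 145.0),
            GroupSummary("NMIBC_PDT", 25, 368.9, 65.2),
        ]
    )
    assert res.f_stat == pytest.approx(187.81, abs=0.01)
    assert (res.df_between, res.df_within) == (2, 72)
    assert res.p_value < 1e-4


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_summary_anova_identity_with_raw_anova(seed):
    """anova_from_summary ∘ summarize ≡ one_way_anova (algebraic identity)."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    groups = {
        f"g{i}": rng.normal(rng.uniform(-50, 50), rng.uniform(0.5, 20), rng.integers(3, 30))
        for i in range(k)
    }
    raw = one_way_anova(groups)
    from_summary = anova_from_summary(summarize(groups))
    assert from_summary.f_stat == pytest.approx(raw.f_stat, abs=1e-10, rel=1e-10)
    assert from_summary.p_value == pytest.approx(raw.p_value, abs=1e-10)
    assert (from_summary.df_between, from_summary.df_within) == (
        raw.df_between, raw.df_within,
    )


def test_anova_scale_invariance():
    rng = np.random.default_rng(0)
    groups = {f"g{i}": rng.normal(i * 10, 3, 20) for i in range(3)}
    scaled = {g: 7.3 * np.asarray(v) for g, v in groups.items()}
    assert one_way_anova(scaled).f_stat == pytest.approx(
        one_way_anova(groups).f_stat, rel=1e-10
    )


def test_posthoc_huge_separation_all_significant():
    rng = np.random.default_rng(42)
    groups = {
        "a": rng.normal(0, 1, 25),
        "b": rng.normal(50, 1, 25),
        "c": rng.normal(100, 1, 25),
    }
    for method in ("tukey", "bonferroni"):
        comparisons = posthoc_pairwise(groups, method=method)
        assert len(comparisons) == 3
        assert all(c.significant[0.001] for c in comparisons)


def test_posthoc_identical_groups_not_significant():
    vals = list(np.linspace(0, 10, 25))
    comparisons = posthoc_pairwise({"a": vals, "b": vals}, method="tukey")
    assert comparisons[0].p_adjusted > 0.99
    assert not comparisons[0].significant[0.05]


def test_bonferroni_is_three_times_raw_p():
    rng = np.random.default_rng(3)
    groups = {f"g{i}": rng.normal(i, 2.0, 15) for i in range(3)}
    comparisons = posthoc_pairwise(groups, method="bonferroni")
    for c in comparisons:
        _, p_raw = sps.ttest_ind(groups[c.group_a], groups[c.group_b])
        assert c.p_adjusted == pytest.approx(min(1.0, 3 * p_raw))
        assert c.p_adjusted >= p_raw


def test_paired_delta_degenerate_cases():
    pre = {f"s{i}": 100.0 + i for i in range(10)}
    same = paired_delta_test(pre, dict(pre))
    assert same.t_stat == 0.0 and same.mean_delta == 0.0 and same.p_value == 1.0
    shifted = {k: v - 10.0 for k, v in pre.items()}
    res = paired_delta_test(pre, shifted)
    assert res.mean_delta == -10.0 and res.p_value == 0.0


def test_paired_delta_mismatched_ids_rejected():
    with pytest.raises(ValueError, match="mismatched"):
        paired_delta_test({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0})


def test_paired_delta_simulation_recovery():
    """True Δ = -350 with SD 100 over n = 25 is recovered within 3 SE."""
    rng = np.random.default_rng(7)
    n = 25
    pre = {f"s{i}": rng.normal(700, 150) for i in range(n)}
    post = {k: v + rng.normal(-350, 100) for k, v in pre.items()}
    res = paired_delta_test(pre, post)
    assert abs(res.mean_delta - (-350)) < 3 * 100 / np.sqrt(n)
    assert res.p_value < 1e-6


def test_levene_reported_not_gating():
    rng = np.random.default_rng(5)
    stat, p = levene_test({"a": rng.normal(0, 1, 30), "b": rng.normal(0, 5, 30)})
    assert stat > 0 and 0 <= p <= 1
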