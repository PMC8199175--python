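"""Fold change, ANOVA/post-hoc, Welch t, BH adjustment, status calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oncomir.diffexp import (
    anova_posthoc,
    bh_adjust,
    call_de_status,
    de_anova_scheme,
    de_ttest_scheme,
    fold_change,
    welch_t,
)
from oncomir.io_matrix import normalize_rpm
from conftest import make_matrix


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------


def test_fold_change_equal_means_is_one():
    assert fold_change([10, 10], [10, 10]) == pytest.approx(1.0)


def test_fold_change_presence_absence_hand_value():
    # means 20 vs 0 with epsilon 0.01 -> 20.01 / 0.01 = 2001
    assert fold_change([20, 20], [0, 0]) == pytest.approx(2001.0)


@given(
    a=st.lists(st.floats(0, 1e4), min_size=1, max_size=10),
    b=st.lists(st.floats(0, 1e4), min_size=1, max_size=10),
)
@settings(max_examples=100, deadline=None)
def test_fold_change_reciprocity(a, b):
    assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


def test_welch_identical_groups_p_one():
    t, p = welch_t([3, 3, 3], [3, 3, 3])
    assert (t, p) == (0.0, 1.0)


def test_welch_swap_negates_t_preserves_p(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 12)
    t1, p1 = welch_t(a, b)
    t2, p2 = welch_t(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_welch_matches_scipy_on_random_instances(rng):
    for _ in range(100):
        na, nb = rng.integers(2, 20), rng.integers(2, 20)
        a = rng.normal(rng.normal(), rng.uniform(0.5, 3), na)
        b = rng.normal(rng.normal(), rng.uniform(0.5, 3), nb)
        t, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


# ---------------------------------------------------------------------------
# ANOVA + post-hoc
# ---------------------------------------------------------------------------


def _anova_oracle(groups):
    """Brute-force sums-of-squares one-way ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw)


def test_anova_identical_values_f_zero_p_one():
    res = anova_posthoc({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
    assert res["F"] == 0.0 and res["p"] == 1.0
    assert all(p == 1.0 for p in res["pairwise"].values())


def test_anova_two_groups_is_squared_pooled_t(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 12)
    res = anova_posthoc({"a": a, "b": b})
    t, _ = stats.ttest_ind(a, b, equal_var=True)
    assert res["F"] == pytest.approx(t**2, rel=1e-10)


def test_anova_matches_bruteforce_oracle(rng):
    for _ in range(100):
        groups = {
            name: rng.normal(rng.normal(), 1.0, rng.integers(3, 15))
            for name in ("FL", "ANL", "LUAD")
        }
        res = anova_posthoc(groups)
        F, p = _anova_oracle(list(groups.values()))
        assert res["F"] == pytest.approx(F, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)
        ref = stats.f_oneway(*groups.values())
        assert res["F"] == pytest.approx(ref.statistic, rel=1e-10)


def test_lsd_posthoc_gated_on_omnibus(rng):
    # three groups drawn from one distribution -> omnibus usually ns
    for _ in range(20):
        groups = {n: rng.normal(0, 1, 10) for n in ("a", "b", "c")}
        res = anova_posthoc(groups)
        if res["p"] >= 0.05:
            assert all(p == 1.0 for p in res["pairwise"].values())


def test_lsd_posthoc_uses_pooled_variance(rng):
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(3, 1, 12),
              "c": rng.normal(0, 1, 9)}
    res = anova_posthoc(groups)
    assert res["p"] < 0.05
    ns = {k: len(v) for k, v in groups.items()}
    n_total, k = sum(ns.values()), 3
    msw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
              for v in groups.values()) / (n_total - k)
    t = (np.mean(groups["a"]) - np.mean(groups["b"])) / np.sqrt(
        msw * (1 / ns["a"] + 1 / ns["b"]))
    expected = 2 * stats.t.sf(abs(t), n_total - k)
    assert res["pairwise"][("a", "b")] == pytest.approx(expected, rel=1e-10)


def test_tukey_posthoc_matches_scipy(rng):
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(2, 1, 10),
              "c": rng.normal(4, 1, 10)}
    res = anova_posthoc(groups, posthoc="tukey")
    ref = stats.tukey_hsd(*groups.values())
    assert res["pairwise"][("a", "b")] == pytest.approx(ref.pvalue[0, 1], abs=1e-8)
    assert res["pairwise"][("b", "c")] == pytest.approx(ref.pvalue[1, 2], abs=1e-8)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Literal step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        j_values = [p[order[j]] * m / (j + 1) for j in range(rank_idx, m)]
        q[i] = min(1.0, min(j_values))
    return q


def test_bh_single_p_unchanged():
    assert bh_adjust([0.031])[0] == pytest.approx(0.031)


def test_bh_hand_stepup_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_matches_oracle_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(200):
        p = rng.uniform(0, 1, rng.integers(1, 50))
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None)
def test_bh_dominates_input_and_preserves_order(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Status calls
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (2.0, 0.001, "ns"),  # FC threshold is strict
        (3.0, 0.04, "over"),
        (0.3, 0.01, "under"),
        (0.5, 0.001, "ns"),
        (3.0, 0.05, "ns"),  # p threshold is strict too
        (1.0, 0.5, "ns"),
    ],
)
def test_call_de_status_thresholds(fc, p, expected):
    assert call_de_status(fc, p) == expected


def test_whole_matrix_schemes_agree_with_manual_calls(rng):
    """Matrix-level DE wrappers produce the same calls as the scalar path."""
    groups = ["FL"] * 5 + ["ANL"] * 6 + ["LUAD"] * 5
    counts = rng.integers(0, 500, size=(12, len(groups))) + 1
    m = normalize_rpm(make_matrix(counts, groups=groups))
    de = de_anova_scheme(m, comparisons=[("LUAD", "ANL"), ("FL", "ANL")],
                         groups=["FL", "ANL", "LUAD"])
    assert set(de["comparison"]) == {"LUAD_vs_ANL", "FL_vs_ANL"}
    assert len(de) == 24
    for _, row in de.iterrows():
        assert row["status"] == call_de_status(row["fc"], row["p_raw"])
    de_t = de_ttest_scheme(m, comparison=("LUAD", "ANL"))
    assert np.allclose(de_t["p_adj"], bh_adjust(de_t["p_raw"].to_numpy()))
    for _, row in de_t.iterrows():
        assert row["status"] == call_de_status(row["fc"], row["p_adj"])
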