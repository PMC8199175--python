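"""Oncofetal criteria, exact congruence test, cluster counts, shared targets."""

import itertools
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncomir.discovery import (
    ConsistencyError,
    classify_oncofetal,
    congruence_table,
    congruence_test,
    count_in_region,
    oncofetal_frame,
    shared_targets,
)
from oncomir.io_matrix import GenomicLocus


# ---------------------------------------------------------------------------
# Oncofetal classification
# ---------------------------------------------------------------------------


def _de(rows, comparison):
    return pd.DataFrame(
        [(m, comparison, fc, p, p, s) for m, fc, p, s in rows],
        columns=["mirna_id", "comparison", "fc", "p_raw", "p_adj", "status"],
    )


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["mirna_id", "fraction_positive", "expressed"]
    ).set_index("mirna_id")


def test_all_criteria_met_is_oncofetal():
    de_d = pd.concat([
        _de([("m1", 5, 0.01, "over")], "LUAD_vs_ANL"),
        _de([("m1", 4, 0.01, "over")], "FL_vs_ANL"),
    ])
    de_v = _de([("m1", 6, 0.001, "over")], "LUAD_vs_ANL")
    anl_d = _calls([("m1", 0.05, False)])
    anl_v = _calls([("m1", 0.0, False)])
    calls = classify_oncofetal(de_d, de_v, anl_d, anl_v)
    assert calls[0].oncofetal and calls[0].crit_a and calls[0].crit_b and calls[0].crit_c


def test_anl_fraction_exactly_ten_percent_fails_criterion_c():
    de_d = pd.concat([
        _de([("m1", 5, 0.01, "over")], "LUAD_vs_ANL"),
        _de([("m1", 4, 0.01, "over")], "FL_vs_ANL"),
    ])
    de_v = _de([("m1", 6, 0.001, "over")], "LUAD_vs_ANL")
    anl_d = _calls([("m1", 0.10, True)])  # 0.10 means expressed
    anl_v = _calls([("m1", 0.0, False)])
    calls = classify_oncofetal(de_d, de_v, anl_d, anl_v)
    assert calls[0].crit_a and calls[0].crit_b
    assert not calls[0].crit_c and not calls[0].oncofetal


def test_missing_mirna_is_consistency_error():
    de_d = pd.concat([
        _de([("m1", 5, 0.01, "over")], "LUAD_vs_ANL"),
        _de([("m1", 4, 0.01, "over")], "FL_vs_ANL"),
    ])
    de_v = _de([("m1", 6, 0.001, "over")], "LUAD_vs_ANL")
    anl_d = _calls([("m1", 0.0, False)])
    anl_v = _calls([("other", 0.0, False)])
    with pytest.raises(ConsistencyError):
        classify_oncofetal(de_d, de_v, anl_d, anl_v)


def test_oncofetal_frame_layout():
    de_d = pd.concat([
        _de([("m1", 5, 0.01, "over"), ("m2", 1, 0.9, "ns")], "LUAD_vs_ANL"),
        _de([("m1", 4, 0.01, "over"), ("m2", 1, 0.9, "ns")], "FL_vs_ANL"),
    ])
    de_v = _de([("m1", 6, 0.001, "over"), ("m2", 1, 0.9, "ns")], "LUAD_vs_ANL")
    anl = _calls([("m1", 0.0, False), ("m2", 0.5, True)])
    df = oncofetal_frame(classify_oncofetal(de_d, de_v, anl, anl))
    assert list(df.columns) == ["crit_a", "crit_b", "crit_c", "oncofetal"]
    assert bool(df.loc["m1", "oncofetal"]) and not bool(df.loc["m2", "oncofetal"])


# ---------------------------------------------------------------------------
# Exact congruence test
# ---------------------------------------------------------------------------


def _fisher_oracle(table):
    """Independent brute-force Freeman–Halton enumeration (itertools)."""
    t = np.asarray(table, dtype=int)
    r, c = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(tab):
        num = 1.0
        for x in r:
            num *= factorial(int(x))
        for x in c:
            num *= factorial(int(x))
        den = float(factorial(n))
        for x in np.asarray(tab).ravel():
            den *= factorial(int(x))
        return num / den

    def tables(row_margins, col_rem):
        if len(row_margins) == 1:
            yield [list(col_rem)]
            return
        ranges = [range(min(row_margins[0], col_rem[j]) + 1)
                  for j in range(len(col_rem))]
        for combo in itertools.product(*ranges):
            if sum(combo) != row_margins[0]:
                continue
            rest = [col_rem[j] - combo[j] for j in range(len(col_rem))]
            for tail in tables(row_margins[1:], rest):
                yield [list(combo)] + tail

    p_obs = prob(t)
    return sum(p for tab in tables(list(r), list(c))
               if (p := prob(tab)) <= p_obs * (1 + 1e-7))


def test_2x2_matches_bruteforce_and_scipy():
    table = [[1, 9], [11, 3]]
    res = congruence_test(table)
    assert res["method"] == "enumeration"
    assert res["p"] == pytest.approx(_fisher_oracle(table), rel=1e-9)
    assert res["p"] == pytest.approx(stats.fisher_exact(table).pvalue, rel=1e-9)


def test_random_2x2_matches_scipy(rng):
    for _ in range(100):
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        res = congruence_test(table)
        assert res["p"] == pytest.approx(stats.fisher_exact(table).pvalue,
                                         rel=1e-9, abs=1e-12)


def test_random_3x3_matches_bruteforce(rng):
    for _ in range(25):
        table = rng.integers(0, 5, size=(3, 3))
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        res = congruence_test(table)
        assert res["method"] == "enumeration"
        assert res["p"] == pytest.approx(_fisher_oracle(table), rel=1e-9)


def test_independence_table_p_near_one():
    # outer-product margins: the observed table is the modal one
    res = congruence_test([[4, 2], [2, 1]])
    assert res["p"] > 0.9


def test_row_permutation_leaves_p_unchanged():
    t = np.array([[5, 1, 0], [2, 6, 1], [0, 2, 7]])
    p1 = congruence_test(t)["p"]
    p2 = congruence_test(t[[2, 0, 1]])["p"]
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_monte_carlo_agrees_with_enumeration():
    t = [[8, 2, 1], [2, 9, 2], [1, 1, 10]]
    exact = congruence_test(t)
    mc = congruence_test(t, seed=5, max_enumeration=0, mc_draws=200_000)
    assert mc["method"] == "monte_carlo"
    assert mc["p"] == pytest.approx(exact["p"], rel=0.15, abs=1e-4)


def test_congruence_rejects_bad_tables():
    with pytest.raises(ValueError):
        congruence_test([[1, -2], [0, 3]])
    with pytest.raises(ValueError):
        congruence_test([[0, 0], [0, 0]])


def test_congruence_table_construction():
    de_a = pd.DataFrame({
        "mirna_id": ["m1", "m2", "m3", "m4"],
        "comparison": "LUAD_vs_ANL",
        "status": ["over", "over", "under", "ns"],
    })
    de_b = pd.DataFrame({
        "mirna_id": ["m1", "m2", "m3", "m4"],
        "comparison": "FL_vs_ANL",
        "status": ["over", "ns", "under", "ns"],
    })
    t = congruence_table(de_a, de_b)
    assert t.to_numpy().tolist() == [[1, 0, 1], [0, 1, 0], [0, 0, 1]]
    t2 = congruence_table(de_a, de_b, collapse=True)
    assert t2.to_numpy().sum() == 4 and t2.shape == (2, 2)


# ---------------------------------------------------------------------------
# Cluster localization
# ---------------------------------------------------------------------------

REGION = GenomicLocus("chr14", "+", 100_800_000, 101_100_000)


def test_count_in_region_empty_hits():
    assert count_in_region([], {}, REGION) == 0


def test_count_in_region_strand_ignored_and_order_invariant(rng):
    ann = {
        "a": GenomicLocus("chr14", "-", 100_900_000, 100_900_021),
        "b": GenomicLocus("chr14", "+", 101_099_980, 101_100_000),
        "c": GenomicLocus("chr14", "+", 101_099_990, 101_100_001),  # sticks out
        "d": GenomicLocus("chr2", "+", 100_900_000, 100_900_021),
    }
    hits = list(ann)
    assert count_in_region(hits, ann, REGION) == 2
    assert count_in_region(hits[::-1], ann, REGION) == 2


def test_count_in_region_matches_bruteforce(rng):
    ann = {}
    for i in range(200):
        chrom = "chr14" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(100_000_000, 102_000_000))
        ann[f"m{i}"] = GenomicLocus(chrom, "+", start, start + 21)
    hits = list(ann)
    expected = sum(
        1 for m in hits
        if ann[m].chrom == "chr14"
        and ann[m].start >= REGION.start and ann[m].end <= REGION.end
    )
    assert count_in_region(hits, ann, REGION) == expected


def test_count_in_region_missing_annotation():
    with pytest.raises(ConsistencyError):
        count_in_region(["nope"], {}, REGION)


# ---------------------------------------------------------------------------
# Shared targets
# ---------------------------------------------------------------------------


def _targets(pairs):
    return pd.DataFrame(pairs, columns=["mirna_id", "gene_symbol"])


def test_shared_targets_threshold_boundary():
    pairs = [("m1", "G1"), ("m2", "G1"), ("m3", "G1"), ("m1", "G2"), ("m2", "G2")]
    assert shared_targets(_targets(pairs), min_mirnas=3) == ["G1"]


def test_shared_targets_min_one_returns_all_genes():
    pairs = [("m1", "G1"), ("m2", "G2")]
    assert shared_targets(_targets(pairs), min_mirnas=1) == ["G1", "G2"]


def test_shared_targets_deduplicates_pairs():
    # repeated (miRNA, gene) pairs must not inflate the distinct-miRNA count
    pairs = [("m1", "G1")] * 5
    assert shared_targets(_targets(pairs), min_mirnas=2) == []
    assert shared_targets(_targets(pairs + [("m2", "G1")]), min_mirnas=2) == ["G1"]


def test_shared_targets_matches_groupby_oracle(rng):
    pairs = [(f"m{rng.integers(6)}", f"G{rng.integers(30)}") for _ in range(300)]
    got = shared_targets(_targets(pairs), min_mirnas=3)
    counts = {}
    for m, g in set(pairs):
        counts[g] = counts.get(g, 0) + 1
    assert got == sorted(g for g, c in counts.items() if c >= 3)
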