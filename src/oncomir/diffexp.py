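"""Dual-scheme differential expression between sample groups.

Two cohort-specific testing schemes are used:

* ``bcwh`` (discovery): one-way ANOVA on log2(RPM+1) across FL/ANL/LUAD with
  a pairwise post-hoc p-value per comparison (Fisher's LSD gated on the
  omnibus test by default, Tukey HSD optionally); no FDR step.
* ``tcga`` (validation): unpaired Welch t-test on log2(RPM+1) per miRNA with
  Benjamini–Hochberg adjustment across all tested miRNAs.

In both schemes a miRNA is called ``over`` when the fold change of group
mean RPM exceeds 2 and the scheme's p-value is below 0.05, ``under`` when
the fold change is below 0.5 with the same p-criterion, else ``ns``. Both
fold-change comparisons are strict. Fold change is the ratio of raw group
mean RPM (numerator = first-named group) with a small epsilon (0.01 RPM)
added to both means so presence/absence contrasts stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_matrix import ExpressionMatrix, UnitError

DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_FC_EPSILON = 0.01
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEResult:
    """Fold change, p-values and status call for one miRNA in one comparison."""

    mirna_id: str
    comparison: str  # e.g. "LUAD_vs_ANL"
    fc: float
    p_raw: float
    p_adj: float | None  # BH-adjusted p (tcga scheme only)
    status: str  # over / under / ns


def fold_change(rpm_a, rpm_b, epsilon: float = DEFAULT_FC_EPSILON) -> float:
    """Ratio of group mean RPM, numerator first, epsilon added to both means."""
    return (float(np.mean(rpm_a)) + epsilon) / (float(np.mean(rpm_b)) + epsilon)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j ≥ i} p_(j)·m/j over the ascending order statistics,
    clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(rpm_a, rpm_b) -> tuple[float, float]:
    """Two-sided unpaired t-test with Welch's correction on the given values.

    Degenerate case (zero variance in both groups, equal means) returns
    t = 0, p = 1.
    """
    a = np.asarray(rpm_a, dtype=float)
    b = np.asarray(rpm_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1)) + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def anova_posthoc(values_by_group: dict[str, np.ndarray],
                  posthoc: str = "lsd") -> dict:
    """One-way fixed-effects ANOVA with pairwise post-hoc p-values.

    Parameters
    ----------
    values_by_group
        Mapping of group label → 1-D array of (already transformed)
        expression values, ≥2 samples per group.
    posthoc
        ``"lsd"`` — Fisher's least significant difference: pairwise t using
        the pooled ANOVA error variance with its degrees of freedom, reported
        only when the omnibus p is below 0.05 (otherwise 1). ``"tukey"`` —
        Tukey's HSD via the studentized-range distribution, not gated.

    Returns a dict with keys ``F``, ``p`` (omnibus) and ``pairwise``
    (mapping of (group_a, group_b) → post-hoc p).
    """
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least two samples per group")
    ns = np.array([a.size for a in arrays])
    k, n_total = len(arrays), int(ns.sum())
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return {"F": 0.0, "p": 1.0, "pairwise": {p: 1.0 for p in _pairs(groups)}}
    if ss_within == 0:
        F, p_omni = np.inf, 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p_omni = float(stats.f.sf(F, df_b, df_w))
    msw = ss_within / df_w

    pairwise: dict[tuple[str, str], float] = {}
    for i, j in _pair_indices(k):
        pair = (groups[i], groups[j])
        if posthoc == "lsd":
            if p_omni >= 0.05:
                pairwise[pair] = 1.0
                continue
            if msw == 0:
                pairwise[pair] = 0.0 if means[i] != means[j] else 1.0
                continue
            t = (means[i] - means[j]) / np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
            pairwise[pair] = float(2.0 * stats.t.sf(abs(t), df_w))
        elif posthoc == "tukey":
            if msw == 0:
                pairwise[pair] = 0.0 if means[i] != means[j] else 1.0
                continue
            q = abs(means[i] - means[j]) / np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
            pairwise[pair] = float(stats.studentized_range.sf(q, k, df_w))
        else:
            raise ValueError(f"unknown post-hoc method {posthoc!r}")
    return {"F": float(F), "p": float(p_omni), "pairwise": pairwise}


def _pairs(groups):
    return [(groups[i], groups[j]) for i, j in _pair_indices(len(groups))]


def _pair_indices(k):
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def call_de_status(fc: float, p: float,
                   alpha: float = DEFAULT_ALPHA,
                   fc_threshold: float = DEFAULT_FC_THRESHOLD) -> str:
    """over / under / ns from a fold change and the scheme's p-value.

    ``over`` iff fc > fc_threshold and p < alpha; ``under`` iff
    fc < 1/fc_threshold and p < alpha; both fold-change comparisons strict.
    """
    if p < alpha:
        if fc > fc_threshold:
            return "over"
        if fc < 1.0 / fc_threshold:
            return "under"
    return "ns"


# ---------------------------------------------------------------------------
# Whole-matrix comparisons
# ---------------------------------------------------------------------------


def _log_transform(rpm: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log2(rpm + pseudocount)


def de_anova_scheme(m: ExpressionMatrix, comparisons: list[tuple[str, str]],
                    groups: list[str] | None = None,
                    posthoc: str = "lsd",
                    alpha: float = DEFAULT_ALPHA,
                    fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    fc_epsilon: float = DEFAULT_FC_EPSILON,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """ANOVA + post-hoc scheme over every miRNA (discovery-cohort style).

    ``comparisons`` are (numerator_group, denominator_group) pairs; the
    omnibus ANOVA spans ``groups`` (default: all groups appearing in any
    comparison). Returns a tidy frame with one row per miRNA × comparison.
    """
    if m.unit != "rpm":
        raise UnitError("differential expression needs an RPM matrix")
    if groups is None:
        groups = sorted({g for pair in comparisons for g in pair})
    cols = {g: m.samples_in_group(g) for g in groups}
    for g, s in cols.items():
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for mirna in m.mirna_ids:
        rpm_row = m.values.loc[mirna]
        by_group = {g: _log_transform(rpm_row[s].to_numpy(), pseudocount)
                    for g, s in cols.items()}
        res = anova_posthoc(by_group, posthoc=posthoc)
        for ga, gb in comparisons:
            p_pair = res["pairwise"].get((ga, gb), res["pairwise"].get((gb, ga)))
            fc = fold_change(rpm_row[cols[ga]], rpm_row[cols[gb]], epsilon=fc_epsilon)
            rows.append((mirna, f"{ga}_vs_{gb}", fc, p_pair, np.nan,
                         call_de_status(fc, p_pair, alpha, fc_threshold)))
    return _frame(rows)


def de_ttest_scheme(m: ExpressionMatrix, comparison: tuple[str, str],
                    alpha: float = DEFAULT_ALPHA,
                    fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    fc_epsilon: float = DEFAULT_FC_EPSILON,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Welch t + Benjamini–Hochberg scheme (validation-cohort style).

    BH adjustment is applied across all miRNAs of this one comparison; the
    status call uses the adjusted p.
    """
    if m.unit != "rpm":
        raise UnitError("differential expression needs an RPM matrix")
    ga, gb = comparison
    sa, sb = m.samples_in_group(ga), m.samples_in_group(gb)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need at least 2 samples per group")
    a = _log_transform(m.values[sa].to_numpy(), pseudocount)
    b = _log_transform(m.values[sb].to_numpy(), pseudocount)
    p_raw = np.array([welch_t(a[i], b[i])[1] for i in range(a.shape[0])])
    p_adj = bh_adjust(p_raw)
    rows = []
    for i, mirna in enumerate(m.mirna_ids):
        fc = fold_change(m.values.loc[mirna, sa], m.values.loc[mirna, sb],
                         epsilon=fc_epsilon)
        rows.append((mirna, f"{ga}_vs_{gb}", fc, float(p_raw[i]), float(p_adj[i]),
                     call_de_status(fc, p_adj[i], alpha, fc_threshold)))
    return _frame(rows)


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["mirna_id", "comparison", "fc", "p_raw", "p_adj", "status"]
    )


def write_de_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
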