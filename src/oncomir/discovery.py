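"""Oncofetal classification, cross-tissue congruence, and cluster localization.

A miRNA is called *oncofetal* when all three criteria hold:

(a) overexpressed in the discovery cohort in both LUAD vs ANL and FL vs ANL;
(b) overexpressed in the validation cohort in LUAD vs ANL;
(c) not expressed (fewer than 10% of samples RPM-positive) in the ANL group
    of *both* cohorts.

The LUAD↔FL congruence of differential-expression status is quantified with
a two-sided exact test on the 3×3 (over/under/ns × over/under/ns)
contingency table — the Freeman–Halton generalization of Fisher's exact
test — by exhaustive enumeration of margin-fixed tables when feasible and a
seeded Patefield Monte Carlo otherwise. Genomic-cluster localization counts
hits fully contained in a region (strand ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

from .io_matrix import GenomicLocus

STATUS_LEVELS = ("over", "under", "ns")

#: largest number of margin-fixed tables we will enumerate exhaustively
_ENUMERATION_CAP = 2_000_000
_MC_DRAWS = 1_000_000


class ConsistencyError(ValueError):
    """Inputs disagree about which miRNAs exist."""


@dataclass(frozen=True)
class OncofetalCall:
    """Per-miRNA breakdown of the three oncofetal criteria."""

    mirna_id: str
    crit_a: bool  # over in discovery LUAD vs ANL and FL vs ANL
    crit_b: bool  # over in validation LUAD vs ANL
    crit_c: bool  # not expressed in ANL of either cohort

    @property
    def oncofetal(self) -> bool:
        return self.crit_a and self.crit_b and self.crit_c


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _status_map(de: pd.DataFrame, comparison: str) -> pd.Series:
    sub = de[de["comparison"] == comparison]
    if sub.empty:
        raise ConsistencyError(f"no DE results for comparison {comparison!r}")
    return sub.set_index("mirna_id")["status"]


def classify_oncofetal(de_discovery: pd.DataFrame, de_validation: pd.DataFrame,
                       calls_discovery_anl: pd.DataFrame,
                       calls_validation_anl: pd.DataFrame) -> list[OncofetalCall]:
    """Evaluate criteria (a)/(b)/(c) for every miRNA.

    Parameters are the tidy DE frames of the two cohorts (discovery must
    contain the LUAD_vs_ANL and FL_vs_ANL comparisons, validation
    LUAD_vs_ANL) and the ANL expression-call frames of both cohorts
    (indexed by mirna_id with an ``expressed`` column). Every miRNA must
    appear in all four inputs.
    """
    luad_d = _status_map(de_discovery, "LUAD_vs_ANL")
    fl_d = _status_map(de_discovery, "FL_vs_ANL")
    luad_v = _status_map(de_validation, "LUAD_vs_ANL")
    mirnas = list(luad_d.index)
    for name, idx in (("discovery FL_vs_ANL", fl_d.index),
                      ("validation LUAD_vs_ANL", luad_v.index),
                      ("discovery ANL calls", calls_discovery_anl.index),
                      ("validation ANL calls", calls_validation_anl.index)):
        missing = set(mirnas) - set(idx)
        if missing:
            raise ConsistencyError(f"miRNAs missing from {name}: {sorted(missing)}")
    out = []
    for m in mirnas:
        a = luad_d[m] == "over" and fl_d[m] == "over"
        b = luad_v[m] == "over"
        c = (not calls_discovery_anl.loc[m, "expressed"]
             and not calls_validation_anl.loc[m, "expressed"])
        out.append(OncofetalCall(m, bool(a), bool(b), bool(c)))
    return out


def oncofetal_frame(calls: list[OncofetalCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.mirna_id, c.crit_a, c.crit_b, c.crit_c, c.oncofetal) for c in calls],
        columns=["mirna_id", "crit_a", "crit_b", "crit_c", "oncofetal"],
    ).set_index("mirna_id")


# ---------------------------------------------------------------------------
# Congruence: exact test on the status × status table
# ---------------------------------------------------------------------------


def congruence_table(de_a: pd.DataFrame, de_b: pd.DataFrame,
                     comparison_a: str = "LUAD_vs_ANL",
                     comparison_b: str = "FL_vs_ANL",
                     collapse: bool = False) -> pd.DataFrame:
    """Status-by-status contingency table over the shared miRNAs.

    Rows = status in ``comparison_a`` (taken from ``de_a``), columns = status
    in ``comparison_b`` (from ``de_b``). ``collapse=True`` folds over/under
    into one "significant" level, giving a 2×2 table.
    """
    sa = _status_map(de_a, comparison_a)
    sb = _status_map(de_b, comparison_b)
    common = sa.index.intersection(sb.index)
    if len(common) == 0:
        raise ConsistencyError("no shared miRNAs between the two comparisons")
    sa, sb = sa[common], sb[common]
    if collapse:
        sa = sa.where(sa == "ns", "significant")
        sb = sb.where(sb == "ns", "significant")
        levels = ["significant", "ns"]
    else:
        levels = list(STATUS_LEVELS)
    table = pd.crosstab(sa, sb).reindex(index=levels, columns=levels, fill_value=0)
    table.index.name, table.columns.name = comparison_a, comparison_b
    return table


def _table_logprob_const(r: np.ndarray, c: np.ndarray, lg: np.ndarray) -> float:
    n = int(r.sum())
    return float(lg[r].sum() + lg[c].sum() - lg[n])


def _enumeration_bound(r: np.ndarray, ncols: int) -> float:
    """Upper bound on the number of margin-fixed tables (compositions)."""
    from math import comb

    bound = 1.0
    for ri in r[:-1]:
        bound *= comb(int(ri) + ncols - 1, ncols - 1)
    return bound


def _exact_pvalue(t: np.ndarray) -> float:
    """Two-sided exact p by exhaustive enumeration of margin-fixed tables."""
    r, c = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    lg = gammaln(np.arange(n + 1, dtype=float) + 1.0)  # lg[k] = log k!
    logp_obs = -lg[t].sum()
    total = 0.0
    extreme = 0.0
    tol = 1e-7 * abs(logp_obs) + 1e-12

    def rec(row: int, col_rem: np.ndarray, acc: float) -> None:
        nonlocal total, extreme
        if row == len(r) - 1:
            logp = acc - lg[col_rem].sum()
            w = np.exp(logp)
            total += w
            if logp <= logp_obs + tol:
                extreme += w
            return
        # enumerate compositions of r[row] over the columns, bounded by col_rem
        def comp(j: int, remaining: int, partial: float, used: list[int]) -> None:
            if j == len(col_rem) - 1:
                if remaining <= col_rem[j]:
                    rec(row + 1, col_rem - np.array(used + [remaining]),
                        partial - lg[remaining])
                return
            for v in range(min(remaining, int(col_rem[j])) + 1):
                comp(j + 1, remaining - v, partial - lg[v], used + [v])

        comp(0, int(r[row]), acc, [])

    rec(0, c.astype(int).copy(), 0.0)
    # normalize: Σ_tables P = 1 up to float error; dividing out removes it
    return min(1.0, extreme / total)


def _montecarlo_pvalue(t: np.ndarray, seed: int, draws: int = _MC_DRAWS) -> float:
    r, c = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    lg = gammaln(np.arange(n + 1, dtype=float) + 1.0)
    logp_obs = -lg[t].sum()
    tol = 1e-7 * abs(logp_obs) + 1e-12
    rng = np.random.default_rng(seed)
    samples = random_table(r, c).rvs(draws, random_state=rng)
    logp = -lg[samples.astype(int)].sum(axis=(1, 2))
    hits = int(np.count_nonzero(logp <= logp_obs + tol))
    return (hits + 1) / (draws + 1)


def congruence_test(table, seed: int = 0, max_enumeration: float = _ENUMERATION_CAP,
                    mc_draws: int = _MC_DRAWS) -> dict:
    """Two-sided exact (Freeman–Halton) test of independence on an r×c table.

    Exhaustive enumeration over all tables with the observed margins when the
    total is ≤ 500 and the enumeration is tractable; otherwise a seeded
    Patefield Monte Carlo estimate with ``mc_draws`` tables. Two-sided in the
    usual sense: sums the probability of every margin-fixed table no more
    probable than the observed one.

    Returns ``{"p": float, "method": "enumeration" | "monte_carlo",
    "table": list}``.
    """
    t = np.asarray(table, dtype=int)
    if (np.asarray(table, dtype=float) != t).any():
        raise ValueError("contingency table must be integer")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    n = int(t.sum())
    if n < 1:
        raise ValueError("contingency table is empty")
    # drop all-zero rows/columns: they carry no information and break margins
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] == 1 or t.shape[1] == 1:
        return {"p": 1.0, "method": "degenerate", "table": t.tolist()}
    bound = _enumeration_bound(t.sum(axis=1), t.shape[1])
    if n <= 500 and bound <= max_enumeration:
        return {"p": _exact_pvalue(t), "method": "enumeration", "table": t.tolist()}
    return {"p": _montecarlo_pvalue(t, seed=seed, draws=mc_draws),
            "method": "monte_carlo", "table": t.tolist()}


# ---------------------------------------------------------------------------
# Cluster localization and shared targets
# ---------------------------------------------------------------------------


def count_in_region(hits: list[str], annotation: dict[str, GenomicLocus],
                    region: GenomicLocus) -> int:
    """Number of hit miRNAs whose locus is fully inside ``region``.

    Containment: same chromosome, start ≥ region.start and end ≤ region.end;
    strand is ignored.
    """
    missing = [h for h in hits if h not in annotation]
    if missing:
        raise ConsistencyError(f"hits without annotation: {missing}")
    count = 0
    for h in hits:
        loc = annotation[h]
        if (loc.chrom == region.chrom
                and loc.start >= region.start and loc.end <= region.end):
            count += 1
    return count


def shared_targets(target_table: pd.DataFrame, min_mirnas: int = 3) -> list[str]:
    """Genes predicted as targets of at least ``min_mirnas`` distinct miRNAs.

    ``target_table`` has columns ``mirna_id`` and ``gene_symbol`` (duplicated
    pairs are collapsed first). Returned sorted lexicographically.
    """
    if target_table.empty:
        return []
    dedup = target_table[["mirna_id", "gene_symbol"]].drop_duplicates()
    counts = dedup.groupby("gene_symbol")["mirna_id"].nunique()
    return sorted(counts.index[counts >= min_mirnas])
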