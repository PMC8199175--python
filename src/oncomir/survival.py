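"""Survival stratification by miRNA positivity: Kaplan–Meier and log-rank.

Patients are dichotomized per miRNA as positive (RPM ≥ 1, inclusive) or
negative (RPM < 1). Overall survival of the two strata is summarized with
the Kaplan–Meier product-limit estimator and compared with the standard
two-group log-rank test (pooled at-risk sets at tied event times, events
processed before censorings at the same time). The per-panel screen runs
one univariate test per miRNA at p < 0.05 without multiplicity correction,
mirroring how small candidate panels are screened in practice; an optional
Benjamini–Hochberg switch is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_matrix import ExpressionMatrix, UnitError
from .diffexp import bh_adjust

logger = logging.getLogger("oncomir")

STRATA = ("positive", "negative")


class ConsistencyError(ValueError):
    """Survival rows and expression samples cannot be joined."""


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time, non-increasing
    at_risk: np.ndarray  # n at risk just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def dichotomize(m: ExpressionMatrix, mirna_id: str,
                rpm_threshold: float = 1.0) -> pd.Series:
    """positive / negative stratum per LUAD sample, threshold inclusive."""
    if m.unit != "rpm":
        raise UnitError("dichotomization needs an RPM matrix")
    if mirna_id not in m.values.index:
        raise ConsistencyError(f"miRNA {mirna_id!r} absent from matrix")
    luad = m.samples_in_group("LUAD")
    rpm = m.values.loc[mirna_id, luad]
    return pd.Series(
        np.where(rpm >= rpm_threshold, "positive", "negative"),
        index=pd.Index(luad, name="sample_id"), name="stratum",
    )


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = Π (1 − d_i/n_i).

    ``time`` are follow-up times (≥ 0), ``event`` the death indicators.
    Censored-only data yields the constant curve S ≡ 1 (no event times).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if t.size == 0:
        raise ValueError("need at least one patient")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    event_times = np.unique(t[e])
    surv, at_risk = [], []
    s = 1.0
    for et in event_times:
        n_i = int(np.count_nonzero(t >= et))  # events precede censorings at ties
        d_i = int(np.count_nonzero((t == et) & e))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(times=event_times, survival=np.asarray(surv),
                   at_risk=np.asarray(at_risk, dtype=int))


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic with 1 df and its p.

    At each distinct pooled event time with d events and n at risk (n_a from
    group a), the expected a-events are e = d·n_a/n with hypergeometric
    variance v = d·(n_a/n)·(1 − n_a/n)·(n − d)/(n − 1). The statistic is
    (Σ(o − e))² / Σv. With no events anywhere, chi2 = 0 and p = 1.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a).astype(bool)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b).astype(bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    event_times = np.unique(t_all[e_all])
    if event_times.size == 0:
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        n_a = int(np.count_nonzero(ta >= et))
        n = int(np.count_nonzero(t_all >= et))
        d = int(np.count_nonzero((t_all == et) & e_all))
        d_a = int(np.count_nonzero((ta == et) & ea))
        if n <= 1:
            continue
        frac = n_a / n
        o_minus_e += d_a - d * frac
        var += d * frac * (1 - frac) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def survival_screen(m: ExpressionMatrix, surv: pd.DataFrame, panel: list[str],
                    alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Univariate log-rank screen of each panel miRNA against outcome.

    ``surv`` is a frame indexed by sample id with ``time`` and ``event``
    columns; samples without survival rows are dropped with a logged count.
    MiRNAs whose dichotomization puts every patient in one stratum are
    reported with ``testable=False`` and are never flagged. Flagging is
    p < alpha on the raw p by default; ``bh=True`` applies a
    Benjamini–Hochberg step across the testable panel first.
    """
    if not {"time", "event"} <= set(surv.columns):
        raise ConsistencyError("survival table needs time and event columns")
    luad = m.samples_in_group("LUAD")
    if not luad:
        raise ConsistencyError("no LUAD samples in the matrix")
    joined = [s for s in luad if s in surv.index]
    if not joined:
        raise ConsistencyError("no LUAD samples have survival rows")
    dropped = len(luad) - len(joined)
    if dropped:
        logger.info("dropped %d LUAD samples without survival data", dropped)
    sub = surv.loc[joined]
    rows = []
    for mirna in panel:
        strata = dichotomize(m, mirna).loc[joined]
        pos = strata == "positive"
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            rows.append((mirna, np.nan, np.nan, n_pos, n_neg, False, False))
            continue
        chi2, p = logrank_test(
            sub.loc[pos.values, "time"], sub.loc[pos.values, "event"],
            sub.loc[~pos.values, "time"], sub.loc[~pos.values, "event"],
        )
        rows.append((mirna, chi2, p, n_pos, n_neg, True, False))
    out = pd.DataFrame(
        rows, columns=["mirna_id", "chi2", "p", "n_pos", "n_neg", "testable", "flagged"]
    ).set_index("mirna_id")
    testable = out["testable"]
    p_use = out.loc[testable, "p"]
    if bh and testable.any():
        p_use = pd.Series(bh_adjust(p_use.to_numpy()), index=p_use.index)
        out.loc[testable, "p_adj"] = p_use
    out.loc[testable, "flagged"] = p_use < alpha
    out["flagged"] = out["flagged"].astype(bool)
    return out
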