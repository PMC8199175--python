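"""Linear panel scorer: published weights, SVM training, ROC/AUC.

A panel scorer is a linear score S = intercept + Σ w_i · x_i over the
log-scaled RPM values of an ordered miRNA panel. The published 13-miRNA
lung oncofetal scorer ships as a fixed artifact (see
:func:`published_scorer`); new scorers are trained as soft-margin linear
SVMs on malignant vs non-malignant samples. AUC is computed as the
Mann–Whitney rank statistic (ties counted half), which equals trapezoidal
integration of the empirical ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_matrix import ExpressionMatrix, UnitError
from .reference import PUBLISHED_PANEL_WEIGHTS

DEFAULT_FEATURE_TRANSFORM = "log2(rpm+1)"


class ConsistencyError(ValueError):
    """Features do not cover the scorer's panel."""


class TrainingError(ValueError):
    """Training data unusable (e.g. a single class)."""


@dataclass
class LinearScorer:
    """Ordered miRNA panel with one weight per member and a decision cutoff."""

    panel: list[str]
    weights: list[float]
    intercept: float = 0.0
    cutoff: float | None = None
    feature_transform: str = DEFAULT_FEATURE_TRANSFORM

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.weights):
            raise ValueError("panel and weights must have equal length")

    def weight_of(self, mirna_id: str) -> float:
        return self.weights[self.panel.index(mirna_id)]

    # -- serialization (bit-exact round trip) --------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel": self.panel,
                "weights": self.weights,
                "intercept": self.intercept,
                "cutoff": self.cutoff,
                "feature_transform": self.feature_transform,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearScorer":
        d = json.loads(text)
        return cls(panel=list(d["panel"]), weights=list(d["weights"]),
                   intercept=d["intercept"], cutoff=d["cutoff"],
                   feature_transform=d["feature_transform"])


def published_scorer() -> LinearScorer:
    """The published 13-miRNA lung oncofetal panel score, verbatim.

    Weights exactly as printed; no intercept was published and the decision
    cutoff was shown only graphically, so it is left unset.
    """
    return LinearScorer(
        panel=list(PUBLISHED_PANEL_WEIGHTS),
        weights=[float(w) for w in PUBLISHED_PANEL_WEIGHTS.values()],
        intercept=0.0,
        cutoff=None,
    )


def score(scorer: LinearScorer, features: dict[str, float] | pd.Series) -> float:
    """S = intercept + Σ w_i·x_i, accumulated left-to-right in panel order."""
    missing = [m for m in scorer.panel if m not in features]
    if missing:
        raise ConsistencyError(f"features missing panel miRNAs: {missing}")
    s = scorer.intercept
    for m, w in zip(scorer.panel, scorer.weights):
        s += w * float(features[m])
    return s


def panel_features(m: ExpressionMatrix, panel: list[str],
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """samples × panel matrix of log2(RPM + pseudocount) features."""
    if m.unit != "rpm":
        raise UnitError("panel features are computed from an RPM matrix")
    missing = [p for p in panel if p not in m.values.index]
    if missing:
        raise ConsistencyError(f"panel miRNAs absent from matrix: {missing}")
    return np.log2(m.values.loc[panel] + pseudocount).T


def score_samples(scorer: LinearScorer, features: pd.DataFrame) -> pd.Series:
    """Score every row of a samples × panel feature frame."""
    return pd.Series(
        [score(scorer, features.loc[s]) for s in features.index],
        index=features.index, name="score",
    )


def fit_linear_svm(X: pd.DataFrame, y, C: float = 1.0,
                   tol: float = 1e-6, seed: int = 0) -> LinearScorer:
    """Train a soft-margin linear SVM (hinge loss, L2 penalty) panel scorer.

    ``X`` is samples × panel features (already transformed); ``y`` is a
    boolean/0-1 malignant indicator. The scorer's weights and intercept are
    the SVM's signed-distance hyperplane, so the decision cutoff is score 0.
    The optimization is convex and deterministic; the seed only feeds any
    stochastic solver fallback.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    clf = SVC(kernel="linear", C=C, tol=tol, random_state=seed)
    clf.fit(X.to_numpy(), y)
    return LinearScorer(
        panel=list(X.columns),
        weights=[float(w) for w in clf.coef_.ravel()],
        intercept=float(clf.intercept_[0]),
        cutoff=0.0,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC sweep plus the Mann–Whitney AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for scores against binary labels.

    AUC is the Mann–Whitney statistic: the fraction of (positive, negative)
    pairs where the positive scores higher, ties counted half. The curve is
    the threshold sweep "positive iff score ≥ t" over the observed scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")

    from scipy.stats import rankdata

    ranks = rankdata(s)  # mid-ranks handle ties exactly
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(~ys)[distinct]
    thresholds = s[order][distinct]
    return RocResult(
        thresholds=np.r_[np.inf, thresholds],
        fpr=np.r_[0.0, fps / n_neg],
        tpr=np.r_[0.0, tps / n_pos],
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
    )
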