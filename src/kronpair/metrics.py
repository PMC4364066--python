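"""Ranking and classification metrics for drug-target predictions.

The central metric is the concordance index (CI): the probability that for
two randomly drawn drug-target pairs with *different* label values, the
predictions are in the correct order.  Formally

    CI = (1/Z) * sum_{y_i > y_j} h(f_i - f_j)

where Z is the number of (ordered) label-discordant pairs and h(u) is the
step function returning 1.0, 0.5, 0.0 for u > 0, u = 0, u < 0.  A CI of 0.5
corresponds to a random predictor and 1.0 to perfect ranking.  On binary
labels the CI coincides with ROC AUC; :func:`auc` computes the AUC through
the independent rank-sum route, so the identity is a genuine cross-check
rather than an alias.

Metrics that are undefined on a given input (all labels equal, a single
class, no positives) return the typed :data:`UNDEFINED` marker rather than
raising, so cross-validation can skip and count undefined folds — the
standard failure mode of small leave-one-out style folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import ShapeError

__all__ = [
    "PairedScores",
    "UNDEFINED",
    "UndefinedMetric",
    "is_defined",
    "concordance_index",
    "auc",
    "auc_pr",
    "permutation_test",
    "METRICS",
]


class UndefinedMetric:
    """Singleton marker for a metric undefined on the given scores."""

    _instance: "UndefinedMetric | None" = None

    def __new__(cls) -> "UndefinedMetric":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = UndefinedMetric()


def is_defined(value: object) -> bool:
    """True unless ``value`` is the undefined-metric marker."""
    return not isinstance(value, UndefinedMetric)


@dataclass
class PairedScores:
    """A label vector and an aligned prediction vector."""

    y: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.f = np.asarray(self.f, dtype=float).ravel()
        if self.y.shape != self.f.shape or self.y.size == 0:
            raise ShapeError(
                f"labels ({self.y.size}) and predictions ({self.f.size}) must "
                "have equal nonzero length"
            )
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.f))):
            raise ShapeError("labels and predictions must be finite")


def _as_scores(y, f) -> PairedScores:
    if isinstance(y, PairedScores) and f is None:
        return y
    return PairedScores(y, f)


def concordance_index(y, f=None) -> float | UndefinedMetric:
    """Concordance index of predictions ``f`` against labels ``y``.

    Computed by a vectorized pairwise sweep, chunked over rows so memory
    stays O(chunk * n); ties in the predictions contribute 1/2.  Returns
    :data:`UNDEFINED` when all labels are equal (Z = 0).
    """
    s = _as_scores(y, f)
    yv, fv = s.y, s.f
    n = yv.size
    num = 0.0
    z = 0
    chunk = max(1, min(n, 2_000_000 // max(n, 1)))
    for start in range(0, n, chunk):
        yi = yv[start : start + chunk, None]
        fi = fv[start : start + chunk, None]
        mask = yi > yv[None, :]
        z += int(mask.sum())
        df = fi - fv[None, :]
        h = np.where(df > 0, 1.0, np.where(df == 0, 0.5, 0.0))
        num += float(h[mask].sum())
    if z == 0:
        return UNDEFINED
    return num / z


def auc(y, f=None) -> float | UndefinedMetric:
    """ROC AUC for binary labels via the Mann-Whitney rank-sum statistic.

    Equals :func:`concordance_index` on the same input (ties get average
    ranks, matching the 1/2 convention).  Returns :data:`UNDEFINED` when
    only one class is present.
    """
    s = _as_scores(y, f)
    classes = np.unique(s.y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ShapeError("auc requires binary {0,1} labels")
    pos = s.y == 1.0
    m_pos = int(pos.sum())
    m_neg = s.y.size - m_pos
    if m_pos == 0 or m_neg == 0:
        return UNDEFINED
    ranks = rankdata(s.f, method="average")
    u = ranks[pos].sum() - m_pos * (m_pos + 1) / 2.0
    return float(u / (m_pos * m_neg))


def auc_pr(y, f=None) -> float | UndefinedMetric:
    """Area under the precision-recall curve for binary labels.

    Convention: thresholds sweep the distinct prediction values in
    descending order with ties grouped at one threshold, and the area is the
    average-precision style sum ``sum_k (R_k - R_{k-1}) * P_k`` over the
    right-continuous step curve.  Returns :data:`UNDEFINED` with zero
    positives.
    """
    s = _as_scores(y, f)
    classes = np.unique(s.y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ShapeError("auc_pr requires binary {0,1} labels")
    m_pos = int((s.y == 1.0).sum())
    if m_pos == 0:
        return UNDEFINED
    order = np.argsort(-s.f, kind="stable")
    ys = s.y[order]
    fs = s.f[order]
    tp = np.cumsum(ys)
    n_pred = np.arange(1, ys.size + 1, dtype=float)
    # keep only the last index of each tie group of prediction values
    last = np.ones(ys.size, dtype=bool)
    last[:-1] = fs[:-1] != fs[1:]
    precision = tp[last] / n_pred[last]
    recall = tp[last] / m_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def permutation_test(
    y, f=None, metric: str = "ci", n_perm: int = 999, seed: int = 0
) -> float | UndefinedMetric:
    """One-sided permutation p-value for a ranking/classification metric.

    Predictions are permuted against the fixed labels ``n_perm`` times with
    a seeded generator; the p-value uses the add-one correction
    ``p = (1 + #{metric_perm >= metric_obs}) / (n_perm + 1)``, counting ties
    conservatively.  An undefined observed metric propagates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s = _as_scores(y, f)
    stat = METRICS[metric]
    observed = stat(s.y, s.f)
    if not is_defined(observed):
        return UNDEFINED
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = stat(s.y, rng.permutation(s.f))
        if is_defined(perm) and perm >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


#: registry used by cross-validation and the command line
METRICS = {
    "ci": concordance_index,
    "auc": auc,
    "aucpr": auc_pr,
}
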