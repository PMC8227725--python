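"""Classifier and segmentation evaluation statistics.

AUROC is computed by the tie-corrected rank (pairwise-concordance) estimator
and the ROC curve is built by sliding a threshold over every distinct score;
the trapezoidal area under the curve equals the rank estimator exactly, which
the test suite asserts as a consistency invariant. Operating points are
reported at Youden's cutoff (J = sensitivity + specificity - 1, ties broken
toward higher sensitivity). Confidence intervals are stratified percentile
bootstrap. DICE scores compare label volumes per class; Spearman correlation
validates automated reads against reference reads.

Scores are dichotomized by ``score >= cutoff`` (closed on the positive side)
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "ContingencyTable",
    "auroc",
    "roc_curve",
    "youden_cutoff",
    "bootstrap_ci",
    "contingency",
    "sens_spec",
    "dice",
    "spearman",
]


@dataclass
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}


@dataclass
class ROCResult:
    """ROC curve with its area and, optionally, a CI and operating point."""

    cutoffs: np.ndarray  # descending; cutoffs[0] = +inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    operating_point: tuple[float, float, float] | None = None  # (cutoff, sens, spec)

    def to_dict(self) -> dict:
        d = {"auroc": self.auroc}
        if self.ci is not None:
            d["ci"] = list(self.ci)
            d["ci_level"] = self.ci_level
        if self.operating_point is not None:
            c, se, sp = self.operating_point
            d["operating_point"] = {"cutoff": c, "sensitivity": se, "specificity": sp}
        return d


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required: got {n_pos} positives and {n_neg} negatives"
        )
    return n_pos, n_neg


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    return scores, labels


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Equivalent to the Mann-Whitney U statistic normalized by the number of
    positive-negative pairs; invariant under strictly monotone transforms of
    the scores.
    """
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_binary(labels)
    ranks = sps.rankdata(scores)  # mid-ranks for ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(scores, labels) -> ROCResult:
    """ROC operating points at every distinct score plus the +inf endpoint.

    ``n`` distinct scores yield ``n + 1`` points, from (sens 0, spec 1) down
    to (sens 1, spec 0); the trapezoidal area equals :func:`auroc` exactly.
    """
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    distinct, first_idx = np.unique(-s_sorted, return_index=True)
    # cumulative counts of positives/negatives with score >= each cutoff
    cum_pos = np.cumsum(y_sorted)
    cum_neg = np.cumsum(1 - y_sorted)
    # index of the last element at each distinct score
    last_idx = np.r_[first_idx[1:], len(s_sorted)] - 1
    tp = cum_pos[last_idx]
    fp = cum_neg[last_idx]
    cutoffs = np.r_[np.inf, -distinct]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    area = float(np.trapezoid(sens, 1.0 - spec))
    return ROCResult(cutoffs, sens, spec, area)


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Operating point maximizing J = sens + spec - 1; ties favor sensitivity."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    i = best[np.argmax(roc.sensitivity[best])]
    return (float(roc.cutoffs[i]), float(roc.sensitivity[i]), float(roc.specificity[i]))


def bootstrap_ci(
    scores,
    labels,
    statistic=auroc,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for ``statistic(scores, labels)``.

    Resampling is within-class, so every resample retains both classes.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; interval will be unstable")
    scores, labels = _as_arrays(scores, labels)
    _check_binary(labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        ]
        vals[b] = statistic(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def contingency(scores, labels, cutoff: float) -> ContingencyTable:
    """2x2 table from dichotomizing at ``score >= cutoff``."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores, labels = _as_arrays(scores, labels)
    pred = scores >= cutoff
    return ContingencyTable(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def sens_spec(table: ContingencyTable) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise ValueError("sensitivity/specificity undefined on an empty margin")
    return (
        table.tp / (table.tp + table.fn),
        table.tn / (table.tn + table.fp),
    )


def dice(mask_a, mask_b, cls: str, *, both_empty: float = 1.0) -> float:
    """Sørensen–Dice coefficient for one class between two label volumes.

    ``2 |A ∩ B| / (|A| + |B|)`` over the voxels of ``cls``; when the class is
    absent from both masks the agreement is perfect by convention
    (``both_empty``, default 1.0).
    """
    if mask_a.geometry != mask_b.geometry:
        raise ValueError("masks have different geometries")
    a = mask_a.class_mask(cls)
    b = mask_b.class_mask(cls)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return both_empty
    return 2.0 * int(np.sum(a & b)) / denom


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D arrays of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    r = sps.spearmanr(x, y).statistic
    return float(r)
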