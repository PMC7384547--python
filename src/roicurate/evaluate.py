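"""Evaluation surfaces for ROI curation classifiers.

Covers the quantities a curation study reports: confusion matrices (as
counts and row proportions), precision / recall / F-beta, interrater
agreement between two human raters, Cohen's d between the confidence
distributions of correct vs. incorrect predictions, and learning curves
(held-out score vs. training-set size) with PELT change-point detection to
locate the size at which performance plateaus.

PELT here is the exact pruned dynamic program over the Gaussian mean-shift
(L2) segment cost; it returns the same segmentation an exhaustive search
over all segmentations would, at O(n)-ish cost thanks to pruning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import (
    AlignmentError,
    ShapeMismatchError,
    SizeError,
    UndefinedEffectError,
)
from .features import LabeledDataset
from .model import ClassifierSpec, Prediction, make_pipeline, _score


# ---------------------------------------------------------------------------
# confusion and P/R/F
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with include as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PRFScores:
    """Precision, recall and F-beta; ``degenerate`` marks a 0/0 convention."""

    precision: float
    recall: float
    f_beta: float
    beta: float = 1.0
    degenerate: bool = False


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(
        [1 if str(v).lower() == "include" else 0 if str(v).lower() == "exclude" else v
         for v in labels]
    ).astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1 or include/exclude)")
    return arr


def confusion(true_labels, predicted_labels) -> tuple[ConfusionCounts, np.ndarray]:
    """Confusion counts plus the row-proportion matrix (rows: true include, true exclude).

    Each row of the proportion matrix is normalized by its true-class count,
    so rows sum to 1 (a row with no members is left at 0).
    """
    y_true = _as_binary(true_labels)
    y_pred = _as_binary(predicted_labels)
    if y_true.size != y_pred.size:
        raise ShapeMismatchError(
            f"label list lengths differ: {y_true.size} vs {y_pred.size}"
        )
    m = _sk_confusion(y_true, y_pred, labels=[1, 0])
    counts = ConfusionCounts(tp=int(m[0, 0]), fn=int(m[0, 1]), fp=int(m[1, 0]), tn=int(m[1, 1]))
    row_sums = m.sum(axis=1, keepdims=True)
    props = np.divide(m, row_sums, out=np.zeros_like(m, dtype=float), where=row_sums > 0)
    return counts, props


def prf_scores(counts: ConfusionCounts, beta: float = 1.0) -> PRFScores:
    """Precision, recall and F-beta from confusion counts.

    F_beta = (1 + beta^2) P R / (beta^2 P + R); beta > 1 weights recall
    (penalizing lost neurons), beta < 1 weights precision (penalizing
    admitted artifacts).  Zero denominators yield 0 with the degenerate
    flag set rather than an exception.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    degenerate = False
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, degenerate = 0.0, True
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, degenerate = 0.0, True
    denom = beta * beta * precision + recall
    if denom > 0:
        f = (1 + beta * beta) * precision * recall / denom
    else:
        f, degenerate = 0.0, True
    return PRFScores(precision=precision, recall=recall, f_beta=f, beta=beta, degenerate=degenerate)


def interrater_agreement(labels_a, labels_b) -> tuple[float, np.ndarray]:
    """Fraction of ROIs on which two raters agree, plus their 2x2 count matrix.

    Rows index rater A (include, exclude), columns rater B.
    """
    a = _as_binary(labels_a)
    b = _as_binary(labels_b)
    if a.size != b.size:
        raise AlignmentError(f"rater label lists differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("need at least one jointly rated ROI")
    m = _sk_confusion(a, b, labels=[1, 0])
    return float((a == b).mean()), m


# ---------------------------------------------------------------------------
# certainty (Cohen's d)
# ---------------------------------------------------------------------------

def cohens_d(sample_a, sample_b) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled sd, variances with ddof=1."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise UndefinedEffectError("pooled standard deviation is zero; d is undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


@dataclass
class CertaintyComparison:
    """Confidence distributions of correct vs. incorrect predictions for one class.

    ``d`` is None when either group is too small (or too uniform) to define
    an effect size.
    """

    direction: str  # "positive_class" (predicted include) or "negative_class"
    group_correct: np.ndarray
    group_incorrect: np.ndarray
    d: float | None = None


def certainty_analysis(
    predictions: list[Prediction], true_labels
) -> dict[str, CertaintyComparison]:
    """Cohen's d of confidences, correct vs. incorrect, per predicted class.

    For predicted includes the groups are true positives vs. false
    positives; for predicted excludes, true negatives vs. false negatives.
    A confident classifier that errs only on genuine edge cases shows a
    large positive d in both directions.
    """
    y_true = _as_binary(true_labels)
    if len(predictions) != y_true.size:
        raise ShapeMismatchError(
            f"{len(predictions)} predictions vs {y_true.size} true labels"
        )
    out: dict[str, CertaintyComparison] = {}
    for direction, pred_label, positive in (
        ("positive_class", "include", 1),
        ("negative_class", "exclude", 0),
    ):
        conf_correct = np.array(
            [p.confidence for p, t in zip(predictions, y_true)
             if p.label == pred_label and t == positive]
        )
        conf_incorrect = np.array(
            [p.confidence for p, t in zip(predictions, y_true)
             if p.label == pred_label and t != positive]
        )
        d: float | None
        if conf_correct.size < 2 or conf_incorrect.size < 2:
            d = None
        else:
            try:
                d = cohens_d(conf_correct, conf_incorrect)
            except UndefinedEffectError:
                d = None
        out[direction] = CertaintyComparison(
            direction=direction,
            group_correct=conf_correct,
            group_incorrect=conf_incorrect,
            d=d,
        )
    return out


# ---------------------------------------------------------------------------
# change-point detection (PELT, mean-shift L2 cost)
# ---------------------------------------------------------------------------

def detect_change_points(scores, penalty: float) -> list[int]:
    """Exact penalized change-point detection on a 1-D series.

    Minimizes sum of within-segment squared deviations from the segment
    mean, plus ``penalty`` per change point, via PELT (pruned exact dynamic
    programming).  Returns the 0-based start indices of every segment after
    the first; a constant series yields no change points, and the number of
    change points is non-increasing in the penalty.
    """
    x = np.asarray(scores, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError(f"series must have length >= 2, got {n}")
    if penalty <= 0:
        raise ValueError(f"penalty must be positive, got {penalty}")
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:
        # L2 cost of segment x[i:j]
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(1, n + 1):
        costs = [F[s] + seg_cost(s, t) + penalty for s in candidates]
        best = int(np.argmin(costs))
        F[t] = costs[best]
        last[t] = candidates[best]
        # pruning: a start point that cannot win later is dropped (K = 0)
        candidates = [s for s, c in zip(candidates, costs) if c - penalty <= F[t]]
        candidates.append(t)

    breaks: list[int] = []
    t = n
    while t > 0:
        s = int(last[t])
        if s > 0:
            breaks.append(s)
        t = s
    return sorted(breaks)


def default_pelt_penalty(scores) -> float:
    """Default penalty 2 * log(n) * var(series): the standard mean-shift scaling."""
    x = np.asarray(scores, dtype=float).ravel()
    return 2.0 * math.log(x.size) * max(float(np.var(x)), 1e-12)


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

@dataclass
class LearningCurve:
    """Held-out score as a function of training-set size, with change points."""

    sizes: list[int]
    scores: list[float]
    change_points: list[int] = field(default_factory=list)
    penalty: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.scores):
            raise ShapeMismatchError("one score per size required")
        if any(b >= a for a, b in zip(self.sizes[1:], self.sizes)):
            raise ValueError("sizes must be strictly increasing")

    @property
    def plateau_size(self) -> int | None:
        """Training-set size at the last detected change point (None if flat)."""
        if not self.change_points:
            return None
        return self.sizes[max(self.change_points)]


def _stratified_allocation(size: int, y: np.ndarray) -> dict[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    props = counts / counts.sum()
    alloc = {int(c): int(round(size * p)) for c, p in zip(classes, props)}
    # largest-remainder style fixup so the allocation sums exactly to size
    drift = size - sum(alloc.values())
    order = sorted(alloc, key=lambda c: -alloc[c])
    i = 0
    while drift != 0:
        c = order[i % len(order)]
        alloc[c] += 1 if drift > 0 else -1
        drift += -1 if drift > 0 else 1
        i += 1
    if min(alloc.values()) < 2:
        raise SizeError(
            f"subsample size {size} leaves a class with < 2 members "
            f"(allocation {alloc}); use a larger size"
        )
    return alloc


def learning_curve(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    sizes,
    seed: int = 0,
    penalty: float | None = None,
    nested: bool = True,
) -> LearningCurve:
    """Held-out objective vs. training-set size, with PELT change points.

    For each size a stratified subsample of the training rows is drawn
    (nested by default: each size's sample contains the previous one's,
    which lowers curve variance), the classifier is refitted from scratch,
    and the score on the fixed test split is recorded.  The subsampling is
    a deterministic function of ``seed``.
    """
    sizes = [int(s) for s in sizes]
    if any(b >= a for a, b in zip(sizes[1:], sizes)):
        raise ValueError("sizes must be strictly increasing")
    X_tr, y_tr = dataset.X_train, dataset.y_train
    X_te, y_te = dataset.X_test, dataset.y_test
    if sizes[-1] > len(y_tr):
        raise SizeError(
            f"largest size {sizes[-1]} exceeds the {len(y_tr)} available training rows"
        )
    rng = np.random.default_rng(seed)
    per_class_order = {
        int(c): rng.permutation(np.flatnonzero(y_tr == c)) for c in np.unique(y_tr)
    }
    beta = spec.effective_beta
    scores = []
    for size in sizes:
        alloc = _stratified_allocation(size, y_tr)
        if nested:
            idx = np.concatenate([per_class_order[c][:k] for c, k in alloc.items()])
        else:
            idx = np.concatenate(
                [rng.choice(np.flatnonzero(y_tr == c), size=k, replace=False)
                 for c, k in alloc.items()]
            )
        pipe = make_pipeline(spec)
        pipe.fit(X_tr[idx], y_tr[idx])
        scores.append(_score(pipe, X_te, y_te, beta))
    pen = default_pelt_penalty(scores) if penalty is None else float(penalty)
    cps = detect_change_points(scores, pen)
    return LearningCurve(sizes=sizes, scores=scores, change_points=cps, penalty=pen)


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

def evaluation_report(
    true_labels, predictions: list[Prediction], beta: float = 1.0
) -> dict:
    """Bundle confusion, P/R/F and certainty analysis into one JSON-able dict."""
    pred_labels = [p.label for p in predictions]
    counts, props = confusion(true_labels, pred_labels)
    prf = prf_scores(counts, beta=beta)
    certainty = certainty_analysis(predictions, true_labels)
    return {
        "n": counts.total,
        "confusion": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
        "confusion_proportions": props.tolist(),
        "precision": prf.precision,
        "recall": prf.recall,
        "f_beta": prf.f_beta,
        "beta": prf.beta,
        "cohens_d": {k: v.d for k, v in certainty.items()},
    }


def export_report(report: dict, path: str) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
        f.write("\n")


def learning_curve_to_csv(curve: LearningCurve, path: str) -> None:
    pd.DataFrame({"size": curve.sizes, "score": curve.scores}).to_csv(path, index=False)


def plot_confusion(proportions: np.ndarray, path: str, title: str = "Confusion matrix") -> None:
    """Render a row-proportion confusion matrix to PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(proportions, cmap="viridis", vmin=0, vmax=1)
    ticks = ["include", "exclude"]
    ax.set_xticks([0, 1], ticks)
    ax.set_yticks([0, 1], ticks)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    for i in range(2):
        for j in range(2):
            ax.text(j, i, f"{proportions[i, j]:.2f}", ha="center", va="center",
                    color="white" if proportions[i, j] < 0.5 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
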