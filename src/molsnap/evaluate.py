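"""Molecule-level evaluation: median aggregation, ROC/AUC, cutoff, metrics.

Per-image probabilities are reduced to one representative score per molecule
by the median over its rotated views. The ROC curve, AUC, Youden-J cutoff
and the eight-metric confusion suite (sensitivity, specificity, balanced
accuracy, accuracy, precision, recall, F value, Matthews correlation
coefficient) are all computed at molecule level, after aggregation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class MoleculeScore:
    mol_id: str
    score: float
    n_images: int

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass(frozen=True)
class MetricsBundle:
    """Confusion counts plus the eight-metric suite at a threshold.

    MCC uses the standard square-root four-factor denominator; any zero
    factor (or an empty predicted-positive set for precision) yields 0 with
    ``degenerate`` flagged.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    bac: float
    accuracy: float
    precision: float
    recall: float
    f_value: float
    mcc: float
    auc: float
    threshold: float
    degenerate: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["degenerate"] = list(self.degenerate)
        return json.dumps(d, indent=2)


def aggregate_median(preds: pd.DataFrame) -> list[MoleculeScore]:
    """Reduce the per-image prediction table to per-molecule median scores.

    Even image counts take the mean of the two central values. The result is
    invariant under row order and sorted by mol_id for stability.
    """
    if len(preds) == 0:
        return []
    if preds["probability"].isna().any():
        raise ValueError("prediction table contains missing probabilities")
    grouped = preds.groupby("mol_id")["probability"]
    return [
        MoleculeScore(mol_id=str(mid), score=float(g.median()), n_images=len(g))
        for mid, g in sorted(grouped, key=lambda kv: str(kv[0]))
    ]


def _as_arrays(scores: Sequence[MoleculeScore], labels: dict[str, str] | Sequence) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([m.score for m in scores], dtype=float)
    if isinstance(labels, dict):
        y = np.array([1 if str(labels[m.mol_id]) == "active" else 0 for m in scores])
    else:
        y = np.array([1 if str(l) in ("active", "1", "True") else 0 for l in labels])
        if len(y) != len(s):
            raise ValueError("labels must align with scores")
    return s, y


def roc_auc(scores: Sequence[MoleculeScore], labels) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC over molecule scores.

    The AUC equals the probability that a random active outscores a random
    inactive, with ties counted one half; the returned curve points are
    (1 - specificity, sensitivity) at every distinct threshold.
    """
    s, y = _as_arrays(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, curve


def select_cutoff(scores: Sequence[MoleculeScore], labels) -> float:
    """Threshold maximizing Youden J = sensitivity + specificity - 1.

    Candidates are the midpoints of adjacent distinct scores plus guard
    points outside the score range; classification is score >= threshold.
    Ties break toward the higher threshold (higher specificity).
    """
    s, y = _as_arrays(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to select a cutoff")
    uniq = np.unique(s)
    candidates = [(uniq[0] - 1.0)] + [float((a + b) / 2) for a, b in zip(uniq[:-1], uniq[1:])] + [uniq[-1] + 1.0]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = float(t), j
    return best_t


def confusion_metrics(
    scores: Sequence[MoleculeScore],
    labels,
    threshold: float,
    auc: float = float("nan"),
) -> MetricsBundle:
    """Eight-metric confusion suite at a frozen threshold (active iff
    score >= threshold)."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s, y = _as_arrays(scores, labels)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    bac = (sensitivity + specificity) / 2.0
    accuracy = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = sensitivity
    f_value = ratio(2 * recall * precision, recall + precision, "f_value")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsBundle(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sensitivity, specificity=specificity, bac=bac,
        accuracy=accuracy, precision=precision, recall=recall,
        f_value=f_value, mcc=mcc, auc=float(auc), threshold=float(threshold),
        degenerate=tuple(degenerate),
    )


def evaluate_predictions(
    preds: pd.DataFrame,
    labels: dict[str, str],
    threshold: float | None = None,
    val_preds: pd.DataFrame | None = None,
    val_labels: dict[str, str] | None = None,
) -> MetricsBundle:
    """End-to-end evaluation of a per-image prediction table.

    Aggregates by median, builds the ROC, and computes metrics at the given
    threshold; when no threshold is supplied the Youden-J cutoff is selected
    on the validation predictions if provided (avoiding optimistic bias), or
    on the test scores themselves as a last resort.
    """
    scores = aggregate_median(preds)
    auc, _ = roc_auc(scores, labels)
    if threshold is None:
        if val_preds is not None and val_labels is not None:
            threshold = select_cutoff(aggregate_median(val_preds), val_labels)
        else:
            threshold = select_cutoff(scores, labels)
    return confusion_metrics(scores, labels, threshold, auc=auc)
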