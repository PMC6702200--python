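"""Classifier performance metrics and group time courses.

Implements the reported metric set: three-class accuracy, Cohen's kappa,
and one-vs-rest sensitivity / specificity / PPV / NPV for the resilient and
vulnerable classifiers, each summarised as mean +/- SD over the repeated
cross-validation runs; plus the modal group assignment across runs and the
per-group lapse time course.

Chance accuracy for a 1:2:1 split is sum_k (n_k/n)^2 = 0.375, the expected
accuracy of a label-preserving random permutation of the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stratify import CLASSES, _session_lapses

__all__ = [
    "confusion",
    "accuracy",
    "kappa",
    "chance_accuracy",
    "binary_metrics",
    "modal_assignment",
    "summarize_cv",
    "group_time_course",
    "CVMetrics",
]

log = logging.getLogger(__name__)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


def confusion(y_true, y_pred) -> np.ndarray:
    """3x3 counts N[true, predicted] in fixed class order."""
    N = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        N[_CLASS_INDEX[t], _CLASS_INDEX[p]] += 1
    return N


def accuracy(conf: np.ndarray) -> float:
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(conf) / total)


def kappa(conf: np.ndarray) -> float:
    """Cohen's kappa: (p_o - p_e)/(1 - p_e), 0 when p_e = 1 (degenerate)."""
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / total
    p_e = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def chance_accuracy(class_counts) -> float:
    """Expected accuracy of a random permutation of the true labels."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0) and counts.sum() <= 0:
        raise ValueError("class counts must be positive")
    props = counts / counts.sum()
    return float(props @ props)


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def binary_metrics(conf: np.ndarray, target: str) -> BinaryMetrics:
    """Collapse to target-vs-rest; zero-denominator rates come back as NaN."""
    if target not in ("resilient", "vulnerable"):
        raise ValueError("target must be 'resilient' or 'vulnerable'")
    t = _CLASS_INDEX[target]
    tp = conf[t, t]
    fn = conf[t].sum() - tp
    fp = conf[:, t].sum() - tp
    tn = conf.sum() - tp - fn - fp

    def rate(num, den, name):
        if den == 0:
            log.warning("%s undefined (zero denominator) for target %s", name, target)
            return float("nan")
        return float(num / den)

    return BinaryMetrics(
        sensitivity=rate(tp, tp + fn, "sensitivity"),
        specificity=rate(tn, tn + fp, "specificity"),
        ppv=rate(tp, tp + fp, "PPV"),
        npv=rate(tn, tn + fn, "NPV"),
    )


def modal_assignment(predictions: pd.DataFrame) -> pd.Series:
    """Most frequent predicted label per participant across CV runs.

    ``predictions``: participants x runs label frame (wrapper.cross_validate).
    Ties break to the lowest class in the fixed order.
    """
    def mode(row) -> str:
        counts = [int((row == c).sum()) for c in CLASSES]
        return CLASSES[int(np.argmax(counts))]

    return predictions.apply(mode, axis=1).rename("modal_label")


@dataclass
class CVMetrics:
    """Mean +/- SD of each metric over the repeated CV runs."""

    repeats: int
    accuracy: tuple
    kappa: tuple
    resilient: dict      # metric name -> (mean, sd)
    vulnerable: dict

    def as_frame(self) -> pd.DataFrame:
        rows = {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
        }
        for cls, d in (("resilient", self.resilient), ("vulnerable", self.vulnerable)):
            for m, v in d.items():
                rows[f"{cls}_{m}"] = v
        return pd.DataFrame(rows, index=["mean", "sd"]).T


def _mean_sd(values) -> tuple:
    arr = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        return (float(np.nanmean(arr)),
                float(np.nanstd(arr, ddof=1)) if arr.size > 1 else 0.0)


def summarize_cv(y_true: pd.Series, predictions: pd.DataFrame) -> CVMetrics:
    """Per-run metrics (one confusion per CV run) summarised mean +/- SD."""
    truth = y_true.loc[predictions.index]
    accs, kaps = [], []
    bins = {"resilient": {m: [] for m in ("sensitivity", "specificity", "ppv", "npv")},
            "vulnerable": {m: [] for m in ("sensitivity", "specificity", "ppv", "npv")}}
    for col in predictions.columns:
        conf = confusion(truth, predictions[col])
        accs.append(accuracy(conf))
        kaps.append(kappa(conf))
        for cls in ("resilient", "vulnerable"):
            bm = binary_metrics(conf, cls)
            for m in bins[cls]:
                bins[cls][m].append(getattr(bm, m))
    return CVMetrics(
        repeats=predictions.shape[1],
        accuracy=_mean_sd(accs),
        kappa=_mean_sd(kaps),
        resilient={m: _mean_sd(v) for m, v in bins["resilient"].items()},
        vulnerable={m: _mean_sd(v) for m, v in bins["vulnerable"].items()},
    )


def group_time_course(study, assignment: pd.Series) -> pd.DataFrame:
    """Mean +/- SEM 500-ms lapse count per assigned group at every session slot.

    Tidy output columns: group, day, time_since_wake, mean_lapses, sem, n.
    Groups with no members are omitted with a warning.
    """
    rows = []
    for s in study.sessions:
        if s.participant_id in assignment.index:
            rows.append((assignment.loc[s.participant_id], s.day,
                         s.time_since_wake, _session_lapses(s)))
    df = pd.DataFrame(rows, columns=["group", "day", "time_since_wake", "lapses"])
    present = set(df["group"].unique())
    for cls in CLASSES:
        if cls not in present:
            log.warning("group %s has no assigned participants; omitted", cls)
    out = (df.groupby(["group", "day", "time_since_wake"])["lapses"]
             .agg(mean_lapses="mean",
                  sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                  n="size")
             .reset_index())
    return out
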