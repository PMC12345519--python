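"""Evaluation metrics, bootstrap statistics and guild aggregation.

Conventions: the confusion matrix has rows = true labels, columns =
predicted labels; precision/recall/F1 are one-vs-rest per class with
unweighted (macro) averages; "accuracy" is the standard multi-class
fraction of correct predictions.  The mean per-class one-vs-rest binary
accuracy -- sum(TP_i + TN_i) / sum(TP_i + TN_i + FP_i + FN_i) -- is also
reported, as ``binary_accuracy_macro``, because some summaries use that
definition; for C classes it equals 1 - 2*(1 - accuracy)/C.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = ["MetricsReport", "evaluate", "roc_auc", "bootstrap_ci", "paired_bootstrap_pvalue", "guild_f1"]


@dataclass
class MetricsReport:
    classes: list
    accuracy: float
    binary_accuracy_macro: float
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    macro_auc: float | None = None
    micro_auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "binary_accuracy_macro": self.binary_accuracy_macro,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }
        if self.macro_auc is not None:
            d["macro_auc"] = self.macro_auc
            d["micro_auc"] = self.micro_auc
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(y_true, y_pred, classes=None, scores: np.ndarray | None = None) -> MetricsReport:
    """Full multi-class report from labels (and optionally class scores).

    A class with no true samples in the test set has undefined recall/F1;
    it is reported as NaN and excluded from the macro averages, with a
    warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
            2 * precision * recall / (precision + recall),
            np.where(np.isnan(precision) | np.isnan(recall), np.nan, 0.0),
        )
    absent = cm.sum(axis=1) == 0
    if absent.any():
        missing = [c for c, a in zip(classes, absent) if a]
        warnings.warn(f"classes absent from test set, metrics undefined: {missing}")

    macro_auc = micro_auc = None
    if scores is not None:
        macro_auc, micro_auc = roc_auc(scores, y_true, classes)

    return MetricsReport(
        classes=classes,
        accuracy=float(tp.sum() / n),
        binary_accuracy_macro=float((tp + tn).sum() / (tp + tn + fp + fn).sum()),
        precision={c: float(p) for c, p in zip(classes, precision)},
        recall={c: float(r) for c, r in zip(classes, recall)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        macro_precision=float(np.nanmean(precision)),
        macro_recall=float(np.nanmean(recall)),
        macro_f1=float(np.nanmean(f1)),
        confusion=cm,
        macro_auc=macro_auc,
        micro_auc=micro_auc,
    )


def roc_auc(scores: np.ndarray, y_true, classes=None) -> tuple[float, float]:
    """(macro, micro) one-vs-rest ROC-AUC from per-class scores."""
    y_true = np.asarray(y_true)
    if classes is None:
        classes = sorted(set(y_true))
    if len(set(y_true)) < 2:
        raise ValueError("ROC-AUC undefined for single-class labels")
    onehot = (y_true[:, None] == np.asarray(classes)[None, :]).astype(int)
    macro = float(roc_auc_score(onehot, scores, average="macro"))
    micro = float(roc_auc_score(onehot, scores, average="micro"))
    return macro, micro


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    statistic=np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    stats = statistic(values[idx], axis=1)
    lo = float(np.percentile(stats, 100 * (1 - level) / 2))
    hi = float(np.percentile(stats, 100 * (1 + level) / 2))
    return lo, hi


def paired_bootstrap_pvalue(
    outcomes_a: np.ndarray, outcomes_b: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Two-sided paired bootstrap p-value for the mean difference.

    Resamples the per-sample outcome differences and reports twice the
    smaller tail fraction of resampled means crossing zero (clipped to 1).
    Identical outcome vectors give p = 1.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    diff = np.asarray(outcomes_a, dtype=float) - np.asarray(outcomes_b, dtype=float)
    if np.all(diff == 0):
        return 1.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
    means = diff[idx].mean(axis=1)
    tail = min((means <= 0).mean(), (means >= 0).mean())
    return float(min(1.0, 2 * tail))


def guild_f1(per_class_f1: dict, guilds: dict) -> dict:
    """Mean per-class F1 within each ecological guild, rounded to 2 dp.

    ``guilds`` maps guild name -> list of class names; every class must
    belong to exactly one guild.  Empty guilds are dropped with a warning.
    """
    seen: dict = {}
    for guild, members in guilds.items():
        for m in members:
            if m in seen:
                raise ValueError(f"class {m!r} assigned to both {seen[m]!r} and {guild!r}")
            seen[m] = guild
    out = {}
    for guild, members in guilds.items():
        vals = [per_class_f1[m] for m in members if m in per_class_f1]
        if not vals:
            warnings.warn(f"guild {guild!r} has no scored members; excluded")
            continue
        out[guild] = round(float(np.mean(vals)), 2)
    return out
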