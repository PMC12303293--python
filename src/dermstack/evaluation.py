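"""Multiclass diagnostic metrics: confusion counts, per-class PPV / recall /
F1 / NPV, macro averages, and dataset splitting.

All metrics are one-vs-rest per class.  With TP, FP, FN, TN the per-class
counts,

    PPV = TP / (TP + FP)        recall = TP / (TP + FN)
    F1  = harmonic mean of PPV and recall
    NPV = TN / (TN + FN)

The overall table row is the *macro* (unweighted) mean of the six per-class
values.  Undefined ratios (zero denominators) are flagged as NaN with a
warning — never silently zeroed.

:func:`recover_counts` inverts published PPV/recall values back to the
minimal integer confusion counts consistent with a known evaluation-set
size: a printed PPV of 0.840909 is the reduced fraction 37/44, a recall of
0.948718 is 37/39, so TP = 37, FP = 7, FN = 2, and TN follows from the
total.  This lets NPV (which is rarely printed alongside) be re-derived and
checked exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from fractions import Fraction
from math import floor, lcm

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "MetricsReport",
    "SplitPlan",
    "confusion_matrix",
    "per_class_metrics",
    "macro_average",
    "accuracy_from_matrix",
    "recover_counts",
    "npv_from_counts",
    "split_dataset",
    "format_report",
    "round_half_up",
]

N_CLASSES = 6
METRIC_NAMES = ("ppv", "recall", "f1", "npv")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(floor(x + 0.5))


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains codes outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclasses.dataclass
class MetricsReport:
    """Per-class and macro diagnostic metrics.

    Per-class arrays are indexed by class code; undefined entries are NaN
    and excluded from ``defined``.
    """

    ppv: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    npv: np.ndarray
    support: np.ndarray
    n_total: int

    @property
    def defined(self) -> np.ndarray:
        """Classes for which all four metrics are defined."""
        stacked = np.vstack([self.ppv, self.recall, self.f1, self.npv])
        return ~np.isnan(stacked).any(axis=0)

    def per_class(self, code: int) -> dict[str, float]:
        return {m: float(getattr(self, m)[code]) for m in METRIC_NAMES}

    def to_frame(self):
        import pandas as pd

        from .imaging import CLASS_NAMES

        return pd.DataFrame(
            {m: getattr(self, m) for m in METRIC_NAMES}
            | {"support": self.support},
            index=pd.Index(CLASS_NAMES, name="class"),
        )


def _safe_ratio(num: int, den: int, what: str, cls: int) -> float:
    if den == 0:
        warnings.warn(
            f"{what} undefined for class {cls} (zero denominator); flagged as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.nan
    return num / den


def per_class_metrics(cm: np.ndarray, n_total: int | None = None) -> MetricsReport:
    """One-vs-rest PPV, recall, F1 and NPV per class from a count matrix.

    ``n_total`` is the number of evaluated samples; NPV needs it to form TN,
    so it is threaded explicitly (defaults to the matrix total).
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix has negative counts")
    k = cm.shape[0]
    if n_total is None:
        n_total = int(cm.sum())

    ppv = np.empty(k)
    recall = np.empty(k)
    f1 = np.empty(k)
    npv = np.empty(k)
    support = cm.sum(axis=1)
    for c in range(k):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = n_total - tp - fp - fn
        ppv[c] = _safe_ratio(tp, tp + fp, "PPV", c)
        recall[c] = _safe_ratio(tp, tp + fn, "recall", c)
        npv[c] = _safe_ratio(tn, tn + fn, "NPV", c)
        if np.isnan(ppv[c]) or np.isnan(recall[c]) or (ppv[c] + recall[c]) == 0:
            if not (np.isnan(ppv[c]) or np.isnan(recall[c])):
                warnings.warn(
                    f"F1 undefined for class {c} (PPV + recall = 0); flagged as NaN",
                    RuntimeWarning,
                    stacklevel=2,
                )
            f1[c] = np.nan
        else:
            f1[c] = 2 * ppv[c] * recall[c] / (ppv[c] + recall[c])
    return MetricsReport(
        ppv=ppv, recall=recall, f1=f1, npv=npv, support=support, n_total=n_total
    )


def macro_average(report: MetricsReport) -> tuple[float, float, float]:
    """Unweighted mean of the six per-class PPVs, recalls and F1s."""
    for m in ("ppv", "recall", "f1"):
        if np.isnan(getattr(report, m)).any():
            raise ValueError(f"macro average undefined: some per-class {m} is NaN")
    return (
        float(report.ppv.mean()),
        float(report.recall.mean()),
        float(report.f1.mean()),
    )


def accuracy_from_matrix(cm: np.ndarray) -> float:
    """trace / total."""
    cm = np.asarray(cm)
    return float(np.trace(cm) / cm.sum())


def recover_counts(
    ppv: float, recall: float, n_total: int, max_denominator: int | None = None
) -> dict[str, int]:
    """Minimal integer confusion counts consistent with printed PPV/recall.

    Interprets the printed decimals as reduced fractions p/q and r/s (via
    ``Fraction.limit_denominator``); TP must be a common multiple of the
    numerators, so the minimal solution is TP = lcm(p, r), with
    TP + FP = TP·q/p and TP + FN = TP·s/r, and TN taken from ``n_total``.
    """
    max_den = max_denominator if max_denominator is not None else n_total
    f_ppv = Fraction(ppv).limit_denominator(max_den)
    f_rec = Fraction(recall).limit_denominator(max_den)
    if f_ppv <= 0 or f_rec <= 0:
        raise ValueError("PPV and recall must be positive to recover counts")
    tp = lcm(f_ppv.numerator, f_rec.numerator)
    predicted_pos = tp * f_ppv.denominator // f_ppv.numerator
    actual_pos = tp * f_rec.denominator // f_rec.numerator
    fp = predicted_pos - tp
    fn = actual_pos - tp
    tn = n_total - tp - fp - fn
    if tn < 0:
        raise ValueError("recovered counts exceed the stated total")
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def npv_from_counts(counts: dict[str, int]) -> float:
    """TN / (TN + FN) from a recovered count dictionary."""
    den = counts["tn"] + counts["fn"]
    if den == 0:
        raise ValueError("NPV undefined: TN + FN = 0")
    return counts["tn"] / den


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation/test index sets covering all samples."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")

    @property
    def train_full(self) -> np.ndarray:
        """Training indices including the validation carve-out."""
        return np.sort(np.concatenate([self.train, self.validation]))


def split_dataset(
    n_samples: int,
    labels=None,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> SplitPlan:
    """80/20 train/test split with a validation carve-out from the train side.

    The test size is ``round_half_up(test_frac * n)`` — so 2298 samples give
    a 1838/460 split — and the validation set is the same rounding of
    ``val_frac`` applied to the training portion.  Stratification keeps
    per-class proportions; deterministic given the seed.
    """
    if not 0 < test_frac < 1 or not 0 <= val_frac < 1:
        raise ValueError("fractions must lie in (0, 1)")
    if n_samples < N_CLASSES:
        raise ValueError("need at least one sample per class worth of data")
    idx = np.arange(n_samples)
    y = None if labels is None else np.asarray(labels)
    if stratify and y is None:
        raise ValueError("stratified split requires labels")

    n_test = round_half_up(test_frac * n_samples)
    train_val, test = train_test_split(
        idx,
        test_size=n_test,
        random_state=seed,
        stratify=y if stratify else None,
    )
    n_val = round_half_up(val_frac * len(train_val))
    if n_val > 0:
        train, val = train_test_split(
            train_val,
            test_size=n_val,
            random_state=seed + 1,
            stratify=y[train_val] if stratify else None,
        )
    else:
        train, val = train_val, np.array([], dtype=int)
    return SplitPlan(
        train=np.sort(train),
        validation=np.sort(val),
        test=np.sort(test),
        seed=seed,
        stratified=stratify,
    )


def format_report(report: MetricsReport) -> str:
    """Human-readable text rendering of a metrics report."""
    from .imaging import CLASS_NAMES

    lines = [
        f"{'class':<6} {'PPV':>9} {'recall':>9} {'F1':>9} {'NPV':>9} {'support':>8}",
    ]
    for c, name in enumerate(CLASS_NAMES):
        cells = []
        for metric in METRIC_NAMES:
            v = getattr(report, metric)[c]
            cells.append("   undef." if np.isnan(v) else f"{v:9.6f}")
        lines.append(f"{name:<6} " + " ".join(cells) + f" {int(report.support[c]):8d}")
    if report.defined.all():
        macro = macro_average(report)
        lines.append(
            f"{'macro':<6} {macro[0]:9.6f} {macro[1]:9.6f} {macro[2]:9.6f}"
            f" {'':>9} {int(report.support.sum()):8d}"
        )
    lines.append(f"evaluated on n = {report.n_total} samples")
    return "\n".join(lines)
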