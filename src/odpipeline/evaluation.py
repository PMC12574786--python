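"""Annotation evaluation: inter-annotator agreement and extraction metrics.

Two subject-matter annotators label a random sample of cases for the
presence of each drug class; consensus labels serve as ground truth for the
pipeline's indicator flags. Agreement is Cohen's kappa; extraction quality
is reported per class (prevalence, sensitivity, precision, NPV, F1) plus an
unweighted macro average across classes.

Zero-denominator metrics are reported as missing (None), never coerced to 0
or 1, so they cannot silently bias macro averages; the macro average then
excludes the undefined components pairwise with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "ConfusionMatrix",
    "ClassMetrics",
    "cohen_kappa",
    "confusion",
    "class_metrics",
    "macro_average",
    "evaluate_annotations",
    "load_annotations",
    "round_display",
]


def round_display(value: Optional[float], places: int = 2) -> Optional[float]:
    """Half-up rounding for display; full precision is kept internally."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_binary(vec: Sequence[int], name: str) -> list[int]:
    out = [int(v) for v in vec]
    if any(v not in (0, 1) for v in out):
        raise ValueError(f"{name} must be binary 0/1 labels")
    return out


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> Optional[float]:
    """Cohen's kappa = (po - pe) / (1 - pe), pe from marginal frequencies.

    Returns 1.0 when observed agreement is perfect; None (flagged) when
    chance agreement pe equals 1 and the statistic is undefined.
    """
    a = _check_binary(labels_a, "labels_a")
    b = _check_binary(labels_b, "labels_b")
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("label vectors must be nonempty")
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    if po == 1.0:
        return 1.0
    pa1, pb1 = sum(a) / n, sum(b) / n
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe == 1.0:
        logger.warning("kappa undefined: chance agreement pe = 1")
        return None
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of system calls against consensus truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(system: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Standard 2x2 counts of binary system output against truth."""
    s = _check_binary(system, "system")
    t = _check_binary(truth, "truth")
    if len(s) != len(t):
        raise ValueError(f"label vectors differ in length: {len(s)} vs {len(t)}")
    tp = sum(1 for x, y in zip(s, t) if x == 1 and y == 1)
    fp = sum(1 for x, y in zip(s, t) if x == 1 and y == 0)
    fn = sum(1 for x, y in zip(s, t) if x == 0 and y == 1)
    tn = sum(1 for x, y in zip(s, t) if x == 0 and y == 0)
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass(frozen=True)
class ClassMetrics:
    """Derived per-class performance; None marks an undefined component."""

    prevalence: Optional[float]
    sensitivity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    f1: Optional[float]

    def display(self, places: int = 2) -> dict[str, Optional[float]]:
        return {
            k: round_display(getattr(self, k), places)
            for k in ("prevalence", "sensitivity", "precision", "npv", "f1")
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Prevalence, sensitivity, precision, NPV, F1 from a 2x2 table.

    Each metric is None when its denominator is zero. F1 is the harmonic
    mean of precision and sensitivity, undefined when either is undefined
    or when both are zero.
    """
    if cm.n < 1:
        raise ValueError("confusion matrix is empty")
    prevalence = _ratio(cm.tp + cm.fn, cm.n)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return ClassMetrics(prevalence, sensitivity, precision, npv, f1)


def macro_average(per_class: Sequence[ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean per component across classes.

    Undefined components are excluded pairwise (with a warning) rather than
    failing or being coerced to a number.
    """
    if not per_class:
        raise ValueError("macro_average requires at least one class")
    values: dict[str, Optional[float]] = {}
    for comp in ("prevalence", "sensitivity", "precision", "npv", "f1"):
        defined = [getattr(m, comp) for m in per_class if getattr(m, comp) is not None]
        if len(defined) < len(per_class):
            logger.warning(
                "macro %s averages %d of %d classes (undefined excluded)",
                comp,
                len(defined),
                len(per_class),
            )
        values[comp] = sum(defined) / len(defined) if defined else None
    return ClassMetrics(**values)


@dataclass
class AnnotationSet:
    """Per-case, per-class binary labels from two annotators, consensus, system."""

    frame: pd.DataFrame

    REQUIRED = ["case_id", "class", "annotator_a", "annotator_b", "consensus", "system"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"annotation table lacks column(s): {missing}")
        for col in ("annotator_a", "annotator_b", "consensus", "system"):
            bad = ~self.frame[col].isin([0, 1, "0", "1"])
            if bad.any():
                raise ValueError(f"non-binary labels in column {col!r}")
            self.frame[col] = self.frame[col].astype(int)

    @property
    def classes(self) -> list[str]:
        return sorted(self.frame["class"].unique())

    def vectors(self, label: str, column: str) -> list[int]:
        sub = self.frame[self.frame["class"] == label].sort_values("case_id")
        return sub[column].tolist()


def load_annotations(path: str | Path) -> AnnotationSet:
    return AnnotationSet(pd.read_csv(path))


def evaluate_annotations(annotations: AnnotationSet) -> pd.DataFrame:
    """Per-class and macro metric table (kappa between annotators included).

    Returns one row per class plus a "macro average" row; metric columns
    hold full-precision values (NaN where undefined).
    """
    rows = []
    per_class: list[ClassMetrics] = []
    kappas: list[Optional[float]] = []
    for label in annotations.classes:
        kappa = cohen_kappa(
            annotations.vectors(label, "annotator_a"),
            annotations.vectors(label, "annotator_b"),
        )
        cm = confusion(
            annotations.vectors(label, "system"),
            annotations.vectors(label, "consensus"),
        )
        metrics = class_metrics(cm)
        per_class.append(metrics)
        kappas.append(kappa)
        rows.append({"indicator": label, "kappa": kappa, **metrics.__dict__})
    macro = macro_average(per_class)
    defined_k = [k for k in kappas if k is not None]
    rows.append(
        {
            "indicator": "macro average",
            "kappa": sum(defined_k) / len(defined_k) if defined_k else None,
            **macro.__dict__,
        }
    )
    return pd.DataFrame(rows)
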