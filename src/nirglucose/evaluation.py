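"""Clinical evaluation statistics for glucose prediction.

Covers the full battery used to judge point-of-care glucometers: 2x2
confusion-matrix metrics at the 126 mg/dL diabetes threshold, ROC/AUC by
threshold sweep, Clarke Error Grid zoning (classical 1987 piecewise rules),
Bland-Altman bias and 95% limits of agreement, the two ISO 15197:2013
accuracy criteria, and exclusion-based feature-group importance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CEGReport",
    "BlandAltmanReport",
    "ISO15197Report",
    "FeatureImportanceReport",
    "EvaluationReport",
    "confusion_metrics",
    "ceg_zone",
    "ceg_zones",
    "ceg_report",
    "bland_altman",
    "roc_curve",
    "iso15197_check",
    "feature_importance_by_exclusion",
    "evaluate_predictions",
]

CEG_ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with the high-glucose class (>= 126 mg/dL) as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label arrays must have equal length")
        return cls(
            tp=int(np.sum((y_pred == 1) & (y_true == 1))),
            fp=int(np.sum((y_pred == 1) & (y_true == 0))),
            fn=int(np.sum((y_pred == 0) & (y_true == 1))),
            tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, sensitivity, specificity as proportions in [0, 1].

    A ratio with a zero denominator is reported as NaN (with a warning at
    computation time), never silently as 0.
    """

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _safe_ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Standard diagnostic metrics from a 2x2 confusion matrix."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    return MetricSet(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=_safe_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        sensitivity=_safe_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_safe_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
    )


# ---------------------------------------------------------------------------
# Clarke Error Grid

def ceg_zones(ref, pred) -> np.ndarray:
    """Vectorized Clarke Error Grid zone for each (reference, predicted) pair.

    Classical piecewise rules with precedence A > E > C > D > B:

    * A: clinically accurate — both below 70, or prediction within +/-20% of
      the reference;
    * E: critical — treating hypo- as hyper-glycemia or vice versa;
    * C: overcorrection regions;
    * D: dangerous failure to detect an out-of-range value;
    * B: everything else (benign deviation).
    """
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("ref and pred must have equal shape")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(pred))):
        raise ValueError("ref and pred must be finite")
    if np.any(ref <= 0) or np.any(pred < 0):
        raise ValueError("ref must be > 0 and pred >= 0")

    zone_a = ((ref <= 70) & (pred <= 70)) | ((pred >= 0.8 * ref) & (pred <= 1.2 * ref))
    zone_e = ((ref >= 180) & (pred <= 70)) | ((ref <= 70) & (pred >= 180))
    zone_c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182)
    )
    zone_d = (
        ((ref >= 240) & (pred >= 70) & (pred <= 180))
        | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
        | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))
    )
    out = np.select([zone_a, zone_e, zone_c, zone_d], ["A", "E", "C", "D"], default="B")
    return out.astype("U1")


def ceg_zone(ref: float, pred: float) -> str:
    """Clarke zone of a single (reference, predicted) glucose pair in mg/dL."""
    return str(ceg_zones(np.asarray([ref], dtype=float), np.asarray([pred], dtype=float))[0])


@dataclass(frozen=True)
class CEGReport:
    """Zone counts and fractions over a set of paired measurements."""

    zone_counts: dict
    n: int

    @property
    def zone_fractions(self) -> dict:
        return {z: self.zone_counts[z] / self.n for z in CEG_ZONES}

    @property
    def frac_ab(self) -> float:
        return (self.zone_counts["A"] + self.zone_counts["B"]) / self.n


def ceg_report(ref, pred) -> CEGReport:
    zones = ceg_zones(np.asarray(ref, dtype=float), np.asarray(pred, dtype=float))
    counts = {z: int(np.sum(zones == z)) for z in CEG_ZONES}
    return CEGReport(zone_counts=counts, n=int(zones.size))


# ---------------------------------------------------------------------------
# Bland-Altman

@dataclass(frozen=True)
class BlandAltmanReport:
    """Mean difference (bias) and 95% limits of agreement bias -/+ 1.96 SD."""

    mode: str
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(ref, pred, mode: str = "percent") -> BlandAltmanReport:
    """Agreement between predicted and reference glucose.

    Differences are ``pred - ref`` in absolute mode (mg/dL) or
    ``100 * (pred - ref) / ref`` in percent mode.  Limits of agreement use the
    sample standard deviation (n-1 denominator).
    """
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape or ref.size < 2:
        raise ValueError("ref and pred must be equal-length series of length >= 2")
    if mode == "absolute":
        diff = pred - ref
    elif mode == "percent":
        if np.any(ref == 0):
            raise ValueError("percent mode requires nonzero reference values")
        diff = 100.0 * (pred - ref) / ref
    else:
        raise ValueError("mode must be 'absolute' or 'percent'")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanReport(
        mode=mode,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        n=int(ref.size),
    )


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_curve(scores, labels):
    """ROC by sweeping a threshold over the unique scores.

    Returns ``(fpr, tpr, thresholds, auc)`` with points ordered from (0, 0) to
    (1, 1).  The trapezoidal AUC equals the normalized Mann-Whitney U
    statistic, with tied score pairs counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve requires both classes present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # collapse tied scores into single sweep points
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


# ---------------------------------------------------------------------------
# ISO 15197:2013

@dataclass(frozen=True)
class ISO15197Report:
    """The two system-accuracy criteria for point-of-care glucometers.

    Criterion 1: at least 95% of results within +/-15 mg/dL of the laboratory
    reference when ref < 100 mg/dL and within +/-15% when ref >= 100 mg/dL
    (boundary inclusive).  Criterion 2: at least 99% of results in error-grid
    zones A or B; evaluated here on the Clarke grid.
    """

    frac_within_low: float
    frac_within_high: float
    frac_within: float
    frac_zone_ab: float
    criterion1_pass: bool
    criterion2_pass: bool
    overall_pass: bool
    n: int


def iso15197_within(ref, pred) -> np.ndarray:
    """Per-pair indicator of the reference-dependent ISO accuracy limit."""
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    err = np.abs(pred - ref)
    return np.where(ref < 100.0, err <= 15.0, err <= 0.15 * ref)


def iso15197_check(ref, pred) -> ISO15197Report:
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape or ref.size < 1:
        raise ValueError("ref and pred must be equal-length nonempty series")
    if np.any(ref <= 0):
        raise ValueError("reference glucose must be > 0")
    within = iso15197_within(ref, pred)
    low = ref < 100.0
    frac_low = float(within[low].mean()) if low.any() else math.nan
    frac_high = float(within[~low].mean()) if (~low).any() else math.nan
    frac = float(within.mean())
    frac_ab = ceg_report(ref, pred).frac_ab
    c1 = frac >= 0.95
    c2 = frac_ab >= 0.99
    return ISO15197Report(
        frac_within_low=frac_low,
        frac_within_high=frac_high,
        frac_within=frac,
        frac_zone_ab=frac_ab,
        criterion1_pass=bool(c1),
        criterion2_pass=bool(c2),
        overall_pass=bool(c1 and c2),
        n=int(ref.size),
    )


# ---------------------------------------------------------------------------
# exclusion feature importance

@dataclass(frozen=True)
class FeatureImportanceReport:
    """Accuracy drop when a feature group is excluded, normalized to sum to 1."""

    group_names: tuple
    baseline_metric: float
    excluded_metric: dict
    raw_drop: dict
    normalized: dict


def feature_importance_by_exclusion(
    feature_groups: dict,
    evaluator,
    all_features=None,
) -> FeatureImportanceReport:
    """Importance of each feature group by retraining without it.

    ``feature_groups`` maps a group name to the list of feature columns it
    contains; the groups must partition the full feature set.  ``evaluator``
    is called with a list of feature names and must return the performance
    metric (larger = better) of a model trained and evaluated on exactly those
    features; it must be deterministic under its own seed.  The raw importance
    of a group is ``max(0, baseline - metric-without-group)``; raw drops are
    normalized to sum to 1 (uniform if every drop is zero).
    """
    names = tuple(feature_groups)
    if len(names) < 2:
        raise ValueError("need at least two feature groups to contrast against the baseline")
    cols = [c for g in names for c in feature_groups[g]]
    if len(set(cols)) != len(cols):
        raise ValueError("feature groups must be disjoint")
    if all_features is not None and set(cols) != set(all_features):
        raise ValueError("feature groups must partition the full feature set")
    full = cols if all_features is None else list(all_features)

    baseline = float(evaluator(full))
    excluded, raw = {}, {}
    for g in names:
        kept = [c for c in full if c not in set(feature_groups[g])]
        m = float(evaluator(kept))
        excluded[g] = m
        raw[g] = max(0.0, baseline - m)
    total = sum(raw.values())
    if total == 0:
        warnings.warn("no feature group affected the metric; reporting uniform importances")
        normalized = {g: 1.0 / len(names) for g in names}
    else:
        normalized = {g: raw[g] / total for g in names}
    return FeatureImportanceReport(
        group_names=names,
        baseline_metric=baseline,
        excluded_metric=excluded,
        raw_drop=raw,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# bundled report

@dataclass(frozen=True)
class EvaluationReport:
    """Everything measured on one set of (reference, predicted) pairs."""

    confusion: ConfusionMatrix
    metrics: MetricSet
    ceg: CEGReport
    bland_altman: BlandAltmanReport
    iso15197: ISO15197Report
    auc: float
    threshold: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        """One row per metric, suitable for CSV export."""
        rows = [
            ("n", self.n),
            ("threshold_mg_dl", self.threshold),
            ("tp", self.confusion.tp),
            ("fp", self.confusion.fp),
            ("fn", self.confusion.fn),
            ("tn", self.confusion.tn),
            ("accuracy", self.metrics.accuracy),
            ("precision", self.metrics.precision),
            ("sensitivity", self.metrics.sensitivity),
            ("specificity", self.metrics.specificity),
            ("auc", self.auc),
            ("bland_altman_mode", self.bland_altman.mode),
            ("bland_altman_bias", self.bland_altman.bias),
            ("bland_altman_loa_low", self.bland_altman.loa_low),
            ("bland_altman_loa_high", self.bland_altman.loa_high),
            ("iso_frac_within", self.iso15197.frac_within),
            ("iso_frac_zone_ab", self.iso15197.frac_zone_ab),
            ("iso_criterion1_pass", self.iso15197.criterion1_pass),
            ("iso_criterion2_pass", self.iso15197.criterion2_pass),
            ("iso_overall_pass", self.iso15197.overall_pass),
        ] + [(f"ceg_zone_{z}", self.ceg.zone_counts[z]) for z in CEG_ZONES]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Evaluation on n={self.n} pairs (DM threshold {self.threshold:g} mg/dL)",
            f"  accuracy    {100 * m.accuracy:6.1f} %",
            f"  precision   {100 * m.precision:6.1f} %",
            f"  sensitivity {100 * m.sensitivity:6.1f} %",
            f"  specificity {100 * m.specificity:6.1f} %",
            f"  AUC         {self.auc:7.3f}",
            "  Clarke zones: "
            + "  ".join(f"{z}={self.ceg.zone_counts[z]}" for z in CEG_ZONES),
            f"  Bland-Altman ({self.bland_altman.mode}): bias {self.bland_altman.bias:+.2f}, "
            f"LoA [{self.bland_altman.loa_low:+.2f}, {self.bland_altman.loa_high:+.2f}]",
            f"  ISO 15197: within-limit {100 * self.iso15197.frac_within:.1f} % "
            f"(criterion 1 {'PASS' if self.iso15197.criterion1_pass else 'FAIL'}), "
            f"zones A+B {100 * self.iso15197.frac_zone_ab:.1f} % "
            f"(criterion 2 {'PASS' if self.iso15197.criterion2_pass else 'FAIL'})",
        ]
        return "\n".join(lines)


def evaluate_predictions(
    ref, pred, threshold: float = 126.0, ba_mode: str = "percent"
) -> EvaluationReport:
    """Full clinical evaluation of predicted vs reference glucose (mg/dL)."""
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    y_true = (ref >= threshold).astype(int)
    y_pred = (pred >= threshold).astype(int)
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    if len(np.unique(y_true)) == 2:
        _, _, _, auc = roc_curve(pred, y_true)
    else:
        auc = math.nan
    return EvaluationReport(
        confusion=cm,
        metrics=confusion_metrics(cm),
        ceg=ceg_report(ref, pred),
        bland_altman=bland_altman(ref, pred, mode=ba_mode),
        iso15197=iso15197_check(ref, pred),
        auc=auc,
        threshold=threshold,
        n=int(ref.size),
    )
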