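"""Segmentation evaluation: confusion matrices, IoU, precision/recall, and
paired significance testing.

Per class c, with TP_c / FP_c / FN_c counted point-wise against the manual
labels:

    IoU_c     = TP_c / (TP_c + FP_c + FN_c)
    P_c       = TP_c / (TP_c + FP_c)
    R_c       = TP_c / (TP_c + FN_c)
    IoU_micro = sum_c TP_c / sum_c (TP_c + FP_c + FN_c)
    IoU_macro = mean of the defined per-class IoU values

Undefined ratios (zero denominator: the class occurs in neither truth nor
prediction) are reported as NaN and excluded from the macro mean rather than
scored as 0.  Differences between paired runs are tested with a two-sided
Wilcoxon signed-rank test and reported with the usual significance stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cloud_io import UNLABELLED, ClassScheme

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = self.scheme.n_classes
        if self.counts.shape != (C, C):
            raise ValueError(f"counts must be ({C}, {C}), got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts).copy()

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    def row_normalised(self) -> np.ndarray:
        """Row percentages: each row of true labels sums to 100 (NaN for empty rows)."""
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, self.counts / row_sums * 100.0, np.nan)


@dataclass
class MetricReport:
    """Per-class and averaged segmentation metrics for one evaluation."""

    iou: np.ndarray  # (C,) per-class IoU, NaN where undefined
    precision: np.ndarray
    recall: np.ndarray
    iou_micro: float
    iou_macro: float
    n_points: int
    scheme: ClassScheme = field(default_factory=ClassScheme)


@dataclass
class SignificanceLabel:
    """Wilcoxon signed-rank outcome with conventional star notation."""

    p_value: float
    stars: str  # "n.s.", "*", "**" or "***"


def confusion_matrix(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    scheme: ClassScheme | None = None,
) -> ConfusionMatrix:
    """Point-wise confusion counts: counts[i, j] = #points true i predicted j."""
    scheme = scheme or ClassScheme()
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    C = scheme.n_classes
    if np.any(t == UNLABELLED) or np.any(p == UNLABELLED):
        raise ValueError("sentinel labels cannot be evaluated; filter them first")
    if np.any((t < 0) | (t >= C)) or np.any((p < 0) | (p >= C)):
        raise ValueError(f"labels must lie in [0, {C})")
    counts = np.bincount(t * C + p, minlength=C * C).reshape(C, C)
    return ConfusionMatrix(counts, scheme=scheme)


def iou_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """IoU_c = TP / (TP + FP + FN); NaN where the class is entirely absent."""
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    denom = (tp + fp + fn).astype(np.float64)
    undefined = denom == 0
    if np.any(undefined):
        logger.warning(
            "classes %s absent from truth and prediction; IoU undefined",
            [cm.scheme.names[c] for c in np.flatnonzero(undefined)],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(undefined, np.nan, tp / denom)


def iou_micro(cm: ConfusionMatrix) -> float:
    """Pooled IoU over all classes: sum TP / sum (TP + FP + FN)."""
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    return float(tp.sum() / (tp + fp + fn).sum())


def iou_macro(per_class: np.ndarray) -> float:
    """Unweighted mean of the defined (non-NaN) per-class IoU values."""
    per_class = np.asarray(per_class, dtype=np.float64)
    if np.all(np.isnan(per_class)):
        return float("nan")
    return float(np.nanmean(per_class))


def precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision TP/(TP+FP) and recall TP/(TP+FN); NaN when undefined."""
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
    return precision, recall


def evaluate(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    scheme: ClassScheme | None = None,
) -> MetricReport:
    """Full metric report for one merged cloud (or any label-vector pair)."""
    cm = confusion_matrix(true_labels, predicted_labels, scheme)
    iou = iou_per_class(cm)
    precision, recall = precision_recall(cm)
    return MetricReport(
        iou=iou,
        precision=precision,
        recall=recall,
        iou_micro=iou_micro(cm),
        iou_macro=iou_macro(iou),
        n_points=int(cm.counts.sum()),
        scheme=cm.scheme,
    )


def diff_normalised(
    cm_a: ConfusionMatrix | np.ndarray, cm_b: ConfusionMatrix | np.ndarray
) -> np.ndarray:
    """Row-normalised(b) - row-normalised(a), in percentage points.

    Accepts count matrices (which are row-normalised first) or matrices that
    are already row percentages — e.g. published confusion tables.
    """
    def as_pct(x: ConfusionMatrix | np.ndarray) -> np.ndarray:
        if isinstance(x, ConfusionMatrix):
            return x.row_normalised()
        return np.asarray(x, dtype=np.float64)

    a, b = as_pct(cm_a), as_pct(cm_b)
    if (
        isinstance(cm_a, ConfusionMatrix)
        and isinstance(cm_b, ConfusionMatrix)
        and cm_a.scheme != cm_b.scheme
    ):
        raise ValueError("confusion matrices use different class schemes")
    if a.shape != b.shape:
        raise ValueError("matrix shapes differ")
    return b - a


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_paired(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> SignificanceLabel:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Exact null distribution for up to 25 non-zero differences, normal
    approximation with continuity correction beyond that.  All-zero
    differences give p = 1 (no evidence of any difference).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for a meaningful test")
    diffs = b - a
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero == 0:
        return SignificanceLabel(p_value=1.0, stars="n.s.")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    p = float(res.pvalue)
    return SignificanceLabel(p_value=p, stars=significance_stars(p))
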