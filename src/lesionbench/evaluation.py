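"""Outcome and agreement measures: partial ROC, scaled pAUC, Dice.

Segmentation quality is summarized by the ROC curve restricted to false
positive rates at or below 10% (whole-brain classification is extremely
imbalanced, so only the low-FPR regime matters clinically).  The scaled
pAUC divides the partial area by the FPR bound, giving a value in [0, 1]
with 1 for perfect ranking of lesion above non-lesion voxels.  Agreement
between binary segmentations (algorithms thresholded at a pooled FPR of
0.5%, plus the manual "silver standard") uses the Dice similarity
coefficient 2|A&B|/(|A|+|B|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics


@dataclass
class ROCCurve:
    """Empirical ROC with tied scores grouped into single steps."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray | None
    n_pos: int
    n_neg: int


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Pooled empirical ROC over all distinct score thresholds."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg)


def scaled_pauc(curve: ROCCurve, fpr_max: float = 0.10) -> float:
    """Trapezoidal area under the ROC for fpr <= fpr_max, divided by fpr_max.

    The curve is linearly interpolated at the fpr_max boundary.  With
    fpr_max = 1 this is the full AUC (the Mann-Whitney statistic).
    """
    if not (0.0 < fpr_max <= 1.0):
        raise ValueError("fpr_max must lie in (0, 1]")
    fpr = np.asarray(curve.fpr, dtype=float)
    tpr = np.asarray(curve.tpr, dtype=float)
    tpr_at = float(np.interp(fpr_max, fpr, tpr))
    keep = fpr < fpr_max
    xs = np.append(fpr[keep], fpr_max)
    ys = np.append(tpr[keep], tpr_at)
    area = float(np.trapezoid(ys, xs))
    return area / fpr_max


def threshold_at_fpr(curve: ROCCurve, target_fpr: float = 0.005) -> float:
    """Smallest score threshold whose pooled FPR is <= target_fpr.

    Binarization is ``score >= threshold``.  If no finite threshold
    satisfies the bound (the top-scoring voxel is a non-lesion voxel and
    target_fpr is below 1/n_neg), +inf is returned, i.e. the empty
    segmentation.
    """
    if not (0.0 <= target_fpr < 1.0):
        raise ValueError("target_fpr must lie in [0, 1)")
    if curve.thresholds is None:
        raise ValueError("curve carries no thresholds")
    ok = np.flatnonzero(curve.fpr <= target_fpr)
    i = int(ok[-1])  # fpr is nondecreasing, thresholds nonincreasing
    return float(curve.thresholds[i])


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B|/(|A|+|B|) of two binary volumes."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty sets defined as 1 (perfect agreement)")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class AgreementMatrix:
    """Symmetric pairwise-Dice table over named segmentations."""

    table: pd.DataFrame
    threshold_fpr: float | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)


def agreement_matrix(
    segmentations: Mapping[str, np.ndarray],
    threshold_fpr: float | None = None,
) -> AgreementMatrix:
    """Pairwise Dice over all named binary segmentations (diagonal = 1)."""
    names = list(segmentations)
    if len(names) < 2:
        raise ValueError("need at least two segmentations")
    shapes = {np.asarray(v).shape for v in segmentations.values()}
    if len(shapes) != 1:
        raise ValueError(f"segmentations do not share a grid: {shapes}")
    vals = np.ones((len(names), len(names)))
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            d = dice(segmentations[ni], segmentations[names[j]])
            vals[i, j] = vals[j, i] = d
    table = pd.DataFrame(vals, index=names, columns=names)
    return AgreementMatrix(table=table, threshold_fpr=threshold_fpr)
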