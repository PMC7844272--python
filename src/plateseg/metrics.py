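"""Intersection-over-union evaluation, confusion matrices, volume fractions.

The headline metric is the unweighted mean intersection-over-union over a
class subset D::

    MIoU^(D)(l, lhat) = (1/|D|) * sum_{j in D} IoU(L_j, Lhat_j),
    IoU(A, B) = |A intersect B| / |A union B|

with ``MIoU^(all)`` taken over all 7 classes and ``MIoU^(org)`` over the 5
organelle classes.  Equal class weighting deliberately emphasizes rare
classes.  An optional boolean mask restricts every count to a region of
interest (e.g. a single labeled cell, or the stitching validity region).

Classes absent from both segmentations within the mask have an undefined IoU
(0/0) and are excluded from the mean by default; ``strict_empty=True``
instead scores them 1.  Classes present in exactly one segmentation
contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CLASSES, N_CLASSES, ORGANELLE_CLASSES, LabelVolume

CLASS_SUBSETS = {"all": tuple(CLASSES), "org": ORGANELLE_CLASSES}


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, LabelVolume) else np.asarray(x)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two binary masks; NaN when both are empty (excluded from means)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)


def miou(
    truth,
    pred,
    classes=CLASSES,
    mask: np.ndarray | None = None,
    strict_empty: bool = False,
) -> float:
    """Mean IoU over a class subset, optionally restricted to a mask."""
    t = _as_array(truth)
    p = _as_array(pred)
    if t.shape != p.shape:
        raise ValueError("truth/prediction shapes must match")
    if len(classes) == 0 or not set(classes) <= set(CLASSES):
        raise ValueError("classes must be a nonempty subset of {0..6}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        t = t[mask]
        p = p[mask]
    vals = []
    for j in classes:
        v = iou(t == j, p == j)
        if np.isnan(v):
            if strict_empty:
                vals.append(1.0)
            continue
        vals.append(v)
    if not vals:
        raise ValueError("no class in the subset is present in either segmentation")
    return float(np.mean(vals))


def confusion_matrix(truth, pred, mask: np.ndarray | None = None) -> np.ndarray:
    """7x7 count matrix; entry (i, j) counts voxels with truth i, prediction j."""
    t = _as_array(truth)
    p = _as_array(pred)
    if t.shape != p.shape:
        raise ValueError("truth/prediction shapes must match")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        t = t[mask]
        p = p[mask]
    idx = t.astype(np.int64).ravel() * N_CLASSES + p.astype(np.int64).ravel()
    return np.bincount(idx, minlength=N_CLASSES * N_CLASSES).reshape(
        N_CLASSES, N_CLASSES
    )


def volume_fractions(labels, cell_mask: np.ndarray) -> dict[int, float]:
    """Per-organelle voxel fraction of the cell: count(class o in mask) / count(mask)."""
    lab = _as_array(labels)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n = int(cell_mask.sum())
    if n == 0:
        raise ValueError("cell mask is empty")
    inside = lab[cell_mask]
    return {o: float((inside == o).sum() / n) for o in ORGANELLE_CLASSES}


def approximate_cell_mask(
    seg, reference_mask: np.ndarray, dilation_radius: int = 2
) -> np.ndarray:
    """Non-background voxels of ``seg`` within a dilation of a reference cell mask.

    The reference mask is binary-dilated ``dilation_radius`` times with the
    6-connected structuring element, then intersected with ``seg != 0``.
    """
    s = _as_array(seg)
    ref = np.asarray(reference_mask, dtype=bool)
    if s.shape != ref.shape:
        raise ValueError("segmentation/reference shapes must match")
    if dilation_radius < 0:
        raise ValueError("dilation radius must be >= 0")
    if dilation_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        ref = ndimage.binary_dilation(ref, structure, iterations=dilation_radius)
    return ref & (s != 0)


def pairwise_report(
    segmentations: dict[str, np.ndarray | LabelVolume],
    classes=ORGANELLE_CLASSES,
    mask: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray, dict[tuple[str, str], np.ndarray]]:
    """Symmetric matrix of pairwise MIoU plus per-pair confusion matrices.

    Used to compare independent annotations of the same region (human
    annotators and/or algorithmic segmentations); there is no privileged
    ground truth, so every unordered pair is scored.
    """
    names = list(segmentations)
    if len(names) < 2:
        raise ValueError("pairwise comparison needs at least 2 segmentations")
    k = len(names)
    mat = np.eye(k)
    confusions: dict[tuple[str, str], np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = segmentations[names[i]], segmentations[names[j]]
            mat[i, j] = mat[j, i] = miou(a, b, classes=classes, mask=mask)
            confusions[(names[i], names[j])] = confusion_matrix(a, b, mask=mask)
    return names, mat, confusions


@dataclass
class MetricsReport:
    """Bundle of the standard evaluation outputs for one prediction."""

    per_class_iou: list[float]
    miou_all: float
    miou_org: float
    confusion: np.ndarray
    volume_fractions: dict[int, float] | None
    mask_used: bool

    def to_dict(self) -> dict:
        return {
            "per_class_iou": self.per_class_iou,
            "miou_all": self.miou_all,
            "miou_org": self.miou_org,
            "confusion": self.confusion.tolist(),
            "volume_fractions": self.volume_fractions,
            "mask_used": self.mask_used,
        }


def evaluate(
    truth,
    pred,
    mask: np.ndarray | None = None,
    cell_mask: np.ndarray | None = None,
) -> MetricsReport:
    """Full evaluation: per-class IoUs, MIoU^(all), MIoU^(org), confusion."""
    t = _as_array(truth)
    p = _as_array(pred)
    per_class = []
    tm = t[mask] if mask is not None else t
    pm = p[mask] if mask is not None else p
    for j in CLASSES:
        per_class.append(iou(tm == j, pm == j))
    return MetricsReport(
        per_class_iou=per_class,
        miou_all=miou(t, p, CLASSES, mask),
        miou_org=miou(t, p, ORGANELLE_CLASSES, mask),
        confusion=confusion_matrix(t, p, mask),
        volume_fractions=(
            volume_fractions(pred, cell_mask) if cell_mask is not None else None
        ),
        mask_used=mask is not None,
    )
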