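"""Per-voxel loss weight construction: W = w + W_cb + W_ep.

The training loss weights every voxel by the sum of a small floor constant
``w``, an inverse-frequency class-balancing term ``W_cb`` (computed once over
the whole training volume), and an edge-preserving term ``W_ep`` that
emphasizes voxels near boundaries between background, cell and organelle
material.  ``W_ep`` is computed independently on each 2D z-slice as a
rectified sum of four *directed* diffusion terms: a binary indicator of a
source class set is blurred with a unit-sum Gaussian kernel, scaled by ``c``,
and kept only on voxels belonging to the target class set::

    W_ep = R_alpha(W_bkgd->cell + W_cell->bkgd + W_cell->org + W_org->cell)

with the rectified rescaling R_alpha(W) = ReLU(W - alpha) * max(W)/(max(W) - alpha),
which zeroes weak responses while mapping the slice maximum to itself.

The diffusion replaces the morphological-distance weight maps of the original
U-Net recipe: it needs no connected-component analysis and is a smooth
function of the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import CLASSES, LabelVolume

#: Named class subsets used by the four directed edge terms.
DEFAULT_CLASS_SETS = {
    "bkgd": frozenset({0}),
    "cell": frozenset({1}),
    "org": frozenset({2, 3, 4, 5, 6}),
}

#: The four (source, target) pairs of the edge-preserving sum.
DIRECTED_TERMS = (
    ("bkgd", "cell"),
    ("cell", "bkgd"),
    ("cell", "org"),
    ("org", "cell"),
)

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


@dataclass
class EdgeWeightParams:
    """Parameters of the weight construction.

    floor_w
        Constant floor ``w`` added everywhere.
    alpha
        Rectification threshold of ``R_alpha``.
    scale_c
        Scale ``c`` applied to each diffused source mask.
    sigma
        Gaussian standard deviation, in lateral pixels of the (binned) volume.
    class_sets
        Named disjoint class subsets; must cover the full class set.
    """

    floor_w: float = 0.01
    alpha: float = 0.25
    scale_c: float = 0.882
    sigma: float = 6.0
    class_sets: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SETS)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < self.scale_c:
            raise ValueError("require 0 <= alpha < scale_c")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        sets = list(self.class_sets.values())
        union: set[int] = set()
        for s in sets:
            if union & s:
                raise ValueError("class_sets must be disjoint")
            union |= set(s)
        if union != set(CLASSES):
            raise ValueError("class_sets must cover the class set {0..6}")


def class_balance_weights(labels: LabelVolume) -> np.ndarray:
    """Inverse-frequency class weights W_cb with max over present classes = 1.

    For classes present in ``labels``, ``W_cb[i] = min_j N_j / N_i`` over
    present classes ``j``; classes absent from the volume get weight 0 (they
    never occur, so their weight is irrelevant and 1/N_i is undefined).
    """
    counts = np.bincount(labels.data.ravel(), minlength=len(CLASSES)).astype(np.float64)
    weights = np.zeros(len(CLASSES), dtype=np.float64)
    present = counts > 0
    if present.any():
        weights[present] = counts[present].min() / counts[present]
    return weights


def diffusion_mask(source_slice: np.ndarray, c: float, sigma: float) -> np.ndarray:
    """M_source(c, sigma) = c * (binary mask convolved with unit-sum Gaussian).

    The kernel is truncated at 4 sigma; boundaries are handled by reflection,
    so an all-one mask maps exactly to the constant ``c``.
    """
    src = np.asarray(source_slice)
    if src.ndim != 2:
        raise ValueError("source slice must be rank 2")
    vals = np.unique(src)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"source slice must be binary, found values {vals[:5]}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return c * ndimage.gaussian_filter(
        src.astype(np.float64), sigma=sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )


def directed_edge_weight(
    labels_slice: np.ndarray,
    source: frozenset[int] | set[int],
    target: frozenset[int] | set[int],
    params: EdgeWeightParams,
) -> np.ndarray:
    """W_source->target: diffused source indicator, masked to target voxels."""
    if set(source) & set(target):
        raise ValueError("source and target class subsets must be disjoint")
    lab = np.asarray(labels_slice)
    src = np.isin(lab, list(source)).astype(np.float64)
    mask = np.isin(lab, list(target))
    out = diffusion_mask(src, params.scale_c, params.sigma)
    out[~mask] = 0.0
    return out


def rectified_rescale(w_slice: np.ndarray, alpha: float) -> np.ndarray:
    """R_alpha(W) = ReLU(W - alpha) * max(W) / (max(W) - alpha).

    Values <= alpha are zeroed and the maximum maps to itself.  If the slice
    maximum does not exceed alpha the result is identically zero (the rescale
    factor would be undefined).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    w = np.asarray(w_slice, dtype=np.float64)
    m = w.max() if w.size else 0.0
    if m <= alpha:
        return np.zeros_like(w)
    return np.maximum(w - alpha, 0.0) * (m / (m - alpha))


def edge_preserving_slice(
    labels_slice: np.ndarray, params: EdgeWeightParams | None = None
) -> np.ndarray:
    """W_ep for one z-slice: rectified sum of the four directed terms."""
    params = params or EdgeWeightParams()
    total = np.zeros(np.asarray(labels_slice).shape, dtype=np.float64)
    for src_name, tgt_name in DIRECTED_TERMS:
        total += directed_edge_weight(
            labels_slice,
            params.class_sets[src_name],
            params.class_sets[tgt_name],
            params,
        )
    return rectified_rescale(total, params.alpha)


@dataclass
class WeightVolume:
    """Rank-3 nonnegative float array weighting the per-voxel loss."""

    data: np.ndarray
    floor_w: float = 0.01

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("weight volume must be rank 3")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("weight volume contains non-finite values")
        if self.data.min() < self.floor_w - 1e-12:
            raise ValueError("weight volume values must be >= floor_w")


def build_weight_volume(
    labels: LabelVolume, params: EdgeWeightParams | None = None
) -> WeightVolume:
    """Assemble W(v) = w + W_cb[label(v)] + W_ep(v).

    W_cb uses counts from the entire 3D volume; W_ep is computed per z-slice.
    """
    params = params or EdgeWeightParams()
    cb = class_balance_weights(labels)
    out = params.floor_w + cb[labels.data.astype(np.int64)]
    for z in range(labels.data.shape[0]):
        out[z] += edge_preserving_slice(labels.data[z], params)
    return WeightVolume(out, floor_w=params.floor_w)
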