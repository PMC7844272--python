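"""Full-volume prediction, Top-k probability-averaging ensembles, thresholding.

A trained network predicts a full volume by tiling it into input windows,
running the forward pass per window, and stitching the output-window class
probabilities (overlaps averaged).  An ensemble averages the stitched
per-voxel class distributions of several member networks -- identical
architectures trained from different random seeds -- and the final
segmentation is the voxelwise argmax (ties broken toward the lowest class
index).  ``Top-k`` denotes the ensemble of the k members with the highest
evaluation-set MIoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import ImageVolume, LabelVolume, N_CLASSES
from .windowing import WindowSpec, stitch_predictions, tile_for_inference


@dataclass
class ClassProbs:
    """Rank-4 (7, z, y, x) per-voxel class probability distributions."""

    data: np.ndarray
    valid: np.ndarray | None = None  # voxels covered by at least one output window

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != N_CLASSES:
            raise ValueError("class probabilities must have shape (7, z, y, x)")
        sums = self.data.sum(axis=0)
        if np.any(self.data < -1e-6) or np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError("per-voxel distributions must be in [0,1] and sum to 1")


def predict_volume(network, vol: ImageVolume, spec: WindowSpec) -> ClassProbs:
    """Tile, forward (the network's output head) and stitch a full volume."""
    corners = tile_for_inference(vol.shape, spec)
    windows = []
    iz, iy, ix = spec.input_shape
    for cz, cy, cx in corners:
        window = vol.data[cz : cz + iz, cy : cy + iy, cx : cx + ix]
        out = network.forward(window[None])[network.output_probs]
        windows.append(out.astype(np.float64))
    probs, valid = stitch_predictions(windows, corners, vol.shape, spec)
    return ClassProbs(probs, valid)


def ensemble_average(probs_list: list[ClassProbs]) -> ClassProbs:
    """Voxelwise arithmetic mean of member class distributions."""
    if not probs_list:
        raise ValueError("ensemble requires at least one member")
    shapes = {p.data.shape for p in probs_list}
    if len(shapes) != 1:
        raise ValueError("ensemble member shapes must match")
    mean = np.mean([p.data for p in probs_list], axis=0)
    valid = None
    valids = [p.valid for p in probs_list if p.valid is not None]
    if valids:
        valid = np.logical_and.reduce(valids)
    return ClassProbs(mean, valid)


def segmentation_from_probs(probs: ClassProbs) -> LabelVolume:
    """Voxelwise argmax (ties toward the lowest class index)."""
    return LabelVolume(np.argmax(probs.data, axis=0).astype(np.uint8))


def top_k(result, k: int) -> list:
    """Load the best-evaluation-MIoU checkpoints of the k top-ranked instances.

    ``result`` is an experiment record exposing ``ranked_instances()`` (see
    ``plateseg.training.ExperimentResult``).
    """
    ranked = result.ranked_instances()
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}]")
    return [rec.load_best_network() for rec in ranked[:k]]


def binarize_segmentation(seg: LabelVolume) -> LabelVolume:
    """Map all non-background classes to 1 (cell material vs background)."""
    return LabelVolume((seg.data != 0).astype(np.uint8))


def threshold_probability_map(prob: np.ndarray, t: float) -> LabelVolume:
    """Binary segmentation assigning class 1 where ``prob > t`` (strict)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    prob = np.asarray(prob)
    if prob.ndim != 3:
        raise ValueError("probability map must be rank 3")
    return LabelVolume((prob > t).astype(np.uint8))
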