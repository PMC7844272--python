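"""Training-window extraction and inference tiling/stitching.

Training windows are placed on a strided corner grid: per axis the corner
positions are {0, s, 2s, ...} up to the last position where the window still
fits (count per axis = floor((S - w)/s) + 1; no extra flush-end window).  With
the default spec -- a (50, 800, 800) volume, (5, 300, 300) windows, spacing
(2, 100, 100) -- this yields 23 * 6 * 6 = 828 windows per epoch.

Networks consume an input-shaped window but predict only a centered
output-shaped region (default (5, 296, 296) from (5, 300, 300), i.e. a
2-voxel lateral margin per side).  Inference tiles a full volume with corners
strided by the output shape, shifting the final corner per axis flush to the
end so every interior voxel is covered; overlapping voxels receive the mean of
the contributing probability vectors.  The global crop margin of the volume is
never covered by any output window; stitching reports it in a validity mask so
metrics can exclude it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


@dataclass
class WindowSpec:
    """Input/output window geometry and training-grid spacing."""

    input_shape: tuple[int, int, int] = (5, 300, 300)
    output_shape: tuple[int, int, int] = (5, 296, 296)
    spacing: tuple[int, int, int] = (2, 100, 100)

    def __post_init__(self) -> None:
        for i, o, s in zip(self.input_shape, self.output_shape, self.spacing):
            if o > i:
                raise ValueError("output shape must not exceed input shape")
            if (i - o) % 2:
                raise ValueError("input-output margin must be even per axis")
            if s < 1:
                raise ValueError("spacing must be >= 1")

    @property
    def margins(self) -> tuple[int, int, int]:
        return tuple((i - o) // 2 for i, o in zip(self.input_shape, self.output_shape))


def corner_grid(
    volume_shape: tuple[int, int, int],
    window_shape: tuple[int, int, int],
    spacing: tuple[int, int, int],
) -> list[tuple[int, int, int]]:
    """Strided top-back-left window corners; no flush-end extra window."""
    axes = []
    for size, w, s in zip(volume_shape, window_shape, spacing):
        if w > size:
            raise ValueError(
                f"window {window_shape} does not fit in volume {volume_shape}"
            )
        axes.append(range(0, size - w + 1, s))
    return [tuple(c) for c in itertools.product(*axes)]


def crop_to_output(window: np.ndarray, output_shape: tuple[int, int, int]) -> np.ndarray:
    """Symmetric centered crop of the trailing three (spatial) axes."""
    spatial = window.shape[-3:]
    slices: list[slice] = [slice(None)] * (window.ndim - 3)
    for size, out in zip(spatial, output_shape):
        if out > size:
            raise ValueError("output shape exceeds window shape")
        if (size - out) % 2:
            raise ValueError(f"margin {size}-{out} is odd; centered crop undefined")
        m = (size - out) // 2
        slices.append(slice(m, m + out))
    return window[tuple(slices)]


def extract_epoch_windows(
    image: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    spec: WindowSpec,
    order_rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """One (input, label, weight) window triple per grid corner, shuffled.

    Label and weight windows are the centered output-shaped crops of the
    co-located input-shaped window.
    """
    if not (image.shape == labels.shape == weights.shape):
        raise ValueError("image/labels/weights shapes must match")
    corners = corner_grid(image.shape, spec.input_shape, spec.spacing)
    if order_rng is not None:
        order = order_rng.permutation(len(corners))
        corners = [corners[i] for i in order]
    out = []
    for cz, cy, cx in corners:
        sl = (
            slice(cz, cz + spec.input_shape[0]),
            slice(cy, cy + spec.input_shape[1]),
            slice(cx, cx + spec.input_shape[2]),
        )
        out.append(
            (
                image[sl],
                crop_to_output(labels[sl], spec.output_shape),
                crop_to_output(weights[sl], spec.output_shape),
            )
        )
    return out


def tile_for_inference(
    volume_shape: tuple[int, int, int], spec: WindowSpec
) -> list[tuple[int, int, int]]:
    """Input-window corners covering a full volume for prediction.

    Corners stride by the output shape; the last corner per axis is shifted
    flush to the end so the union of output windows covers every voxel of the
    crop interior (the volume minus the global margins).
    """
    axes = []
    for size, w, o in zip(volume_shape, spec.input_shape, spec.output_shape):
        if w > size:
            raise ValueError(f"volume {volume_shape} smaller than window {spec.input_shape}")
        positions = list(range(0, size - w + 1, o))
        if positions[-1] != size - w:
            positions.append(size - w)
        axes.append(positions)
    return [tuple(c) for c in itertools.product(*axes)]


def stitch_predictions(
    per_window_probs: list[np.ndarray],
    corners: list[tuple[int, int, int]],
    volume_shape: tuple[int, int, int],
    spec: WindowSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-window class probabilities into a full-volume array.

    Parameters
    ----------
    per_window_probs
        Rank-4 ``(n_classes, *output_shape)`` arrays, one per corner.
    corners
        Input-window corners (as from :func:`tile_for_inference`).

    Returns
    -------
    probs, valid
        ``probs`` is ``(n_classes, z, y, x)``; voxels covered by no output
        window (the global crop margin) hold uniform distributions and are
        flagged False in the boolean ``valid`` mask.
    """
    if len(per_window_probs) != len(corners):
        raise ValueError("one probability window required per corner")
    n_classes = per_window_probs[0].shape[0]
    mz, my, mx = spec.margins
    acc = np.zeros((n_classes,) + tuple(volume_shape), dtype=np.float64)
    count = np.zeros(volume_shape, dtype=np.int64)
    for probs, (cz, cy, cx) in zip(per_window_probs, corners):
        if probs.shape != (n_classes,) + tuple(spec.output_shape):
            raise ValueError("window probability shape does not match spec")
        sl = (
            slice(cz + mz, cz + mz + spec.output_shape[0]),
            slice(cy + my, cy + my + spec.output_shape[1]),
            slice(cx + mx, cx + mx + spec.output_shape[2]),
        )
        acc[(slice(None),) + sl] += probs
        count[sl] += 1
    valid = count > 0
    interior = np.zeros(volume_shape, dtype=bool)
    interior[
        mz : volume_shape[0] - mz or None,
        my : volume_shape[1] - my or None,
        mx : volume_shape[2] - mx or None,
    ] = True
    if np.any(interior & ~valid):
        raise ValueError("a voxel inside the valid region was covered by no window")
    acc[:, valid] /= count[valid]
    acc[:, ~valid] = 1.0 / n_classes
    return acc, valid
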