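"""Synthetic platelet-like phantom volumes for download-free testing.

The phantom emulates the statistical and geometric structure of anisotropic
SBF-SEM platelet data under the 7-class schema: ellipsoidal cells (class 1)
on background (class 0), containing nested organelles placed strictly inside
the cell body -- elongated mitochondria (2), thin tortuous canalicular
channels (3), round alpha granules (4) and small dense granules (5) each with
a concentric dense-granule core (6).  Geometry is anisotropy-aware: axial (z)
extents are ~5x smaller in voxels than lateral extents, matching 50 nm axial
vs 10 nm lateral sampling.  The grayscale image assigns a per-class intensity
mean, adds Gaussian noise, applies an anisotropic blur (stronger along z, the
block-face cutting axis), and is z-scored.

The defaults aim for class frequencies close enough (within roughly an order
of magnitude, except for the unavoidable background/core extremes) that the
inverse-frequency class balancing of the loss is meaningfully exercised.
Annotator-style disagreement is emulated by :func:`perturb_labels`, which
erodes/dilates and flips small regions with strength scaled by ``severity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume, LabelVolume

DEFAULT_DENSITIES = {2: 0.08, 3: 0.05, 4: 0.07, 5: 0.05, 6: 0.02}
DEFAULT_INTENSITIES = {0: 0.90, 1: 0.55, 2: 0.32, 3: 0.75, 4: 0.42, 5: 0.18, 6: 0.04}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 128, 128)
    n_cells: int = 3
    organelle_density: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    intensity_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_std: float = 0.08
    z_blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < m for s, m in zip(self.shape, (8, 32, 32))):
            raise ValueError("phantom shape must be at least (8, 32, 32)")
        if any(d < 0 for d in self.organelle_density.values()):
            raise ValueError("organelle densities must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Boolean mask of an axis-z ellipsoid, optionally rotated in the lateral plane."""
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dz = (z - center[0]) / radii[0]
    yy = y - center[1]
    xx = x - center[2]
    u = (np.cos(angle) * yy + np.sin(angle) * xx) / radii[1]
    v = (-np.sin(angle) * yy + np.cos(angle) * xx) / radii[2]
    return dz**2 + u**2 + v**2 <= 1.0


def _place_cells(
    labels: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, tuple[float, float, float]]]:
    """Place non-overlapping ellipsoidal cells; returns (mask, radii) per cell."""
    sz, sy, sx = labels.shape
    cells: list[tuple[np.ndarray, tuple[float, float, float]]] = []
    for _ in range(config.n_cells):
        placed = False
        for attempt in range(40):
            shrink = 1.0 - 0.08 * attempt
            rz = max(4.0, rng.uniform(0.30, 0.42) * sz * shrink)
            ry = max(12.0, rng.uniform(0.24, 0.36) * sy * shrink)
            rx = max(12.0, rng.uniform(0.24, 0.36) * sx * shrink)
            cz = rng.uniform(rz, sz - rz)
            cy = rng.uniform(ry, sy - ry)
            cx = rng.uniform(rx, sx - rx)
            mask = _ellipsoid_mask(labels.shape, (cz, cy, cx), (rz, ry, rx))
            if not np.any(labels[mask] != 0):
                labels[mask] = 1
                cells.append((mask, (rz, ry, rx)))
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a non-overlapping cell; shrink n_cells")
    return cells


def _stamp_blobs(
    labels: np.ndarray,
    cell_mask: np.ndarray,
    cls: int,
    budget: int,
    radii_fn,
    rng: np.random.Generator,
    core_ratio: float | None = None,
    clip: bool = False,
) -> int:
    """Stamp ellipsoidal blobs of class ``cls`` onto class-1 voxels of one cell.

    By default a blob is only accepted where every voxel is currently cell
    body, keeping organelles strictly inside cells and mutually disjoint;
    with ``clip=True`` a blob may instead be clipped against existing content
    (accepted if at least half survives).  With ``core_ratio`` set, a
    concentric core (class 6) is nested inside each blob with at least a
    one-voxel shell in every direction.
    """
    cand = np.argwhere(cell_mask & (labels == 1))
    placed = 0
    attempts = 0
    max_attempts = 400
    while placed < budget and attempts < max_attempts and len(cand):
        attempts += 1
        center = cand[rng.integers(len(cand))].astype(float)
        radii = radii_fn()
        angle = rng.uniform(0, np.pi)
        mask = _ellipsoid_mask(labels.shape, tuple(center), radii, angle)
        if not mask.any():
            continue
        if clip:
            full = int(mask.sum())
            mask = mask & (labels == 1) & cell_mask
            if mask.sum() < 0.5 * full:
                continue
        elif np.any(labels[mask] != 1) or np.any(~cell_mask[mask]):
            continue
        labels[mask] = cls
        if core_ratio is not None:
            # erosion by the full 26-connected structure guarantees the core
            # dilates back inside the granule (a >= 1 voxel shell everywhere)
            struct = ndimage.generate_binary_structure(3, 3)
            iters = 1 + (core_ratio < 0.35)
            core = ndimage.binary_erosion(mask, struct, iterations=iters)
            if core.any():
                labels[core] = 6
        placed += int(mask.sum())
    return placed


def _stamp_tubes(
    labels: np.ndarray,
    cell_mask: np.ndarray,
    budget: int,
    rng: np.random.Generator,
) -> int:
    """Thin tortuous canalicular channels: lateral random walks with z drift."""
    sz, sy, sx = labels.shape
    cand = np.argwhere(cell_mask & (labels == 1))
    placed = 0
    attempts = 0
    while placed < budget and attempts < 60 and len(cand):
        attempts += 1
        pos = cand[rng.integers(len(cand))].astype(float)
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction) + 1e-9
        tube = np.zeros_like(labels, dtype=bool)
        for _ in range(rng.integers(20, 45)):
            direction += rng.normal(scale=0.45, size=2)
            direction /= np.linalg.norm(direction) + 1e-9
            pos[1:] += direction * 2.0
            pos[0] += rng.normal(scale=0.25)
            iz, iy, ix = (int(round(p)) for p in pos)
            if not (0 <= iz < sz and 0 <= iy < sy and 0 <= ix < sx):
                break
            r = int(rng.integers(1, 3))
            tube |= _ellipsoid_mask(labels.shape, (iz, iy, ix), (1.0, r, r))
        tube &= (labels == 1) & cell_mask  # clip to remaining cell interior
        labels[tube] = 3
        placed += int(tube.sum())
    return placed


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, LabelVolume]:
    """Generate a paired (image, labels) phantom volume; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    labels = np.zeros(config.shape, dtype=np.uint8)
    if config.n_cells > 0:
        cells = _place_cells(labels, config, rng)
        dens = config.organelle_density
        core_ratio = None
        if dens.get(5, 0) > 0:
            core_ratio = float(
                np.clip((dens.get(6, 0.0) / max(dens[5], 1e-9)) ** (1.0 / 3.0), 0.3, 0.7)
            )
        for mask, (crz, cry, crx) in cells:
            cell_vox = int(mask.sum())
            # keep a one-voxel cellular rim: organelles go strictly inside
            mask = ndimage.binary_erosion(
                mask, ndimage.generate_binary_structure(3, 1)
            )
            # organelle extents scale with (and are capped by) the host cell
            lat = min(cry, crx)

            def clamp(lo, hi, cap):
                hi = min(hi, cap)
                return rng.uniform(min(lo, hi), hi)

            requested = {
                c: int(dens.get(c, 0.0) * cell_vox) for c in (2, 3, 4, 5)
            }
            got = {}
            # dense granules go first: their nested cores need intact blobs
            got[5] = _stamp_blobs(
                labels,
                mask,
                5,
                requested[5],
                lambda: (
                    clamp(2.0, 3.0, 0.45 * crz),
                    clamp(4.5, 6.5, 0.3 * lat),
                    clamp(4.5, 6.5, 0.3 * lat),
                ),
                rng,
                core_ratio=core_ratio,
            )
            got[2] = _stamp_blobs(
                labels,
                mask,
                2,
                requested[2],
                lambda: (
                    clamp(1.2, 2.2, 0.4 * crz),
                    clamp(7.0, 12.0, 0.45 * lat),
                    clamp(2.5, 4.0, 0.25 * lat),
                ),
                rng,
                clip=True,
            )
            got[4] = _stamp_blobs(
                labels,
                mask,
                4,
                requested[4],
                lambda: (
                    clamp(1.2, 2.0, 0.4 * crz),
                    clamp(3.5, 6.0, 0.3 * lat),
                    clamp(3.5, 6.0, 0.3 * lat),
                ),
                rng,
                clip=True,
            )
            got[3] = _stamp_tubes(labels, mask, requested[3], rng)
            for c, want in requested.items():
                if want > 0 and got[c] < 0.4 * want:
                    raise RuntimeError(
                        f"organelle density for class {c} too high: placed "
                        f"{got[c]}/{want} voxels inside the cell"
                    )
    means = np.array(
        [config.intensity_means[c] for c in range(7)], dtype=np.float64
    )
    image = means[labels]
    image = image + rng.normal(0.0, config.noise_std, size=image.shape)
    sig = config.z_blur_sigma
    if sig > 0:
        image = ndimage.gaussian_filter(image, sigma=(sig, 0.4 * sig, 0.4 * sig))
    image = (image - image.mean()) / image.std()
    return ImageVolume(image.astype(np.float32)), LabelVolume(labels)


def perturb_labels(labels: LabelVolume, severity: float, seed: int) -> LabelVolume:
    """Emulate annotator disagreement by boundary and small-region edits.

    With strength scaled by ``severity`` in [0, 1]: random organelle regions
    are eroded or dilated (dilation only claims cell-body voxels), and small
    random blobs are flipped to another class drawn from the classes present
    (plus background/cell).  ``severity=0`` is the identity.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    out = labels.data.copy()
    if severity == 0:
        return LabelVolume(out)
    rng = np.random.default_rng(seed)
    structure = ndimage.generate_binary_structure(3, 1)
    for cls in (2, 3, 4, 5, 6):
        mask = out == cls
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=structure)
        for i in range(1, n + 1):
            if rng.random() > severity:
                continue
            region = comp == i
            iters = 1 + int(round(2 * severity * rng.random()))
            if rng.random() < 0.5:
                shrunk = ndimage.binary_erosion(region, structure, iterations=iters)
                out[region & ~shrunk] = 1 if cls != 6 else 5
            else:
                grown = ndimage.binary_dilation(region, structure, iterations=iters)
                out[grown & (out == 1)] = cls
    # small-region class flips
    sz, sy, sx = out.shape
    present = [int(c) for c in np.unique(labels.data)]
    targets = sorted(set(present) | {0, 1})
    n_blobs = int(severity * out.size / 2500)
    for _ in range(n_blobs):
        center = (
            rng.uniform(0, sz - 1),
            rng.uniform(0, sy - 1),
            rng.uniform(0, sx - 1),
        )
        radii = (rng.uniform(1, 2), rng.uniform(2, 4), rng.uniform(2, 4))
        blob = _ellipsoid_mask(out.shape, center, radii)
        out[blob] = rng.choice(targets)
    return LabelVolume(out)
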