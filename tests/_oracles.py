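"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is recomputed from first principles (explicit loops, set
arithmetic, dense direct summation) without calling the implementation under
test, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

TRUNCATE = 4.0


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = int(TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def direct_gaussian_blur(slice2d: np.ndarray, sigma: float) -> np.ndarray:
    """Dense direct-summation 2D convolution with a unit-sum Gaussian kernel.

    Symmetric (reflect-including-edge) boundary padding, kernel truncated at
    4 sigma -- evaluated tap by tap, O(n^2 k^2) work.
    """
    k1 = gaussian_kernel_1d(sigma)
    r = len(k1) // 2
    kernel = np.outer(k1, k1)
    h, w = slice2d.shape
    padded = np.pad(np.asarray(slice2d, dtype=np.float64), r, mode="symmetric")
    out = np.zeros((h, w), dtype=np.float64)
    for i in range(kernel.shape[0]):
        for j in range(kernel.shape[1]):
            out += kernel[i, j] * padded[i : i + h, j : j + w]
    return out


def oracle_edge_slice(
    labels_slice: np.ndarray,
    floor_w: float,
    alpha: float,
    c: float,
    sigma: float,
) -> np.ndarray:
    """Edge-preserving weight term for one slice, from the defining formulas."""
    lab = np.asarray(labels_slice)
    sets = {"bkgd": {0}, "cell": {1}, "org": {2, 3, 4, 5, 6}}
    total = np.zeros(lab.shape, dtype=np.float64)
    for src, tgt in (("bkgd", "cell"), ("cell", "bkgd"),
                     ("cell", "org"), ("org", "cell")):
        indicator = np.isin(lab, list(sets[src])).astype(np.float64)
        blurred = c * direct_gaussian_blur(indicator, sigma)
        masked = np.where(np.isin(lab, list(sets[tgt])), blurred, 0.0)
        total += masked
    m = total.max()
    if m <= alpha:
        return np.zeros_like(total)
    return np.maximum(total - alpha, 0.0) * (m / (m - alpha))


def oracle_weight_volume(
    labels: np.ndarray,
    floor_w: float = 0.01,
    alpha: float = 0.25,
    c: float = 0.882,
    sigma: float = 6.0,
) -> np.ndarray:
    """Full weight volume w + W_cb + W_ep via explicit per-voxel computation."""
    labels = np.asarray(labels)
    counts = {}
    for v in labels.ravel():
        counts[int(v)] = counts.get(int(v), 0) + 1
    nmin = min(counts.values())
    cb = {cls: nmin / n for cls, n in counts.items()}
    out = np.zeros(labels.shape, dtype=np.float64)
    for z in range(labels.shape[0]):
        ep = oracle_edge_slice(labels[z], floor_w, alpha, c, sigma)
        for y in range(labels.shape[1]):
            for x in range(labels.shape[2]):
                out[z, y, x] = floor_w + cb[int(labels[z, y, x])] + ep[y, x]
    return out


def oracle_total_loss(
    onehot: np.ndarray,
    xhat_3d: np.ndarray | None,
    xhat_2d: np.ndarray | None,
    weights: np.ndarray,
    c_2d: float,
    lambda_2d: float,
    lambda_3d: float,
    lambda_p: float,
    theta_2d: list[np.ndarray],
    theta_3d: list[np.ndarray],
    theta_2dp: list[np.ndarray],
    theta_3dp: list[np.ndarray],
    use_multi_loss: bool = True,
) -> float:
    """Naive per-voxel double-loop evaluation of the regularized weighted loss."""
    nz, ny, nx = weights.shape
    n = nz * ny * nx
    total = 0.0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                cls = int(np.argmax(onehot[:, z, y, x]))
                w = weights[z, y, x]
                if xhat_3d is not None:
                    total += w * -np.log(max(xhat_3d[cls, z, y, x], 1e-12)) / n
                if xhat_2d is not None and use_multi_loss:
                    total += (
                        c_2d * w * -np.log(max(xhat_2d[cls, z, y, x], 1e-12)) / n
                    )
    for lam, group in (
        (lambda_2d, theta_2d),
        (lambda_3d, theta_3d),
        (lambda_p, theta_2dp),
        (lambda_p, theta_3dp),
    ):
        for arr in group:
            total += lam * float((np.asarray(arr, dtype=np.float64) ** 2).sum())
    return total


def oracle_miou(
    truth: np.ndarray,
    pred: np.ndarray,
    classes,
    mask: np.ndarray | None = None,
) -> float:
    """Set-arithmetic MIoU: voxel coordinate sets, Python set ops."""
    coords = list(np.ndindex(truth.shape))
    if mask is not None:
        coords = [c for c in coords if mask[c]]
    vals = []
    for j in classes:
        a = {c for c in coords if truth[c] == j}
        b = {c for c in coords if pred[c] == j}
        union = a | b
        if not union:
            continue
        vals.append(len(a & b) / len(union))
    return float(np.mean(vals))


def oracle_corner_count(volume_shape, window_shape, spacing) -> int:
    """Brute-force enumeration of strided in-bounds window corners."""
    total = 1
    for size, w, s in zip(volume_shape, window_shape, spacing):
        count = 0
        pos = 0
        while pos + w <= size:
            count += 1
            pos += s
        total *= count
    return total
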