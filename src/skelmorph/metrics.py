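"""Evaluation metrics for skeletons and reconstructions.

Chamfer/Hausdorff distances between point sets (skeleton vs ground-truth
skeleton, reconstructed surface vs input surface), reconstructed volume from
the union of balls swept along skeleton links, and relative-error percentages
for volume, neuron length and branch count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "chamfer",
    "hausdorff",
    "normalize_for_metric",
    "reconstruct_samples",
    "reconstruct_volume",
    "vol_pct",
    "feature_pct",
    "MetricReport",
]


@dataclass
class MetricReport:
    cd_recon: float = np.nan
    hd_recon: float = np.nan
    cd_skel: float = np.nan
    hd_skel: float = np.nan
    vol_pct: float = np.nan
    len_pct: float = np.nan
    num_pct: float = np.nan

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _check_sets(x, y):
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("point sets must be non-empty")
    return x, y


def chamfer(x, y, mode: str = "sum") -> float:
    """Bidirectional nearest-neighbor distance between two point sets.

    ``mode="sum"`` adds all nearest-neighbor distances in both directions (the
    training-loss form); ``mode="mean"`` averages each direction so the value
    is comparable across clouds of different sizes.
    """
    x, y = _check_sets(x, y)
    d_xy = cKDTree(y).query(x)[0]
    d_yx = cKDTree(x).query(y)[0]
    if mode == "sum":
        return float(d_xy.sum() + d_yx.sum())
    if mode == "mean":
        return float(d_xy.mean() + d_yx.mean())
    raise ValueError(f"unknown mode {mode!r}")


def hausdorff(x, y) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    x, y = _check_sets(x, y)
    return float(max(directed_hausdorff(x, y)[0], directed_hausdorff(y, x)[0]))


def normalize_for_metric(points) -> np.ndarray:
    """Center a point set at the origin and scale into ``[-1, 1]^3``.

    Applied independently to each set being compared before the skeleton and
    reconstruction metrics, so shapes are compared at a canonical scale.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    centered = pts - pts.mean(axis=0)
    scale = np.abs(centered).max()
    if scale <= 0:
        raise ValueError("degenerate point set")
    return centered / scale


def _interpolated_spheres(mesh, spacing_factor: float = 0.5):
    """Node spheres plus spheres linearly interpolated along every link."""
    centers = np.asarray(mesh.spheres.centers, float)
    radii = np.asarray(mesh.spheres.radii, float)
    all_c = [centers]
    all_r = [radii]
    adj = np.asarray(mesh.adjacency)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    for i, j in zip(ii, jj):
        d = np.linalg.norm(centers[i] - centers[j])
        step = spacing_factor * max(min(radii[i], radii[j]), 1e-3)
        n_mid = int(d / step)
        if n_mid < 1:
            continue
        ts = np.linspace(0, 1, n_mid + 2)[1:-1]
        all_c.append(centers[i] + ts[:, None] * (centers[j] - centers[i]))
        all_r.append(radii[i] + ts * (radii[j] - radii[i]))
    return np.vstack(all_c), np.concatenate(all_r)


def reconstruct_samples(mesh, k: int = 64, seed: int = 0) -> np.ndarray:
    """Sample the surface of the shape implied by a skeleton mesh.

    The shape is the union of the skeleton spheres and of spheres linearly
    interpolated (center and radius) along every link; ``k`` points are drawn
    uniformly on each sphere and samples strictly interior to the union are
    rejected.
    """
    centers, radii = _interpolated_spheres(mesh)
    rng = np.random.default_rng(seed)
    S = len(centers)
    dirs = rng.normal(size=(S, k, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    pts = (centers[:, None, :] + dirs * radii[:, None, None]).reshape(-1, 3)
    # reject points strictly inside any *other* sphere of the union
    keep = np.ones(len(pts), dtype=bool)
    for chunk in np.array_split(np.arange(len(pts)), max(1, len(pts) // 20000)):
        d = np.linalg.norm(pts[chunk, None, :] - centers[None, :, :], axis=2)
        keep[chunk] = ~np.any(d < radii[None, :] - 1e-9, axis=1)
    out = pts[keep]
    if len(out) == 0:  # fully nested spheres: fall back to the largest sphere
        imax = int(np.argmax(radii))
        out = pts[imax * k:(imax + 1) * k]
    return out


def reconstruct_volume(mesh, resolution: int = 128) -> float:
    """Volume of the union of balls along the skeleton mesh, by voxelization."""
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    centers, radii = _interpolated_spheres(mesh)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    pad = (hi - lo).max() / resolution
    lo, hi = lo - pad, hi + pad
    axes = [np.linspace(lo[i], hi[i], resolution) for i in range(3)]
    cell = np.prod([(hi[i] - lo[i]) / (resolution - 1) for i in range(3)])
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    count = 0
    for chunk in np.array_split(grid, max(1, len(grid) // 50000)):
        d2 = ((chunk[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        count += int(np.any(d2 < radii[None, :] ** 2, axis=1).sum())
    return float(count * cell)


def vol_pct(v_recon: float, v_g: float) -> float:
    """Relative volume error, in percent: ``100 |v_recon - v_g| / v_g``."""
    if v_g <= 0:
        raise ValueError("ground-truth volume must be positive")
    return 100.0 * abs(v_recon - v_g) / v_g


def feature_pct(computed: float, truth: float) -> float:
    """Relative absolute error in percent (used for len-pct and num-pct).

    A zero ground truth with a zero computed value is reported as 0; a zero
    ground truth with a nonzero computed value is undefined and raises.
    """
    if truth == 0:
        if computed == 0:
            return 0.0
        raise ValueError("relative error undefined: ground truth is 0 "
                         f"but computed value is {computed}")
    if truth < 0:
        raise ValueError("ground truth must be nonnegative")
    return 100.0 * abs(computed - truth) / truth
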