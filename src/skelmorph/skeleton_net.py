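"""Unsupervised skeleton-sphere prediction from surface point clouds.

A hierarchical set-abstraction encoder (farthest-point sampling, radius-ball
grouping, shared per-point MLP with max-pooling, features concatenated across
two grouping radii per level) produces sampled points ``P'`` with contextual
features ``F``. A per-point MLP with a per-column softmax yields convex
combination weights ``W``; skeleton centers are ``C = W^T P'`` and radii
``R = W^T D`` where ``D`` holds each surface point's distance to its closest
center. Training is unsupervised, minimizing

    lambda_s * L_s  +  lambda_p * L_p  +  lambda_r * L_r  +  lambda_n * L_n

where ``L_s`` is the Chamfer distance between samples on the predicted sphere
surfaces and ``P'``, ``L_p`` the point-to-sphere reconstruction error,
``L_r = -sum r`` a radius regularizer, and ``L_n`` the skeleton-to-surface
norm loss: spokes (skeleton point to closest surface point) should align with
the outward surface normal, which keeps skeleton points inside the shape even
when it is concave.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .nn import MLP, Adam, Parameter, Tensor, as_tensor
from .pointcloud import SurfacePointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonSpheres",
    "EncoderOutput",
    "TrainConfig",
    "SkeletonModel",
    "TrainResult",
    "farthest_point_sampling",
    "combine_centers",
    "closest_distances",
    "combine_radii",
    "sample_sphere_points",
    "loss_sampling",
    "loss_point2sphere",
    "loss_radius",
    "loss_norm",
    "train_skeleton",
]


@dataclass
class SkeletonSpheres:
    """N skeleton spheres: centers (N, 3) and nonnegative radii (N,)."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")
        if np.any(self.radii < -1e-9):
            raise ValueError("radii must be nonnegative")
        self.radii = np.maximum(self.radii, 0.0)

    def __len__(self):
        return len(self.centers)


@dataclass
class EncoderOutput:
    """Sampled points P' with their contextual features F."""

    sampled_points: np.ndarray      # (M', 3)
    features: Tensor                # (M', D), on the autodiff graph
    sample_indices: np.ndarray      # indices of P' in the input cloud


@dataclass
class TrainConfig:
    """Hyperparameters of the skeleton predictor.

    Loss weights keep the radius regularizer small relative to the two
    reconstruction losses so it cannot dominate; the number of spheres ``N``
    suits neuron-scale clouds by default and should be reduced to 4-16 for
    simple parametric fixtures.
    """

    n_spheres: int = 100
    m_prime: int = 64
    feature_dim: int = 128
    lambda_s: float = 0.3
    lambda_p: float = 0.6
    lambda_r: float = 0.4e-2
    lambda_n: float = 0.1
    sphere_samples: int = 8
    epochs: int = 300
    lr: float = 1e-3
    seed: int = 0
    level_sizes: Tuple[int, ...] = (128, 64)
    level_radii: Tuple[Tuple[float, float], ...] = ((0.2, 0.4), (0.4, 0.8))
    group_size: int = 16
    hidden: int = 32

    def __post_init__(self):
        if min(self.lambda_s, self.lambda_p, self.lambda_r, self.lambda_n) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.level_sizes[-1] != self.m_prime:
            self.level_sizes = tuple(self.level_sizes[:-1]) + (self.m_prime,)


# ---------------------------------------------------------------------------
# sampling and algebraic building blocks
# ---------------------------------------------------------------------------


def farthest_point_sampling(points: np.ndarray, m: int, seed: int = 0,
                            start_index: Optional[int] = None) -> np.ndarray:
    """Iterative farthest point sampling.

    The first index is drawn from ``seed`` (or given explicitly); each
    following index maximizes the minimum distance to the chosen set, ties
    broken by the smallest index.
    """
    points = np.asarray(points, float)
    M = len(points)
    if not 1 <= m <= M:
        raise ValueError(f"m={m} out of range for {M} points")
    first = (int(np.random.default_rng(seed).integers(M))
             if start_index is None else int(start_index))
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = first
    mind = np.linalg.norm(points - points[first], axis=1)
    for t in range(1, m):
        nxt = int(np.argmax(mind))
        chosen[t] = nxt
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    return chosen


def _pairwise_dist(P: Tensor, C: Tensor) -> Tensor:
    """Differentiable (M, N) Euclidean distance matrix."""
    P, C = as_tensor(P), as_tensor(C)
    p2 = (P * P).sum(axis=1, keepdims=True)            # (M, 1)
    c2 = (C * C).sum(axis=1, keepdims=True).T          # (1, N)
    d2 = p2 + c2 - 2.0 * (P @ C.T)
    return d2.clip_min(1e-12).sqrt()


def _maybe_scalar(value: Tensor, inputs) -> float | Tensor:
    """Return a float when no input was on the autodiff graph."""
    if any(isinstance(x, Tensor) and x.requires_grad for x in inputs):
        return value
    return value.item()


def combine_centers(W, P_prime):
    """Centers as a convex combination of sampled points: ``C = W^T P'``."""
    W, P = as_tensor(W), as_tensor(P_prime)
    if W.shape[0] != P.shape[0]:
        raise ValueError("W and P' row counts differ")
    out = W.T @ P
    return out if (W.requires_grad or P.requires_grad) else out.numpy()


def closest_distances(P_prime, C):
    """Per surface point, the distance to its closest skeleton center."""
    C = as_tensor(C)
    if C.shape[0] == 0:
        raise ValueError("empty center set")
    d = _pairwise_dist(as_tensor(P_prime), C).min(axis=1)
    return d if (as_tensor(P_prime).requires_grad or C.requires_grad) else d.numpy()


def combine_radii(W, d_vec):
    """Radii from the same weights: ``R = W^T D``."""
    W, d = as_tensor(W), as_tensor(d_vec)
    out = W.T @ d.reshape(-1, 1)
    out = out.reshape(-1)
    return out if (W.requires_grad or d.requires_grad) else out.numpy()


def sample_sphere_points(spheres, k: int, seed: int = 0,
                         centers_t: Optional[Tensor] = None,
                         radii_t: Optional[Tensor] = None):
    """``k`` uniform samples on the surface of each skeleton sphere.

    With ``centers_t``/``radii_t`` given, the samples stay differentiable with
    respect to centers and radii (the random directions are constants).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    centers = np.atleast_2d(np.asarray(spheres.centers, float))
    radii = np.atleast_1d(np.asarray(spheres.radii, float))
    if np.any(radii < 0):
        raise ValueError("negative radius")
    N = len(centers)
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(N * k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rep = np.repeat(np.arange(N), k)
    if centers_t is None:
        return centers[rep] + dirs * radii[rep][:, None]
    c = centers_t.gather_rows(rep)
    r = radii_t.gather_rows(rep).reshape(-1, 1)
    return c + Tensor(dirs) * r


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def loss_sampling(T, P_prime):
    """Sampling loss: bidirectional Chamfer sum between sphere-surface
    samples ``T`` and the sampled surface points ``P'``."""
    T, P = as_tensor(T), as_tensor(P_prime)
    if T.shape[0] == 0 or P.shape[0] == 0:
        raise ValueError("empty point set")
    d = _pairwise_dist(P, T)  # (M, |T|)
    out = d.min(axis=1).sum() + d.min(axis=0).sum()
    return _maybe_scalar(out, (T, P))


def _abs_t(x: Tensor) -> Tensor:
    return (x * x).clip_min(1e-18).sqrt()


def loss_point2sphere(P_prime, spheres, centers_t: Optional[Tensor] = None,
                      radii_t: Optional[Tensor] = None, signed: bool = False):
    """Point-to-sphere reconstruction loss: each surface point should sit on
    the surface of its closest sphere, and each sphere's closest surface
    point should lie at its radius.

    The default penalizes the absolute deviation ``|min dist - r|`` in both
    terms; ``signed=True`` uses the raw signed differences instead (which
    rewards radius overshoot and is kept only for comparison).
    """
    P = as_tensor(P_prime)
    C = centers_t if centers_t is not None else as_tensor(spheres.centers)
    R = radii_t if radii_t is not None else as_tensor(spheres.radii)
    if C.shape[0] == 0:
        raise ValueError("empty center set")
    d = _pairwise_dist(P, C)                       # (M, N)
    idx_c_of_p = np.argmin(d.numpy(), axis=1)
    dev1 = d.min(axis=1) - R.gather_rows(idx_c_of_p)
    dev2 = d.min(axis=0) - R
    if not signed:
        dev1, dev2 = _abs_t(dev1), _abs_t(dev2)
    out = dev1.sum() + dev2.sum()
    return _maybe_scalar(out, (P, C, R))


def loss_radius(spheres, radii_t: Optional[Tensor] = None):
    """Radius regularizer: ``-sum r`` (encourages large, stable radii)."""
    R = radii_t if radii_t is not None else as_tensor(spheres.radii)
    return _maybe_scalar(-R.sum(), (R,))


def loss_norm(P_prime, normals, spheres, centers_t: Optional[Tensor] = None):
    """Skeleton-to-surface norm loss.

    Every spoke (from a skeleton point to its closest surface point, and from
    each surface point back to its closest skeleton point) should align with
    the outward surface normal at that surface point; each misalignment term
    is ``1 - n . spoke/|spoke|`` in [0, 2]. Zero-length spokes are skipped.
    """
    if normals is None:
        raise ValueError("normals are required for the norm loss")
    P = as_tensor(P_prime)
    C = centers_t if centers_t is not None else as_tensor(spheres.centers)
    normals = np.asarray(normals, float)
    d = _pairwise_dist(P, C)                       # (M, N)
    dnp = d.numpy()

    # spokes from each skeleton point to its closest surface point
    idx_p_of_c = np.argmin(dnp, axis=0)            # (N,)
    p_sel = Tensor(P.numpy()[idx_p_of_c])
    spoke_c = p_sel - C                            # (N, 3)
    len_c = (spoke_c * spoke_c).sum(axis=1).clip_min(1e-18).sqrt()
    mask_c = (dnp[idx_p_of_c, np.arange(dnp.shape[1])] > 1e-9).astype(float)
    n_skipped = int(len(mask_c) - mask_c.sum())
    dot_c = (spoke_c * Tensor(normals[idx_p_of_c])).sum(axis=1) / len_c
    term_c = ((1.0 - dot_c) * Tensor(mask_c)).sum()

    # spokes from each surface point to its closest skeleton point
    idx_c_of_p = np.argmin(dnp, axis=1)            # (M,)
    c_sel = C.gather_rows(idx_c_of_p)
    spoke_p = P - c_sel
    len_p = (spoke_p * spoke_p).sum(axis=1).clip_min(1e-18).sqrt()
    mask_p = (dnp[np.arange(dnp.shape[0]), idx_c_of_p] > 1e-9).astype(float)
    n_skipped += int(len(mask_p) - mask_p.sum())
    dot_p = (spoke_p * Tensor(normals)).sum(axis=1) / len_p
    term_p = ((1.0 - dot_p) * Tensor(mask_p)).sum()
    if n_skipped:
        logger.debug("loss_norm: skipped %d zero-length spokes", n_skipped)
    out = term_c + term_p
    return _maybe_scalar(out, (P, C))


# ---------------------------------------------------------------------------
# encoder and model
# ---------------------------------------------------------------------------


class _SetAbstraction:
    """One set-abstraction level: FPS -> radius grouping -> PointNet -> pool,
    run at two grouping radii whose features are concatenated."""

    def __init__(self, rng, n_out, radii, k, f_in, hidden, f_out):
        self.n_out, self.radii, self.k = n_out, radii, k
        self.mlps = [MLP(rng, [f_in + 3, hidden, f_out // len(radii)],
                         final_relu=True) for _ in radii]

    def group_indices(self, pts, centroids, rng):
        """(n_out, k) neighbor indices per grouping radius; within-radius
        points are kept (subsampled deterministically when over k, padded by
        the nearest neighbor when under)."""
        tree = cKDTree(pts)
        out = []
        for rad in self.radii:
            lists = tree.query_ball_point(centroids, rad)
            nearest = tree.query(centroids, k=1)[1]
            idx = np.empty((len(centroids), self.k), dtype=np.int64)
            for i, lst in enumerate(lists):
                if len(lst) == 0:
                    lst = [int(nearest[i])]
                lst = np.asarray(lst)
                if len(lst) >= self.k:
                    sel = rng.choice(len(lst), size=self.k, replace=False)
                    idx[i] = lst[sel]
                else:
                    pad = np.full(self.k - len(lst), lst[0])
                    idx[i] = np.concatenate([lst, pad])
            out.append(idx)
        return out

    def __call__(self, pts, feats, group_idx, cent_idx):
        cents = pts[cent_idx]
        outs = []
        for mlp, idx in zip(self.mlps, group_idx):
            rel = pts[idx] - cents[:, None, :]               # (n, k, 3)
            rel_flat = Tensor(rel.reshape(-1, 3))
            f_nb = feats.gather_rows(idx.ravel())            # (n*k, f_in)
            h = mlp(Tensor.concat([rel_flat, f_nb], axis=1))
            h = h.reshape(len(cents), self.k, -1).max(axis=1)
            outs.append(h)
        return cents, Tensor.concat(outs, axis=1)

    def parameters(self):
        return [p for m in self.mlps for p in m.parameters()]


class SkeletonModel:
    """Encoder + weight-MLP predicting skeleton spheres from a cloud."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = 3  # initial per-point features: the coordinates themselves
        self.levels = []
        for n_out, radii in zip(config.level_sizes, config.level_radii):
            mid = (config.hidden if n_out != config.level_sizes[-1]
                   else config.feature_dim)
            self.levels.append(_SetAbstraction(
                rng, n_out, radii, config.group_size, f, config.hidden, mid))
            f = mid
        self.weight_mlp = MLP(rng, [config.feature_dim, config.hidden,
                                    config.n_spheres])
        self._rng = rng
        self._cache: dict = {}

    def parameters(self):
        ps = [p for lvl in self.levels for p in lvl.parameters()]
        return ps + self.weight_mlp.parameters()

    def save(self, path: str) -> None:
        """Write all parameters to a single checkpoint file (npz)."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)

    def load(self, path: str) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.parameters()):
                arr = data[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint incompatible with config")
                p.data = arr

    def _plan(self, cloud: SurfacePointCloud):
        """Grouping/sampling indices depend only on coordinates: cached."""
        key = id(cloud)
        if key in self._cache:
            return self._cache[key]
        cfg = self.config
        plan = []
        pts = cloud.points
        rng = np.random.default_rng(cfg.seed + 1)
        for lvl in self.levels:
            if lvl.n_out > len(pts):
                raise ValueError("cloud smaller than encoder level size")
            cent_idx = farthest_point_sampling(pts, lvl.n_out, seed=cfg.seed)
            gidx = lvl.group_indices(pts, pts[cent_idx], rng)
            plan.append((cent_idx, gidx))
            pts = pts[cent_idx]
        self._cache[key] = plan
        return plan

    def encode(self, cloud: SurfacePointCloud) -> EncoderOutput:
        plan = self._plan(cloud)
        pts = cloud.points
        feats = Tensor(pts)
        global_idx = np.arange(len(pts))
        for lvl, (cent_idx, gidx) in zip(self.levels, plan):
            pts, feats = lvl(pts, feats, gidx, cent_idx)
            global_idx = global_idx[cent_idx]
        return EncoderOutput(pts, feats, global_idx)


def predict_weights(enc: EncoderOutput, model: SkeletonModel) -> Tensor:
    """Convex-combination weights: MLP logits, softmax over the M' axis so
    every column is a distribution over sampled surface points."""
    logits = model.weight_mlp(enc.features)        # (M', N)
    return logits.softmax(axis=0)


def _forward(model: SkeletonModel, cloud: SurfacePointCloud, epoch: int):
    enc = model.encode(cloud)
    W = predict_weights(enc, model)
    P = Tensor(enc.sampled_points)
    C = W.T @ P                                    # (N, 3)
    d_vec = _pairwise_dist(P, C).min(axis=1)
    R = (W.T @ d_vec.reshape(-1, 1)).reshape(-1)
    return enc, W, C, R


def _loss(model, cloud, enc, W, C, R, epoch):
    cfg = model.config
    P = enc.sampled_points
    spheres = SkeletonSpheres(C.numpy(), np.maximum(R.numpy(), 0.0))
    T = sample_sphere_points(spheres, cfg.sphere_samples,
                             seed=cfg.seed * 100003 + epoch,
                             centers_t=C, radii_t=R)
    total = cfg.lambda_s * loss_sampling(T, Tensor(P))
    total = total + cfg.lambda_p * loss_point2sphere(
        Tensor(P), spheres, centers_t=C, radii_t=R)
    total = total + cfg.lambda_r * loss_radius(spheres, radii_t=R)
    if cfg.lambda_n > 0:
        normals = (cloud.normals[enc.sample_indices]
                   if cloud.normals is not None else None)
        total = total + cfg.lambda_n * loss_norm(
            Tensor(P), normals, spheres, centers_t=C)
    return total


@dataclass
class TrainResult:
    model: SkeletonModel
    spheres: List[SkeletonSpheres]
    initial_spheres: List[SkeletonSpheres]
    loss_history: List[float] = field(default_factory=list)
    weights: List[np.ndarray] = field(default_factory=list)
    encoder_outputs: List[EncoderOutput] = field(default_factory=list)


def predict_spheres(model: SkeletonModel, cloud: SurfacePointCloud
                    ) -> Tuple[SkeletonSpheres, np.ndarray, EncoderOutput]:
    """Predict skeleton spheres (and weights/features) for one cloud."""
    enc, W, C, R = _forward(model, cloud, epoch=0)
    return (SkeletonSpheres(C.numpy(), np.maximum(R.numpy(), 0.0)),
            W.numpy(), enc)


def train_skeleton(clouds: Sequence[SurfacePointCloud], config: TrainConfig
                   ) -> TrainResult:
    """Train the skeleton predictor on one or more clouds (unsupervised).

    Each cloud is one batch; optimization is Adam on the weighted loss sum.
    Raises on divergence (non-finite loss).
    """
    model = SkeletonModel(config)
    initial = [predict_spheres(model, c)[0] for c in clouds]
    opt = Adam(model.parameters(), lr=config.lr)
    history = []
    for epoch in range(config.epochs):
        total = 0.0
        for cloud in clouds:
            enc, W, C, R = _forward(model, cloud, epoch)
            loss = _loss(model, cloud, enc, W, C, R, epoch)
            if not np.isfinite(loss.numpy()):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.numpy()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        history.append(total / len(clouds))
    spheres, weights, encs = [], [], []
    for cloud in clouds:
        s, w, e = predict_spheres(model, cloud)
        spheres.append(s)
        weights.append(w)
        encs.append(e)
    return TrainResult(model, spheres, initial, history, weights, encs)
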