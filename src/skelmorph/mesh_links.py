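"""Link prediction: connect skeleton spheres into a skeleton mesh.

Two simple priors seed an initial adjacency: mutual/nearest-neighbor centers
are linked, and so are overlapping spheres (center distance below the radius
sum). A graph auto-encoder (graph-convolution encoder over the prior
adjacency, symmetric inner-product decoder with logistic squashing) is then
trained against the prior links with a masked balanced cross-entropy, and the
estimated edge probabilities are thresholded into the final mesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import Adam, Parameter, Tensor, glorot
from .skeleton_net import SkeletonSpheres

__all__ = [
    "SkeletonMesh",
    "GAEConfig",
    "init_adjacency",
    "link_features",
    "mbce_loss",
    "train_gae",
    "threshold_links",
    "predict_links",
]


@dataclass
class SkeletonMesh:
    """Skeleton spheres plus a symmetric binary adjacency (no self-loops)."""

    spheres: SkeletonSpheres
    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.shape != (len(self.spheres), len(self.spheres)):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(A, 0)
        self.adjacency = A.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class GAEConfig:
    hidden: int = 32
    latent: int = 16
    epochs: int = 400
    lr: float = 1e-2
    seed: int = 0
    neg_ratio: float = 4.0


def init_adjacency(spheres: SkeletonSpheres) -> np.ndarray:
    """Prior adjacency: nearest-center links plus overlapping-sphere links."""
    N = len(spheres)
    if N < 2:
        raise ValueError("need at least two spheres")
    C, R = spheres.centers, spheres.radii
    d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    A = np.zeros((N, N), dtype=np.int8)
    nearest = np.argmin(d, axis=1)
    A[np.arange(N), nearest] = 1          # prior 1: nearest neighbor (either way)
    A |= A.T
    overlap = d < (R[:, None] + R[None, :])   # prior 2: spheres overlap
    A |= overlap.astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def link_features(spheres: SkeletonSpheres, W: np.ndarray,
                  F: np.ndarray) -> np.ndarray:
    """Per-sphere features: concatenation of center, radius and ``W^T F``."""
    WtF = np.asarray(W).T @ np.asarray(F)
    return np.hstack([spheres.centers, spheres.radii[:, None], WtF])


def mbce_loss(A_hat, A_target, mask):
    """Masked balanced cross-entropy over edge probabilities.

    Within the mask, the positive class is reweighted by the negatives-to-
    positives count ratio; the result is the weighted mean of the per-entry
    cross-entropies.
    """
    A_hat = A_hat if isinstance(A_hat, Tensor) else Tensor(A_hat)
    t = np.asarray(A_target, float)
    m = np.asarray(mask, float)
    if A_hat.shape != t.shape or t.shape != m.shape:
        raise ValueError("shape mismatch")
    n_pos = float((m * t).sum())
    n_neg = float((m * (1 - t)).sum())
    if n_pos + n_neg == 0:
        raise ValueError("mask selects no entries")
    w_pos = (n_neg / n_pos) if (n_pos > 0 and n_neg > 0) else 1.0
    weights = m * (w_pos * t + (1 - t))
    eps = 1e-12
    ce = (-Tensor(t) * A_hat.clip_min(eps).log()
          - Tensor(1 - t) * (1.0 - A_hat).clip_min(eps).log())
    out = (Tensor(weights) * ce).sum() / weights.sum()
    return out if A_hat.requires_grad else out.item()


def _norm_adj(A: np.ndarray) -> np.ndarray:
    """Symmetric degree-normalized adjacency with self-loops."""
    At = A.astype(float) + np.eye(len(A))
    dinv = 1.0 / np.sqrt(At.sum(axis=1))
    return At * dinv[:, None] * dinv[None, :]


class _GAE:
    def __init__(self, rng, d_in, cfg: GAEConfig):
        self.W1 = Parameter(glorot(rng, d_in, cfg.hidden))
        self.W2 = Parameter(glorot(rng, cfg.hidden, cfg.latent))

    def __call__(self, X: Tensor, A_norm: np.ndarray) -> Tensor:
        An = Tensor(A_norm)
        H = (An @ (X @ self.W1)).relu()
        Z = An @ (H @ self.W2)
        return (Z @ Z.T).sigmoid()   # symmetric by construction

    def parameters(self):
        return [self.W1, self.W2]


def train_gae(features: np.ndarray, A_ini: np.ndarray,
              config: Optional[GAEConfig] = None) -> np.ndarray:
    """Train the link-prediction GAE against the prior adjacency.

    The training mask holds every prior-positive pair plus an equal-count
    random sample of non-edges, redrawn each epoch, so supervision stays
    balanced without declaring all unknown pairs negative. Returns the
    estimated symmetric edge-probability matrix.
    """
    cfg = config or GAEConfig()
    A_ini = np.asarray(A_ini)
    N = len(A_ini)
    rng = np.random.default_rng(cfg.seed)
    X = Tensor(_standardize(features))
    A_norm = _norm_adj(A_ini)
    gae = _GAE(rng, X.shape[1], cfg)
    opt = Adam(gae.parameters(), lr=cfg.lr)
    iu = np.triu_indices(N, k=1)
    pos = A_ini[iu] > 0
    n_pos = int(pos.sum())
    for epoch in range(cfg.epochs):
        mask = np.zeros((N, N))
        mask[iu[0][pos], iu[1][pos]] = 1
        neg_pool = np.nonzero(~pos)[0]
        n_neg = min(len(neg_pool), max(1, int(cfg.neg_ratio * n_pos)))
        if n_neg > 0 and len(neg_pool) > 0:
            sel = rng.choice(neg_pool, size=n_neg, replace=False)
            mask[iu[0][sel], iu[1][sel]] = 1
        mask = mask + mask.T
        A_hat = gae(X, A_norm)
        loss = mbce_loss(A_hat, A_ini.astype(float), mask)
        if not np.isfinite(loss.numpy()):
            raise FloatingPointError(f"GAE diverged at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
    out = gae(X, A_norm).numpy()
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def _standardize(X) -> np.ndarray:
    X = np.asarray(X, float)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    return (X - X.mean(axis=0)) / std


def threshold_links(A_hat: np.ndarray, spheres: SkeletonSpheres,
                    tau: float = 0.5, connect: bool = True,
                    prune_collinear: bool = True) -> SkeletonMesh:
    """Binarize edge probabilities at ``tau``.

    Nodes left isolated are reattached to their nearest center, and (by
    default) remaining connected components are bridged through their closest
    center pair, so the skeleton mesh downstream graph analysis sees is a
    single connected structure.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    A_hat = np.asarray(A_hat, float)
    A = (np.maximum(A_hat, A_hat.T) >= tau).astype(np.int8)
    np.fill_diagonal(A, 0)
    N = len(A)
    d = np.linalg.norm(spheres.centers[:, None] - spheres.centers[None, :],
                       axis=2)
    np.fill_diagonal(d, np.inf)
    if prune_collinear:
        # Drop near-collinear skip links: an edge whose two endpoints are
        # already joined through an intermediate linked sphere lying on
        # (almost) the same line adds no structure -- its segment runs along
        # the mesh anyway -- but corrupts path-based length measurements.
        # Genuine triangles/cycles (intermediate node well off the line) are
        # kept.
        for i, j in sorted(zip(*np.nonzero(np.triu(A, 1))),
                           key=lambda e: -d[e[0], e[1]]):
            via = np.nonzero((A[i] > 0) & (A[j] > 0))[0]
            via = via[(via != i) & (via != j)]
            if len(via) and np.any(d[i, j] >= 0.95 * (d[i, via] + d[via, j])):
                A[i, j] = A[j, i] = 0
    for i in np.nonzero(A.sum(axis=1) == 0)[0]:
        if N > 1:
            j = int(np.argmin(d[i]))
            A[i, j] = A[j, i] = 1
    if connect and N > 1:
        import networkx as nx

        g = nx.from_numpy_array(A)
        comps = list(nx.connected_components(g))
        while len(comps) > 1:
            a = np.fromiter(comps[0], dtype=int)
            rest = np.fromiter(set(range(N)) - set(comps[0]), dtype=int)
            sub = d[np.ix_(a, rest)]
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            A[a[i], rest[j]] = A[rest[j], a[i]] = 1
            g.add_edge(int(a[i]), int(rest[j]))
            comps = list(nx.connected_components(g))
    return SkeletonMesh(spheres, A)


def predict_links(spheres: SkeletonSpheres, W: np.ndarray, F: np.ndarray,
                  config: Optional[GAEConfig] = None,
                  tau: float = 0.5) -> SkeletonMesh:
    """Full link-prediction stage: priors -> GAE -> thresholded mesh."""
    A_ini = init_adjacency(spheres)
    feats = link_features(spheres, W, F)
    A_hat = train_gae(feats, A_ini, config)
    return threshold_links(A_hat, spheres, tau)
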