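"""Parametric 3D shapes with analytic medial skeletons.

Five families cover the geometric regimes the pipeline must handle: a sphere
(degenerate point skeleton), a capsule (curve skeleton), an ellipsoid (true
surface skeleton, a medial disk), a Y-shaped tube (branched curve skeleton)
and a crescent (concave bent tube, the failure mode the surface-norm loss is
designed for). Each shape provides area-uniform surface sampling, analytic
normals, an implicit inside/outside function and a ground-truth skeleton with
total length, branch count and volume, so the whole pipeline is testable
without any external data.

A brute-force medial-axis oracle (`brute_force_mat`) independently recovers
skeleton points as interior grid points whose nearest surface samples come
from at least two sufficiently different directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import SurfacePointCloud, write_cloud

__all__ = [
    "ShapeSpec",
    "GroundTruth",
    "make_shape",
    "brute_force_mat",
    "make_labeled_dataset",
    "save_ground_truth",
    "DEFAULT_PARAMS",
    "FAMILIES",
]

FAMILIES = ("sphere", "capsule", "ellipsoid", "y_tube", "crescent")

DEFAULT_PARAMS: Dict[str, Dict[str, float]] = {
    "sphere": {"radius": 1.0},
    "capsule": {"length": 4.0, "radius": 0.5},
    "ellipsoid": {"a": 2.0, "b": 1.0, "c": 0.5},
    "y_tube": {"trunk": 3.0, "arm": 2.0, "angle": 0.9, "radius": 0.35},
    "crescent": {"bend_radius": 1.0, "tube_radius": 0.3, "arc": 4.0},
}


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one synthetic cloud; identical specs give identical output."""

    family: str
    params: Optional[Dict[str, float]] = None
    n_points: int = 1024
    noise_sigma: float = 0.0
    seed: int = 0

    def resolved_params(self) -> Dict[str, float]:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        p = dict(DEFAULT_PARAMS[self.family])
        if self.params:
            p.update(self.params)
        if any(v <= 0 for v in p.values()):
            raise ValueError(f"non-positive shape parameter in {p}")
        return p

    def validate(self):
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.resolved_params()


@dataclass
class GroundTruth:
    """Analytic medial structure of a synthetic shape."""

    skeleton_points: np.ndarray          # (K, 3)
    skeleton_radii: np.ndarray           # (K,)
    graph_edges: List[Tuple[int, int]]
    total_length: float
    n_branches: int
    volume: float

    def __post_init__(self):
        self.skeleton_points = np.atleast_2d(np.asarray(self.skeleton_points, float))
        self.skeleton_radii = np.atleast_1d(np.asarray(self.skeleton_radii, float))
        K = len(self.skeleton_points)
        for i, j in self.graph_edges:
            if not (0 <= i < K and 0 <= j < K):
                raise ValueError(f"edge ({i},{j}) references missing node")
        if self.total_length < 0 or self.n_branches < 0 or self.volume <= 0:
            raise ValueError("invalid ground-truth summary values")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points ``p`` (Q,3) to segment a-b."""
    ab = b - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def _chain_edges(n: int, offset: int = 0) -> List[Tuple[int, int]]:
    return [(offset + i, offset + i + 1) for i in range(n - 1)]


def _polyline(a, b, n) -> np.ndarray:
    return a[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (b - a)[None, :]


class _Shape:
    """Internal per-family geometry: sampling, normals, implicit, ground truth."""

    def __init__(self, params: Dict[str, float]):
        self.p = params

    def sample(self, n: int, rng: np.random.Generator):
        raise NotImplementedError

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """Signed value: negative strictly inside, positive outside."""
        raise NotImplementedError

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def ground_truth(self) -> GroundTruth:
        raise NotImplementedError


class _Sphere(_Shape):
    def sample(self, n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * self.p["radius"], v

    def implicit(self, pts):
        return np.linalg.norm(pts, axis=1) - self.p["radius"]

    def bounds(self):
        r = self.p["radius"] * 1.15
        return -np.full(3, r), np.full(3, r)

    def ground_truth(self):
        r = self.p["radius"]
        return GroundTruth(np.zeros((1, 3)), np.array([r]), [],
                           0.0, 0, 4.0 / 3.0 * math.pi * r**3)


class _Capsule(_Shape):
    """Cylinder of given axial length along x, hemispherical caps, radius r."""

    def _ends(self):
        L = self.p["length"]
        return np.array([-L / 2, 0, 0.0]), np.array([L / 2, 0, 0.0])

    def sample(self, n, rng):
        L, r = self.p["length"], self.p["radius"]
        area_side = 2 * math.pi * r * L
        area_caps = 4 * math.pi * r**2
        n_side = int(round(n * area_side / (area_side + area_caps)))
        x = rng.uniform(-L / 2, L / 2, n_side)
        phi = rng.uniform(0, 2 * math.pi, n_side)
        side = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])
        n_side_normals = np.column_stack(
            [np.zeros(n_side), np.cos(phi), np.sin(phi)])
        m = n - n_side
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        centers = np.where(v[:, [0]] >= 0, L / 2, -L / 2)
        caps = np.column_stack([centers[:, 0], np.zeros(m), np.zeros(m)]) + r * v
        pts = np.vstack([side, caps])
        normals = np.vstack([n_side_normals, v])
        return pts, normals

    def implicit(self, pts):
        a, b = self._ends()
        return _segment_distance(pts, a, b) - self.p["radius"]

    def bounds(self):
        L, r = self.p["length"], self.p["radius"]
        hi = np.array([L / 2 + r, r, r]) * 1.15
        return -hi, hi

    def ground_truth(self):
        L, r = self.p["length"], self.p["radius"]
        a, b = self._ends()
        n_nodes = 16
        pts = _polyline(a, b, n_nodes)
        vol = math.pi * r**2 * L + 4.0 / 3.0 * math.pi * r**3
        return GroundTruth(pts, np.full(n_nodes, r), _chain_edges(n_nodes),
                           L, 0, vol)


class _Ellipsoid(_Shape):
    """Ellipsoid with semi-axes a > b > c; medial skeleton is a planar disk."""

    def sample(self, n, rng):
        a, b, c = self.p["a"], self.p["b"], self.p["c"]
        pts = np.empty((0, 3))
        us = np.empty((0, 3))
        while len(pts) < n:
            m = max(4 * (n - len(pts)), 256)
            u = rng.normal(size=(m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            # area element of the map u -> (a ux, b uy, c uz)
            w = np.sqrt((b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2
                        + (a * b * u[:, 2]) ** 2)
            keep = rng.uniform(0, a * b, m) < w
            pts = np.vstack([pts, u[keep] * np.array([a, b, c])])
            us = np.vstack([us, u[keep]])
        pts, us = pts[:n], us[:n]
        normals = pts / np.array([a**2, b**2, c**2])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return pts, normals

    def implicit(self, pts):
        a, b, c = self.p["a"], self.p["b"], self.p["c"]
        return (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2 - 1.0

    def bounds(self):
        hi = np.array([self.p["a"], self.p["b"], self.p["c"]]) * 1.15
        return -hi, hi

    def _medial_ellipse(self):
        a, b, c = self.p["a"], self.p["b"], self.p["c"]
        return (a * a - c * c) / a, (b * b - c * c) / b

    def ground_truth(self):
        a, b, c = self.p["a"], self.p["b"], self.p["c"]
        alpha, beta = self._medial_ellipse()
        # sample the medial disk on concentric rings; radii measured against a
        # dense surface sampling (the medial radius has no simple closed form)
        pts = [np.zeros(3)]
        for frac in (0.45, 0.9):
            for t in np.linspace(0, 2 * math.pi, 12, endpoint=False):
                pts.append([frac * alpha * math.cos(t), frac * beta * math.sin(t), 0.0])
        pts = np.asarray(pts)
        rng = np.random.default_rng(0)
        surf, _ = self.sample(20000, rng)
        radii = cKDTree(surf).query(pts)[0]
        edges = [(0, i) for i in range(1, 13)]
        edges += [(i, i + 12) for i in range(1, 13)]
        vol = 4.0 / 3.0 * math.pi * a * b * c
        return GroundTruth(pts, radii, edges, 2 * alpha, 0, vol)


class _YTube(_Shape):
    """Rounded tube tree: trunk along +x, two arms splitting at the junction."""

    def _segments(self):
        p = self.p
        A = np.zeros(3)
        J = np.array([p["trunk"], 0.0, 0.0])
        d1 = np.array([math.cos(p["angle"]), math.sin(p["angle"]), 0.0])
        d2 = np.array([math.cos(p["angle"]), -math.sin(p["angle"]), 0.0])
        return [(A, J), (J, J + p["arm"] * d1), (J, J + p["arm"] * d2)]

    def _dist_to_skeleton(self, pts):
        return np.min([_segment_distance(pts, a, b) for a, b in self._segments()],
                      axis=0)

    def sample(self, n, rng):
        r = self.p["radius"]
        segs = self._segments()
        lengths = np.array([np.linalg.norm(b - a) for a, b in segs])
        pts_out, nrm_out = [], []
        need = n
        while need > 0:
            m = max(2 * need, 256)
            # pick a segment by lateral area, then a point on its tube;
            # free endpoints carry hemispherical caps
            cap = 0.5 * (4 * math.pi * r**2) / (2 * math.pi * r)  # = r, as length
            wl = lengths + np.array([cap, cap, cap])  # caps at A and both tips
            seg_idx = rng.choice(3, size=m, p=wl / wl.sum())
            cand = np.empty((m, 3))
            for k, (a, b) in enumerate(segs):
                sel = seg_idx == k
                mk = int(sel.sum())
                if mk == 0:
                    continue
                axis = (b - a) / lengths[k]
                t = rng.uniform(-cap, lengths[k] + cap, mk)
                # orthonormal frame around the axis
                ref = np.array([0.0, 0.0, 1.0])
                e1 = np.cross(axis, ref)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(axis, e1)
                phi = rng.uniform(0, 2 * math.pi, mk)
                ring = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
                tc = np.clip(t, 0, lengths[k])
                core = a + np.outer(tc, axis)
                over = t - tc  # signed axial overshoot into a cap
                ax_part = np.outer(over, axis)
                rad = np.sqrt(np.maximum(r**2 - over**2, 0.0))
                cand[sel] = core + ax_part + ring * rad[:, None]
            d = self._dist_to_skeleton(cand)
            keep = d > r - 1e-9  # on the union surface, not inside another tube
            # the junction at J is interior to all tubes' caps -> no cap at J:
            # reject cap samples that fall inside the union handles this
            cand = cand[keep][:need]
            pts_out.append(cand)
            need -= len(cand)
        pts = np.vstack(pts_out)[:n]
        normals = self._normals(pts)
        return pts, normals

    def _normals(self, pts):
        dists = np.stack([_segment_distance(pts, a, b) for a, b in self._segments()])
        nearest = np.argmin(dists, axis=0)
        out = np.empty_like(pts)
        for k, (a, b) in enumerate(self._segments()):
            sel = nearest == k
            ab = b - a
            t = np.clip((pts[sel] - a) @ ab / (ab @ ab), 0, 1)
            proj = a + t[:, None] * ab
            v = pts[sel] - proj
            out[sel] = v / np.linalg.norm(v, axis=1, keepdims=True)
        return out

    def implicit(self, pts):
        return self._dist_to_skeleton(pts) - self.p["radius"]

    def bounds(self):
        p = self.p
        xmax = p["trunk"] + p["arm"] * math.cos(p["angle"]) + p["radius"]
        ymax = p["arm"] * math.sin(p["angle"]) + p["radius"]
        lo = np.array([-p["radius"], -ymax, -p["radius"]]) * 1.15
        hi = np.array([xmax, ymax, p["radius"]]) * 1.15
        return lo, hi

    def ground_truth(self):
        p = self.p
        segs = self._segments()
        n_trunk, n_arm = 10, 7
        trunk = _polyline(*segs[0], n_trunk)
        arm1 = _polyline(*segs[1], n_arm)[1:]  # junction node shared
        arm2 = _polyline(*segs[2], n_arm)[1:]
        pts = np.vstack([trunk, arm1, arm2])
        edges = _chain_edges(n_trunk)
        j = n_trunk - 1
        edges += [(j, n_trunk)] + _chain_edges(n_arm - 1, n_trunk)
        a2 = n_trunk + n_arm - 1
        edges += [(j, a2)] + _chain_edges(n_arm - 1, a2)
        vol = self._voxel_volume()
        return GroundTruth(pts, np.full(len(pts), p["radius"]), edges,
                           p["trunk"] + p["arm"], 1, vol)

    def _voxel_volume(self, res: int = 128) -> float:
        lo, hi = self.bounds()
        axes = [np.linspace(lo[i], hi[i], res) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = self.implicit(grid) < 0
        cell = np.prod((hi - lo) / (res - 1))
        return float(inside.sum() * cell)


class _Crescent(_Shape):
    """Concave bent tube: circular-arc centerline with hemispherical caps."""

    def _arc_params(self):
        return self.p["bend_radius"], self.p["tube_radius"], self.p["arc"]

    def _nearest_arc(self, pts):
        R, _, arc = self._arc_params()
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        ang = np.clip(ang, -arc / 2, arc / 2)
        q = np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros(len(pts))])
        return q, ang

    def implicit(self, pts):
        q, _ = self._nearest_arc(pts)
        return np.linalg.norm(pts - q, axis=1) - self.p["tube_radius"]

    def sample(self, n, rng):
        R, r, arc = self._arc_params()
        pts_out, nrm_out = [], []
        need = n
        cap_len = r  # cap area expressed as equivalent centerline length
        while need > 0:
            m = max(2 * need, 256)
            t = rng.uniform(-arc / 2 - cap_len / R, arc / 2 + cap_len / R, m)
            tc = np.clip(t, -arc / 2, arc / 2)
            over = (t - tc) * R
            e_r = np.column_stack([np.cos(tc), np.sin(tc), np.zeros(m)])
            e_t = np.column_stack([-np.sin(tc), np.cos(tc), np.zeros(m)])
            e_z = np.array([0.0, 0.0, 1.0])
            # tube angle, weighted by the bent-tube area element (R + r cos psi)
            psi = rng.uniform(0, 2 * math.pi, m)
            accept = rng.uniform(0, R + r, m) < R + r * np.cos(psi)
            rad = np.sqrt(np.maximum(r**2 - over**2, 0.0))
            center = R * e_r + e_t * over[:, None]
            offset = (np.cos(psi)[:, None] * e_r + np.sin(psi)[:, None] * e_z)
            cand = center + rad[:, None] * offset
            d = self.implicit(cand)
            keep = accept & (d > -1e-9)
            cand = cand[keep][:need]
            pts_out.append(cand)
            need -= len(cand)
        pts = np.vstack(pts_out)[:n]
        q, _ = self._nearest_arc(pts)
        v = pts - q
        normals = v / np.linalg.norm(v, axis=1, keepdims=True)
        return pts, normals

    def bounds(self):
        R, r, _ = self._arc_params()
        hi = np.array([R + r, R + r, r]) * 1.15
        return -hi, hi

    def ground_truth(self):
        R, r, arc = self._arc_params()
        n_nodes = 16
        ts = np.linspace(-arc / 2, arc / 2, n_nodes)
        pts = np.column_stack([R * np.cos(ts), R * np.sin(ts), np.zeros(n_nodes)])
        # Pappus: swept tube volume is (disk area) x (centerline length)
        vol = math.pi * r**2 * R * arc + 4.0 / 3.0 * math.pi * r**3
        return GroundTruth(pts, np.full(n_nodes, r), _chain_edges(n_nodes),
                           R * arc, 0, vol)


_SHAPE_CLASSES = {
    "sphere": _Sphere,
    "capsule": _Capsule,
    "ellipsoid": _Ellipsoid,
    "y_tube": _YTube,
    "crescent": _Crescent,
}


def _shape_for(spec: ShapeSpec) -> _Shape:
    spec.validate()
    return _SHAPE_CLASSES[spec.family](spec.resolved_params())


def make_shape(spec: ShapeSpec) -> Tuple[SurfacePointCloud, GroundTruth]:
    """Generate a surface point cloud (with analytic normals) and its
    ground-truth medial skeleton. Deterministic given the spec."""
    shape = _shape_for(spec)
    rng = np.random.default_rng(spec.seed)
    pts, normals = shape.sample(spec.n_points, rng)
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(scale=spec.noise_sigma, size=pts.shape)
    return SurfacePointCloud(pts, normals), shape.ground_truth()


def inside_fraction(spec: ShapeSpec, points: np.ndarray) -> float:
    """Fraction of ``points`` strictly inside the shape's implicit surface."""
    shape = _shape_for(spec)
    return float(np.mean(shape.implicit(np.atleast_2d(points)) < 0))


def brute_force_mat(spec: ShapeSpec, grid_resolution: int = 32,
                    n_dense: int = 120000, angle_deg: float = 30.0,
                    ) -> List[Tuple[np.ndarray, float]]:
    """Brute-force medial-axis oracle on a regular grid.

    A grid point interior to the shape is a medial point when its nearest
    surface samples include two whose directions differ by more than
    ``angle_deg`` at (discretization-corrected) equal distance; the distance to
    the nearest sample is the medial radius. Independent of the learned
    pipeline; used as a ground-truth cross-check.
    """
    if grid_resolution < 16:
        raise ValueError("grid_resolution must be >= 16")
    shape = _shape_for(spec)
    rng = np.random.default_rng(0)  # oracle sampling is fixed, not spec.seed
    surf, _ = shape.sample(n_dense, rng)
    tree = cKDTree(surf)
    lo, hi = shape.bounds()
    axes = [np.linspace(lo[i], hi[i], grid_resolution) for i in range(3)]
    cell_mean = float(np.mean((hi - lo) / (grid_resolution - 1)))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    interior = grid[shape.implicit(grid) < 0]
    if len(interior) == 0:
        return []
    d1, idx1 = tree.query(interior, k=1)
    cos_thresh = math.cos(math.radians(angle_deg))
    # Distance slack for "equally close in a second direction". A point at
    # offset e from the medial axis sees its best >angle sample at excess
    # distance ~ e*(1-cos(angle)), so the cell-scaled term localizes
    # detections to about one grid cell. A non-medial point at distance d
    # from the surface sees spurious angular spread ~2*atan(sqrt(2*eps/d))
    # plus the nearest-sample direction noise, so the slack is also capped
    # at a fraction of d1, and interior points closer to the surface than
    # 16 sample spacings are dropped outright (their direction field is
    # discretization noise; these are the insignificant small-radius spikes
    # a simplified medial axis removes anyway).
    sec_gap = 1.0 / cos_thresh - 1.0
    eps = np.minimum(0.15 * cell_mean, 0.2 * sec_gap * d1)
    spacing = float(np.median(tree.query(surf[::89], k=2)[0][:, 1]))
    deep = d1 >= 16.0 * spacing
    balls = tree.query_ball_point(interior[deep], r=(d1 + eps)[deep],
                                  workers=-1)
    out = []
    for q, members in zip(np.nonzero(deep)[0], balls):
        dirs = surf[members] - interior[q]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ref = surf[idx1[q]] - interior[q]
        ref /= np.linalg.norm(ref)
        if np.any(dirs @ ref < cos_thresh):
            out.append((interior[q], float(d1[q])))
    return out


def make_labeled_dataset(n_per_class: int, families: Sequence[str],
                         seed: int = 0, n_points: int = 1024,
                         noise_sigma: float = 0.0,
                         param_jitter: float = 0.15,
                         ) -> List[Tuple[SurfacePointCloud, GroundTruth, str]]:
    """Labeled dataset: per-class parameter jitter, labels = family names."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    families = list(families)
    if len(families) < 2:
        raise ValueError("need at least two families")
    rng = np.random.default_rng(seed)
    out = []
    for fam in families:
        base = DEFAULT_PARAMS[fam]
        for _ in range(n_per_class):
            params = {k: v * float(rng.uniform(1 - param_jitter, 1 + param_jitter))
                      for k, v in base.items()}
            spec = ShapeSpec(fam, params, n_points=n_points,
                             noise_sigma=noise_sigma,
                             seed=int(rng.integers(2**31 - 1)))
            cloud, gt = make_shape(spec)
            out.append((cloud, gt, fam))
    return out


def ground_truth_to_graph(gt: GroundTruth):
    """Ground-truth skeleton as a weighted graph (see skeleton_graph)."""
    from .skeleton_graph import build_graph_from_arrays

    return build_graph_from_arrays(gt.skeleton_points, gt.skeleton_radii,
                                   gt.graph_edges)


def save_ground_truth(gt: GroundTruth, path: str) -> None:
    """Write the ground-truth skeleton: SWC when it is a tree, otherwise a
    node-table + edge-list text file."""
    import networkx as nx

    from .skeleton_graph import write_edge_list, write_swc

    g = ground_truth_to_graph(gt)
    if nx.is_tree(g):
        write_swc(g, path)
    else:
        write_edge_list(g, path)


def save_cloud(cloud: SurfacePointCloud, path: str) -> None:
    write_cloud(cloud, path)
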