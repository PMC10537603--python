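"""Surface point-cloud container, file I/O, resampling and normal estimation.

The cloud is the pipeline's input object: ``M x 3`` coordinates, optionally
with outward unit normals. Normals are estimated from local covariance
(smallest principal axis of each k-neighborhood); resampling to a fixed point
count weights each point by its mean distance to its nearest neighbors so that
sparse regions are kept preferentially.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

__all__ = [
    "SurfacePointCloud",
    "read_cloud",
    "write_cloud",
    "resample_weighted",
    "estimate_normals",
    "normalize_unit_cube",
]


@dataclass
class SurfacePointCloud:
    """Points on the surface of a 3D shape, with optional unit normals."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    scale_transform: Optional[dict] = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (M, 3) array")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_original_frame(self, points: np.ndarray) -> np.ndarray:
        """Map points from the normalized frame back to input coordinates."""
        if self.scale_transform is None:
            return np.asarray(points)
        t = self.scale_transform
        return np.asarray(points) * t["scale"] + t["center"]


# ---------------------------------------------------------------------------
# I/O.  PLY is written/parsed directly (ascii and binary_little_endian, with
# per-vertex normals, which mesh-centric loaders drop for point clouds);
# OBJ reading goes through trimesh, faces ignored.
# ---------------------------------------------------------------------------

_PLY_TYPES = {"float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
              "uchar": "u1", "uint8": "u1", "int": "<i4", "int32": "<i4"}


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("ply", "obj", "xyz", "txt"):
        raise ValueError(f"unknown point-cloud extension: {ext!r}")
    return "xyz" if ext == "txt" else ext


def _read_ply(path: str) -> SurfacePointCloud:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tok = line.decode("ascii").strip().split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise ValueError(f"{path}: list property on vertices")
                props.append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex == 0:
            raise ValueError(f"{path}: no vertices")
        dtype = np.dtype(props)
        if fmt == "ascii":
            rows = np.loadtxt(fh, max_rows=n_vertex, dtype=np.float64, ndmin=2)
            if rows.shape != (n_vertex, len(props)):
                raise ValueError(f"{path}: bad vertex table shape")
            data = {name: rows[:, i] for i, (name, _) in enumerate(props)}
        else:
            raw = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype,
                                count=n_vertex)
            data = {name: raw[name].astype(np.float64) for name, _ in props}
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfacePointCloud(pts, normals)


def _write_ply(cloud: SurfacePointCloud, path: str, binary: bool = False) -> None:
    names = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.normals is not None else [])
    arr = (cloud.points if cloud.normals is None
           else np.hstack([cloud.points, cloud.normals]))
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
    header += [f"property double {n}" for n in names]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())
        else:
            np.savetxt(fh, arr, fmt="%.10g")


def read_cloud(path: str, fmt: Optional[str] = None) -> SurfacePointCloud:
    """Read a point cloud from PLY, OBJ (vertices only) or XYZ text."""
    fmt = fmt or _detect_format(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "obj":
        import trimesh

        obj = trimesh.load(path, process=False)
        verts = np.asarray(obj.vertices, dtype=np.float64)
        if verts.size == 0:
            raise ValueError(f"{path}: no vertices in OBJ")
        return SurfacePointCloud(verts)
    if fmt == "xyz":
        arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
        if arr.shape[1] not in (3, 6):
            raise ValueError(f"{path}: expected 3 or 6 columns, got {arr.shape[1]}")
        normals = None
        if arr.shape[1] == 6:
            normals = arr[:, 3:6]
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return SurfacePointCloud(arr[:, :3], normals)
    raise ValueError(f"unknown format {fmt!r}")


def write_cloud(cloud: SurfacePointCloud, path: str,
                fmt: Optional[str] = None, binary: bool = False) -> None:
    """Write a point cloud as PLY, OBJ or XYZ text."""
    fmt = fmt or _detect_format(path)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "obj":
        with open(path, "w") as fh:
            for p in cloud.points:
                fh.write(f"v {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    elif fmt == "xyz":
        arr = (cloud.points if cloud.normals is None
               else np.hstack([cloud.points, cloud.normals]))
        np.savetxt(path, arr, fmt="%.10g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Resampling, normals, normalization
# ---------------------------------------------------------------------------


def resample_weighted(cloud: SurfacePointCloud, m: int,
                      k_neighbors: int = 8, seed: int = 0) -> SurfacePointCloud:
    """Draw ``m`` points without replacement, weighted by local sparseness.

    Each point's weight is its mean distance to its ``k_neighbors`` nearest
    neighbors, so isolated points are retained at a higher rate than points in
    dense regions. If ``m >= M`` the input cloud is returned unchanged.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    M = len(cloud)
    if m >= M:
        return cloud
    k = min(k_neighbors, M - 1)
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    weights = dists[:, 1:].mean(axis=1)
    total = weights.sum()
    p = np.full(M, 1.0 / M) if total <= 0 else weights / total
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(M, size=m, replace=False, p=p))
    normals = cloud.normals[idx] if cloud.normals is not None else None
    return SurfacePointCloud(cloud.points[idx], normals,
                             scale_transform=cloud.scale_transform)


def _orient_mst(points: np.ndarray, normals: np.ndarray, k: int) -> np.ndarray:
    """Propagate a consistent normal orientation along a Euclidean MST."""
    import scipy.sparse as sp

    M = len(points)
    tree = cKDTree(points)
    dists, idxs = tree.query(points, k=min(k, M - 1) + 1)
    rows = np.repeat(np.arange(M), idxs.shape[1] - 1)
    cols = idxs[:, 1:].ravel()
    graph = sp.coo_matrix((dists[:, 1:].ravel(), (rows, cols)), shape=(M, M))
    mst = minimum_spanning_tree(graph).tocsr()
    mst = mst + mst.T
    out = normals.copy()
    seen = np.zeros(M, dtype=bool)
    # start from the point with the largest z: its normal should face +z
    root = int(np.argmax(points[:, 2]))
    if out[root, 2] < 0:
        out[root] = -out[root]
    stack = [root]
    seen[root] = True
    while stack:
        i = stack.pop()
        for j in mst.indices[mst.indptr[i]:mst.indptr[i + 1]]:
            if seen[j]:
                continue
            seen[j] = True
            if np.dot(out[i], out[j]) < 0:
                out[j] = -out[j]
            stack.append(j)
    return out


def estimate_normals(cloud: SurfacePointCloud, k_neighbors: int = 16,
                     orientation: str = "centroid") -> SurfacePointCloud:
    """Estimate outward unit normals by local covariance analysis.

    The normal at each point is the eigenvector with the smallest eigenvalue
    of its k-neighborhood covariance (the direction of least variance).
    Orientation: ``"centroid"`` flips each normal to point away from the cloud
    centroid (adequate for star-shaped surfaces); ``"mst"`` propagates a
    consistent orientation along a minimum spanning tree for strongly
    non-star-shaped clouds.
    """
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    M = len(cloud)
    if M <= k_neighbors:
        raise ValueError("cloud smaller than k_neighbors")
    tree = cKDTree(cloud.points)
    _, idxs = tree.query(cloud.points, k=k_neighbors + 1)
    nbrs = cloud.points[idxs]  # (M, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("mki,mkj->mij", centered, centered)
    if np.any(np.abs(cov).sum(axis=(1, 2)) < 1e-30):
        raise ValueError("degenerate neighborhood: coincident points")
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    if orientation == "centroid":
        outward = cloud.points - cloud.points.mean(axis=0)
        flip = np.einsum("ij,ij->i", normals, outward) < 0
        normals[flip] = -normals[flip]
    elif orientation == "mst":
        normals = _orient_mst(cloud.points, normals, k_neighbors)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return SurfacePointCloud(cloud.points, normals,
                             scale_transform=cloud.scale_transform)


def normalize_unit_cube(cloud: SurfacePointCloud) -> SurfacePointCloud:
    """Center at the centroid and scale isotropically into ``[-1, 1]^3``.

    A single scale (the maximum absolute coordinate after centering) is used,
    preserving aspect ratios. The transform is recorded on the returned cloud
    so downstream skeletons can be mapped back to input coordinates.
    """
    center = cloud.points.mean(axis=0)
    shifted = cloud.points - center
    scale = np.abs(shifted).max()
    if scale <= 0:
        raise ValueError("degenerate cloud: all points identical")
    return SurfacePointCloud(shifted / scale, cloud.normals,
                             scale_transform={"center": center, "scale": scale})
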