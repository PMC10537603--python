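"""Skeleton-sphere prediction: sampling, algebra, losses, training recovery.

Every loss operation is checked against an independent brute-force double-loop
reimplementation on random small instances.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from skelmorph.nn import Tensor
from skelmorph.pointcloud import normalize_unit_cube
from skelmorph.skeleton_net import (SkeletonSpheres, TrainConfig,
                                    combine_centers, combine_radii,
                                    closest_distances,
                                    farthest_point_sampling, loss_norm,
                                    loss_point2sphere, loss_radius,
                                    loss_sampling, predict_spheres,
                                    sample_sphere_points, train_skeleton)
from skelmorph.synth import ShapeSpec, make_shape

rng = np.random.default_rng(42)


def in_hull(point, hull_pts) -> bool:
    """Exact convex-hull membership by linear programming."""
    n = len(hull_pts)
    res = linprog(np.zeros(n), A_eq=np.vstack([hull_pts.T, np.ones(n)]),
                  b_eq=np.append(point, 1.0), bounds=[(0, None)] * n,
                  method="highs")
    return res.success


# -- brute-force oracles (independent double loops) ---------------------------

def bf_chamfer_sum(T, P):
    s = 0.0
    for p in P:
        s += min(np.linalg.norm(p - t) for t in T)
    for t in T:
        s += min(np.linalg.norm(t - p) for p in P)
    return s


def bf_point2sphere(P, C, R):
    s = 0.0
    for p in P:
        dists = [np.linalg.norm(p - c) for c in C]
        i = int(np.argmin(dists))
        s += abs(dists[i] - R[i])
    for i, c in enumerate(C):
        s += abs(min(np.linalg.norm(c - p) for p in P) - R[i])
    return s


def bf_point2sphere_signed(P, C, R):
    s = 0.0
    for p in P:
        dists = [np.linalg.norm(p - c) for c in C]
        i = int(np.argmin(dists))
        s += dists[i] - R[i]
    for i, c in enumerate(C):
        s += min(np.linalg.norm(c - p) for p in P) - R[i]
    return s


def bf_norm_loss(P, normals, C):
    s = 0.0
    for i, c in enumerate(C):
        dists = [np.linalg.norm(p - c) for p in P]
        j = int(np.argmin(dists))
        if dists[j] > 1e-9:
            spoke = (P[j] - c) / dists[j]
            s += 1.0 - np.dot(normals[j], spoke)
    for j, p in enumerate(P):
        dists = [np.linalg.norm(p - c) for c in C]
        i = int(np.argmin(dists))
        if dists[i] > 1e-9:
            spoke = (p - C[i]) / dists[i]
            s += 1.0 - np.dot(normals[j], spoke)
    return s


class TestFPS:
    def test_collinear_endpoints(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        idx = farthest_point_sampling(pts, 2, start_index=0)
        assert set(idx) == {0, 3}

    def test_m_equals_M_returns_all(self):
        pts = rng.normal(size=(20, 3))
        assert set(farthest_point_sampling(pts, 20, seed=1)) == set(range(20))

    def test_spread_beats_random_subsets(self):
        pts = np.random.default_rng(7).normal(size=(100, 3))
        idx = farthest_point_sampling(pts, 10, seed=0)

        def min_pair(sub):
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
            return d[np.triu_indices(len(sub), 1)].min()

        fps_spread = min_pair(pts[idx])
        r = np.random.default_rng(8)
        for _ in range(50):
            assert fps_spread >= min_pair(pts[r.choice(100, 10, replace=False)])

    def test_determinism_and_bounds(self):
        pts = rng.normal(size=(30, 3))
        assert np.array_equal(farthest_point_sampling(pts, 5, seed=3),
                              farthest_point_sampling(pts, 5, seed=3))
        with pytest.raises(ValueError):
            farthest_point_sampling(pts, 31)


class TestCombineOps:
    def test_one_hot_column_selects_point(self):
        P = rng.normal(size=(6, 3))
        W = np.zeros((6, 2))
        W[2, 0] = 1.0
        W[4, 1] = 1.0
        C = combine_centers(W, P)
        assert np.allclose(C, P[[2, 4]])

    def test_uniform_column_gives_centroid(self):
        P = rng.normal(size=(8, 3))
        W = np.full((8, 1), 1 / 8)
        assert np.allclose(combine_centers(W, P), P.mean(axis=0))

    def test_centers_inside_convex_hull(self):
        P = np.random.default_rng(3).normal(size=(20, 3))
        logits = np.random.default_rng(4).normal(size=(20, 5))
        W = np.exp(logits) / np.exp(logits).sum(axis=0)
        C = combine_centers(W, P)
        for c in C:
            assert in_hull(c, P)

    def test_closest_distances_examples_and_brute_force(self):
        assert np.allclose(
            closest_distances(np.array([[2.0, 0, 0]]),
                              np.array([[0.0, 0, 0], [1.0, 0, 0]])), [1.0])
        P = rng.normal(size=(50, 3))
        C = rng.normal(size=(5, 3))
        bf = [min(np.linalg.norm(p - c) for c in C) for p in P]
        assert np.allclose(closest_distances(P, C), bf, rtol=1e-9)
        # a surface point coinciding with a center: zero up to the sqrt floor
        assert closest_distances(C[[0]], C)[0] < 1e-5

    def test_combine_radii(self):
        d = np.array([1.0, 2.0, 3.0])
        W = np.zeros((3, 2))
        W[1, 0] = 1.0
        W[:, 1] = 1 / 3
        R = combine_radii(W, d)
        assert R[0] == pytest.approx(2.0)
        assert R[1] == pytest.approx(2.0)  # mean of d

    def test_unit_sphere_single_center_radius_one(self):
        cloud, _ = make_shape(ShapeSpec("sphere", n_points=128))
        W = np.full((128, 1), 1 / 128)
        d = closest_distances(cloud.points, np.zeros((1, 3)))
        assert combine_radii(W, d)[0] == pytest.approx(1.0)


class TestSphereSampling:
    def test_samples_on_sphere_surface(self):
        s = SkeletonSpheres(np.zeros((1, 3)), np.array([1.0]))
        T = sample_sphere_points(s, 100, seed=0)
        assert np.allclose(np.linalg.norm(T, axis=1), 1.0, atol=1e-6)

    def test_zero_radius_collapses_to_center(self):
        s = SkeletonSpheres(np.array([[1.0, 2, 3]]), np.array([0.0]))
        T = sample_sphere_points(s, 10, seed=0)
        assert np.allclose(T, [1.0, 2, 3])

    def test_count_and_negative_radius(self):
        s = SkeletonSpheres(rng.normal(size=(2, 3)), np.array([0.5, 1.0]))
        assert sample_sphere_points(s, 10, seed=0).shape == (20, 3)
        with pytest.raises(ValueError):
            SkeletonSpheres(np.zeros((1, 3)), np.array([-0.5]))
        with pytest.raises(ValueError):
            sample_sphere_points(s, 0)


class TestLosses:
    def test_sampling_loss_examples(self):
        P = np.array([[3.0, 4.0, 0.0]])
        T = np.array([[0.0, 0.0, 0.0]])
        assert loss_sampling(T, P) == pytest.approx(10.0)
        assert loss_sampling(P, P) == pytest.approx(0.0, abs=1e-5)

    def test_sampling_loss_brute_force(self):
        T = rng.normal(size=(13, 3))
        P = rng.normal(size=(17, 3))
        assert loss_sampling(T, P) == pytest.approx(
            bf_chamfer_sum(T, P), rel=1e-9)

    def test_point2sphere_examples(self):
        cloud, _ = make_shape(ShapeSpec("sphere", n_points=128))
        s = SkeletonSpheres(np.zeros((1, 3)), np.array([1.0]))
        assert loss_point2sphere(cloud.points, s) == pytest.approx(0.0, abs=1e-5)
        s2 = SkeletonSpheres(np.zeros((1, 3)), np.array([0.0]))
        assert loss_point2sphere(np.array([[1.0, 0, 0]]), s2) == pytest.approx(2.0)

    @pytest.mark.parametrize("signed", [False, True])
    def test_point2sphere_brute_force(self, signed):
        P = rng.normal(size=(15, 3))
        C = rng.normal(size=(4, 3))
        R = np.abs(rng.normal(size=4))
        s = SkeletonSpheres(C, R)
        bf = (bf_point2sphere_signed if signed else bf_point2sphere)(P, C, R)
        assert loss_point2sphere(P, s, signed=signed) == pytest.approx(
            bf, rel=1e-9)

    def test_radius_loss(self):
        s = SkeletonSpheres(np.zeros((2, 3)), np.array([0.5, 1.5]))
        assert loss_radius(s) == pytest.approx(-2.0)
        z = SkeletonSpheres(np.zeros((2, 3)), np.zeros(2))
        assert loss_radius(z) == 0.0
        d = SkeletonSpheres(np.zeros((2, 3)), np.array([1.0, 3.0]))
        assert loss_radius(d) == pytest.approx(2 * loss_radius(s))

    def test_norm_loss_aligned_and_antialigned(self):
        P = np.array([[1.0, 0, 0]])
        s = SkeletonSpheres(np.zeros((1, 3)), np.array([1.0]))
        aligned = loss_norm(P, np.array([[1.0, 0, 0]]), s)
        anti = loss_norm(P, np.array([[-1.0, 0, 0]]), s)
        assert aligned == pytest.approx(0.0, abs=1e-12)
        assert anti == pytest.approx(4.0)

    def test_norm_loss_radial_sphere_is_zero(self):
        cloud, _ = make_shape(ShapeSpec("sphere", n_points=256))
        s = SkeletonSpheres(np.zeros((1, 3)), np.array([1.0]))
        assert loss_norm(cloud.points, cloud.normals, s) == pytest.approx(
            0.0, abs=1e-6)

    def test_norm_loss_brute_force_and_range(self):
        P = rng.normal(size=(12, 3))
        normals = rng.normal(size=(12, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        C = rng.normal(size=(3, 3))
        s = SkeletonSpheres(C, np.ones(3))
        val = loss_norm(P, normals, s)
        assert val == pytest.approx(bf_norm_loss(P, normals, C), rel=1e-9)
        assert 0.0 <= val <= 2.0 * (len(C) + len(P))

    def test_norm_loss_requires_normals(self):
        s = SkeletonSpheres(np.zeros((1, 3)), np.ones(1))
        with pytest.raises(ValueError):
            loss_norm(np.ones((2, 3)), None, s)


class TestTraining:
    def test_sphere_fixture_recovers_center_and_radius(self, sphere_train):
        cloud, gt, result = sphere_train
        s = result.spheres[0]
        assert np.linalg.norm(s.centers, axis=1).max() < 0.2
        assert abs(s.radii.mean() - 1.0) < 0.1

    def test_capsule_fixture_centers_near_axis(self, capsule_train):
        cloud, gt, result = capsule_train
        t = cloud.scale_transform
        axis = (gt.skeleton_points - t["center"]) / t["scale"]
        a, b = axis[0], axis[-1]
        ab = b - a
        s = result.spheres[0]
        tt = np.clip((s.centers - a) @ ab / (ab @ ab), 0, 1)
        d = np.linalg.norm(s.centers - (a + tt[:, None] * ab), axis=1)
        assert (d < 0.15).mean() >= 0.9

    def test_skeleton_chamfer_halves_during_training(self, capsule_train):
        from skelmorph.metrics import chamfer

        cloud, gt, result = capsule_train
        t = cloud.scale_transform
        axis = (gt.skeleton_points - t["center"]) / t["scale"]
        cd0 = chamfer(result.initial_spheres[0].centers, axis, mode="mean")
        cd1 = chamfer(result.spheres[0].centers, axis, mode="mean")
        assert cd1 < cd0 / 2

    def test_weight_columns_sum_to_one(self, capsule_train):
        _, _, result = capsule_train
        W = result.weights[0]
        assert np.abs(W.sum(axis=0) - 1.0).max() < 1e-5
        assert W.min() >= 0

    def test_final_centers_inside_hull_of_sampled_points(self, capsule_train):
        _, _, result = capsule_train
        P = result.encoder_outputs[0].sampled_points
        for c in result.spheres[0].centers:
            assert in_hull(c, P)

    def test_training_is_deterministic(self):
        cloud, _ = make_shape(ShapeSpec("sphere", n_points=256, seed=1))
        cloud = normalize_unit_cube(cloud)
        cfg = TrainConfig(n_spheres=4, m_prime=32, feature_dim=16, epochs=5,
                          seed=1, level_sizes=(64, 32), hidden=16)
        a = train_skeleton([cloud], cfg)
        b = train_skeleton([cloud], cfg)
        assert np.array_equal(a.spheres[0].centers, b.spheres[0].centers)
        assert a.loss_history == b.loss_history
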