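"""Shared fixtures: synthetic fixture clouds and (session-scoped) training
runs reused by both the unit tests and the end-to-end pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from skelmorph.pointcloud import normalize_unit_cube
from skelmorph.skeleton_net import TrainConfig, train_skeleton
from skelmorph.synth import ShapeSpec, make_shape


def fixture_config(**overrides) -> TrainConfig:
    """Tiny-encoder training configuration used for parametric fixtures."""
    base = dict(n_spheres=8, m_prime=64, feature_dim=32, epochs=300, seed=0,
                level_sizes=(128, 64), hidden=32)
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture(scope="session")
def sphere_train():
    cloud, gt = make_shape(ShapeSpec("sphere", n_points=512, seed=3))
    cloud = normalize_unit_cube(cloud)
    result = train_skeleton([cloud], fixture_config(n_spheres=4))
    return cloud, gt, result


@pytest.fixture(scope="session")
def capsule_train():
    cloud, gt = make_shape(ShapeSpec("capsule", n_points=512, seed=3))
    cloud = normalize_unit_cube(cloud)
    result = train_skeleton([cloud], fixture_config(n_spheres=12))
    return cloud, gt, result


@pytest.fixture(scope="session")
def ytube_chain():
    """Full pipeline on the branched-tube fixture: spheres -> mesh -> graph."""
    from skelmorph.mesh_links import GAEConfig, predict_links
    from skelmorph.skeleton_graph import build_graph

    spec = ShapeSpec("y_tube", n_points=700, seed=2)
    cloud, gt = make_shape(spec)
    cloudn = normalize_unit_cube(cloud)
    result = train_skeleton([cloudn], fixture_config(n_spheres=10, seed=2))
    spheres = result.spheres[0]
    mesh = predict_links(spheres, result.weights[0],
                         result.encoder_outputs[0].features.numpy(),
                         GAEConfig(seed=2))
    graph = build_graph(mesh)
    return spec, cloudn, gt, mesh, graph


@pytest.fixture(scope="session")
def embedding_run():
    """Embedding pipeline on the labeled 3-family dataset (30 train / 30 test)."""
    from skelmorph.embedding import EmbedConfig, embed, train_embedder
    from skelmorph.synth import ground_truth_to_graph, make_labeled_dataset

    families = ["sphere", "capsule", "y_tube"]
    data = make_labeled_dataset(20, families, seed=11, n_points=256)
    graphs = [ground_truth_to_graph(gt) for _, gt, _ in data]
    labels = [lab for _, _, lab in data]
    train_idx = [i for f in families
                 for i in [j for j, l in enumerate(labels) if l == f][:10]]
    test_idx = [i for f in families
                for i in [j for j, l in enumerate(labels) if l == f][10:]]
    embedder = train_embedder([graphs[i] for i in train_idx],
                              EmbedConfig(epochs=150, seed=0))
    train_vecs = np.array([embed(graphs[i], embedder) for i in train_idx])
    test_vecs = np.array([embed(graphs[i], embedder) for i in test_idx])
    return (embedder, train_vecs, [labels[i] for i in train_idx],
            test_vecs, [labels[i] for i in test_idx])
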