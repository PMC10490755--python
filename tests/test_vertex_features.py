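"""Curvature-aware subsampling, grouping, mini-PointNet, decode/interpolate."""

import numpy as np
import pytest

from myomesh.autodiff import Tensor
from myomesh.vertex_features import (
    MiniPointNet,
    SetAbstractionConfig,
    VertexFeatureNet,
    _interpolate,
    build_feature_plan,
    encode_local,
    estimate_pseudo_curvature,
    geometric_subsample,
    group,
    partition_regions,
)
from oracles import brute_force_nearest


def crease_cloud(n_per_side=150, seed=0):
    """Two half-planes meeting at a 90-degree dihedral along the y axis."""
    rng = np.random.default_rng(seed)
    a = np.stack([rng.uniform(0, 2, n_per_side), rng.uniform(-1, 1, n_per_side),
                  np.zeros(n_per_side)], axis=1)
    b = np.stack([np.zeros(n_per_side), rng.uniform(-1, 1, n_per_side),
                  rng.uniform(0, 2, n_per_side)], axis=1)
    return np.concatenate([a, b])


# ----------------------------------------------------------------- curvature


def test_planar_cloud_has_zero_curvature():
    rng = np.random.default_rng(1)
    pts = np.stack([rng.uniform(-1, 1, 200), rng.uniform(-1, 1, 200), np.zeros(200)], axis=1)
    angles = estimate_pseudo_curvature(pts, k=12)
    assert np.all(angles < 1e-6)


def test_sphere_curvature_positive_and_uniform():
    rng = np.random.default_rng(2)
    v = rng.normal(size=(500, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    angles = estimate_pseudo_curvature(v, k=16)
    assert np.all(angles > 0)
    # symmetry: scores roughly equal across the sphere
    assert angles.std() / angles.mean() < 0.5


def test_crease_scores_exceed_flats():
    pts = crease_cloud()
    angles = estimate_pseudo_curvature(pts, k=16)
    near_crease = (np.abs(pts[:, 0]) < 0.15) & (np.abs(pts[:, 2]) < 0.15)
    far = (pts[:, 0] > 0.5) | (pts[:, 2] > 0.5)
    assert angles[near_crease].mean() > 3 * angles[far].mean()
    scores = partition_regions(angles, threshold=5.0)
    assert scores.geometric[near_crease].mean() > 0.9
    assert scores.geometric[far].mean() < 0.1


def test_degenerate_neighbourhood_warns_and_scores_zero():
    pts = np.zeros((10, 3))
    with pytest.warns(UserWarning):
        angles = estimate_pseudo_curvature(pts, k=4)
    assert np.all(angles == 0)


def test_partition_requires_positive_threshold():
    with pytest.raises(ValueError):
        partition_regions(np.zeros(5), threshold=0.0)


# --------------------------------------------------------------- subsampling


def test_subsample_full_and_single():
    pts = crease_cloud(50)
    full, idx = geometric_subsample(pts, len(pts), rng=0)
    assert sorted(idx.tolist()) == list(range(len(pts)))
    one, idx1 = geometric_subsample(pts, 1, rng=0)
    assert one.shape == (1, 3) and 0 <= idx1[0] < len(pts)


@pytest.mark.parametrize("n", [1, 7, 50, 123, 299])
def test_subsample_exact_count(n):
    pts = crease_cloud(150)
    sampled, idx = geometric_subsample(pts, n, rng=3)
    assert len(sampled) == n
    assert len(np.unique(idx)) == n  # without replacement


def test_subsample_out_of_range():
    pts = crease_cloud(10)
    with pytest.raises(ValueError):
        geometric_subsample(pts, len(pts) + 1, rng=0)


def test_subsample_oversamples_geometric_region():
    """Crease points (~20% of the cloud) exceed their base fraction in at
    least 95 of 100 seeded draws of n = N/2 at 2x oversampling."""
    pts = crease_cloud(200, seed=5)
    angles = estimate_pseudo_curvature(pts, k=16)
    scores = partition_regions(angles, threshold=5.0)
    base_fraction = scores.geometric.mean()
    assert 0.05 < base_fraction < 0.45
    wins = 0
    for s in range(100):
        _, idx = geometric_subsample(pts, len(pts) // 2, rng=s, scores=scores)
        if scores.geometric[idx].mean() > base_fraction:
            wins += 1
    assert wins >= 95


def test_subsample_uniform_fallback_when_one_region_empty():
    rng = np.random.default_rng(6)
    flat = np.stack([rng.uniform(0, 1, 50), rng.uniform(0, 1, 50), np.zeros(50)], axis=1)
    _, idx = geometric_subsample(flat, 20, rng=1)
    assert len(idx) == 20


# ------------------------------------------------------------------ grouping


def test_group_coincident_centroid():
    cloud = np.array([[0.0, 0, 0], [5, 0, 0], [0, 5, 0]])
    regions = group(cloud[:1], cloud, K=1)
    assert regions.indices[0, 0] == 0
    assert np.allclose(regions.relative[0, 0], 0.0)


def test_group_translation_invariant_relative_coordinates():
    rng = np.random.default_rng(7)
    cloud = rng.normal(size=(30, 3))
    cents = cloud[:5]
    a = group(cents, cloud, K=4)
    b = group(cents + 100.0, cloud + 100.0, K=4)
    assert np.array_equal(a.indices, b.indices)
    assert np.allclose(a.relative, b.relative, atol=1e-9)


def test_group_matches_brute_force_k3():
    rng = np.random.default_rng(8)
    cloud = rng.normal(size=(10, 3))
    cents = rng.normal(size=(4, 3))
    regions = group(cents, cloud, K=3)
    for i, c in enumerate(cents):
        d = np.linalg.norm(cloud - c, axis=1)
        assert set(regions.indices[i]) == set(np.argsort(d)[:3])


def test_group_k_exceeding_cloud():
    with pytest.raises(ValueError):
        group(np.zeros((1, 3)), np.zeros((2, 3)), K=3)


# ------------------------------------------------------------- mini pointnet


def test_encoder_permutation_invariant():
    rng = np.random.default_rng(9)
    cloud = rng.normal(size=(40, 3))
    regions = group(cloud[:6], cloud, K=8)
    enc = MiniPointNet(3, (16, 32), np.random.default_rng(0))
    base = encode_local(regions, enc).data
    for _ in range(5):
        perm = rng.permutation(8)
        shuffled = type(regions)(
            indices=regions.indices[:, perm], relative=regions.relative[:, perm]
        )
        assert np.allclose(encode_local(shuffled, enc).data, base, atol=1e-6)


def test_encoder_zero_weights_give_zero_features():
    enc = MiniPointNet(3, (8,), np.random.default_rng(0))
    enc.layers[0][0].data[:] = 0.0
    cloud = np.random.default_rng(1).normal(size=(20, 3))
    regions = group(cloud[:3], cloud, K=5)
    assert np.allclose(encode_local(regions, enc).data, 0.0)


def test_encoder_hand_set_weights_max_pool():
    """One linear layer, two-point region: output = elementwise max of the
    two transformed (ReLU-clipped) points."""
    enc = MiniPointNet(3, (2,), np.random.default_rng(0))
    W = np.array([[1.0, 0], [0, 1.0], [1.0, 1.0]], dtype=np.float32)
    enc.layers[0][0].data = W
    enc.layers[0][1].data[:] = 0.0
    rel = np.array([[[1.0, 2.0, 3.0], [4.0, -1.0, 0.5]]])  # one region, K=2
    regions = type(group(np.zeros((1, 3)), np.zeros((2, 3)), K=1))(
        indices=np.array([[0, 1]]), relative=rel
    )
    out = encode_local(regions, enc).data[0]
    expected = np.maximum(np.maximum(rel[0, 0] @ W, 0), np.maximum(rel[0, 1] @ W, 0))
    assert np.allclose(out, expected)


# ------------------------------------------------------- abstraction/decode


def test_config_validation():
    with pytest.raises(ValueError):
        SetAbstractionConfig(n_centroids=(64, 64, 32))
    with pytest.raises(ValueError):
        SetAbstractionConfig(group_k=2)


def test_set_abstraction_levels_and_determinism(shell_cloud):
    cfg = SetAbstractionConfig.for_cloud_size(len(shell_cloud), width_scale=0.25)
    net = VertexFeatureNet(cfg, seed=0)
    plan1 = build_feature_plan(shell_cloud, cfg, seed=5)
    plan2 = build_feature_plan(shell_cloud, cfg, seed=5)
    for a, b in zip(plan1.sample_indices, plan2.sample_indices):
        assert np.array_equal(a, b)  # bit-identical centroid selection
    levels = net.set_abstraction(plan1)
    counts = [len(p) for p in levels.points]
    assert counts == sorted(counts, reverse=True)
    assert all(a > b for a, b in zip(counts, counts[1:]))


def test_feature_field_shape_and_determinism(shell_cloud):
    cfg = SetAbstractionConfig.for_cloud_size(len(shell_cloud), width_scale=0.25)
    net = VertexFeatureNet(cfg, seed=0)
    plan = build_feature_plan(shell_cloud, cfg, seed=5)
    f1 = net.forward(plan).data
    f2 = net.forward(plan).data
    assert f1.shape == (len(shell_cloud), cfg.feature_dim)
    assert np.array_equal(f1, f2)


def test_feature_field_translation_invariant():
    """Relative-coordinate construction plus internal centering: a global
    translation of the cloud leaves the decoded features unchanged.  (Uses a
    generic cloud; on exact-lattice clouds nearest-neighbour ties make any
    KD-tree pipeline tie-break-dependent.)"""
    cloud = np.random.default_rng(0).normal(size=(600, 3)).astype(np.float32)
    cfg = SetAbstractionConfig.for_cloud_size(len(cloud), width_scale=0.25)
    net = VertexFeatureNet(cfg, seed=0)
    f1 = net.forward(build_feature_plan(cloud, cfg, seed=5)).data
    f2 = net.forward(build_feature_plan(cloud + 3.7, cfg, seed=5)).data
    assert np.allclose(f1, f2, atol=1e-4)


def test_interpolation_limits():
    feats = Tensor(np.array([[1.0, 2.0], [3.0, 4.0], [10.0, 20.0]]))
    # fine point coincident with centroid 1: weight 1 on it
    idx = np.array([[1, 0, 2]])
    w = np.array([[1.0, 0.0, 0.0]])
    assert np.allclose(_interpolate(feats, idx, w).data, [[3.0, 4.0]])
    # single-centroid skeleton: every point receives that feature
    idx1 = np.zeros((5, 1), dtype=int)
    w1 = np.ones((5, 1))
    out = _interpolate(Tensor(np.array([[7.0, 8.0]])), idx1, w1).data
    assert np.allclose(out, np.tile([7.0, 8.0], (5, 1)))


def test_centroid_overflow_raises(shell_cloud):
    cfg = SetAbstractionConfig(n_centroids=(len(shell_cloud) + 10, 8, 4))
    with pytest.raises(ValueError):
        build_feature_plan(shell_cloud, cfg, seed=0)
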