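"""Training losses: hand-evaluated examples, invariants, gradient checks."""

import numpy as np
import pytest

from myomesh import VoxelMask, cubify
from myomesh.autodiff import Tensor
from myomesh.losses import (
    CorrespondenceSets,
    LossWeights,
    SampledPair,
    chamfer_loss,
    edge_regularization,
    nearest_correspondences,
    normal_loss,
    sample_surface_differentiable,
    total_loss,
)
from oracles import brute_force_nearest


def make_pair(pp, pn, gp, gn):
    return SampledPair(
        Tensor(np.asarray(pp, dtype=float)),
        Tensor(np.asarray(pn, dtype=float)),
        np.asarray(gp, dtype=float),
        np.asarray(gn, dtype=float),
    )


def unit_cube_mesh():
    occ = np.ones((1, 1, 1), dtype=bool)
    return cubify(VoxelMask(occ))


# ------------------------------------------------------------ correspondences


def test_identity_correspondences():
    P = np.random.default_rng(0).normal(size=(20, 3))
    corr = nearest_correspondences(P, P)
    assert np.array_equal(corr.p_to_g, np.arange(20))
    assert np.array_equal(corr.g_to_p, np.arange(20))


def test_simple_two_point_correspondence():
    corr = nearest_correspondences([[0, 0, 0]], [[1, 0, 0], [5, 0, 0]])
    assert corr.p_to_g[0] == 0


def test_correspondences_match_brute_force():
    rng = np.random.default_rng(3)
    P, G = rng.normal(size=(50, 3)), rng.normal(size=(60, 3))
    corr = nearest_correspondences(P, G)
    assert np.array_equal(corr.p_to_g, brute_force_nearest(P, G))
    assert np.array_equal(corr.g_to_p, brute_force_nearest(G, P))


# ------------------------------------------------------------------- chamfer


def test_chamfer_identical_clouds_is_zero():
    P = np.random.default_rng(1).normal(size=(15, 3))
    pair = make_pair(P, np.tile([0, 0, 1.0], (15, 1)), P, np.tile([0, 0, 1.0], (15, 1)))
    corr = nearest_correspondences(P, P)
    assert chamfer_loss(pair, corr).item() == pytest.approx(0.0, abs=1e-12)


def test_chamfer_hand_example_sums_squared_means():
    """Single points one unit apart: 1^2 + 1^2 = 2."""
    pair = make_pair([[0, 0, 0]], [[0, 0, 1.0]], [[1, 0, 0]], [[0, 0, 1.0]])
    corr = nearest_correspondences(pair.pred_points, pair.label_points)
    assert chamfer_loss(pair, corr).item() == pytest.approx(2.0, abs=1e-9)


def test_chamfer_scales_quadratically():
    rng = np.random.default_rng(2)
    P, G = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
    n = np.tile([1.0, 0, 0], (30, 1))
    base = chamfer_loss(make_pair(P, n, G, n), nearest_correspondences(P, G)).item()
    scaled = chamfer_loss(
        make_pair(3.0 * P, n, 3.0 * G, n), nearest_correspondences(3 * P, 3 * G)
    ).item()
    assert scaled == pytest.approx(9.0 * base, rel=1e-10)


def test_chamfer_symmetric_for_equal_sizes():
    rng = np.random.default_rng(4)
    P, G = rng.normal(size=(25, 3)), rng.normal(size=(25, 3))
    n = np.tile([1.0, 0, 0], (25, 1))
    a = chamfer_loss(make_pair(P, n, G, n), nearest_correspondences(P, G)).item()
    b = chamfer_loss(make_pair(G, n, P, n), nearest_correspondences(G, P)).item()
    assert a == pytest.approx(b, rel=1e-10)


# -------------------------------------------------------------------- normal


def test_normal_identical_is_minus_two():
    P = np.random.default_rng(5).normal(size=(10, 3))
    n = np.tile([0, 1.0, 0], (10, 1))
    pair = make_pair(P, n, P, n)
    corr = nearest_correspondences(P, P)
    assert normal_loss(pair, corr).item() == pytest.approx(-2.0, abs=1e-9)


def test_normal_orthogonal_is_zero():
    P = np.random.default_rng(6).normal(size=(10, 3))
    pair = make_pair(P, np.tile([1.0, 0, 0], (10, 1)), P, np.tile([0, 1.0, 0], (10, 1)))
    corr = nearest_correspondences(P, P)
    assert normal_loss(pair, corr).item() == pytest.approx(0.0, abs=1e-9)


def test_normal_mixed_angles_hand_value():
    """Two matched points with normal angles 0 and 60 degrees:
    -(1 + 0.5)/2 per direction, both directions: -1.5."""
    P = np.array([[0, 0, 0], [10.0, 0, 0]])
    pn = np.array([[0, 0, 1.0], [0, 0, 1.0]])
    gn = np.array([[0, 0, 1.0], [0, np.sin(np.pi / 3), 0.5]])
    pair = make_pair(P, pn, P, gn)
    corr = nearest_correspondences(P, P)
    assert normal_loss(pair, corr).item() == pytest.approx(-1.5, abs=1e-9)


def test_normal_warns_and_renormalizes_non_unit():
    P = np.array([[0.0, 0, 0]])
    pair = make_pair(P, [[0, 0, 1.0]], P, [[0, 0, 2.0]])
    corr = nearest_correspondences(P, P)
    with pytest.warns(UserWarning):
        assert normal_loss(pair, corr).item() == pytest.approx(-2.0, abs=1e-9)


# ---------------------------------------------------------------------- edge


def test_edge_unit_lengths():
    square = Tensor(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float))
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    assert edge_regularization(square, edges).item() == pytest.approx(1.0, abs=1e-12)


def test_edge_single_cube_mean():
    """Unit cube mesh: 12 edges of length 1, 6 face diagonals of length
    sqrt(2); mean squared length (12 + 12)/18 = 4/3."""
    mesh = unit_cube_mesh()
    assert edge_regularization(mesh).item() == pytest.approx(4.0 / 3.0, abs=1e-9)


def test_edge_scales_quadratically():
    mesh = unit_cube_mesh()
    doubled = mesh.with_vertices(mesh.vertices * 2.0)
    assert edge_regularization(doubled).item() == pytest.approx(4 * 4.0 / 3.0, abs=1e-9)


def test_edge_requires_edges():
    with pytest.raises(ValueError):
        edge_regularization(Tensor(np.zeros((3, 3))), np.empty((0, 2), dtype=int))


# --------------------------------------------------------------------- total


def test_total_loss_reduces_to_chamfer_without_weights():
    rng = np.random.default_rng(7)
    mesh = unit_cube_mesh()
    pairs, chams = [], []
    for _ in range(3):
        P, G = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        n = np.tile([0, 0, 1.0], (10, 1))
        pairs.append(make_pair(P, n, G, n))
        chams.append(chamfer_loss(pairs[-1], nearest_correspondences(P, G)).item())
    loss = total_loss(pairs, [mesh] * 3, LossWeights(0.0, 0.0))
    assert loss.item() == pytest.approx(sum(chams), rel=1e-9)


def test_total_loss_hand_composition():
    """One module with the hand-built pair and the unit cube:
    2 + 0.01 * (-1.5) + 0.2 * (4/3)."""
    mesh = unit_cube_mesh()
    pn = np.array([[0, 0, 1.0], [0, 0, 1.0]])
    gn = np.array([[0, 0, 1.0], [0, np.sin(np.pi / 3), 0.5]])
    # matched pairs at distance 1 along x, normals at 0 and 60 degrees
    pp = np.array([[0, 0, 0], [10.0, 0, 0]])
    gp = pp + np.array([1.0, 0, 0])
    pair = make_pair(pp, pn, gp, gn)
    loss = total_loss([pair], [mesh], LossWeights(0.01, 0.2))
    expected = 2.0 + 0.01 * (-1.5) + 0.2 * (4.0 / 3.0)
    assert loss.item() == pytest.approx(expected, abs=1e-9)


def test_total_loss_identical_prediction():
    """Perfect prediction: Lc = 0, Ln = -2, so -2 lambda1 + lambda2 Le."""
    mesh = unit_cube_mesh()
    P = np.random.default_rng(8).normal(size=(12, 3))
    n = np.tile([1.0, 0, 0], (12, 1))
    pair = make_pair(P, n, P, n)
    w = LossWeights(0.01, 0.2)
    loss = total_loss([pair], [mesh], w)
    expected = -2 * 0.01 + 0.2 * (4.0 / 3.0)
    assert loss.item() == pytest.approx(expected, abs=1e-9)


# ----------------------------------------------------------------- gradients


def test_loss_gradients_match_finite_differences():
    """Analytic gradients of Lc + lambda1 Ln + lambda2 Le with respect to
    vertex positions agree with central differences (fixed samples and
    correspondences, away from abs/relu kinks)."""
    rng = np.random.default_rng(9)
    mesh = unit_cube_mesh()
    base = mesh.vertices + rng.normal(0, 0.05, mesh.vertices.shape)
    G = rng.normal(0.5, 0.4, size=(30, 3))
    Gn = rng.normal(size=(30, 3))
    Gn /= np.linalg.norm(Gn, axis=1, keepdims=True)
    fixed_faces = rng.integers(0, mesh.n_faces, size=40)
    w = np.abs(rng.normal(size=(40, 3)))
    w /= w.sum(axis=1, keepdims=True)
    edges = mesh.edge_array()

    def loss_of(V, corr):
        Vt = Tensor(V.copy(), requires_grad=True)
        va = Vt.gather(mesh.faces[fixed_faces, 0])
        vb = Vt.gather(mesh.faces[fixed_faces, 1])
        vc = Vt.gather(mesh.faces[fixed_faces, 2])
        pp = va * w[:, :1] + vb * w[:, 1:2] + vc * w[:, 2:3]
        from myomesh.autodiff import cross

        nr = cross(vb - va, vc - va)
        pn = nr / (nr * nr).sum(axis=1, keepdims=True).sqrt()
        pair = SampledPair(pp, pn, G, Gn)
        val = (
            chamfer_loss(pair, corr)
            + 0.01 * normal_loss(pair, corr)
            + 0.2 * edge_regularization(Vt, edges)
        )
        return val, Vt

    corr = nearest_correspondences(
        np.einsum("nk,nkd->nd", w, base[mesh.faces[fixed_faces]]), G
    )
    val, Vt = loss_of(base, corr)
    val.backward()
    eps = 1e-6
    for idx in [(0, 0), (3, 1), (7, 2), (4, 0)]:
        vp, vm = base.copy(), base.copy()
        vp[idx] += eps
        vm[idx] -= eps
        fd = (loss_of(vp, corr)[0].item() - loss_of(vm, corr)[0].item()) / (2 * eps)
        assert Vt.grad[idx] == pytest.approx(fd, abs=1e-4)


def test_sampled_points_lie_on_surface():
    mesh = unit_cube_mesh()
    V = Tensor(mesh.vertices)
    pts, normals = sample_surface_differentiable(V, mesh.faces, 200, np.random.default_rng(0))
    assert pts.shape == (200, 3)
    assert np.allclose(np.linalg.norm(normals.data, axis=1), 1.0, atol=1e-6)
    # unit cube surface: every point has at least one coordinate at 0 or 1
    on_face = np.isclose(pts.data, 0.0, atol=1e-9) | np.isclose(pts.data, 1.0, atol=1e-9)
    assert on_face.any(axis=1).all()


def test_loss_weights_validate():
    with pytest.raises(ValueError):
        LossWeights(-0.1, 0.2)
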