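"""Cubify: per-voxel cube meshing with shared-face deletion and merging."""

import numpy as np
import pytest

from myomesh import EmptyMaskError, TriangleMesh, VoxelMask, cubify, merge_duplicates, mesh_stats
from myomesh.voxel_mesh import _CUBE_TRIANGLES


def test_single_voxel_counts(single_voxel_mask):
    """One voxel becomes a cube of 8 vertices, 18 edges, 12 triangles."""
    mesh = cubify(single_voxel_mask)
    stats = mesh_stats(mesh)
    assert (stats.n_vertices, stats.n_edges, stats.n_faces) == (8, 18, 12)
    assert stats.euler_characteristic == 2
    assert stats.n_boundary_edges == 0


def test_single_voxel_outward_orientation(single_voxel_mask):
    tm = cubify(single_voxel_mask).to_trimesh()
    assert tm.is_watertight and tm.is_winding_consistent
    assert tm.volume == pytest.approx(1.0)


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        cubify(VoxelMask(occupancy=np.zeros((4, 4, 4), dtype=bool)))


def test_nonpositive_spacing_rejected():
    occ = np.ones((1, 1, 1), dtype=bool)
    with pytest.raises(ValueError):
        VoxelMask(occupancy=occ, spacing=(1.0, 0.0, 1.0))


def test_two_adjacent_voxels(two_voxel_mask):
    """Shared internal wall deleted: 12 vertices, 30 edges, 20 faces."""
    stats = mesh_stats(cubify(two_voxel_mask))
    assert (stats.n_vertices, stats.n_edges, stats.n_faces) == (12, 30, 20)
    assert stats.euler_characteristic == 2


def test_bar_and_ring_topology():
    bar = np.zeros((5, 3, 3), dtype=bool)
    bar[1:4, 1, 1] = True
    assert mesh_stats(cubify(VoxelMask(bar))).euler_characteristic == 2
    ring = np.zeros((3, 5, 5), dtype=bool)
    ring[1, 1:4, 1:4] = True
    ring[1, 2, 2] = False  # 3x3 ring of voxels: a solid torus
    assert mesh_stats(cubify(VoxelMask(ring))).euler_characteristic == 0


def test_spacing_and_origin_scale_world_coordinates(single_voxel_mask):
    mask = VoxelMask(
        occupancy=single_voxel_mask.occupancy,
        spacing=(2.0, 3.0, 4.0),
        origin=(10.0, 0.0, -5.0),
    )
    mesh = cubify(mask)
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    assert np.allclose(hi - lo, mask.spacing)
    assert np.allclose(lo, mask.origin + mask.spacing)  # voxel index (1,1,1)


def _raw_cube_soup(voxels):
    """Unmerged triangle soup of per-voxel cubes (duplicate walls intact)."""
    tris = []
    for v in voxels:
        base = np.asarray(v)
        tris.append(base[None, None, :] + _CUBE_TRIANGLES)
    corners = np.concatenate(tris).reshape(-1, 3).astype(float)
    n = len(corners)
    return TriangleMesh(vertices=corners, faces=np.arange(n).reshape(-1, 3))


def test_merge_deletes_coincident_wall_pairs():
    """24 raw triangles of two adjacent cubes collapse to 20: both copies of
    the 2+2 shared-wall triangles are removed."""
    raw = _raw_cube_soup([(0, 0, 0), (1, 0, 0)])
    assert raw.n_faces == 24
    merged = merge_duplicates(raw)
    assert merged.n_faces == 20
    assert mesh_stats(merged).euler_characteristic == 2


def test_merge_idempotent(single_voxel_mask):
    mesh = cubify(single_voxel_mask)
    again = merge_duplicates(mesh)
    assert again.n_faces == mesh.n_faces
    assert again.n_vertices == mesh.n_vertices
    # identical geometry up to vertex reordering
    a = again.vertices[np.lexsort(again.vertices.T)]
    b = mesh.vertices[np.lexsort(mesh.vertices.T)]
    assert np.allclose(a, b)


def test_mesh_stats_empty_mesh():
    stats = mesh_stats(TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int)))
    assert (stats.n_vertices, stats.n_edges, stats.n_faces) == (0, 0, 0)
    assert stats.n_boundary_edges == 0


def _solid_euler_characteristic(occ):
    """Euler characteristic of the occupied cubical complex (independent
    oracle): chi(solid) = V - E + F - C over unique lattice cells."""
    verts, edges, faces = set(), set(), set()
    cells = 0
    for z, y, x in zip(*np.nonzero(occ)):
        cells += 1
        corners = [(x + dx, y + dy, z + dz) for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]
        verts.update(corners)
        for axis in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    e0 = [x, y, z]
                    e0[(axis + 1) % 3] += a
                    e0[(axis + 2) % 3] += b
                    e1 = list(e0)
                    e1[axis] += 1
                    edges.add((tuple(e0), tuple(e1)))
            for side in (0, 1):
                f = [x, y, z]
                f[axis] += side
                faces.add((axis, tuple(f)))
    return len(verts) - len(edges) + len(faces) - cells


def _has_nonmanifold_contact(occ):
    """True when two occupied voxels touch only along an edge or corner."""
    zs, ys, xs = np.nonzero(occ)
    occupied = set(zip(zs.tolist(), ys.tolist(), xs.tolist()))
    for z, y, x in occupied:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if abs(dz) + abs(dy) + abs(dx) < 2:
                        continue
                    if (z + dz, y + dy, x + dx) not in occupied:
                        continue
                    # diagonal neighbour: non-manifold unless a shared
                    # face-neighbour bridges the two
                    bridged = False
                    for axis, d in (("z", dz), ("y", dy), ("x", dx)):
                        probe = {
                            "z": (z + dz, y, x),
                            "y": (z, y + dy, x),
                            "x": (z, y, x + dx),
                        }[axis]
                        if d != 0 and probe in occupied:
                            mid = {
                                "z": (z, y + dy, x + dx),
                                "y": (z + dz, y, x + dx),
                                "x": (z + dz, y + dy, x),
                            }[axis]
                            if abs(dz) + abs(dy) + abs(dx) == 2 or mid in occupied:
                                bridged = True
                    if not bridged:
                        return True
    return False


@pytest.mark.parametrize("trial", range(20))
def test_random_solids_surface_area_and_closure(trial):
    """On random voxel solids: internal walls are gone (surface area equals
    exposed-face count) and, absent diagonal-only contact, the surface is
    closed with chi(surface) = 2 chi(solid)."""
    rng = np.random.default_rng(100 + trial)
    occ = rng.random((8, 8, 8)) < 0.35
    if not occ.any():
        occ[4, 4, 4] = True
    mask = VoxelMask(occupancy=occ)
    mesh = cubify(mask)
    # exposed-face oracle by direct adjacency scan
    exposed = 0
    padded = np.pad(occ, 1)
    for axis in range(3):
        for step in (-1, 1):
            shifted = np.roll(padded, step, axis=axis)
            exposed += int((padded & ~shifted).sum())
    assert mesh.area() == pytest.approx(exposed)
    if not _has_nonmanifold_contact(occ):
        stats = mesh_stats(mesh)
        assert stats.n_boundary_edges == 0  # every edge in exactly two faces
        assert stats.euler_characteristic == 2 * _solid_euler_characteristic(occ)


def test_translation_equivariance():
    rng = np.random.default_rng(5)
    occ = np.zeros((6, 6, 6), dtype=bool)
    occ[1:4, 2:5, 1:3] = rng.random((3, 3, 2)) < 0.7
    occ[2, 3, 1] = True
    base = cubify(VoxelMask(occ))
    shifted = np.zeros_like(occ)
    shifted[:, :, 1:] = occ[:, :, :-1]  # +1 voxel along x
    moved = cubify(VoxelMask(shifted))
    order = np.lexsort(base.vertices.T)
    order2 = np.lexsort(moved.vertices.T)
    assert np.allclose(moved.vertices[order2], base.vertices[order] + [1, 0, 0])
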