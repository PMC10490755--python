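"""Shared fixtures: tiny voxel solids and desk-scale synthetic shells."""

import numpy as np
import pytest

from myomesh.synthetic_data import Case, ShellSpec, generate_shell
from myomesh.types import VoxelMask


@pytest.fixture
def single_voxel_mask():
    occ = np.zeros((3, 3, 3), dtype=bool)
    occ[1, 1, 1] = True
    return VoxelMask(occupancy=occ)


@pytest.fixture
def two_voxel_mask():
    occ = np.zeros((3, 3, 4), dtype=bool)
    occ[1, 1, 1] = occ[1, 1, 2] = True
    return VoxelMask(occupancy=occ)


@pytest.fixture(scope="session")
def small_shell():
    """One desk-scale shell (40-cube grid) with mild twist/bend, no noise."""
    spec = ShellSpec(
        outer_axes=(10.0, 9.0, 15.0),
        thickness=3.0,
        truncation=0.75,
        twist_deg=6.0,
        bend=0.04,
        noise_p=0.0,
        grid_size=40,
        seed=7,
        mesh_theta=40,
        mesh_rings=24,
    )
    mask, label = generate_shell(spec)
    return Case(mask=mask, label=label, case_id="small_shell")


@pytest.fixture(scope="session")
def shell_cloud(small_shell):
    """Vertex point cloud of the cubified small shell, normalized."""
    from myomesh import cubify

    mesh = cubify(small_shell.mask)
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    return (v / np.abs(v).max()).astype(np.float32)
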