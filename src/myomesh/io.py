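"""Reading and writing the pipeline's file formats.

Masks travel as NIfTI volumes (any nonzero voxel is occupied); meshes as
PLY (binary little-endian), OBJ or ASCII STL, chosen by file extension.
NIfTI arrays are indexed (i, j, k) = (x, y, z); internally occupancy grids
are indexed [z, y, x], so axes are transposed on the way in and out.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .types import TriangleMesh, VoxelMask

logger = logging.getLogger(__name__)

__all__ = ["load_mask", "save_mask", "load_mesh", "save_mesh"]


def load_mask(path, spacing_override=None) -> VoxelMask:
    """Read a binary NIfTI volume as a VoxelMask (nonzero = occupied)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    occupancy = np.transpose(data != 0, (2, 1, 0))  # (x,y,z) -> (z,y,x)
    if spacing_override is not None:
        spacing = np.asarray(spacing_override, dtype=float)
    else:
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    affine = img.affine
    origin = affine[:3, 3].astype(float)
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.abs(off_diag).max() > 1e-6:
        logger.warning(
            "non-axis-aligned NIfTI affine; using voxel spacing and translation only"
        )
    return VoxelMask(occupancy=occupancy, spacing=spacing, origin=origin)


def save_mask(mask: VoxelMask, path) -> None:
    """Write a VoxelMask as an uint8 NIfTI volume."""
    import nibabel as nib

    data = np.transpose(mask.occupancy.astype(np.uint8), (2, 1, 0))
    affine = np.diag([*mask.spacing, 1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_mesh(path) -> TriangleMesh:
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return TriangleMesh.from_trimesh(tm)


def save_mesh(mesh: TriangleMesh, path, vertex_scalars=None) -> None:
    """Write PLY/OBJ/STL by extension; optional per-vertex scalar is encoded
    as a viridis vertex colour (PLY only), used by difference maps."""
    tm = mesh.to_trimesh()
    path = Path(path)
    if vertex_scalars is not None and path.suffix.lower() == ".ply":
        from matplotlib import cm

        s = np.asarray(vertex_scalars, dtype=float)
        rng = s.max() - s.min()
        norm = (s - s.min()) / (rng if rng > 0 else 1.0)
        tm.visual.vertex_colors = (cm.viridis(norm) * 255).astype(np.uint8)
    tm.export(str(path))
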