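"""Core containers: voxel masks and triangular meshes.

Coordinate convention (documented once, used everywhere): occupancy grids are
indexed ``[z, y, x]`` as produced by stacking short-axis segmentation slices;
world coordinates are ``(x, y, z)`` in millimetres.  Voxel ``(iz, iy, ix)``
occupies the axis-aligned cell ``origin + (ix, iy, iz) * spacing`` to
``origin + (ix+1, iy+1, iz+1) * spacing``; mesh vertices produced from a mask
sit on cell corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class VoxelMask:
    """Binary occupancy grid of the left myocardium with physical metadata.

    Parameters
    ----------
    occupancy : (Z, Y, X) bool array
        True where the voxel belongs to the myocardium.
    spacing : (3,) float array
        Physical voxel size (sx, sy, sz) in mm; strictly positive.
    origin : (3,) float array
        World coordinate of the corner of voxel (0, 0, 0), in mm.
    """

    occupancy: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array indexed [z, y, x]")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive on all axes")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class TriangleMesh:
    """Triangle surface mesh: world-coordinate vertices and index faces.

    The edge set is derived from the faces; an edge is an unordered vertex
    pair appearing in at least one face.  For a closed manifold every edge is
    shared by exactly two faces and V - E + F = 2 - 2g.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")

    # ------------------------------------------------------------------ edges
    def edge_array(self, unique: bool = True) -> np.ndarray:
        """Edges as an (E, 2) array of sorted vertex-index pairs."""
        if len(self.faces) == 0:
            return np.empty((0, 2), dtype=np.int64)
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        if unique:
            e = np.unique(e, axis=0)
        return e

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self.edge_array())

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    # --------------------------------------------------------------- geometry
    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        n = np.cross(
            v[self.faces[:, 1]] - v[self.faces[:, 0]],
            v[self.faces[:, 2]] - v[self.faces[:, 0]],
        )
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.maximum(norms, 1e-30)
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new vertex positions."""
        return TriangleMesh(vertices=np.asarray(vertices, dtype=float), faces=self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    # ---------------------------------------------------------------- interop
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))
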