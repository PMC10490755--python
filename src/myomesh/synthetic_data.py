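"""Synthetic left-myocardium-like cases with analytic ground truth.

Clinical cardiac MR segmentations are not distributable, so training and
evaluation run on an idealization of the left-ventricular myocardium: a
thick-walled ellipsoidal shell, truncated at the base, with annular
short-axis cross-sections.  Optional smooth twist/bend deformations vary the
anatomy between subjects, and Bernoulli flips of boundary voxels emulate the
raggedness of real segmentation masks.  The ground-truth label surface is
the smooth analytic shell (outer wall + inner wall + basal rim), closed and
manifold, so surface sampling on labels never fails.

Augmentation mirrors the clinical protocol: a seeded random rigid transform
plus isotropic scaling applied consistently to the mask (nearest-neighbour
resampling) and the label mesh.  A dataset manifest reproduces the study
proportions — 10 base anatomies augmented to 80 cases, split 60 train /
20 validation, with a separate pool of held-out test anatomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .types import TriangleMesh, VoxelMask

__all__ = [
    "ShellSpec",
    "Case",
    "CaseDescriptor",
    "DatasetManifest",
    "generate_shell",
    "augment",
    "make_dataset",
    "random_spec",
]


@dataclass
class ShellSpec:
    """Analytic description of one myocardium-like shell.

    All lengths are in voxels of the target grid.  The solid is the region
    between two confocal-ish ellipsoids (outer semi-axes ``outer_axes``,
    inner semi-axes reduced by ``thickness``), kept below the basal
    truncation plane.  ``truncation`` is the fraction of the outer z-extent
    retained, measured from the apex; it must cut through both surfaces so
    the wall is a genus-0 solid with an annular rim.
    """

    outer_axes: tuple = (23.0, 23.0, 37.0)
    thickness: float = 6.0
    truncation: float = 0.75
    twist_deg: float = 0.0
    bend: float = 0.0
    noise_p: float = 0.0
    slice_jitter: float = 0.0
    grid_size: int = 96
    seed: int = 0
    mesh_theta: int = 64
    mesh_rings: int = 40

    def __post_init__(self):
        a, b, c = self.outer_axes
        if self.thickness <= 0 or self.thickness >= min(a, b, c):
            raise ValueError("wall thickness must be positive and below the smallest semi-axis")
        if not 0 < self.truncation <= 1:
            raise ValueError("truncation fraction must lie in (0, 1]")
        z_cut = self.z_cut
        if not -(c - self.thickness) < z_cut < (c - self.thickness):
            raise ValueError(
                "truncation plane must cut both the outer and inner surfaces "
                "(adjust truncation or thickness)"
            )
        if 2 * max(a, b) + 4 > self.grid_size or 2 * c + 4 > self.grid_size:
            raise ValueError("grid too small to contain the shell")

    @property
    def z_cut(self) -> float:
        """Basal truncation plane height (apex at z = -c)."""
        return self.outer_axes[2] * (2.0 * self.truncation - 1.0)


@dataclass
class Case:
    """One dataset case: voxel mask plus analytic label surface."""

    mask: VoxelMask
    label: TriangleMesh
    case_id: str = ""
    meta: dict = field(default_factory=dict)


# ------------------------------------------------------------- deformation


def _deform(points: np.ndarray, spec: ShellSpec) -> np.ndarray:
    """Forward smooth deformation: twist about the long axis then lateral
    bend; z is preserved, so the map is exactly invertible."""
    c = spec.outer_axes[2]
    p = np.array(points, dtype=float)
    if spec.twist_deg:
        ang = np.radians(spec.twist_deg) * (p[..., 2] / c)
        ca, sa = np.cos(ang), np.sin(ang)
        x, y = p[..., 0].copy(), p[..., 1].copy()
        p[..., 0] = ca * x - sa * y
        p[..., 1] = sa * x + ca * y
    if spec.bend:
        p[..., 0] = p[..., 0] + spec.bend * c * (p[..., 2] / c) ** 2
    return p


def _undeform(points: np.ndarray, spec: ShellSpec) -> np.ndarray:
    c = spec.outer_axes[2]
    p = np.array(points, dtype=float)
    if spec.bend:
        p[..., 0] = p[..., 0] - spec.bend * c * (p[..., 2] / c) ** 2
    if spec.twist_deg:
        ang = -np.radians(spec.twist_deg) * (p[..., 2] / c)
        ca, sa = np.cos(ang), np.sin(ang)
        x, y = p[..., 0].copy(), p[..., 1].copy()
        p[..., 0] = ca * x - sa * y
        p[..., 1] = sa * x + ca * y
    return p


# -------------------------------------------------------------- generation


def generate_shell(spec: ShellSpec) -> tuple[VoxelMask, TriangleMesh]:
    """Rasterize the shell into a voxel mask and triangulate its analytic
    label surface (closed, manifold, consistently outward-oriented)."""
    g = spec.grid_size
    center = np.full(3, g / 2.0)
    a, b, c = spec.outer_axes
    t = spec.thickness
    zc, yc, xc = np.meshgrid(
        np.arange(g) + 0.5, np.arange(g) + 0.5, np.arange(g) + 0.5, indexing="ij"
    )
    w = np.stack([xc, yc, zc], axis=-1) - center
    u = _undeform(w, spec)
    q_out = (u[..., 0] / a) ** 2 + (u[..., 1] / b) ** 2 + (u[..., 2] / c) ** 2
    q_in = (u[..., 0] / (a - t)) ** 2 + (u[..., 1] / (b - t)) ** 2 + (
        u[..., 2] / (c - t)
    ) ** 2
    occ = (q_out <= 1.0) & (q_in >= 1.0) & (u[..., 2] <= spec.z_cut)
    rng = np.random.default_rng(spec.seed)
    if spec.slice_jitter > 0:
        # inter-slice inconsistency of stacked 2D segmentations: whole
        # short-axis slices shifted laterally by one voxel
        for iz in range(g):
            if occ[iz].any() and rng.random() < spec.slice_jitter:
                axis = int(rng.integers(2))
                step = int(rng.choice([-1, 1]))
                occ[iz] = np.roll(occ[iz], step, axis=axis)
    if spec.noise_p > 0:
        boundary = occ ^ ndimage.binary_erosion(occ)
        boundary |= ndimage.binary_dilation(occ) ^ occ
        flips = boundary & (rng.random(occ.shape) < spec.noise_p)
        occ = occ ^ flips
    mask = VoxelMask(occupancy=occ, spacing=np.ones(3), origin=np.zeros(3))
    label = _shell_label_mesh(spec)
    label.vertices = _deform(label.vertices, spec) + center
    return mask, TriangleMesh(label.vertices, label.faces)


def _ring(axes_ab, phi: float, n_theta: int, cz: float) -> np.ndarray:
    """One latitude ring of an ellipsoid at polar angle phi (apex: phi=pi)."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    s = np.sin(phi)
    return np.stack(
        [axes_ab[0] * s * np.cos(theta), axes_ab[1] * s * np.sin(theta),
         np.full(n_theta, cz * np.cos(phi))],
        axis=1,
    )


def _lathe_faces(ring_index: Sequence[int], n_theta: int, apex: int | None, flip: bool):
    """Triangles of a surface of revolution given ring start offsets."""
    faces = []
    if apex is not None:
        first = ring_index[0]
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            tri = (apex, first + jn, first + j)
            faces.append(tri[::-1] if flip else tri)
    for r0, r1 in zip(ring_index[:-1], ring_index[1:]):
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            q = [(r0 + j, r0 + jn, r1 + jn), (r0 + j, r1 + jn, r1 + j)]
            for tri in q:
                faces.append(tuple(reversed(tri)) if flip else tri)
    return faces


def _shell_label_mesh(spec: ShellSpec) -> TriangleMesh:
    """Triangulate outer wall + inner wall + basal rim in undeformed,
    centered coordinates."""
    a, b, c = spec.outer_axes
    t = spec.thickness
    nt = spec.mesh_theta
    z_cut = spec.z_cut

    def surface(axes, rings_total):
        ax, bx, cx = axes
        phi_cut = np.arccos(np.clip(z_cut / cx, -1.0, 1.0))
        phis = np.linspace(np.pi, phi_cut, rings_total + 1)[1:]
        rings = [_ring((ax, bx), phi, nt, cx) for phi in phis]
        apex = np.array([[0.0, 0.0, -cx]])
        return apex, rings

    n_out = spec.mesh_rings
    n_in = max(8, int(round(spec.mesh_rings * (c - t) / c)))
    apex_o, rings_o = surface((a, b, c), n_out)
    apex_i, rings_i = surface((a - t, b - t, c - t), n_in)

    verts = [apex_o] + rings_o + [apex_i] + rings_i
    offsets, total = [], 0
    for v in verts:
        offsets.append(total)
        total += len(v)
    vertices = np.concatenate(verts)

    out_rings = offsets[1 : 1 + n_out]
    in_start = 1 + n_out
    in_rings = offsets[in_start + 1 : in_start + 1 + n_in]
    faces = []
    faces += _lathe_faces(out_rings, nt, apex=offsets[0], flip=False)
    faces += _lathe_faces(in_rings, nt, apex=offsets[in_start], flip=True)
    # basal rim: outer top ring to inner top ring, normal +z
    o_top, i_top = out_rings[-1], in_rings[-1]
    for j in range(nt):
        jn = (j + 1) % nt
        faces.append((o_top + j, o_top + jn, i_top + jn))
        faces.append((o_top + j, i_top + jn, i_top + j))
    return TriangleMesh(vertices=vertices, faces=np.asarray(faces))


# ------------------------------------------------------------- augmentation


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.radians(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx

def augment(
    case: Case,
    seed: int,
    max_rotation_deg: float = 15.0,
    scale_range: tuple = (0.8, 1.2),
    max_translation: float = 4.0,
) -> Case:
    """Random rigid transform + isotropic scale applied consistently to mask
    (nearest-neighbour resampling about the grid centre) and label mesh."""
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    s = rng.uniform(*scale_range)
    trans = rng.uniform(-max_translation, max_translation, size=3)
    R = _rotation_matrix(angles)
    shape = case.mask.occupancy.shape
    ctr = np.array([shape[2], shape[1], shape[0]], dtype=float) / 2.0  # (x, y, z)

    new_label = case.label.with_vertices(
        (case.label.vertices - ctr) @ R.T * s + ctr + trans
    )
    # resample mask: input index = J M (J o + 0.5) + ... with J the axis
    # reversal between index order (z, y, x) and world order (x, y, z)
    J = np.eye(3)[::-1]
    M_world = R.T / s  # inverse of w -> s R w
    matrix = J @ M_world @ J
    off_world = M_world @ (0.5 - ctr - trans) + ctr - 0.5
    offset = J @ off_world
    occ = ndimage.affine_transform(
        case.mask.occupancy.astype(np.uint8), matrix, offset=offset, order=0,
        mode="constant", cval=0,
    ).astype(bool)
    meta = dict(case.meta)
    meta["augment"] = {
        "seed": int(seed),
        "angles_deg": angles.tolist(),
        "scale": float(s),
        "translation": trans.tolist(),
    }
    return Case(
        mask=VoxelMask(occ, case.mask.spacing, case.mask.origin),
        label=new_label,
        case_id=f"{case.case_id}+aug{seed}",
        meta=meta,
    )


# ----------------------------------------------------------------- dataset


def random_spec(
    rng: np.random.Generator,
    grid_size: int = 96,
    noise_p: float = 0.1,
    slice_jitter: float = 0.4,
    scale: float = 1.0,
) -> ShellSpec:
    """Draw one anatomy from the study's spec ranges (semi-axes a, b in
    [18, 28], c in [30, 45], wall thickness in [4, 8] voxels on a 96-cube
    grid; `scale` shrinks everything proportionally for desk-scale runs).

    Mask degradation defaults emulate segmentation-derived masks rather than
    clean rasterizations: boundary Bernoulli flips plus per-slice lateral
    jitter, sized so the initial cubified surface is substantially worse
    than the reconstruction target (the regime the deformation network is
    built for).
    """
    a = rng.uniform(18, 28) * scale
    b = rng.uniform(18, 28) * scale
    c = rng.uniform(30, 45) * scale
    t = rng.uniform(4, 8) * scale
    return ShellSpec(
        outer_axes=(a, b, c),
        thickness=max(t, 2.0),
        truncation=rng.uniform(0.68, 0.82),
        twist_deg=rng.uniform(0, 12),
        bend=rng.uniform(0, 0.08),
        noise_p=noise_p,
        slice_jitter=slice_jitter,
        grid_size=grid_size,
        seed=int(rng.integers(2**31 - 1)),
        mesh_theta=max(24, int(64 * scale)),
        mesh_rings=max(16, int(40 * scale)),
    )


@dataclass
class CaseDescriptor:
    """Reproducible recipe for one case (realized lazily)."""

    case_id: str
    split: str  # train | val | test
    base_seed: int
    augment_seed: int | None = None

    def realize(
        self,
        grid_size: int = 96,
        noise_p: float = 0.1,
        scale: float = 1.0,
        slice_jitter: float = 0.4,
    ) -> Case:
        rng = np.random.default_rng(self.base_seed)
        spec = random_spec(
            rng, grid_size=grid_size, noise_p=noise_p, slice_jitter=slice_jitter, scale=scale
        )
        mask, label = generate_shell(spec)
        case = Case(mask=mask, label=label, case_id=self.case_id, meta={"spec_seed": self.base_seed})
        if self.augment_seed is not None:
            case = augment(case, self.augment_seed)
            case.case_id = self.case_id
        return case


@dataclass
class DatasetManifest:
    """All case recipes plus the generation parameters they share."""

    cases: list
    grid_size: int = 96
    noise_p: float = 0.1
    slice_jitter: float = 0.4
    scale: float = 1.0
    master_seed: int = 0

    def split(self, name: str) -> list:
        return [c for c in self.cases if c.split == name]

    def realize(self, name: str) -> Iterator[Case]:
        for desc in self.split(name):
            yield desc.realize(
                self.grid_size, self.noise_p, self.scale, self.slice_jitter
            )

    def to_rows(self) -> list[dict]:
        return [
            {
                "case_id": c.case_id,
                "split": c.split,
                "base_seed": c.base_seed,
                "augment_seed": "" if c.augment_seed is None else c.augment_seed,
            }
            for c in self.cases
        ]


def make_dataset(
    n_base: int = 10,
    n_augment: int = 80,
    splits: tuple = (60, 20),
    n_test: int = 10,
    seed: int = 0,
    grid_size: int = 96,
    noise_p: float = 0.1,
    slice_jitter: float = 0.4,
    scale: float = 1.0,
) -> DatasetManifest:
    """Build a reproducible manifest mirroring the study proportions.

    `n_base` anatomies are expanded to `n_augment` cases by augmentation
    (the first variant of each anatomy is the identity), randomly assigned
    to train/val according to `splits`; `n_test` fresh anatomies form the
    held-out test pool.
    """
    if sum(splits) != n_augment:
        raise ValueError("train+val split sizes must sum to n_augment")
    if n_augment % n_base != 0:
        raise ValueError("n_augment must be a multiple of n_base")
    rng = np.random.default_rng(seed)
    per_base = n_augment // n_base
    base_seeds = rng.integers(2**31 - 1, size=n_base + n_test)
    cases = []
    for i in range(n_base):
        for v in range(per_base):
            cases.append(
                CaseDescriptor(
                    case_id=f"shell{i:03d}v{v}",
                    split="train",  # reassigned below
                    base_seed=int(base_seeds[i]),
                    augment_seed=None if v == 0 else int(rng.integers(2**31 - 1)),
                )
            )
    order = rng.permutation(n_augment)
    for rank, idx in enumerate(order):
        cases[idx].split = "train" if rank < splits[0] else "val"
    for j in range(n_test):
        cases.append(
            CaseDescriptor(
                case_id=f"test{j:03d}",
                split="test",
                base_seed=int(base_seeds[n_base + j]),
            )
        )
    return DatasetManifest(
        cases=cases,
        grid_size=grid_size,
        noise_p=noise_p,
        slice_jitter=slice_jitter,
        scale=scale,
        master_seed=seed,
    )
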