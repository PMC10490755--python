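"""Per-vertex skeleton features from the initial mesh's point cloud.

The vertices of the cubified mesh are treated as a point cloud and encoded by
a hierarchy of set-abstraction levels (sample -> group -> mini-PointNet),
then decoded back to every original vertex by inverse-distance interpolation
with skip connections — an encoder/decoder in the PointNet++ family, with one
departure: centroid *sampling is curvature-aware* rather than uniform or
farthest-point.  A pseudo-curvature score (mean angle between each
neighbour direction and the point's fitted tangent plane) splits the cloud
into a "geometric" region (score above a threshold, default 5 degrees) and a
"flat" region, and the geometric region is sampled at twice the per-point
rate, so creases, the apex and the rim keep more centroids.

The geometry-dependent part of the computation (centroid choice, grouping
indices, interpolation weights) depends only on coordinates, so it is
precomputed once per mesh as a :class:`FeaturePlan`; the learned part
(:class:`VertexFeatureNet`) runs on the plan and is differentiable.
The decoder output is one 128-dimensional feature per original vertex — the
feature field ``P`` fused into every mesh deformation module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Parameter, Tensor, concat

__all__ = [
    "CurvatureScore",
    "SetAbstractionConfig",
    "SkeletonLevels",
    "FeaturePlan",
    "MiniPointNet",
    "VertexFeatureNet",
    "estimate_pseudo_curvature",
    "partition_regions",
    "geometric_subsample",
    "group",
    "encode_local",
    "build_feature_plan",
]


# --------------------------------------------------------------- curvature


@dataclass
class CurvatureScore:
    """Per-point pseudo-curvature angles (degrees) and region labels."""

    angles: np.ndarray  # (N,) mean neighbour angle above tangent plane
    geometric: np.ndarray  # (N,) bool; True where angle exceeds the threshold
    threshold: float


def estimate_pseudo_curvature(points: np.ndarray, k: int = 16) -> np.ndarray:
    """Mean angle (degrees) between each point's neighbour directions and its
    fitted tangent plane; 0 for locally planar data, larger where curvature
    is larger.

    The tangent plane is the principal plane of the k nearest neighbours
    (smallest-eigenvalue direction of their scatter is the normal).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n <= k:
        k = max(1, n - 1)
    if k < 1:
        return np.zeros(n)
    _, idx = cKDTree(points).query(points, k=k + 1)
    nbr = points[idx[:, 1:]]  # (N, k, 3) neighbours excluding self
    d = nbr - points[:, None, :]
    lengths = np.linalg.norm(d, axis=2)
    degenerate = lengths.max(axis=1) < 1e-12
    if degenerate.any():
        warnings.warn("degenerate (coincident) neighbourhoods; curvature set to 0")
    centered = d - d.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, :, 0]  # smallest-eigenvalue direction
    sin_angle = np.abs(np.einsum("nki,ni->nk", d, normal)) / np.maximum(lengths, 1e-30)
    angles = np.degrees(np.arcsin(np.clip(sin_angle, -1.0, 1.0))).mean(axis=1)
    angles[degenerate] = 0.0
    return angles


def partition_regions(angles: np.ndarray, threshold: float = 5.0) -> CurvatureScore:
    """Label points with angle above `threshold` (degrees) as geometric."""
    if threshold <= 0:
        raise ValueError("curvature threshold must be positive")
    angles = np.asarray(angles, dtype=float)
    return CurvatureScore(angles=angles, geometric=angles > threshold, threshold=threshold)


def geometric_subsample(
    points: np.ndarray,
    n: int,
    threshold: float = 5.0,
    rng: np.random.Generator | int | None = 0,
    oversample: float = 2.0,
    curvature_k: int = 16,
    scores: CurvatureScore | None = None,
):
    """Draw exactly `n` centroid points, oversampling the high-curvature region.

    Sampling is uniform *within* each region; the geometric region's quota is
    proportional to ``oversample`` per point (largest-remainder rounding,
    clipped to region sizes).  Falls back to plain uniform sampling when one
    region is empty.

    Returns
    -------
    (sampled points, index array into `points`)
    """
    points = np.asarray(points, dtype=float)
    N = len(points)
    if not 1 <= n <= N:
        raise ValueError(f"sample count {n} outside [1, {N}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if scores is None:
        scores = partition_regions(estimate_pseudo_curvature(points, k=curvature_k), threshold)
    geo = np.flatnonzero(scores.geometric)
    flat = np.flatnonzero(~scores.geometric)
    if len(geo) == 0 or len(flat) == 0:
        idx = rng.choice(N, size=n, replace=False)
        return points[idx], idx
    w_geo = oversample * len(geo)
    quota_geo = int(np.floor(n * w_geo / (w_geo + len(flat))))
    remainder = n * w_geo / (w_geo + len(flat)) - quota_geo
    if remainder >= 0.5:
        quota_geo += 1
    quota_geo = min(max(quota_geo, n - len(flat)), len(geo), n)
    quota_flat = n - quota_geo
    idx = np.concatenate(
        [
            rng.choice(geo, size=quota_geo, replace=False),
            rng.choice(flat, size=quota_flat, replace=False),
        ]
    )
    return points[idx], idx


# ----------------------------------------------------------------- grouping


@dataclass
class GroupedRegions:
    """K-nearest-neighbour regions around each centroid."""

    indices: np.ndarray  # (C, K) indices into the source cloud
    relative: np.ndarray  # (C, K, 3) point - centroid


def group(centroids: np.ndarray, cloud: np.ndarray, K: int) -> GroupedRegions:
    """Assign each centroid its K nearest cloud points, in centroid-relative
    coordinates (translation-invariant by construction)."""
    centroids = np.asarray(centroids, dtype=float)
    cloud = np.asarray(cloud, dtype=float)
    if K > len(cloud):
        raise ValueError("K exceeds cloud size")
    _, idx = cKDTree(cloud).query(centroids, k=K)
    idx = idx.reshape(len(centroids), K)
    relative = cloud[idx] - centroids[:, None, :]
    return GroupedRegions(indices=idx, relative=relative)


# ------------------------------------------------------------------ network


@dataclass
class SetAbstractionConfig:
    """Architecture of the feature encoder/decoder.

    Defaults target a ~2000-vertex initial mesh; `for_cloud_size` rescales
    centroid counts proportionally for other sizes.
    """

    n_centroids: Sequence[int] = (512, 128, 32)
    group_k: int = 32
    encoder_widths: Sequence[Sequence[int]] = ((64, 64), (128, 128), (256, 256))
    decoder_widths: Sequence[int] = (256, 128, 128)
    feature_dim: int = 128
    curvature_k: int = 16
    curvature_threshold: float = 5.0
    oversample: float = 2.0

    def __post_init__(self):
        c = tuple(self.n_centroids)
        if any(a <= b for a, b in zip(c, c[1:])):
            raise ValueError("centroid counts must be strictly decreasing")
        if self.group_k < 3:
            raise ValueError("grouping neighbourhood K must be >= 3")
        if len(self.encoder_widths) != len(c) or len(self.decoder_widths) != len(c):
            raise ValueError("need one encoder and one decoder stage per level")

    def scaled_centroids(self, n_points: int) -> "SetAbstractionConfig":
        """Copy of this config with centroid counts rescaled to a cloud of
        `n_points` (reference size 2000), widths unchanged — the per-case
        geometry varies, the learned weights are shared."""
        from dataclasses import replace

        base = np.asarray(self.n_centroids, dtype=float) * n_points / 2000.0
        cents = np.maximum(np.round(base).astype(int), [12, 6, 3][: len(self.n_centroids)])
        cents = np.minimum(cents, max(n_points - 1, 3))
        for i in range(1, len(cents)):
            cents[i] = min(cents[i], cents[i - 1] - 1)
        cents = np.maximum(cents, 1)
        return replace(self, n_centroids=tuple(int(c) for c in cents))

    @classmethod
    def for_cloud_size(cls, n_points: int, width_scale: float = 1.0, **kw) -> "SetAbstractionConfig":
        """Scale centroid counts to the cloud size and optionally thin widths."""
        base = np.array([512, 128, 32]) * n_points / 2000.0
        cents = np.maximum(np.round(base).astype(int), [12, 6, 3])
        cents = np.minimum(cents, max(n_points - 1, 3))
        # enforce strict decrease
        for i in range(1, 3):
            cents[i] = min(cents[i], cents[i - 1] - 1)
        cents = np.maximum(cents, [3, 2, 1])
        enc = tuple(
            tuple(max(8, int(round(w * width_scale))) for w in level)
            for level in ((64, 64), (128, 128), (256, 256))
        )
        dec = tuple(max(8, int(round(w * width_scale))) for w in (256, 128))
        return cls(
            n_centroids=tuple(int(c) for c in cents),
            encoder_widths=enc,
            decoder_widths=dec + (128,),  # decoder always ends at feature_dim
            **kw,
        )


@dataclass
class SkeletonLevels:
    """Centroid coordinates and features per abstraction level (the learned
    skeleton of the shape, coarser at each level)."""

    points: list  # list of (C_i, 3) arrays
    features: list  # list of Tensors (C_i, W_i)


@dataclass
class FeaturePlan:
    """Geometry-only precomputation for one point cloud: centroid choices,
    grouping indices and interpolation weights for every level.

    `skeleton_displacements` holds, per original vertex, the vector from the
    vertex to the inverse-distance-weighted position of its nearest skeleton
    centroids at every abstraction level — the point-to-skeleton offset at
    increasing receptive fields, fused into mesh deformation alongside the
    learned features.
    """

    original_points: np.ndarray
    level_points: list = field(default_factory=list)
    sample_indices: list = field(default_factory=list)
    groups: list = field(default_factory=list)  # GroupedRegions per level
    interp: list = field(default_factory=list)  # (idx (Nf,3), w (Nf,3)) coarse->fine
    skeleton_displacements: np.ndarray | None = None  # (N, 3 * levels)


def build_feature_plan(
    points: np.ndarray, config: SetAbstractionConfig, seed: int | None = 0
) -> FeaturePlan:
    """Run the non-learned geometry pipeline once: curvature-aware sampling,
    grouping and interpolation neighbourhoods for all levels.

    The cloud is centered internally, so the plan (and hence the decoded
    feature field) is invariant to global translation of the input.
    """
    points = np.asarray(points, dtype=np.float64)
    points = points - points.mean(axis=0)
    rng = np.random.default_rng(seed)
    plan = FeaturePlan(original_points=points)
    current = points
    for n_c in config.n_centroids:
        if n_c > len(current):
            raise ValueError(
                f"centroid count {n_c} exceeds available points {len(current)}"
            )
        _, idx = geometric_subsample(
            current,
            n_c,
            threshold=config.curvature_threshold,
            rng=rng,
            oversample=config.oversample,
            curvature_k=config.curvature_k,
        )
        centroids = current[idx]
        regions = group(centroids, current, min(config.group_k, len(current)))
        regions.relative = regions.relative.astype(np.float32)
        plan.sample_indices.append(idx)
        plan.level_points.append(centroids)
        plan.groups.append(regions)
        current = centroids
    # interpolation plans, coarsest level back to the original cloud
    fine_sets = [points] + plan.level_points[:-1]
    for level in range(len(config.n_centroids) - 1, -1, -1):
        coarse = plan.level_points[level]
        fine = fine_sets[level]
        k = min(3, len(coarse))
        d, idx = cKDTree(coarse).query(fine, k=k)
        d = d.reshape(len(fine), k)
        idx = idx.reshape(len(fine), k)
        w = 1.0 / (d + 1e-8)
        w = (w / w.sum(axis=1, keepdims=True)).astype(np.float32)
        plan.interp.append((idx, w))
    plan.interp.reverse()  # interp[level] maps level's centroids -> finer set
    # point-to-skeleton displacement at every level
    disp = []
    for centroids in plan.level_points:
        k = min(3, len(centroids))
        d, idx = cKDTree(centroids).query(points, k=k)
        d = d.reshape(len(points), k)
        idx = idx.reshape(len(points), k)
        w = 1.0 / (d + 1e-8)
        w = w / w.sum(axis=1, keepdims=True)
        nearest = np.einsum("nk,nkd->nd", w, centroids[idx])
        disp.append(nearest - points)
    plan.skeleton_displacements = np.concatenate(disp, axis=1).astype(np.float32)
    return plan


class MiniPointNet:
    """Shared per-point MLP followed by symmetric max-pooling over each
    region — permutation-invariant by construction."""

    def __init__(self, in_dim: int, widths: Sequence[int], rng: np.random.Generator):
        self.layers = []
        d = in_dim
        for w in widths:
            bound = np.sqrt(6.0 / d)
            self.layers.append(
                (
                    Parameter(rng.uniform(-bound, bound, size=(d, w))),
                    Parameter(np.zeros(w)),
                )
            )
            d = w
        self.out_dim = d

    def __call__(self, x: Tensor) -> Tensor:
        """x: (C, K, in_dim) region tensor -> (C, out_dim) pooled features."""
        for W, b in self.layers:
            x = (x @ W + b).relu()
        return x.amax(axis=1)

    def parameters(self):
        return [p for layer in self.layers for p in layer]


class _PointMLP:
    """Shared per-point MLP (no pooling), used by the decoder."""

    def __init__(self, in_dim: int, widths: Sequence[int], rng: np.random.Generator):
        self.layers = []
        d = in_dim
        for w in widths:
            bound = np.sqrt(6.0 / d)
            self.layers.append(
                (
                    Parameter(rng.uniform(-bound, bound, size=(d, w))),
                    Parameter(np.zeros(w)),
                )
            )
            d = w
        self.out_dim = d

    def __call__(self, x: Tensor) -> Tensor:
        for W, b in self.layers:
            x = (x @ W + b).relu()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer]


def encode_local(regions: GroupedRegions, encoder: MiniPointNet, features: Tensor | None = None) -> Tensor:
    """Encode each local region into one feature vector.

    Region input is the relative coordinates, concatenated with the source
    points' feature vectors when present; output is order-invariant within
    each region (max-pool symmetry).
    """
    x = Tensor(regions.relative)
    if features is not None:
        x = concat([x, features.gather(regions.indices)], axis=-1)
    return encoder(x)


class VertexFeatureNet:
    """Encoder-decoder producing a `feature_dim` vector per original vertex."""

    def __init__(self, config: SetAbstractionConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoders = []
        in_dim = 3  # relative coordinates only at the first level
        for widths in config.encoder_widths:
            enc = MiniPointNet(in_dim, widths, rng)
            self.encoders.append(enc)
            in_dim = 3 + enc.out_dim
        self.decoders = []
        L = len(config.n_centroids)
        coarse_dim = self.encoders[-1].out_dim
        for step in range(L):
            # steps L-1..1 concatenate the same-level skip features; step 0
            # (back to the original cloud) has no skip
            level = L - 2 - step
            skip_dim = self.encoders[level].out_dim if level >= 0 else 0
            out_w = config.decoder_widths[step] if step < L - 1 else config.feature_dim
            dec = _PointMLP(coarse_dim + skip_dim, (out_w,), rng)
            self.decoders.append(dec)
            coarse_dim = dec.out_dim

    # ------------------------------------------------------------- operations
    def set_abstraction(self, plan: FeaturePlan) -> SkeletonLevels:
        """Encoder pass: sample -> group -> encode at every level."""
        feats = None
        levels = SkeletonLevels(points=list(plan.level_points), features=[])
        for regions, encoder in zip(plan.groups, self.encoders):
            feats = encode_local(regions, encoder, feats)
            levels.features.append(feats)
        return levels

    def decode_interpolate(self, skeleton: SkeletonLevels, plan: FeaturePlan) -> Tensor:
        """Decoder pass: propagate skeleton features back to every original
        vertex by inverse-distance interpolation plus skip connections."""
        L = len(skeleton.features)
        f = skeleton.features[-1]
        for step, dec in enumerate(self.decoders):
            level = L - 1 - step  # level whose centroids currently hold f
            idx, w = plan.interp[level]
            interp = _interpolate(f, idx, w)
            skip_level = level - 1
            if skip_level >= 0:
                interp = concat([interp, skeleton.features[skip_level]], axis=-1)
            f = dec(interp)
        return f

    def forward(self, plan: FeaturePlan) -> Tensor:
        """Full encoder-decoder: (N, 3) cloud plan -> (N, feature_dim)."""
        return self.decode_interpolate(self.set_abstraction(plan), plan)

    # ------------------------------------------------------------ bookkeeping
    def parameters(self):
        ps = []
        for m in self.encoders + self.decoders:
            ps.extend(m.parameters())
        return ps

    def state_items(self, prefix: str = "features"):
        items = []
        for i, enc in enumerate(self.encoders):
            for j, (W, b) in enumerate(enc.layers):
                items += [(f"{prefix}.enc{i}.{j}.W", W), (f"{prefix}.enc{i}.{j}.b", b)]
        for i, dec in enumerate(self.decoders):
            for j, (W, b) in enumerate(dec.layers):
                items += [(f"{prefix}.dec{i}.{j}.W", W), (f"{prefix}.dec{i}.{j}.b", b)]
        return items


def _interpolate(features: Tensor, idx: np.ndarray, w: np.ndarray) -> Tensor:
    """Inverse-distance weighted combination of coarse features at fine points."""
    out = None
    for k in range(idx.shape[1]):
        term = features.gather(idx[:, k]) * w[:, k : k + 1]
        out = term if out is None else out + term
    return out
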