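"""Skeleton feature learning: curvature-aware sampling and decoding.

Shows the geometric half of the vertex-feature module: pseudo-curvature
scores, the geometric/flat split, the multi-level skeleton, and the decoded
128-dimensional per-vertex feature field.
"""

import numpy as np

from myomesh import cubify
from myomesh.synthetic_data import ShellSpec, generate_shell
from myomesh.vertex_features import (
    SetAbstractionConfig, VertexFeatureNet, build_feature_plan,
    estimate_pseudo_curvature, partition_regions,
)

mask, _ = generate_shell(
    ShellSpec(outer_axes=(10, 9, 15), thickness=3, grid_size=40, seed=7,
              mesh_theta=40, mesh_rings=24)
)
mesh = cubify(mask)
cloud = mesh.vertices - mesh.vertices.mean(axis=0)
cloud = (cloud / np.abs(cloud).max()).astype(np.float32)

angles = estimate_pseudo_curvature(cloud, k=16)
scores = partition_regions(angles, threshold=5.0)
print(f"{len(cloud)} vertices; mean pseudo-curvature angle {angles.mean():.1f} deg")
print(f"geometric region (angle > 5 deg): {scores.geometric.mean():.0%} of points "
      f"- sampled at twice the rate of the flat region")

config = SetAbstractionConfig.for_cloud_size(len(cloud), width_scale=0.25)
plan = build_feature_plan(cloud, config, seed=0)
net = VertexFeatureNet(config, seed=0)
levels = net.set_abstraction(plan)
print("skeleton levels:", [len(p) for p in levels.points], "centroids")

field = net.decode_interpolate(levels, plan)
print(f"decoded feature field: {field.shape[0]} vertices x {field.shape[1]} channels")
print(f"skeleton displacement channels: {plan.skeleton_displacements.shape[1]} "
      f"(vertex-to-skeleton offset at each level)")
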