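"""Cubify: from a binary voxel mask to the initial boundary mesh.

Builds a small synthetic myocardium-like mask, converts it to a triangle
mesh and prints its element counts and integrity indicators.
"""

from myomesh import cubify, mesh_stats
from myomesh.synthetic_data import ShellSpec, generate_shell

spec = ShellSpec(
    outer_axes=(10, 9, 15), thickness=3, grid_size=40,
    twist_deg=6, bend=0.04, seed=7, mesh_theta=40, mesh_rings=24,
)
mask, label = generate_shell(spec)
mesh = cubify(mask)
stats = mesh_stats(mesh)

print(f"occupied voxels: {mask.n_occupied}")
print(f"initial mesh:    V={stats.n_vertices} E={stats.n_edges} F={stats.n_faces}")
print(f"euler characteristic: {stats.euler_characteristic} "
      f"(2 = closed genus-0 surface)")
print(f"open edges: {stats.n_boundary_edges} (0 = watertight)")
# The mesh is a staircase approximation of the smooth shell; the
# deformation network (example 03) exists to remove the staircase.
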