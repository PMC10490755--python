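# Methods

`myomesh` reconstructs a personalized left-myocardium surface from a binary
3D segmentation mask in three stages: initial mesh generation (cubify),
per-vertex skeleton feature learning on the mesh's point cloud, and iterated
mesh deformation by a residual graph convolutional network. This note
documents the model, its assumptions, the parameters that matter, and the
design choices made where more than one reasonable design existed.

## Initial mesh generation

Each occupied voxel becomes a cube of 12 triangles, 18 edges and 8 vertices;
triangles shared between face-adjacent voxels are deleted in coincident
pairs, and coincident vertices and edges are merged, leaving the boundary
surface only. The merge is performed on the integer voxel lattice before
scaling to world millimetres, so no floating-point coincidence tolerance is
involved. Cube quads are split along the diagonal through the
lexicographically smallest lattice corner; because this rule is shared by
the two cubes on either side of an internal wall, wall deletion is an exact
combinatorial cancellation.

Properties and edge cases:

* For a 6-connected genus-0 voxel solid the output is a closed, outward-
  oriented 2-manifold with V − E + F = 2. For a general solid the surface
  satisfies χ(surface) = 2 χ(solid) whenever the solid is a 3-manifold.
* Voxels meeting only along an edge or corner produce non-manifold surface
  elements. The mesh is kept as-is and a warning is logged; downstream
  stages (graph construction, sampling, losses) are agnostic to this.
* Disconnected components are meshed together; face cancellation cannot
  occur across components, so this equals meshing them independently.

The deliberately blocky result is the *input* to learning, not a final
product: the deformation network exists to remove the staircase.

## Synthetic study data

Clinical cardiac MR segmentations cannot ship with the package, so training
and evaluation use an idealized left-ventricular myocardium: a thick-walled
ellipsoidal shell truncated at the base (annular short-axis cross-sections),
with smooth twist and bend deformations for between-subject variability.
Anatomy ranges (semi-axes a, b ∈ [18, 28], c ∈ [30, 45] voxels, wall
thickness ∈ [4, 8] voxels on a 96³ grid) give cubified meshes of roughly
15–35k vertices. The analytic shell (outer wall + inner wall + basal rim)
is triangulated directly and serves as the ground-truth label surface; it
is closed and consistently oriented, so area-weighted sampling on it never
fails.

Masks are degraded to emulate segmentation-derived input rather than a
clean rasterization, for two reasons: segmentation output is what the
pipeline receives in practice, and with clean masks the initial mesh is
already at the accuracy floor, leaving the deformation stage nothing to
demonstrate. Two mechanisms are used, both seeded:

* per-slice lateral jitter (probability 0.4 per slice, ±1 voxel): the
  classic inter-slice inconsistency of stacked 2D segmentations;
* Bernoulli flips of boundary-adjacent voxels (p = 0.1): local raggedness.

Augmentation applies a random rigid rotation (±15° per axis), isotropic
scale (0.8–1.2) and translation (±4 voxels) consistently to the mask
(nearest-neighbour resampling) and the label mesh. Dataset manifests mirror
the study proportions (10 base anatomies → 80 augmented cases → 60/20
train/validation, separate test anatomies) and are fully reproducible from
one master seed.

What the generator does **not** emulate: MR intensities, papillary muscles
and trabeculation, regional wall-thickness variation, through-plane motion,
and anisotropic slice spacing. Passing tests therefore demonstrate that the
pipeline recovers smooth anatomy from staircase-plus-segmentation-noise
masks of roughly myocardial geometry — not clinical performance.

## Vertex feature learning

The initial mesh's vertices are treated as a point cloud and encoded by
three set-abstraction levels (sample → group → mini-PointNet), then decoded
back to all vertices by inverse-distance interpolation with skip
connections. Two departures from uniform practice:

* **Curvature-aware sampling.** A pseudo-curvature score per point is the
  mean angle between each of its k = 16 nearest-neighbour directions and
  its PCA tangent plane (0° for planar neighbourhoods). Points scoring
  above 5° form the "geometric" region, sampled at twice the per-point rate
  of the flat region (largest-remainder quotas, uniform within regions), so
  creases, the apex and the rim keep more centroids.
* **Skeleton context.** Besides the learned 128-dimensional feature field
  P, the feature pathway outputs explicit geometric context: the
  displacement from each vertex to the inverse-distance-weighted position
  of its 3 nearest skeleton centroids at every level (9 channels), and the
  vertex's one-ring Laplacian displacement (neighbour mean − vertex,
  refreshed from each deformation module's input mesh). Laplacian
  coordinates are the standard local shape descriptor on meshes; these
  channels carry local-relationship information at the same magnitude as
  the offsets the network predicts. Without them, shared-weight training
  cannot learn staircase-scale corrections within a short schedule (direct
  per-vertex optimization of the identical loss converges easily — the
  objective is informative, the parameterization bottleneck is real).

Defaults: centroid counts (512, 128, 32) per 2000 input points (rescaled
proportionally per mesh, widths fixed), grouping neighbourhood K = 32,
encoder widths (64, 64)/(128, 128)/(256, 256), decoder ending in 128
channels, interpolation over 3 nearest centroids with ε = 1e-8. The cloud
is centered internally, making the decoded field translation-invariant; the
encoder consumes region-relative coordinates only.

## Mesh deformation

The mesh graph is the vertex adjacency of the initial mesh; topology is
fixed throughout. The basic operation is

    f_k_new = ReLU( w0 f_k + Σ_{j ∈ N(k)} w1 f_j ),

a learned self-transform plus a learned neighbour aggregate (neighbour sums
are computed through a sparse adjacency matrix). A residual block stacks
two convolutions and adds its input back. One deformation module runs one
entry convolution, three residual blocks, and a linear graph-convolution
head that outputs a per-vertex 3D offset; vertex features for the next
module are the last hidden activations. Three modules are cascaded, each
consuming the previous module's output mesh; the feature field P is
computed once from the initial mesh and fused (after rescaling the
128-channel block to unit aggregate power) into every module.

Choices worth recording: offsets rather than absolute positions (identity
at initialization, zero-initialized heads); no bias terms (the convolution
formula above is used as-is); hidden width 128 at full scale; the head sees
the hidden features together with the current position and its Laplacian
displacement, so position-linear corrections (smoothing, small affine
fixes) lie on a well-scaled linear path; small-uniform (±0.01) weight
initialization elsewhere.

## Training objective

Per deformation module, with P and G point clouds (2000–6000 points,
scaled with mesh size) sampled area-weighted on the predicted and label
surfaces:

* Chamfer: L_c = mean_p ‖p − g(p)‖² + mean_g ‖g − p(g)‖² (squared, sums of
  the two direction means);
* normal: L_n = −mean_p |n_p·n_g| − mean_g |n_g·n_p| ∈ [−2, 0];
* edge: L_e = mean squared edge length of the deformed mesh.

Total: Σ_modules (L_c + λ₁ L_n + λ₂ L_e). Samples are barycentric
combinations of the vertex tensor with face normals from cross products, so
every term is differentiable in the vertex positions; nearest-neighbour
correspondences are recomputed per step and treated as constants.

**Loss-weight calibration.** λ₁ and λ₂ balance terms whose magnitudes
depend on the coordinate scale of the data, so they are calibrated, not
transplanted: term magnitudes are measured at the initial (identity)
deformation on validation cases and the closest-to-balancing values are
taken from the search grids λ₁ ∈ {0.001, 0.005, 0.01, 0.015, 0.02},
λ₂ ∈ {0.05, 0.1, 0.15, 0.2, 0.25}. On the normalized synthetic shells this
selects λ₁ = 0.001, λ₂ = 0.25; the full-scale defaults remain λ₁ = 0.01,
λ₂ = 0.2. A full validation grid search (`lambda_grid_search`) is
available when budget allows.

## Training protocol

Batch size 1 (one case per optimizer step): cubify → normalize by the
initial mesh's centroid and max-abs scale → feature field → three-module
deformation → total loss → Adam step. Validation Chamfer (unsquared,
normalized coordinates) is logged per epoch; the best-validation weights
are kept. All randomness (shell generation, sampling, initialization, case
order) derives from the config seed; identical configs produce bit-identical
loss curves and weights.

Two configurations:

* full scale: 15 epochs, Adam at 5·10⁻⁵, decay ×0.5 at epochs 8 and 12,
  width 128;
* desk scale (the tested configuration): 5 epochs, Adam at 5·10⁻³ with
  decay ×0.5 at epochs 3 and 4 (the same fractions of the run), hidden
  width 32, encoder widths scaled ×0.25, loss weights calibrated as above,
  10,000 evaluation samples. The desk-scale learning rate is set for a
  ~100-step budget; rates an order of magnitude higher kill the ReLU units
  outright, an order lower cannot move the weights measurably.

The reference experiment (`run_desk_study`, also what
`scripts/acceptance.py` reruns) uses 20 distinct shell anatomies at 96³:
13 train, 3 validation, 4 held-out test, 5 epochs. On held-out shells the
deformed surface's mean Chamfer falls ~10–13% below the initial cubified
surface's, and normal consistency rises; the no-deep-feature ablation
(feature pathway zeroed: P, skeleton displacements and Laplacian context
all removed, the counterpart of removing the feature module) loses
essentially the whole improvement, and the no-deformation ablation returns
the initial mesh by definition.

## Evaluation metrics

90,000 samples per surface at full scale (10,000 at desk scale), after
joint normalization by the label's centroid and max-abs scale so that
τ thresholds are size-independent:

* Chamfer: unsquared symmetric mean nearest-neighbour distance by default
  (the squared convention is available behind a flag and both appear in
  reports — the two differ and the choice is stated wherever a number is
  printed);
* normal consistency: mean |cos| between corresponding normals, both
  directions averaged; in [0, 1];
* F1_τ = 2·P·R / (P + R + δ) with δ = 1e-5, precision/recall as
  percentages of samples within τ ∈ {0.1, 0.3, 0.5} of the other cloud;
* mesh difference maps: exact vertex-to-surface distances (candidate
  triangles from a centroid KD-tree, exact point-triangle distance),
  binned and exportable as vertex-coloured PLY.

## Numerical notes

* Autodiff: a compact tape-based reverse-mode engine over numpy
  (`myomesh.autodiff`); float32 in the hot path; neighbour aggregation as
  CSR sparse matmul; max-pool routes gradients to first argmax; Adam with
  bias correction.
* Degenerate inputs: empty masks and zero-area meshes raise; coincident
  curvature neighbourhoods score 0 with a warning; non-unit normals are
  renormalized with a warning; NaN losses abort training with a diagnostic.
* Nearest-neighbour ties are resolved by KD-tree order; on exact-lattice
  clouds this makes tie-dependent quantities (centroid choice) sensitive to
  coordinate perturbations — inherent to any KD-tree pipeline.

## Known limitations

* The synthetic study shows desk-scale, directional results (deformation
  helps; feature pathway helps); it does not reproduce clinical-data
  accuracy values.
* Non-manifold voxel contacts are carried through rather than repaired.
* The feature encoder's learned weights contribute little within the short
  desk-scale schedule; their value grows with the training budget, while
  the explicit skeleton context carries the short-schedule improvement.
* Adaptive, density-aware grouping neighbourhoods are not implemented.
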