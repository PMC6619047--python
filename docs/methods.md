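# Methods

This note documents the models, numerical choices and limitations behind
`fibermap`. All lengths are in mm, times in ms; fibers are sign-agnostic
unit directions (f ≡ −f).

## Geometry model and synthetic fixtures

The pipeline targets thin atrial shells: a closed endocardial surface
extruded outward by the wall thickness (2 mm, the accepted average for
human atria), meshed with tetrahedra at a ~0.9 mm target edge (two to
three elements through the wall). No clinical geometries ship with the
package; the `synth` module generates stand-ins with every property the
algorithms rely on:

* **Shells** — an icosphere mapped onto an ellipsoid (semi-axes
  `radii`), extruded along the ellipsoid normal in
  `ceil(thickness/target_edge)` prism layers, each prism split into three
  tets with globally consistent diagonals (sorting vertices by global
  index makes the splits conform across prisms). Endo/epi node sets are
  tagged exactly by construction. Optional *bumps* (Gaussian radial
  bulges, the stand-in for appendages and patient-specific shape quirks)
  and *orifices* (angular holes with tagged rims, the stand-in for vein
  and valve openings).
* **Fibers** — closed-form tangential fields evaluable at any point:
  circumferential (f ∝ ẑ × n̂), helical (rotated toward the meridian by a
  fixed angle), and two-layer (helix angle growing linearly endo→epi to
  90°, so the two surfaces carry orthogonal fields — the synthetic
  analogue of distinct wall layers on the posterior left atrium). At the
  two poles the circumferential direction is undefined; those nodes get
  a limit-rule direction and are flagged.
* **Warps** — sums of low-frequency vector sinusoids plus an optional
  affine part, with analytic Jacobian. `SyntheticWarp.smooth` rescales
  mode gains so Σ‖a‖‖k‖ ≤ 0.5, which bounds ‖∂u/∂x‖ < 1 and guarantees a
  positive Jacobian determinant; diffeomorphy is additionally verified by
  sampling det F on a 32³ grid. Warped images are resampled through the
  inverse map, found per voxel by fixed-point iteration to 1e-3 mm.
* **Landmarks** — 13 points at fixed directions (poles plus a
  golden-spiral spread) on the epicardial surface; because the directions
  are shared across specs, landmark sets of two different shells
  correspond by position, which is the synthetic analogue of anatomically
  matched landmarks at vein/valve orifices.

What the fixtures do *not* emulate: real atrial topology (appendage,
pulmonary-vein trunks, Bachmann-bundle bridge, two chambers), wall
thickness variation, segmentation noise, and fiber-bundle discontinuities
between regions. Passing tests therefore demonstrate correctness of the
machinery and its accuracy on smooth shape variation, not clinical
accuracy on real anatomies.

The fixture shells use endocardial radii of 8–12 mm — a factor 2–3
smaller than adult atria — so that 0.6 mm-voxel registration grids stay
near 64³; this is a deliberate scale reduction of the geometry, not of
the method's parameters (thickness, voxel size, α, pyramid depth are the
full-scale values).

## Alignment

`rigid_from_landmarks` is the Kabsch/Umeyama least-squares fit without
scaling: SVD of the cross-covariance of centered landmark pairs, with the
smallest singular direction sign-corrected so det R = +1 (no
reflections). Collinear configurations (second singular value ~0) are
rejected. `icp_affine` alternates KD-tree nearest-neighbor
correspondences (atlas → patient, no outlier trimming) with a closed-form
least-squares affine fit; it stops when the mean correspondence distance
improves by < 1e-4 mm (default) or after 100 iterations. A fitted affine
with |det| < 1e-8 aborts (cloud collapse).

## Voxelization

Binary occupancy: a voxel is 1 iff its center lies inside some tet
(inclusive barycentric test, tolerance 1e-9), on a grid of isotropic
0.6 mm voxels padded by 8 voxels. A 1-voxel morphological dilation
(6-connected) is applied by default: a binary rasterization of a 2 mm
wall at 0.6 mm voxels is fragile, and the slight thickening matches how
such binary shell images behave; the later interpolation back to mesh
nodes is a weighted-neighbor average and is insensitive to it. No
partial-volume fractions — smoothing happens in the registration pyramid.

## Elastic registration

Objective J(u) = D(u) + α S(u) over a per-voxel displacement u on the
fixed (patient) grid, with φ(x) = x + u(x) sampled into the moving
(atlas) image:

* **D** — midpoint-rule SSD, ½ Σ (I_a(φ(x)) − I_p(x))² · voxelVolume,
  trilinear interpolation, 0 outside the moving image.
* **S** — linearized (Navier-type) elastic energy
  Σ w(x)[μ/4 Σᵢⱼ(∂ᵢuⱼ+∂ⱼuᵢ)² + λ/2 (div u)²]·voxelVolume with μ = 1,
  λ = 0 by default, scaled by α = 0.1. Derivatives are central
  differences with 4-point third-order one-sided stencils at the grid
  boundary, and w are trapezoidal product quadrature weights; with these
  choices the discrete energy converges to the continuum integral at
  second order (measured order 1.92 over the 17³/33³/65³ refinement
  study of a sinusoidal field), and S vanishes exactly on infinitesimal
  rigid fields — the correct null space for a similarity-driven
  registration whose global pose is pinned by the preceding affine step.
* **Gauss–Newton** — each iteration solves
  (JᵀJ + αH) δ = −(∇D + αHu), where JᵀJ is the per-voxel 3×3 outer
  product of the (pre-smoothed) moving-image gradient at φ and H the
  sparse elastic Hessian, by Jacobi-preconditioned conjugate gradients
  (relative tolerance 1e-8, ≤200 iterations). Armijo backtracking (≤10
  halvings) guarantees a non-increasing objective; a level terminates on
  relative objective decrease < 1e-4, 30 iterations, a vanishing step, or
  a stalled line search (flagged unless the level already improved).
* **Pyramid** — 4 levels; each coarser level smooths with a normalized
  Gaussian (σ = 1 voxel) and subsamples by 2, doubling the voxel size;
  coarse results are prolonged by componentwise trilinear interpolation
  (exact on linear fields). Both images are pre-smoothed (σ = 1 voxel)
  at every level: on raw binaries the image gradient is zero almost
  everywhere and Gauss–Newton would not move.

Registration direction: the displacement lives on the patient grid and
maps into the atlas image, so the mesh-deforming atlas→patient point map
is φ⁻¹, computed on the grid by per-voxel fixed-point inversion (1e-3 mm
tolerance). On the synthetic benchmark (3 mm sinusoidal warp of a shell
image, 0.6 mm voxels) this recovers the ground-truth inverse-warp
displacement with a mean error of ≈0.30 mm over occupied voxels and a
post-registration Dice of ≈0.97.

A caveat on identifiability: a binary image of a smooth thin shell
constrains only the wall-*normal* motion — tangential sliding changes
the image nowhere (the aperture problem), and long-wavelength warps are
nearly affine over the shell, i.e. largely the global-alignment stage's
business. Warp-recovery experiments are therefore run on shells whose
orifices and bumps anchor tangential motion, and the reproduction script
uses detrended warps (`SyntheticWarp.smooth_nonaffine`: constant and
linear terms cancelled at the shell center) so that the measured error
reflects the elastic stage's actual task, the non-affine residual.

## Fiber mapping

All scattered interpolation uses inverse-distance weighting over the k
nearest sources with weights 1/dᵖ, k = 8 and p = 2 by default (the
neighbor count and power are not critical; both are exposed in config),
and an exact-hit rule below 1e-9 mm. The Jacobian of u is formed by
central differences on the voxel grid and then IDW-interpolated to nodes
(differencing before interpolating matches the grid-based character of
the displacement). The total deformation gradient at an atlas node is the
chain-rule product of the elastic Jacobian and the affine linear part;
nodes where det F ≤ 0 fall back to the affine alone and are reported.

Reorientation strategies: *preservation of principal directions*
f′ = F f/‖F f‖ (default — it keeps the stretch-induced direction change,
which is the point of registering shapes that genuinely differ) and
*finite strain* f′ = R f with F = RU via SVD-based polar decomposition
(retained for comparison; identical for rigid F).

Surface transfer averages fibers across neighbors, which is meaningless
for sign-ambiguous directions unless the representatives agree: each
neighbor fiber is first flipped into the hemisphere of the nearest
neighbor's fiber. Averages that still cancel below 1e-6 are flagged and
filled from the nearest resolved node; the same flag-and-fill rule
handles fibers that are near-normal to the surface after tangential
projection. Surface normals are area-weighted incident-triangle normals
oriented outward by the shell-centroid rule.

## Harmonic lift

Componentwise Laplace solves with P1 tetrahedral finite elements:
Dirichlet data on endo∪epi nodes, natural (zero-flux) conditions on any
other boundary (orifice rims — our choice; rims are thin
rings far from most of the wall, and zero-flux leaves them governed by
their surroundings). Before assembly the boundary data are made
sign-consistent by a breadth-first sweep over surface edges (flip f→−f to
agree with the visiting neighbor), preventing artificial cancellation of
antipodal representatives. Systems up to 2×10⁵ free nodes are solved by
sparse LU (one factorization, three right-hand sides), larger ones by
conjugate gradients. Interior nodes whose lifted vector cancels below
1e-6 are flagged and filled from the nearest resolved node. Componentwise
lifting followed by renormalization is the standard "harmonic lifting" of
vector data; it is not geodesic interpolation on the projective sphere,
and through-wall rotations of up to 90° (the two-layer case) interpolate
monotonically but with the chord, not arc, parameterization.

## Activation surrogate

The full electromechanical model (monodomain + ionic cell model,
finite-strain mechanics, hemodynamics) is out of scope; a deliberately
simple anisotropic eikonal surrogate checks that mapped and defined
fibers yield similar activation *patterns*. Activation times are Dijkstra
shortest paths over mesh edges with the elliptic travel-time metric
t(e) = √((e·f)²/v_long² + (‖e‖²−(e·f)²)/v_trans²), f the sign-aligned
mean fiber of the edge's endpoints. This is the consistent graph
metrization of anisotropic conduction: a straight crossing of a fiber
field costs exactly L/v_trans and no zigzag of fast-direction edges can
undercut it. (Weighting edges by the directional speed
√(v_long²cos²θ + v_trans²sin²θ) instead is *not* metric-consistent:
45° zigzags would cross fibers ~40% faster than the straight path.)
Defaults v_long = 0.6, v_trans = 0.6/√10 mm/ms reflect the 10:1
longitudinal/transverse diffusivity ratio of atrial monodomain models,
whose velocity ratio is √10. The graph metric overestimates continuum
travel times in directions not represented by mesh edges (up to ~13% on
a Kuhn-split lattice, a bias that does not vanish under refinement);
activation-time *differences* between two fiber fields on the same mesh
are insensitive to this shared bias. On the synthetic atlas/patient pair
the maximum activation-time difference between mapped and defined fibers
is a few percent.

## Determinism and degenerate inputs

There is no hidden randomness: fixtures are seeded, ICP ties break toward
the lowest index, CG is deterministic, and identical inputs give
bit-identical pipeline reports. Degenerate inputs fail loudly: meshes
without tets, non-unit fibers, collinear landmarks, collapsing ICP fits,
empty Dirichlet sets and out-of-domain interpolation points all raise
typed errors; pipeline stages wrap them with the stage name.

## Known limitations

* Shell fixtures are geometrically simple; bundle-boundary
  discontinuities, which dominate the mapping error on real atria, appear
  here only at the circumferential field's poles.
* The elastic regularizer is linearized; very large deformations would
  need a hyperelastic or diffeomorphic model.
* Eikonal-by-Dijkstra is a pattern-level surrogate, not an
  electrophysiology solver.
* Harmonic lifting can cancel opposing boundary data in symmetric
  configurations; such nodes are filled heuristically and flagged rather
  than resolved by a richer interpolation.
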