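# Methods

## Problem and model

During endoscopic-ultrasound (EUS) guided procedures of the upper GI tract,
a 2D sector-shaped ultrasound view must be registered to a pre-procedure 3D
CT/MR volume to give the endoscopist anatomical context. `eusplan`
implements a simulation-based planning method that, before the procedure,
identifies the transducer positions and view orientations from which that
registration initialisation will be most accurate and most robust.

The registration model is rigid **landmark-to-structure** alignment: each
intra-procedure landmark is tagged only with the anatomical structure it
belongs to (e.g. "a point on the splenic vein"), never with a specific
point. Pre-procedure structures are point clouds — triangulated surfaces
for organs, medial-axis centrelines for vessels and ducts. Registration
alternates, as in iterative closest point (ICP), between assigning each
landmark its nearest point *within its own labelled structure* and solving
the closed-form (SVD/Kabsch) least-squares rigid transform; it starts from
a stochastic correspondence (a uniformly random point of the landmark's
structure) and keeps the best of `n_starts` restarts. The label constraint
is what distinguishes the method from plain ICP. A minimum of three
landmarks is required for the six degrees of freedom to be determined.

## Plane sampling and landmark extraction

Acoustic coupling requires the transducer to touch the stomach (or
duodenum) wall, so candidate apex positions are the vertices of the
contact-organ surface, decimated to a mean vertex spacing of 5.33 mm
(about half a transducer width). At each vertex a base sector plane is
aimed along the inward surface normal and rotated about the three axes of
the vertex's local frame on a uniform grid of ±60°; with the default 30°
step this gives 5³ = 125 planes per vertex (a 20° step, 343 planes, is
available by configuration — the two conventions in circulation disagree,
and 125 matches the plane count actually used). Sector geometry defaults
to a 120° fan and 50 mm depth, matching standard clinical EUS transducers.

Each structure crossing a plane contributes cross-section "features":
8-connected components of the nearest-neighbour-resampled label mask at
0.5 mm pixel pitch, clipped to the sector. Features under 5 mm² are
discarded (strict `< 5` — too small to identify confidently on EUS), and a
plane is usable only with ≥ 3 surviving features. Landmarks are extracted
automatically: the cross-section centroid for vessels/ducts, and for
organs the visible-boundary point nearest the mean of the visible boundary
(the boundary is taken from the unclipped in-plane contour so sector-edge
clipping lines are never mistaken for anatomy; a component whose true
contour lies entirely outside the sector yields no landmark).

## Monte-Carlo TRE estimation

Landmark localisation error is modelled as zero-mean isotropic Gaussian
noise: σ = 2 mm per axis for organ-boundary landmarks, and for vessel/duct
centroids σ = (w + h)/12 where (w, h) is the visible cross-section's
bounding box — a larger, more ambiguous section gets a proportionally
larger uncertainty. (The bracketed reading of this rule as a scalar SD is
a documented choice; the rule is a configurable callable.) Because the
landmarks are generated in the pre-procedure frame, the ground-truth pose
is the identity, and each Monte-Carlo draw perturbs the landmarks,
registers them, and summarises the recovered transform T by

- `TRE_plane` — RMS of |p − T p| over the sector's pixel grid (1 mm pitch
  by default; the per-point sum is evaluated exactly through the grid's
  first and second moments, which is algebraically identical to the
  brute-force form and is verified against it in the tests);
- `TRE_surface` — the same RMS over the vertices of the clinical target
  structure (e.g. the pancreas).

Two-plane initialisations pool the landmarks of both planes; the second
plane's set is additionally displaced by a random rigid tracking error
(σ = 0.4 mm position per axis, σ = 0.36° rotation per axis, composed about
the second plane's apex in fixed x-y-z order — composition order is a
documented choice), representative of tracked flexible endoscopes.
Defaults are 1000 draws per single plane and 100 per pair.

## Plane selection

Planes are ranked by the **90th percentile** (nearest-rank convention:
the sorted sample at rank ⌈0.9 n⌉) of their TRE samples — the upper bound
of the nonparametric 90% prediction interval, i.e. the error not exceeded
with 90% probability. This penalises heavy-tailed, non-robust planes that
a mean-TRE ranking would favour. Pairs are drawn by 2D Latin-hypercube
sampling over the usable-plane index domain (one sample per stratum per
dimension; self-pairs and unordered duplicates dropped), with a default
budget of twice the number of contact vertices. Because optimising over
many noisy p90 estimates preferentially selects planes whose estimate
happened to be low, the winner is re-scored on fresh draws under a seed
disjoint from the optimisation seed (1000 by default). A per-vertex map of
the best (minimum over orientations) p90 over the contact surface is
exported as a PLY scalar field; vertices with no usable plane are flagged.
The per-vertex minimum is a documented choice — it is the planning-relevant
reduction, since the endoscopist can orient the probe freely at a position.

## Reference phantom

The built-in phantom voxelises analytic primitives — superellipsoids for
organs, constant-radius tubes around polylines for vessels — at 1 mm
isotropic spacing in a 150×150×130 mm volume, with adult-abdominal sizes:
a hollow rotated stomach shell (the contact surface, 4 mm wall), a
pancreas target flanked by the splenic vein, liver, gallbladder, left
kidney, aorta, inferior vena cava and portal vein. Rotated, offset
ellipsoids remove all rigid self-symmetry, so registration has a unique
global optimum (verified by randomized search in the tests). The analytic
parameters are returned alongside the volume and serve as oracles for
every geometric stage.

What the phantom does *not* emulate: CT intensities and segmentation error
(the method consumes labels), organ deformation between imaging and
procedure, acoustic artefacts (visibility is purely geometric), and the
anatomical complexity of a real stomach (a J-shaped organ yields a richer
normal field than an ellipsoid shell). Passing tests therefore demonstrate
correctness of the geometry, noise model, registration and selection
machinery, and reproduction of the method's qualitative findings at
phantom scale — not clinical accuracy on patient data.

## Numerical choices and study scales

- Marching cubes at iso-level 0.5 after a Gaussian pre-smooth of the
  binary mask (σ = 0.8 voxels, configurable). The pre-smooth removes the
  ~10% staircase over-estimate of surface area that raw binary isosurfaces
  carry; a digitised sphere's area is then reproduced to well under 1%.
- Decimation is vertex clustering with an adaptive cell size targeting the
  requested mean edge length (two corrective passes, ±10% internal
  tolerance). Several deterministic grid offsets are tried and the first
  watertight result kept; for structures thin relative to the target edge
  the result can contain fold-over fins but always remains closed (no
  boundary edges), which is all downstream stages require.
- Centrelines use Lee et al.'s parallel 3D medial-axis thinning
  (26-connected) as implemented in scikit-image.
- ICP convergence: |ΔRMS| < 1e-4 mm or 100 iterations; nearest-point
  queries via k-d trees, exactly equivalent to a linear scan (tested);
  the many (draw × restart) chains of a simulation are iterated as one
  batch through stacked 3×3 SVDs, which is what makes thousand-draw
  simulations take seconds.
- Stochastic restarts sample the basin of the global optimum with small
  per-start probability (fractions of a percent on the reference phantom
  for 12-landmark sets), so degenerate noiseless checks use thousands of
  restarts, while routine simulation uses the default `n_starts = 10` —
  deliberately: residual convergence failures are part of the TRE
  distribution the method is designed to summarise robustly (they are why
  the 90th percentile, not the mean, is the objective).
- Automatically extracted landmarks carry a deterministic offset from the
  point-cloud structure representations (raster contour vs mesh vertices,
  decimated contact mesh, off-axis centroids of grazing vessel sections).
  TRE distributions therefore do not collapse to zero as σ → 0 for
  plane-extracted landmarks; the (w+h)/12 vessel rule models precisely
  this section-elongation ambiguity.
- All randomness flows from a single seed per run (correspondence
  initialisation, landmark noise, tracking noise, vertex and pair
  sampling); identical seeds reproduce volumes, distributions and
  rankings bit for bit.
- Test- and acceptance-scale studies sample 12 contact vertices (capped at
  100 candidate planes), score with 100 draws, and re-estimate winners
  with 500 independent draws; these sizes are the package's study
  conditions for the phantom experiments and are stated in the outputs.

## Known limitations

- Rigid registration only; deformation is out of scope.
- No acoustic simulation: a feature counts as visible whenever it
  intersects the sector geometrically, with no occlusion model.
- Oblique (sheared) voxel grids are rejected rather than resampled.
- The LHS pair budget trades pair-space coverage for runtime; with very
  few usable planes the de-duplicated pair list can be shorter than the
  requested budget.
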