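# Methods

This note records the models, conventions and design choices behind
`swarmreg`, in the order a reader meets them: optimizer, benchmarks,
transform/metric, phantom, registration.

## Hybrid particle swarm optimizer

The optimizer maintains `n_particles` candidate parameter vectors in a box
domain. Per particle and iteration:

    v ← w·v + c1·r1·(p_best − x) + c2·r2·(g − x)
    x ← x + v

* `c1 = c2 = 2.0` (the classic acceleration constants).
* Inertia `w` starts at `w_max = 0.98` and decreases linearly by
  `(w_min − w_max)/T` per iteration to `w_min = 0.4`, shifting the swarm
  from exploration to exploitation. (Descriptions of this schedule
  sometimes quote 0.4 as the *initial* weight; a decreasing schedule from
  0.4 to 0.4 would be degenerate, so the package starts at the maximum.
  Both endpoints are configurable.)
* `r1, r2 ~ U(0,1)` are drawn fresh per term per particle. By default they
  are scalars (`rand_per_dimension=False`), matching the scalar notation of
  the update rule; per-dimension draws are available and are the default
  for registration (below).
* Velocities are clamped componentwise to `v_max_fraction = 0.5` of the
  per-dimension range; positions are clamped to the bounds with velocity
  left unchanged. These are the simplest rules consistent with bounded
  domains.
* The optimizer maximizes internally; `SearchSpace(sense="minimize")`
  negates the objective at the boundary.

**Hybrid ingredients.** The swarm is partitioned into `n_subpopulations`
islands (sizes differing by at most 1; at least 2 members each). Within an
island the attractor `g` in the update is that island's own best — not the
global best — otherwise the islands would confer no diversity; the global
best is a promotion/reporting target only. Once per iteration, after all
island updates:

1. Island bests are sorted; the leaders of the two best islands act as
   parents.
2. Arithmetic crossover with one shared draw `r` (making the two offspring
   a complementary convex pair): `x'_i = r·x_i + (1−r)·x_j` and
   symmetrically.
3. Offspring velocities keep each parent's speed but point along the
   parents' summed direction, `V = (v_i + v_j)/‖v_i + v_j‖`,
   `v'_i = ‖v_i‖·V`. The notation this realizes is dimensionally ambiguous
   in its original form ("v_i V" with two vectors); the speed-preserving
   reading is adopted. If the parent velocities cancel exactly, they are
   kept unchanged.
4. Each offspring replaces the worst member (lowest personal best; ties →
   lowest index) of its parent's island, and that slot's personal best is
   re-initialized from the offspring's own evaluation.

With `n_subpopulations = 1` (crossover impossible) the code path reduces to
plain PSO; a separate, independently written single-swarm implementation is
kept (`pso_optimize`) and the test suite asserts the two replay each other
bit for bit under the same seed.

## Benchmarks and the error score

Four classic minimization problems: sphere (d=3, [−5.12, 5.11]),
Rosenbrock/De Jong F2 (d=2, [−2.048, 2.047]), Rastrigin A=10 (d=20,
[−5.12, 5.11]), Griewank (d=10, [−5.12, 5.12]). Two printed-form
curiosities are resolved in favor of the standard functions: the F2 variant
`100(x1²−x2)+(1−x1²)²` has its domain minimum on the boundary rather than
at (1,1) and is kept only as `f2_as_printed`; the Griewank product term is
`cos(x_i/√i)`, whose minimum a dense grid oracle confirms at the origin.

Run quality is summarized as the **range-normalized mean squared error** of
the best position against the known optimum, in percent:

    err% = 100 · (1/d) · Σ_i ((x_i − x*_i)/(u_i − l_i))²

It is 0 exactly at the optimum, 100 when every coordinate is off by a full
range, and invariant under joint affine rescaling of bounds and positions.
The harness runs `n_runs` independent trials (trial r is seeded
`base_seed + r`) and reports the arithmetic mean. Under the standard
protocol (56 particles, 4 islands, 100 generations, 40 runs) the hybrid's
mean errors on Rastrigin-20 and Griewank-10 land near 1%, clearly below
plain PSO under the identical budget; the island-count sweep (5600
particles nominally; the tests run a 560-particle scale-down) shows the
characteristic non-monotone shape — moderate island counts help, many
2-member islands hurt.

## Rigid transform, resampling, metric

* **Volume**: scalar grid `data[ix, iy, iz]`, voxel spacing in mm, world
  origin; voxel centers at `origin + index·spacing`. NIfTI I/O via nibabel
  (diagonal affine), MetaImage via SimpleITK; axis orientation metadata
  beyond spacing/origin is not interpreted.
* **Rotation matrix**: the Euler matrix stated in the module docstring,
  equal to `Rz(−γ)·Ry(−β)·Rx(−α)`. The form it was transcribed from
  contains one sign error (entry (2,3)) that breaks orthonormality; the
  minimally corrected matrix is used, verified symbolically and
  property-tested (`RᵀR = I`, `det R = +1` for arbitrary angles). At
  (0, 0, 90°) its first column is (0, −1, 0).
* **Convention**: angles in degrees at all interfaces (radians internally),
  translations in mm, rotation about a configurable center defaulting to
  the volume's world center: `T(p) = R(p − c) + c + t`.
* **Resampling**: backward (pull) warping — each output voxel's world
  coordinate is mapped through the transform into the moving volume and
  trilinearly interpolated (`scipy.ndimage.map_coordinates`, order 1).
  Out-of-volume samples take a fill value and are flagged in a validity
  mask so the metric can exclude them.
* **Joint histogram / MI**: uniform bins (default 64 per image) spanning
  each image's observed range; entropies in bits; `MI = H(A)+H(B)−H(A,B)`.
  Plug-in MI is a KL divergence, hence ≥ 0, symmetric, equal to `H(A)` for
  identical images, and invariant to bijective bin relabeling — all
  asserted by tests. Bin edges for registration are frozen once from the
  untransformed images so every candidate transform is scored on the same
  binning. Masked-out voxels are excluded rather than binned at the fill
  value, which would otherwise inflate MI.

## Synthetic multimodal phantom

The generator stands in for simulated CT/MR-like volume pairs
(default 128 × 128 × 15 voxels at 2.59 × 2.59 × 8.0 mm; the registration
tests use a 64 × 64 × 15 scale-down). Design rationale:

* **Geometry**: an elongated "body" ellipsoid nearly filling the field, an
  off-center "organ", a small bright inclusion and an off-center box.
  In-plane elongation makes rotation identifiable; the off-center
  structures break the body's residual 180° symmetry.
* **Multi-scale intensity content.** Real volumes contain both large smooth
  structures and fine detail; both matter for MI registration. The smooth
  oblique intensity gradient (`gradient = 0.4`) gives the MI surface a wide
  capture basin; a fixed aperiodic smooth random field
  (`texture_amplitude = 18` on a 0–240 intensity scale, cubic-interpolated
  from a coarse lattice with a hard-coded seed) sharpens the peak at true
  alignment. The texture is deliberately *not* periodic — periodic texture
  was observed to create spurious remote MI maxima — and is treated as
  anatomy: it does not vary with the experiment seed, so the only
  stochastic element of a pair is the additive noise.
* **Modalities**: the fixed image is the phantom itself; the moving image
  passes through a non-monotone piecewise-linear lookup
  (0→180, 60→20, 120→220, 200→80) before being warped through the inverse
  of the ground-truth transform. The non-monotone relationship defeats
  correlation-type metrics while leaving MI intact — the multimodal
  premise.
* **Noise**: additive Gaussian, default 1% of the moving image's dynamic
  range; the recovery experiments use noise-free pairs.

What passing phantom tests do **not** show: robustness to anatomically
realistic texture statistics, intensity inhomogeneity fields, partial
fields of view, or resolution anisotropy beyond the thick-slice grid used
here. External clinical volumes with gold-standard fiducials are not
bundled; the fiducial (landmark) error metric is implemented and exercised
on synthetic gold-standard transforms instead.

## Registration

`RigidRegistration` maximizes MI over the 6 rigid parameters with the
hybrid optimizer. Choices that matter:

* **Parameter bounds** (the search is global; these set its extent):
  translations within ± half the field of view per axis; rotations ±30°
  about x and y, ±180° in-plane. Fully configurable.
* **Normalization**: the heterogeneous parameters are mapped to the unit
  cube inside the optimizer so one velocity clamp governs all six.
* **Per-dimension rand draws** are the registration default: with scalar
  draws each particle's move is confined to the plane spanned by its two
  attractor differences, which measurably slowed late-stage convergence of
  the angles; per-dimension draws recover sub-degree precision.
* **Minimum overlap** (`min_overlap = 0.25` default; the bundled
  experiments use 0.5): a candidate transform is scored 0 unless at least
  this fraction of reference voxels maps inside the moving volume. Plug-in
  MI estimated from few samples is biased upward, so without the guard the
  optimizer is drawn to near-disjoint placements whose inflated MI can beat
  the true peak. If every candidate in a run violates the guard the fit
  aborts with advice to widen the bounds.
* **Restarts**: `fit(n_restarts=k)` repeats the optimization from
  independent initializations (seeds `s, s+1, …`) and keeps the highest-MI
  run — the standard guard against the occasional run that settles on a
  secondary optimum (for the bundled phantom, the residual 180° in-plane
  basin; such runs score visibly lower MI, so selection by MI is reliable).
  The registration experiments use 3 restarts.
* **Accuracy reporting**: `diff = ‖error‖₂/3` per 3-parameter block
  (translations; angles in degrees), validated against every published
  comparison cell it was reverse-engineered from. Angular error is raw
  arithmetic difference — no modular wrapping — matching how those
  published cells are computed (e.g. 149.49° vs 120° counts as 29.49°).

## Problem sizes and determinism

The test suite and the acceptance script generate every input
programmatically: benchmark statistics use 40 runs of the 56-particle
protocol; the island sweep runs at 560 particles; registration experiments
run at 64 × 64 × 15 with 3 restarts of the 56 × 100 protocol. All
randomness in a run descends from a single integer seed; repeated runs with
the same seed are bitwise identical.

## Known limitations

* Plain (unnormalized) MI only; normalized-MI variants, Parzen/partial-
  volume estimators and metric gradients are out of scope, as are nonrigid
  transforms, multi-resolution pyramids, and 2D paths.
* The rigid-parameter search treats angles on a flat interval; ±180°
  wrap-around is not identified.
* The optimizer is a global stochastic search: per-run success on a sharp
  6-d MI surface is probabilistic by nature (hence restarts), and no
  parameter uncertainties are produced.
* Baseline optimizers from the comparative literature (genetic-algorithm
  and gradient-descent registration) are not implemented.
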