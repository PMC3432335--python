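# swarmreg

Hybrid particle swarm optimization (HPSO) for rigid multimodal 3D medical
image registration, with the benchmark harness and synthetic phantom data
needed to validate it end to end.

## The problem

Aligning two 3D medical volumes acquired with different physics (CT vs MR,
MR vs PET) cannot rely on intensity agreement: the same tissue takes
unrelated — often non-monotonically related — intensities in the two
modalities. The standard answer is to search for the rigid transform
**T** = (t_x, t_y, t_z, α, β, γ) that maximizes the mutual information
between the fixed image f₁ and the warped moving image f₂:

    T̂ = argmax_T  MI( f₁(x), f₂(T(x)) ),    MI(A,B) = H(A) + H(B) − H(A,B)

with entropies estimated from a discrete joint intensity histogram. The MI
surface over the six rigid parameters is non-convex and full of local
optima, so gradient methods need a good initialization while plain global
optimizers struggle as dimension grows.

## The optimizer

`swarmreg` implements a hybrid PSO that grafts two genetic-algorithm ideas
onto the classic velocity update

    v ← w·v + c₁·r₁·(p_best − x) + c₂·r₂·(g − x),    x ← x + v

with inertia w decreasing linearly from 0.98 to 0.4 and c₁ = c₂ = 2:

* **Subpopulations (islands).** The swarm is partitioned; each island
  evolves around its own best, preserving diversity.
* **Crossover.** Once per iteration the two best island leaders produce two
  offspring by arithmetic crossover, x′ᵢ = r·xᵢ + (1−r)·xⱼ, with
  speed-preserving velocity recombination along the parents' summed
  direction; each offspring replaces the worst member of its parent island.

With one island and crossover off, the hybrid reduces exactly (bit for bit
under the same seed) to plain PSO.

## Worked example

Generate a synthetic multimodal pair whose ground-truth alignment is a
(20, 10, 2) mm translation plus a 120° in-plane rotation, then register it:

```python
from swarmreg import (PhantomSpec, RigidRegistration,
                      ground_truth_transform, make_multimodal_pair)

spec = PhantomSpec(size=(64, 64, 15), noise_sd=0.0, seed=0)
truth = ground_truth_transform(spec, tx=20, ty=10, tz=2, gamma=120)
fixed, moving, _ = make_multimodal_pair(spec, truth)

model = RigidRegistration(fixed, moving, bins=64, min_overlap=0.5)
result = model.fit(seed=0, n_restarts=3)
result.evaluate_against_truth(truth)
print(result.summary())
```

```
Rigid MI Registration Results
==============================================
fixed:  shape (64, 64, 15), spacing [2.59, 2.59, 8.0] mm
moving: shape (64, 64, 15), spacing [2.59, 2.59, 8.0] mm
metric: mutual information, 64 bins
optimizer: 56 particles, 4 subpopulations, 100 iterations, seed 2
best MI: 1.5290 bits (fixed-image entropy 2.3470 bits)
----------------------------------------------
parameter     estimate       lower       upper
tx             20.2073      -82.88       82.88
ty             10.0482      -82.88       82.88
tz              0.3125      -60.00       60.00
alpha          -0.0198      -30.00       30.00
beta           -0.0176      -30.00       30.00
gamma         119.6358     -180.00      180.00
----------------------------------------------
diff vs truth: translation 0.5670
               rotation    0.1217 deg
```

The six estimates are the recovered transform (translations in mm, angles
in degrees); the model's default optimizer is the 56-particle, 4-island,
100-iteration protocol. `diff` is the per-block accuracy summary used
throughout the package — the Euclidean norm of the 3-vector parameter
error divided by 3 — so this run recovered the rotation to 0.12° and the
translation to 0.57 on that scale. (Seed 2 in the header identifies the
winning restart of the three.)

The same pipeline is scriptable from the shell:

```bash
swarmreg phantom --tx 20 --ty 10 --tz 2 --gamma 120 --noise-sd 0 --out ph/
swarmreg register --fixed ph/fixed.nii.gz --moving ph/moving.nii.gz \
                  --truth ph/truth.json --out reg/
swarmreg benchmark --function F3 --method hpso --runs 40 --seed 1 --out bench/
swarmreg sweep --subpops 1,2,4,8 --particles 560 --out sweep/
```

## Benchmarks

`swarmreg.benchmarks` carries four classic minimization problems — sphere
(d=3), Rosenbrock (d=2), Rastrigin (d=20), Griewank (d=10) — and a harness
that averages the range-normalized mean squared error of the best position
(×100, in percent) over independently seeded runs. On the hard multimodal
functions the hybrid consistently beats plain PSO under the same budget,
and accuracy versus the number of islands is non-monotone: a moderate
island count helps, while many tiny islands hurt.

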