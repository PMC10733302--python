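# kinkvesicle

Brownian-dynamics simulation and analysis of **self-propelled rods confined
in kinked vesicles** — a minimal 2D model of a steerable "vesicular robot".

A closed membrane ring of N_v = 100 bonded disks encapsulates N_a rigid
rods (dimers or trimers of tangent disks) that self-propel with a force
F_A = Pe·k_BT along their axes. A single membrane triplet is held at an
interior angle θ_kink < π — the *kink*. The active rods accumulate at the
boundary, form dense stackings at the kink, and collectively propel the
whole superstructure: depending on θ_kink, rod density ρ = N_a/(N_v σ),
Péclet number and membrane rigidity, the vesicle moves linearly or in
circles, toward the kink (forward) or away from it. The package provides:

* the force field (WCA excluded volume, FENE membrane bonds, harmonic
  bending, kink constraint) and a compiled overdamped integrator

      γ ṙ = Σ F_WCA + F_A ê + F_ves + √(2γk_BT) η(t),
      γ_r ω̇ = Σ T_WCA + √(2γ_r k_BT) ζ(t),

  with γ = 1, γ_r = σ³γ/3, k_BT = 0.01, Δt = 10⁻⁴ τ in a periodic box of
  side 125 σ;
* configuration builders (relaxed kinked membranes, random rod fillings,
  deterministic frozen stackings at the kink);
* the full descriptor stack: distance-cutoff rod clusters, kink-axis
  motion metrics, Kåsa circle fits, body-frame spatial maps, KDE curves,
  and the six-way motion classification
  (unbiased / unclustered / linear / circular × forward / backward);
* the analytic stacking → rotation balance Σ|v_⊥||l| = I_vesicle·ω for
  ideal wall-aligned stackings, with enumeration of the symmetry-distinct
  stacking classes and validation against frozen-stacking simulations;
* time-dependent protocols (switchable rod species, kink-angle ramps) for
  steerable-motion experiments.

See `docs/methods.md` for the model definition, parameter defaults and
numerical choices.

## Worked example

```python
import math
import kinkvesicle as kv

params  = kv.SimulationParams(duration=300.0, seed=11)   # desk scale
vesicle = kv.VesicleSpec(kink_angle=5 * math.pi / 6)
rod     = kv.RodSpec(n_disks=3, peclet=75)               # trimers, Pe = 75

membrane = kv.build_vesicle(vesicle, params)
state    = kv.place_rods(membrane, rod, density=0.1, rng=params.seed)
traj     = kv.run(state, vesicle, rod, params, output_stride=20_000)

mc = kv.classify_motion(traj, vesicle, rod, params)
print(mc.regime, mc.normalized_speed, mc.circle_radius)
```

This builds the relaxed teardrop membrane (kink angle reached to better
than 0.01 rad, realized bond length ≈ 1.1 σ, perimeter ≈ 110 σ), fills it
with ten trimers and integrates 3·10⁶ steps. The classifier output is the
regime label plus the numbers behind it — the run above prints:

```
unclustered 0.03066584387804308 inf
```

meaning: within this short window the largest rod cluster held half the
rods in only 45% of the window frames — just under the 50% rule —
(kink-stack nucleation typically needs ~10³ τ), the centroid moved at 3%
of the free rod speed v_a = 0.75 σ/τ, and the track was straighter than
any finite fitted circle. Longer runs (≳ 10³ τ) in this cell develop a
dense parallel stack at the kink and switch the label to `linear_forward`
with v/v_a ≈ 0.05–0.1 and radii above the 500 σ linear/circular boundary.

The analytic rotor (`examples/04_stacking_rotation.py`) prints, for five
rods at a π/3 kink, the three rotation-causing stacking classes and their
predicted angular velocities:

```
   class  rotating  omega (rad/tau)
  (5, 0)      True        -0.001202
  (4, 1)      True        -0.000721
  (3, 2)      True        -0.000240
```

`examples/` contains one short narrative script per capability; the
`kinkvesicle` command-line tool exposes the same functionality
(`build`, `run`, `analyze`, `rotor`, `scan`, `protocol-demo`).

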