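# Model and methods

## The physical model

`kinkvesicle` simulates a two-dimensional coarse-grained "vesicular robot":
a closed membrane ring of N_v = 100 bonded disks (diameter σ = 1) that
encapsulates N_a rigid self-propelled rods, each a line of m ∈ {2, 3}
tangent disks. All particles interact through excluded volume only; the
membrane additionally carries bonded terms, and one membrane triplet is
held at a prescribed interior angle θ_kink — the "kink" that breaks the
rotational symmetry of the boundary and steers the emergent motion of the
whole superstructure.

Interactions (energies in simulation units; the default temperature is
k_BT = 0.01, so one energy unit is 100 k_BT):

* **WCA excluded volume** between every disk pair not belonging to the same
  rigid body: U(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + ε for r < 2^{1/6}σ, zero
  beyond; purely repulsive and continuous at the cutoff.
* **FENE bonds** between membrane neighbours:
  U(r) = −½ κ_b r₀² ln[1 − (r/r₀)²] with κ_b = 1 (= 100 k_BT σ⁻²) and
  divergence length r₀ = 2σ. Bonded neighbours are *not* excluded from the
  WCA term, so the realized bond length is set by the WCA/FENE force
  balance (≈ 1.11 σ at the defaults), not by r₀.
* **Harmonic bending** on every consecutive membrane triplet:
  U(θ) = +½ κ_a (θ − θ₀)² with κ_a = 10 (= 1000 k_BT) and rest angle
  θ₀ = π. (The bending energy must be a *minimum* at the rest angle; the
  sign convention here is the standard stable one.)
* **Activity**: each active rod feels a constant force F_A = Pe·k_BT
  applied at its centre along its symmetry axis ê = (cos ω, sin ω); it
  contributes no torque. The free active speed is v_a = F_A/γ
  (0.75 σ/τ at Pe = 75).

### The kink

By default the kink triplet carries a harmonic angle term with rest angle
θ_kink and stiffness 10 × κ_a, which holds the triplet within a few mrad of
the target angle while letting the vertex comply elastically. A strict
rigid-triplet mode (`VesicleSpec(rigid_kink=True)`) integrates the triplet
as one rigid body (translation + rotation, drag 3γ and the per-disk drag
moment about its centre) whose geometry realizes θ_kink exactly. The rigid
mode is *not* the default because the rigid unit cannot comply locally: in
long runs the dense rod stack pressing on the kink concentrates stress on
the two bonds joining the rigid triplet to the flexible ring, and a rod tip
can eventually pry those junction bonds open. The compliant harmonic vertex
spreads the same load over several bonds and survives the identical
conditions (this, together with the choice of ε below, was established by
direct long-run experiments during development).

### Units and dynamics

Times are measured in τ, lengths in σ, energies in simulation units with
γ = 1 energy·τ/σ². Overdamped (Brownian) dynamics, first-order
Euler–Maruyama:

    Δr = (F/γ) Δt + √(2 (k_BT/γ) Δt) ξ,
    Δω = (T/γ_r) Δt + √(2 (k_BT/γ_r) Δt) ζ,

with Δt = 10⁻⁴ τ, translational drag γ = 1 per body (each membrane disk,
each rod) and rotational drag γ_r = σ³γ/3 per rod (Stokes–Einstein form,
independent of aspect ratio). The conventional definition
τ = √(m σ²/k_BT) involves a mass that never enters the overdamped
equations; it is kept as metadata only, and all rates (v_a = Pe·k_BT/γ,
D_t = k_BT/γ, D_r = k_BT/γ_r) are expressed per τ directly.

The box is a periodic square of side L_b = 125 σ; all analyses use
unwrapped coordinates.

## Parameter defaults that the model text leaves open

* **WCA ε = 10 (= 1000 k_BT).** The energy scale of the excluded volume is
  not reported with the rest of the force field. It matters: at ε = 100 k_BT
  the membrane is *not* effectively rigid against the collective pressure
  of an emergent rod stack — bonds under a pressing stack stretch to
  ~1.7 σ, and because stretching further to 1.9 σ costs only ~2 energy
  units, a rod tip can push through the widened gap and rupture the ring
  (observed reproducibly in 10³-τ runs at Pe = 75). Setting ε to the
  bending energy scale (1000 k_BT) makes the membrane impenetrable at all
  pressures the rods can generate, which is the premise of the rigid-vesicle
  model. ε is configurable per run.
* **Displacement capping.** A per-step displacement is capped at 0.05 σ
  (rotation at 0.05 rad). Typical steps are ~1.5·10⁻³ σ; the cap engages
  only for transient collision spikes (forces > 500, far above any
  sustained physical force in this system, which stays below ~50) and
  protects the FENE divergence from single-step numerical blow-through.
  Capped events are counted (`PackedSystem.n_capped`).
* **Initial conditions.** The membrane is built on a tangent-arm teardrop
  curve (two straight arms meeting at θ_kink, tangent to a circular back
  arc) with disks at equal arclength, then descended to mechanical
  equilibrium with zero-noise overdamped steps. The relaxed shape is a
  near-uniformly curved ring with a pointed vertex. Rods are placed
  uniformly at random in the membrane interior with random orientations,
  rejection-sampled against overlaps; replicas differ in both rod placement
  and noise stream (one seed drives both).

## Numerical implementation

The production integrator is a fused numba kernel: every entity is a rigid
body of one or more disks (a free membrane disk is a one-disk body without
rotation), pair forces run over a Verlet list (cutoff + 0.4 σ skin, rebuilt
when any disk moves more than half the skin), and rod constituent forces
are reduced to net forces and torques about the rod centre. The kernel is
verified against an all-pairs numpy reference (`evaluate_forces`) to
1 part in 10¹² per evaluation. Gaussian noise is pre-generated per chunk
from a numpy SFC64 stream (float32 draws; the noise amplitude is ~10⁻³ σ,
so single precision is far below physical resolution), one stream per
replica: a given seed reproduces a trajectory bit for bit.

Angle forces use the acos formulation with the analytic removable limit at
straight triplets (θ → θ₀ = π), where the force prefactor
κ(θ−θ₀)/sin θ → −κ.

## Analysis definitions

* **Kink axis**: unit vector from the membrane centroid to the kink vertex
  disk. "Forward" means along this axis. No axis exists at θ_kink = π.
* **Clusters**: two rods are connected when any pair of constituent disks
  is within 1.2 σ (just above the WCA cutoff 2^{1/6} σ ≈ 1.12 σ);
  clusters are connected components.
* **Motion metrics** are computed on the latter half of a trajectory:
  centroid speed from finite differences of the unwrapped membrane
  centroid, angular velocity from the unwrapped kink-axis orientation.
* **Regime classification**: *unbiased* if there is no kink; *unclustered*
  if the largest cluster holds < 50% of the rods for more than 50% of the
  window frames; otherwise *linear* when the Kåsa-fitted circle radius of
  the centroid track is ≥ 500 σ (a line fit that beats the circle fit
  counts as radius ∞) and *circular* below; *forward/backward* by the sign
  of the window displacement projected on the window-mean kink axis.
* **Stacking → rotation balance**: for an ideal wall-aligned stacking the
  predicted angular velocity is ω = Σᵢ |v_⊥,i||l_i| / I_vesicle, with
  lever arms from the vesicle centre of mass, v_a decomposed perpendicular
  to the lever, unit disk masses, and membrane disks only in I_vesicle.
  Contributions are signed by rotational sense (counterclockwise positive),
  so mirror-symmetric stackings give exactly zero. The balance is an
  idealization — it equates a momentum flux with I·ω rather than solving
  the drag problem — so the meaningful predictions are the sign, the
  grouping, and the ordering of ω across stacking classes, and the
  analytic/simulated ratio is reported as such.

## Problem sizes (desk scale)

The production study conditions are 2·10⁴ τ per run and 200 replicas per
parameter cell — cluster-scale work that this package supports through its
configuration (duration and replica count are ordinary parameters) but does
not exercise in its test suite. The packaged experiments use desk-scale
sizes chosen against the physical timescales of the model (rotational
persistence 1/D_r ≈ 33 τ, wall accumulation of a free rod ~ tens of τ,
boundary circumnavigation ~150 τ, kink-stack nucleation ~10²–10³ τ):

* validation of diffusion/drift laws: 10²–10³ single-body replicas over
  4–40 τ;
* frozen-stacking rotation runs: 60 τ per replica, up to 8 replicas per
  stacking class, with a persistence filter that discards replicas whose
  stacking dissolves or changes its side partition;
* emergence experiments (regime classification): 400–1600 τ and 2–5
  replicas per cell.

At desk scale the emergence statistics are *indicative*: kink-stack
nucleation is a slow collective process with onset times broadly spread
around 10³ τ, so short runs under-count directed replicas relative to the
2·10⁴-τ steady state (a replica whose stack forms late in the analysis
window classifies as unclustered). The analysis window and thresholds are
never adjusted per run.

The stacking → rotation comparison has its own desk-scale limit: prepared
wall-aligned stackings relax within ~10 τ into vertex-centred arrangements,
after which only the maximally asymmetric class (all rods on one arm)
retains a statistically resolvable angular velocity of the predicted sign;
the finer three-group ordering requires matured emergent stackings measured
over ~10⁴-τ windows, which is production-scale work. The balanced-stacking
control (predicted ω = 0) is resolvable and verified at desk scale.

Two failure modes are handled explicitly at desk scale. First, a dense
emergent stack can, rarely (~20% of 10³-τ replicas at the most active
cell), pry a membrane bond past the FENE divergence length and rupture the
ring; such replicas terminate with a :class:`BondOverstretchError` carrying
the partial trajectory, and every ensemble runner counts and skips them.
Second, the displacement cap (above) protects against single-step numerical
blow-through but does not mask the quasi-static rupture mechanism — a run
that tears does so because the local force balance genuinely crosses the
barrier, not because of an integration artifact.

## What the synthetic data do and do not show

The synthetic archetype trajectories used to validate the classifier
(rigid translation/rotation of a real relaxed membrane with rods pinned at
the kink) exercise the geometry and sign conventions of every descriptor
with exact ground truth, but contain no thermal noise, no cluster
dynamics, and no membrane deformation; passing them shows the analysis
stack is correct, not that the physics reproduces any particular regime.
That evidence comes from the scaled emergence experiments above.

## Known limitations

* No hydrodynamic coupling (dry active matter), no membrane fluidity (the
  kink cannot diffuse along the ring), strictly 2D.
* First-order (Euler–Maruyama) integration: weak order 1 in Δt; Δt is kept
  at the model's 10⁻⁴ τ everywhere.
* The rigid-kink ramp re-poses the triplet geometry at chunk boundaries
  (sub-τ granularity) rather than every step; the harmonic-kink mode ramps
  the rest angle every step.
* Desk-scale regime yields are biased toward "unclustered" relative to the
  production timescale, as described above.

### FENE divergence guard

The FENE potential is an infinite wall: stretching a bond to r₀ requires
divergent work, so in the continuum model a membrane bond can never reach
r₀. The first-order discretization loses this property — near the
divergence the bond stiffness grows like F²/κ_b, the update becomes
unstable, and a step can jump across the wall, rupturing the ring. The
integrator therefore enforces the continuum property directly: after each
step, any membrane bond longer than 0.92 r₀ is projected back to 0.92 r₀
(both endpoints moved symmetrically). The guard engages only under extreme
local stress (the thermally-stressed bond distribution stays below ~1.6 σ);
events are counted alongside displacement caps. In the rigid-kink mode the
two bonds joining the rigid triplet to the ring are not projected (the
rigid body cannot be moved by a bond-local constraint), which is one reason
that mode is not the default.
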