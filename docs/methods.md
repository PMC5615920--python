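# Methods

`contranet` couples an analytical prediction of whether a disordered
cytoskeletal network contracts or expands with a 2D agent-based
Brownian-dynamics simulation of the same declared system, so the two can be
compared quantitatively.  This note records the model, the numerical
choices, and what the synthetic scenarios do and do not capture.

## The configuration census and χ

A percolated network transmits tension through *elementary bridges*: the
piece of filament between two bound connector subunits.  The theory lists
every configuration of two subunits on a focal filament (oriented minus →
plus, subunit positions x₁ < x₂) and records for each

* the expected separation a_i,
* the relative speed v_i = v(x₂) − v(x₁) computed from the *unloaded* motor
  speeds (+v₀ for a plus-end motor, −v₀ for a minus-end motor, 0 for
  binders), and
* a probability weight p_i.

A configuration with v_i < 0 pulls its two network anchor points together
(contractile); v_i > 0 pushes them apart (expansile); v_i = 0 is neutral
(co-moving motors) or static (two binders).  The prediction is the scalar

    χ = Σ p_i Φ_i v_i / Σ p_i a_i,

contraction for χ < 0 and expansion for χ > 0.  Only the numerator's sign
and relative magnitude matter for the phase prediction; the denominator
normalizes χ to a strain rate.  The predicted radial velocity of an
isotropic network of radius R in d dimensions is taken as dR/dt = χ·R/d,
with the overall constant exposed (`predicted_radial_rate(..., constant=)`)
because absolute calibration against a particular drag environment is out
of scope.

### Census rules

* Each of the two connectors contributes the one subunit bound to the focal
  filament; the partner subunit anchors to the rest of the network.  Both
  subunits of a single connector are never placed on the focal filament
  (such self-loops carry no network stress).
* Either subunit of a heterodimeric connector can be the focal one.
* Minus-end binders sit at abscissa 0, plus-end binders at L; two same-end
  binders coincide (a_i = 0, static).  Anywhere-binding subunits of
  different kinds yield two distinct ordered placements; identical kinds
  one.
* Entries identical under (subunit kind, unloaded speed) are merged, so two
  connector types sharing a motor subunit contribute one merged motor
  state.  This merging is what makes the census of the two motor/end-binder
  types contain six configurations and the motor+crosslinker census four.
* Default separations: mesh size L₁ for two side-bound subunits, L/2 for a
  side/end pair, L for opposite ends.  These only scale χ, never flip its
  sign.

### Occupancy models

p_i is the product of the two site probabilities.  Three interchangeable
models supply them:

* `OccupancyModel.actomyosin(P_M, P_C)` — the two-species model with
  crosslinker precedence: a crossing acts as a moving motor site with
  probability P_M(1−P_C) and as a static crosslinked site with probability
  P_C.  This reproduces the closed forms below exactly.
* `OccupancyModel.simplified(system)` — all kinetics and counts equal; each
  subunit kind receives a site probability proportional to its share of
  subunit slots.  Used for the 15-type pair survey, where only relative
  weights matter.
* `OccupancyModel.kinetic(system, n_crossings)` — a Poisson closure: the
  mean occupancy per crossing is μ = count·duty/crossings with duty =
  k_on/(k_on+k_off), and P(≥1) = 1−exp(−μ).  Used for composition sweeps,
  where it produces the required vanishing endpoints and interior optimum.
  The closure is a declared modeling choice, not a fitted quantity.

### Regime weighting Φ

* rigid: Φ ≡ 1 — with motors and crosslinkers the contractile and expansile
  entries cancel exactly and the network is neutral.
* flexible: expansile entries are discarded (Φ = 0): any compressed segment
  buckles.  Numerator of the motor+crosslinker system:
  −P_M P_C (1−P_C) v.
* semiflexible: a segment buckles only if it is longer than the Euler
  threshold b = π√(κ/f) (pinned-end boundary conditions — connectors are
  point constraints — with f the motor stall force) *and* no intermediate
  crossing is pinned by a crosslinker.  With mesh size L₁ a buckling length
  spans β₀ = b/L₁ crossings, so the expansile entry survives with
  probability 1 − (1−P_C)^(max(β₀,1)−1), giving the numerator
  −P_M P_C (1−P_C)^max(β₀,1) v.  The exponent is clamped at one so the
  b ≤ L₁ limit reproduces the always-buckle flexible expression exactly;
  one power of (1−P_C) lives in the configuration weight (the motor site
  must be free of crosslinkers) and the remaining β₀−1 in the survival
  factor.

The mesh statistics come from the random-needle result: a filament of
length L among n uniformly placed filaments in area A crosses
2(n−1)L²/(πA) others on average; L₁ = L/crossings.  This is validated
against a Monte-Carlo intersection counter on a torus in the test suite.

## The Brownian-dynamics engine

Filaments are oriented strings of equidistant points (segment 0.5 μm,
default length 3 μm) moving by overdamped explicit Euler–Maruyama steps
with isotropic per-point drag γ_point = γ·segment (γ = 5 pN·s/μm² by
default, chosen so a free 3 μm filament diffuses a negligible fraction of
its length over 30 s).  Forces: discrete bending elasticity (the gradient
of (κ/2seg³)Σ|p_{i−1}−2p_i+p_{i+1}|², which conserves total momentum by
construction), zero-rest-length Hookean connector springs (k = 100 pN/μm),
and thermal noise of variance 2kT·dt/γ per degree of freedom
(kT = 0.0042 pN·μm).

**Inextensibility.**  Constant filament length is enforced by constraint
projection after each step: the linearized segment-length constraints form
a tridiagonal Lagrange-multiplier system per filament (diagonal 2,
off-diagonals −ê_i·ê_{i+1}) solved by the Thomas algorithm, batched across
filaments and iterated to a 0.05 % relative tolerance.  The correction
field telescopes along the chain, so filament centroids — and hence
momentum balance — are preserved exactly.  This replaces stiff longitudinal
springs, which would add the dominant stiffness to the explicit stability
budget for no physical gain.

**Rigid filaments** (infinite κ) advance as rigid bodies: translation with
drag γL, rotation about the centroid with drag γL³/12, noise on both.

**Connectors.**  Free connectors are point particles with diffusivity
kT/γ_c (γ_c = 0.002 pN·s/μm, D ≈ 2 μm²/s).  Each subunit binds at rate
k_on = 10 s⁻¹ when a filament lies within ε = 0.05 μm, attaching at the
closest point (end binders: at their designated end when it is within
δ = 0.05 μm); both subunits of one connector never occupy the same
filament.  All subunits detach at the force-independent rate
k_off = 1 s⁻¹, a default chosen so the motor run length v₀/k_off = 1 μm
stays below the filament length: bound motors then sample filament
positions roughly uniformly, which is the occupancy assumption of the
census theory.  Processive motors whose run length exceeds the filament
length instead pile up at the ends they walk toward (the antenna effect)
and leave the theory's validity domain.  Motor subunits advance their abscissa at
v = v₀·clamp(1 − f_opp/f_s, 0, 1) where f_opp is the component of the
spring force opposing motion (v₀ = 1 μm/s, f_s = 5 pN); the clamp declares
that assisting loads do not produce super-speed and opposing loads never
reverse the motor.  A motor reaching a filament end detaches immediately.
The kinetic parameters above are declared defaults, all exposed in the
scenario schema.

**Minifilaments** are rigid 0.5 μm rods with a plus-end motor subunit
permanently at each end, advanced as rigid bodies with translational drag
γ·L_b and rotational drag γ·L_b³/3 (the end-heavy drag of two motor heads
at ±L_b/2 rather than a uniform rod, since the heads dominate the bound
geometry).

**Binding search.**  A k-d tree over filament vertices (with native
wrap-around in periodic boxes) is rebuilt every 10 steps with a 0.1 μm
motion margin; binding attempts are sampled first at rate k_on and only
sampled subunits are searched, which is distributionally identical to
testing everyone and much cheaper.  Candidate attachments are verified with
exact point-segment distances, so the tree prunes but cannot produce false
positives.

**Turnover** removes one uniformly chosen filament and inserts a fresh
straight one at a random pose, as Poisson events at total rate R; the
filament count is invariant and the mean individual lifetime is N/R.

**Stability.**  The explicit scheme requires dt < γ_point/(4k_max); worlds
violating this at build time are rejected.  Dense spots (many springs
converging on one filament) can transiently exceed the single-spring bound,
so `run_simulation(adaptive_dt=True)` halves dt when a step would move any
point further than half a segment (the step is discarded before any state
changes) and doubles it back after a stable stretch.  An optional
`kinetics_stride` performs binding/unbinding/motor updates every few
dynamics steps with correspondingly scaled probabilities; at the default
rates (k_on·dt ≪ 1) the sampled distributions are unchanged and the long
cortex runs use stride 5.

## Observables

* Network radius: √2 × rms distance of filament points from the centroid —
  the exact disc radius for a uniformly filled disc; under periodic
  boundaries the centroid is the per-axis circular mean and distances use
  the minimum image.
* Contraction rate: minus the least-squares slope of R(t)/R(0) over the
  window from t = 0 until the normalized radius first changes by 20 %
  (positive = contracting; exact on affine series).  Series with no
  qualifying window fall back to the first 20 % of samples and are flagged.
* Local density: filament points in a fixed axis-aligned square covering
  6 % of a periodic box.
* Pulsatility: the linearly detrended density series is scanned for local
  maxima above one standard deviation separated by at least one filament
  lifetime; *pulsed* requires ≥ 3 peaks and a coefficient of variation
  > 0.2 over the steady window (first 20 % of the series discarded).
  Otherwise the series is a *monotonic* collapse when it has either settled
  onto a persistent pattern (early/late variance ratio of the detrended
  series > 5) or is still condensing monotonically toward one
  (|corr(t, density)| > 0.8) — at desk scale the collapse often has not
  completed within the simulated window, which is why both signatures are
  recognized; anything else is *neutral*.  The thresholds are named module
  constants.
* Neutrality band for theory–simulation comparisons: 3× the standard
  deviation of fitted rates of connector-free networks of the same
  geometry across 5 seeds.

## Scenario presets and problem sizes

Presets carry the published study conditions at scale 1.0 (`actomyosin`:
1,500 flexible filaments κ = 0.01 pN·μm², 12,000 + 12,000 connectors, disc
radius 15 μm; `end-binder-mixture`: 1,500 rigid filaments with 48,000 /
1,500 motor/end-binder connectors, radius 15 μm; pair-survey conditions:
4,000 filaments, 32,000 + 32,000 connectors, radius 25 μm;
`cortex-turnover`: 1,400 filaments κ = 0.075 pN·μm², 22,400 minifilaments,
5,600 crosslinkers, 16 μm periodic box, R = 64 s⁻¹).  The scale factor
multiplies counts and the domain area jointly, preserving all number
densities, composition ratios, and the filament lifetime, so scaled-down
runs probe the same physical regime with stronger finite-size noise.

The shipped comparison studies run at desk scale, chosen as the smallest
sizes at which the qualitative behaviors are robust in a pure
numpy implementation: the pair-survey subsample at scale 0.025 (~100
filaments, 1,600 connectors, 10 s simulated per system) and the pulsatility
runs at scale 0.16 (224 filaments, 4,480 minifilaments + 1,120
crosslinkers, box 6.4 μm, 110 s ≈ 5 filament lifetimes, kinetics stride 6).

## What the synthetic scenarios do not capture

Everything is 2D; steric interactions are deliberately absent (in 2D they
would force unphysical crossings artifacts); filaments neither grow nor
shrink; unbinding is force-independent; hydrodynamic coupling is ignored;
connector counts are fixed.  Passing tests therefore demonstrate the
internal consistency of theory and simulation under these model
assumptions — not that a particular biological cortex follows the same
numbers.  Mechanisms requiring two filaments and two connectors (the
zipper effect) or motor-accumulation profiles (the antenna effect) are
outside the one-filament census by construction.

## Known limitations

* The explicit integrator needs small steps in dense contracted foci;
  adaptive halving keeps runs stable but slows the final collapse phase.
* The neutrality band is measured on connector-free networks; active but
  theoretically neutral systems (e.g. balanced motor mixtures) fluctuate
  more than that baseline and weak residual drifts — buckling-mediated
  cohesion among them — can exceed it at small scale, even when their
  rates are an order of magnitude below those of non-neutral systems.
* χ's absolute scale depends on the declared a_i convention; only signs and
  magnitude ratios are compared with simulation.
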