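# Methods

## The walking model

Each pedestrian *i* is a disc of radius `body_radius` = 0.2 m with a
comfortable speed `v0_i` and an attributed circulation sign (±1).  Its
destination is refreshed every step to a point `d_dest` = 5 m away along
the ring tangent at its current position, so the goal keeps sliding ahead
around the corridor.  Steering works in two stages:

1. **Heading choice.**  Candidate headings α are sampled on a uniform grid
   of `n_directions` = 61 values spanning ±45° (the vision half-angle)
   around the looking direction α₀ (toward the destination).  For each
   candidate, the anticipated free path f(α) is the distance the body
   could travel at `v0_i` before first surface contact with a wall circle
   or another pedestrian, the latter extrapolated linearly at its current
   velocity; free rays are capped at the horizon `d_max` = 10 m.  The
   chosen heading minimises the anticipated distance to the destination,
   d(α)² = d_max² + f(α)² − 2·d_max·f(α)·cos(α₀ − α).  Ties prefer the
   smallest deviation |α − α₀|; exact left/right ties are broken by a
   seeded coin flip so no systematic chirality enters.
2. **Speed choice.**  `v_des = min(v0, d_h/τ)` with `d_h = f(α_des)` and
   τ = 0.5 s: pedestrians keep a time-headway τ to the first obstacle on
   their chosen path and stop when it reaches contact.

The acceleration combines velocity relaxation toward the desired velocity
with linear-spring contact forces against overlapping bodies and walls
(`k_contact` = 10³ per metre of overlap, entering the acceleration
directly):

    dv_i/dt = (v_des e_des − v_i)/τ + Σ_j k·g(r_i + r_j − d_ij)·n_ij + wall terms,

with g(x) = max(x, 0).  Two readings of the contact regime are
implemented; the default `contact_mode='add'` keeps the steering term
active during contact (the combined equation above), while
`'substitute'` suppresses it whenever any overlap exists.  The additive
form is the default because under strict substitution the dense N = 60
crowd never reaches the ordered phase: contacts strip agents of steering
exactly when coordination matters most.

Two numerical rules matter for dense crowds and are worth stating
explicitly:

* **Touching bodies are excluded from anticipation.**  A disc at contact
  distance subtends ~90°, so a single touching neighbour would otherwise
  occlude the entire ±45° vision field and every contact would become an
  absorbing deadlock (verified: all speeds → 0 within 30 s at N = 60).
  Contact is instead resolved by the repulsive spring, and f(α) counts
  only collisions that have not yet happened.
* **Integration step.**  Symplectic Euler (velocity then position) with
  dt = 0.025 s.  The pair contact spring oscillates at √(2k) ≈ 45 rad/s,
  so steps above ~0.045 s are outside the stability region and blow up in
  dense crowds; dt = 0.025 leaves a factor-two margin while keeping a 60 s
  N = 60 run at a few seconds of wall time (the steering kernel is
  numba-compiled, with a pure-numpy reference implementation that the test
  suite checks against it).

Runs start from rest at uniformly random non-overlapping positions
(rejection sampling), with N/2 agents per circulation sign and v0 drawn
from a Gaussian(1.2, σ) truncated below at 0.3 m/s (an untruncated draw at
σ = 0.3 can produce near-zero or negative walkers).  Trajectories are
recorded at 10 Hz regardless of dt.  Every run is a pure function of its
seed.

## Clustering and lifetimes

Pedestrian *j* follows *i* at time *t* if min over s ∈ [t, t+1 s] of
|x_j(s) − x_i(t)| < 0.6 m (forward window; frames within one window of the
recording end are skipped rather than evaluated with a shrunken window).
Clusters are connected components of the symmetrised relation.  Edges are
restricted to same-direction pairs by default: lanes are groups walking
the same way, and an unrestricted rule chains opposite streams through
near-passes so thoroughly that disordered states collapse to a handful of
components (measured: maximum ~9 components at N = 60 instead of ~19).
The direction-agnostic variant remains available via
`ClusteringParams(same_direction_only=False)`.

Partitions are evaluated at 10 Hz, so lifetimes have 0.1 s resolution.  A
cluster's identity is its exact membership set; any gain or loss kills the
old set and births the new ones.  Sets alive at the last evaluation are
right-censored at their age, and survival is estimated with the
Kaplan–Meier product-limit estimator (via `lifelines`) — discarding
censored sets instead would bias lifetimes downward on 60 s recordings.

## Stretched-exponential fit

`p(t) = a·exp(−b·t^κ)` is fitted by scanning κ over [0.1, 1.5] in steps of
0.01 and, at each κ, fitting a weighted least-squares line of log p
against t^κ; the κ with the highest R² wins, with a = exp(intercept) and
b = −slope.  Points with t ≤ 0, p ≤ 0 or fewer than 3 surviving clusters
are dropped.  Weights are proportional to p itself: Kaplan–Meier noise in
log space grows without bound as p → 0, and an unweighted fit picks up a
systematic upward κ bias of up to +0.07 from the tail, while
inverse-variance (Greenwood) weights over-concentrate on the quantised
head of pooled simulation curves.  The bounded weight w ∝ p recovers
(κ, b) from 5000 inverse-CDF-sampled lifetimes within ±0.04 / ±5%,
checked in the test suite for κ ∈ {0.4, 0.5, 0.6, 1.0}.

T95 — the age at which a cluster has a 95% chance of having changed — has
the closed form `(ln(a/0.05)/b)^(1/κ)`; a ≤ 0.05 yields the boundary
value 0 with a warning.  The amplitude a is fitted, not pinned to 1, and
lands close to 1 on simulated curves.

## Field measures

Local density at a point x is Σ_j exp(−d_jx²/R²)/(πR²) with R = 0.7 m;
the 1/(πR²) prefactor normalises the kernel to unit mass so the plane
integral of ρ returns N.  The directional profile ρ(θ, t) averages the
local density over 20 radial sample points between the walls along
direction θ; the angular grid defaults to 72 sectors of 5°.  The local
radial speed v_r(θ, t) is the sector mean of |dr_j/dt| (absolute value:
lane-leaving in either radial sense counts), with radial velocities from
central finite differences at the 10 Hz trajectory rate; empty sectors
are NaN and are excluded — never imputed as zero — from the Pearson
correlation between ρ and v_r, which discards the first 10 s transient.

## Payoff

Flows are counted at 8 equally spaced radial cross-sections: a crossing
counts only in the pedestrian's attributed sense (wrong-way excursions do
not add), and the first 10 s are discarded.  The collective payoff
C = (J_cw + J_acw)/J_uni compares bidirectional throughput with a
unidirectional baseline at the same N, σ and geometry, averaged over 3
seeded all-one-direction runs; C = 1 means the opposing stream costs
nothing.  Since the baseline question is open — a σ-matched heterogeneous
crowd or a homogeneous one — the σ-matched reading is used ("same density
level" fixes N, not σ).  The individual payoff P_i is the time-mean of
(v_i·ê_i)/v0_i with ê_i the tangent in i's attributed sense; it can
transiently exceed 1 through contact pushes and is reported unclamped.
The heterogeneity sweep runs 5 bidirectional replications per σ at
N = 30, pools lifetimes per σ for the T95 fit, and bins P by v0 in
0.1 m/s bins (empty bins absent).

## What the synthetic fixtures do and do not show

The fixtures are idealised by construction: perfectly circular lanes at
constant angular speed, instantaneous switches between static
configurations, and uncorrelated random walks.  They make the analysis
answers provable (a two-lane fixture must yield exactly 2 clusters for
every δ ∈ [0.4, 0.8] m and window ∈ [0.5, 1.5] s; a switching fixture
must yield completed lifetimes exactly equal to its period), which is the
point — realism is the simulator's job.  Passing fixture tests therefore
validates the measurement machinery, not the behavioural model; the
simulation-level checks (order/disorder alternation, relaxation
exponents, density/radial-speed coupling, heterogeneity trends) are the
ones that probe the model.  Tracking noise is emulated as i.i.d. Gaussian
position jitter, which reproduces the amplitude but not the temporal
correlation or occlusion structure of real motion-capture error.

## Problem sizes

The packaged analyses use 60 s recordings at 10 Hz, matching the
experimental protocol.  Relaxation exponents are pooled over 10 seeded
replications per crowd size in the test suite and 20 in the acceptance
script; the heterogeneity sweep uses N = 30 with 5 replications per σ and
3 baseline runs.  These sizes keep the full suite at roughly ten minutes
on one CPU while leaving the pooled survival curves with thousands of
lifetimes each.

## Known limitations

* The model sustains contact-mediated flow in dense opposing streams;
  real pedestrians rarely touch.  Radial jostling during contact inflates
  v_r in crowded sectors, which weakens (but does not flip) the negative
  density/radial-speed coupling relative to gap-driven overtaking.
* The relaxation exponent at N = 60 comes out near 0.6 rather than 0.5,
  at the edge of the reproduction tolerance; at N = 30 it is ~0.65.  The
  N-ordering of the two exponents reverses under the direction-agnostic
  clustering variant, suggesting the exponents are sensitive to the exact
  follow-edge rule, which the lane definition leaves open.
* Lifetime resolution equals the evaluation step (0.1 s); exponents shift
  by ~0.05 across evaluation rates between 1 and 10 Hz.
* No social groups, anticipation beyond linear extrapolation, or
  non-circular obstacles.
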