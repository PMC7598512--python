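# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Body model

The swimmer is five rigid segments in the sagittal plane: left leg, right
leg, trunk, combined arms, head. Legs and trunk share the hip point; arms
and head attach at the shoulder (the distal end of the trunk). The
generalized coordinates are the hip position and five segment orientation
angles (CCW from +x, so downward-from-horizontal is negative); with their
velocities the state has 14 components. The fingertip is a rigid
extension of the arm axis beyond the wrist (`hand_extension`), because
entry distance is defined at the fingertips while the digitized landmark
is the wrist.

Inertial parameters come from anthropometric measurements through a
coefficient table of relative masses, COM fractions and radius-of-gyration
fractions per sub-segment (head+neck, thorax, abdomen, pelvis, upper arm,
forearm, hand, thigh, shank, foot). The shipped defaults are the adjusted
Zatsiorsky fractions in common biomechanical use (de Leva style); they are
deliberately swappable — every downstream computation consumes only the
composed `AnthropometricProfile`. Sub-segments stack end to end; feet and
hands carry mass beyond the distal landmark (pointed toes, outstretched
hands) without extending the landmark length. Composed masses are
rescaled to match measured total body mass exactly. Circumference columns
are accepted in the measurement schema for completeness but the default
regression-fraction table uses lengths and total mass only.

Conventions fixed here: the head attaches at the shoulder point, and the
"legs trail" branch is used for full extension (θ_leg = θ_trunk + π,
θ_arms = θ_head = θ_trunk).

## Entry-state reconstruction

Input: landmark positions (ankles, hip, shoulder, vertex, wrist) in three
frames 0.02 s apart centred on water entry, with optional per-landmark
weights (default equal — the study design reports a single pooled
digitization reliability, not per-landmark precision).

The three frames are fitted by three chain configurations. Rigid segment
lengths are enforced *by parameterization* (angles + hip position can
only produce length-consistent landmarks), and the flight-phase mechanics
by *elimination*: the only external force before entry is gravity, so the
whole-body COM must satisfy COM₁ − 2·COM₂ + COM₃ = (0, −g)·Δt². Because
the COM is the hip position plus an angle-dependent offset, the third
frame's hip position is a function of the other 19 parameters, and the
problem becomes an unconstrained nonlinear least squares (36 residuals,
19 parameters) solved by Levenberg–Marquardt. Initialization is
deterministic: per-frame hip from the measured hip, angles from atan2 of
measured landmark pairs. Entry state = middle-frame configuration;
velocities are central differences over 2Δt (no second derivatives are
ever needed). Angular-momentum equality across frames is *not* imposed.

At the study's digitization noise (0.7 cm SD per coordinate) the
Monte-Carlo mean COM position error is ≈ 2.5 mm and the mean COM speed
error ≈ 0.16 m/s (200 replicates; asserted bounds 20 mm and 0.25 m/s).
A central-difference velocity of an exact rigid rotation carries an
O(ω³Δt²) truncation error (~5·10⁻⁵ rad/s here), which sets the noiseless
velocity tolerance.

## Immersion dynamics

From water entry until all landmarks are below the waterline the chain
moves under gravity only; hydrodynamic forces (drag, buoyancy, added
mass, splash) are deliberately absent. The body is "pulled to extension"
by visco-elastic moments at the four joints:

M = −k · dead(θ_rel; θ₀) − b · θ̇_rel,

where dead(·) is a symmetric dead zone of half-width θ₀ about full
extension (zero moment inside, linear outside). At the default θ₀ = 0 the
spring is purely linear. Damping acts everywhere, including inside the
dead zone. Defaults k = 1000 Nm/rad, b = 150 Nms/rad, θ₀ = 0 are the
values selected by the entry-hole grid search; the search grid defaults to
k ∈ {600…1000} Nm/rad, θ₀ ∈ {0…20}°, b ∈ {5, 25, 50, 100, 150} Nms/rad,
with ties broken toward (higher k, higher b, lower θ₀).

Equations of motion are assembled from segment-COM Jacobians:
M(q)·q̈ = Q_gravity + Q_joint − Σ m_k·J_kᵀ(J̇_k·q̇), with rotational
inertias on the diagonal. The test suite cross-checks this assembly
against an independent symbolic Lagrangian derivation (sympy) at random
states (agreement to 1e-8).

Integration is classical fixed-step RK4 at dt = 1e-4 s — the 1000 Nm/rad
springs are stiff, and the step-halving test confirms event times are
converged to ≪ 1e-5 s at this step. Events (COM crossing the waterline,
full immersion) are located by linear interpolation between bracketing
steps. Because the moments are internal, two exact invariants hold and
are asserted on every simulated trajectory in the tests: the COM follows
the closed-form projectile, and whole-body angular momentum about the COM
is constant. Total mechanical energy (kinetic + gravitational + elastic)
is non-increasing whenever b > 0.

The entry-hole diameter is the range of x-coordinates where any body line
(legs, trunk, shoulder→fingertip, shoulder→vertex) intersects the
waterline at any step. Segments are lines, so a perfectly streamlined
vertical entry gives a vanishing hole; oblique entries accumulate drift
because gravity curves the COM path while the body axis rotates at its
own rate.

A useful exact property: with θ₀ = 0, a perfectly aligned body with a
common angular velocity is an invariant manifold of the dynamics — it
stays aligned and rotates uniformly. The synthetic generator exploits
this to evolve its (aligned) entries in closed form; the equivalence with
the RK4 simulation is tested to 1e-6.

## Start metrics

All Table-style variables are computed from the entry state and the
interpolated COMcrossWL state: COM/hand positions, velocity components,
direction (atan2) and magnitude, trunk entry angle at both instants, and
the absolute wrapped difference between trunk axis and velocity direction
at COMcrossWL (wrap convention: difference taken in (−π, π], then the
absolute value). Scalar metrics: hip velocity at 5 m = 1/(t₅.₅ − t₄.₅);
outcome5m = v₅ₘ/TTO5; z-score15m standardizes TTO15 per swimmer with the
sample (n−1) SD. The 4.5/5.5/15-m crossing times are inputs (from timing
systems in real data, from the generator in synthetic data); this package
does not re-derive them from video.

## Statistical pipeline

Screening: pooled OLS of each of the three responses (outcome5m, TTO15,
z-score15m) on each candidate; a candidate is dropped if any slope
p-value exceeds 0.3. Collinearity: connected components of the graph with
edges |r| ≥ 0.75 among survivors; per component the variable with the
highest *average bearing* is kept — implemented as the mean r² across the
three screening responses (a `min_p` strategy is available; "average
bearing" admits several readings and this one is the package's
documented choice).

Mixed models: `statsmodels` MixedLM with a per-swimmer random intercept.
Coefficients, SEs and Wald p-values (normal reference) come from the REML
fit; a parallel ML fit supplies log-likelihoods for likelihood-ratio
tests (χ² = 2Δℓ, df = parameter-count difference). Step-down removes the
highest-p fixed effect, refitting until all remaining p < 0.05; ties
remove the later variable in declared order. The sex confounder rule
refits with sex added and retains it if any coefficient changes by ≥ 10%
relative. Validation: VIF_j = 1/(1 − R²_j), Shapiro–Wilk on the estimated
random intercepts (BLUPs), LR tests final-vs-null and full-vs-final, and
*two* variance-explained measures reported side by side —
1 − σ²_resid/var(y) and the conditional R² (variance of fixed+random
fitted values over var(y)) — because the two conventions differ by up to
a percentage point and the literature rarely says which it used. No
multiple-testing correction is applied anywhere, matching the screening
philosophy of the procedure. Optimizer note: the default MixedLM
optimizer is used, with Powell/CG retries when convergence fails or the
likelihood is non-finite; a vanishing random-intercept variance is
returned flagged (`singular=True`), with BLUPs identically zero.

## Synthetic cohorts

The generator reproduces the study design: 14 swimmers (8 M, 6 F), six
instruction conditions ("regular", "short block time", "steep take-off",
"flat take-off", "submaximal effort", "without arms") × 4 repeats over
three sessions ("regular" always in session 1, the rest shuffled 1+2+2).
Anthropometrics are drawn from the published group means/SDs (height
1.86 ± 0.04 m / 1.73 ± 0.04 m, mass 78.9 ± 5.0 / 65.6 ± 7.5 kg) with
height-proportional segment lengths.

Entry states are *aligned* bodies with the fingertip pinned on the
waterline: per start the generator draws the horizontal COM velocity,
entry distance and COMcrossWL entry angle around the published condition
means, decomposed into sex shifts, between-swimmer offsets and
within-swimmer noise such that the pooled spreads match the published
pooled SDs (the split itself is not published; the defaults are the
package's calibration). The body's angular velocity is chosen so the
rigid rotation reaches the drawn COMcrossWL entry angle exactly at the
closed-form COM crossing time. Responses are linear predictors plus a
per-swimmer intercept plus Gaussian residual:
TTO15 with coefficients (9.623, −0.310, −0.575, −0.511) and residual SD
0.23 s; TTO5 with (2.033, −0.144, −0.106, −0.178) and residual SD
0.042 s (back-computed from the published TTO5 variance 0.02 and its
91.3% explained fraction). Random-intercept SDs (0.45 s and 0.10 s, plus
small sex shifts) are calibrated so the total response variances match
the published 0.38 and 0.02.

Hip crossing times are synthetic plumbing: underwater hip speed decays in
space, v(x) = v_s + (v_x,entry − v_s)·exp(−(x − x_entry)/2 m), toward a
per-swimmer swim speed (1.9 ± 0.15 m/s), and the 4.5/5.5-m times are
placed around the drawn TTO5 by the closed-form time-of-passage integral.
This makes the emergent hip velocity at 5 m — and therefore outcome5m —
co-vary with the entry state the way the published screening table shows,
but it is *not* a hydrodynamic model. Rare draws where the hip would
reach 4.5 m before water entry are shifted forward in time (well under 1%
of starts).

What the generator does **not** emulate: bent/asymmetric entries (real
swimmers are only approximately aligned), hydrodynamic deceleration of
the COM, skill-dependent underwater undulation, digitization outliers and
frame-timing error, or condition effects on vertical entry velocity.
Passing tests therefore show that the pipeline recovers known structure
under the study's nominal conditions — not that the model is correct for
arbitrary real video.

A truth ledger (every latent draw per swimmer and start) accompanies each
cohort; reading only the ledger reproduces every response exactly, which
is asserted in the tests. All randomness flows from a single seeded
generator: identical config + seed gives byte-identical CSV output.

## Problem sizes used in the checks

The statistical acceptance checks run 100 replicate cohorts of
14 × 24 starts for recovery/power/null-rejection and 500 small
random-intercept datasets (12 groups × 12) for the null LR distribution;
the reconstruction Monte-Carlo uses 200 triplets (100 in the acceptance
script). These sizes put the Monte-Carlo error well below the asserted
margins while keeping the default suite in the minutes range on one core.

## Known limitations

- The reconstruction reproduces the *published description* of the
  constrained-optimization step (rigid segments + ballistic COM); the
  original algorithm's internals are not public, so bit-compatibility is
  not claimed.
- A near-boundary random-intercept variance makes single REML estimates
  fluctuate; tests use medians over replicates where that matters.
- The collinearity-pruning decision between entry distance and COM-x at
  COMcrossWL is intrinsically close (their average bearings differ by
  ~0.02 in mean r², in synthetic and published data alike), so the
  selected set can differ between replicate cohorts even when the fitted
  coefficients of the final model are stable.
- Entry-hole minimization scores line-segment crossings; there is no
  cross-sectional area or splash physics.
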