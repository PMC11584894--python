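# Methods

This note documents the model, the estimation problem, the numerical
choices and the synthetic benchmark that ships with the package — the
things a maintainer or a careful user needs that the API reference does
not say.

## Rigid-body model

A quadruped is a tree of solid cylinders. Each link carries three
*absolute* orientation angles (intrinsic X–Y–Z Euler angles of the link in
the world frame); the generalized coordinate vector is

    q = [base position (3), link angles (3 per link)],   nq = 3 + 3L,

so 30 coordinates for the bundled 9-link model and 54 for the 17-link
cheetah layout. Link inertia comes from the solid-cylinder closed forms
(transverse m(3r² + L²)/12, axial m r²/2) about the cylinder axis, which is
a per-link local unit vector: +x for axial body segments, −z for leg
segments. Letting legs point "down" in their zero pose keeps their pitch
angles near zero and far from the Euler singularity at ±π/2; the synthetic
gaits never approach it. No reparameterisation is attempted — gimbal
proximity is a documented limitation, not an error.

Because angles are absolute, joints do not remove coordinates. Joint
geometry is enforced by explicit scalar constraints on rotation-matrix
columns: a revolute joint (elbows, knees) requires the child's x and z axes
to stay orthogonal to the parent's y axis (two residuals, leaving rotation
about the parent's y only); a universal joint (mid-spine of the 17-link
layout) keeps one of them (one residual); a ball joint (hips, shoulders)
adds none. The multipliers of these constraints — the joint constraint
torques λ_c — appear in the equation of motion next to the ground reaction
forces λ_g:

    M(q) q̈ + C(q, q̇) q̇ = G(q) + B(q) τ + J_cᵀ λ_c + J_gᵀ λ_g .

Joint torques τ have one variable per joint degree of freedom (1 revolute,
2 universal, 3 spherical) and act as equal-and-opposite pure torque pairs
on the two links of the joint, mapped through the links' angular-velocity
maps; base translation and orientation are unactuated. Spherical-joint
torques are expressed in the world frame; reported torque magnitudes are
convention-dependent (link frames sit at the proximal joint).

M, C q̇ and G are evaluated numerically as projected Newton–Euler sums:
per-link COM and angular Jacobians give M = Σ JᵀG J; the inverse-dynamics
evaluation at (q, q̇, 0) and (q, 0, 0) yields C q̇ and −G. This closed-form
numeric route (rather than symbolically compiled Lagrangians) was chosen
because it evaluates in microseconds for batches of states, is valid for
any skeleton without a compilation step, and is complex-analytic, so the
estimator obtains machine-precision Jacobians by complex-step
differentiation. The test suite validates it against a finite-difference
Lagrangian oracle (energies differentiated numerically) on more than a
hundred random states and by passive-flight energy conservation.

## The estimation problem

Given per-camera 2D keypoint tracks, calibrations, a skeleton and a known
contact schedule, one trajectory optimisation estimates all q_k, τ_k,
λ_c,k and λ_g,k on an N-node grid with timestep h:

* backward-Euler integration, q_k = q_{k−1} + h q̇_k and
  q̇_k = q̇_{k−1} + h q̈_k;
* the equation of motion with an additive disturbance w_k that absorbs
  model error (reported, never discarded);
* joint-geometry equalities at every node;
* contact: on stance nodes the vertical force is positive (floor 10⁻³ N),
  the tangential components — split into nonnegative (+,−) pairs — obey the
  linearised friction pyramid |λ_t| ≤ μ λ_z with μ = 1.3, and the foot
  velocity is boxed, |v_f| ≤ ε, by a per-stance slack ε ≤ 1 penalised in
  the cost;
* in *sinusoidal* mode the ground forces are additionally box-bounded
  within ±20 % of a synthesised template (plus a 1 N absolute floor so zero
  crossings are not pinned); *freeform* mode drops those boxes.

The cost is

    α₁ Σ C(v/σ) + α₂ Σ w² + α₃ (10 Σ τ² + 0.1 h² Σ ẍ²) + 1000 Σ ε²,

with α = (1, 10000, 1). C is a redescending robust kernel with knots
(a, b, c) = (3, 10, 20) in σ units: quadratic to a, linear to b, a smooth
ease-out to c, constant beyond — outliers lose influence entirely. The
per-observation scale is σ = σ_base / max(confidence, 0.1) with
σ_base = 5 px, further multiplied by a per-camera `confidence_scale`
(0.6 for the far-side cameras of the synthetic rig, mirroring calibrations
recovered indirectly). ẍ is the second difference of the 3D marker
positions; the enormous α₂ makes the solution physically consistent first
and image-accurate second. The GRF template: vertical force is a half sine
over the stance whose amplitude comes from a linear model of peak force (in
body weights) against speed — defaults (0.45 + 0.10·v) BW, chosen to be
impulse-consistent with the bundled walk's duty factor at its reference
speed and meant to be recalibrated per species; fore–aft force is a natural
cubic spline through five control points (zero at start, mid and end of
stance, −A/2 braking, +A/4 propulsion at 25 % and 75 % of stance — the
braking-first sign and the peak timing are package choices); lateral force
is identically zero, so the band leaves the lateral component free (the
band constrains only components the template actually uses).

### Reduction and solver

Inside the solver all forces and torques are normalised by body weight
(length scale 1 m). Three exact reductions shrink the problem before any
iteration happens:

1. the integration equalities are eliminated — q̇ and q̈ *are* the backward
   differences of the stored node states (plus one explicit q̇₀ variable),
   so those constraints hold to machine precision by construction;
2. marker positions and reprojection errors are evaluated in closed form
   from q;
3. at fixed kinematics the force variables of each node decouple into a
   small strictly convex QP (dynamics penalty + their own regularisers,
   subject to their boxes, the pyramid and the band), which is solved
   exactly by a deterministic dual working-set method. Minimising them out
   leaves a problem in (q, q̇₀, ε) whose value and gradient are exact by
   the envelope theorem.

The reduced problem — ~1.5k variables, joint-geometry equalities and
no-slip inequalities — is solved with scipy's trust-constr, fed the
analytic sparse constraint Jacobian and a Gauss–Newton Hessian in which
the dynamics-penalty block is the Schur complement over the re-optimising
force variables (without that correction the curvature along
force-supported directions is overestimated by orders of magnitude and the
solver crawls). Dynamics derivatives come from batched complex-step
differentiation of the inverse dynamics; a small diagonal damping (10⁻²)
keeps the Gauss–Newton Hessian uniformly positive definite. Two cheap
polish steps follow the solve: a Gauss–Newton projection of every node
onto the joint-geometry manifold (micro-radian corrections, residuals to
~10⁻¹²), and an analytic update of each ε to the smallest slack covering
its interval. Exactness of the inner QPs matters more than it looks: any
solver noise there makes the partially-minimised objective non-smooth and
defeats the trust-region logic.

The seed is triangulation (DLT + Gauss–Newton refinement) of all markers
with ≥2 views, linear interpolation over gaps, Savitzky–Golay smoothing
(window 11, order 3 — near-lossless for smooth gaits, essential under
pixel noise), damped per-frame inverse kinematics with soft joint-geometry
penalties, a light smoothing pass over the joint trajectory, and a
per-node linear least-squares fill-in of the force variables.

The split of tangential forces into (+,−) pairs leaves the objective flat
along (λ⁺ + λ⁻); a tiny quadratic regulariser (10⁻⁶ on the split
components) removes the null direction that an interior-point barrier
would otherwise have to resolve.

## The synthetic benchmark

The generator builds a complete trial for a dog-sized 9-link quadruped
(torso 20 kg, upper legs 1.6 kg, lower legs 0.6 kg, total 28.8 kg; leg
segments 0.28 m + 0.26 m) so that everything above is testable with no
external data. Design goals, in order: the truth must satisfy the
*discrete* (backward-Euler) dynamics exactly (‖w‖∞ < 10⁻⁶); stance feet
must be exactly pinned; truth forces should stay near the sinusoidal
template, as force-plate traces of steady gaits do.

The gait is a lateral-sequence walk: footfalls at stride fractions
(LH 0, LF ¼, RH ½, RF ¾), duty factor 0.75, one stride of 0.6 s on 48
nodes at 80 Hz, 0.7 m/s. A walk rather than a faster gait because exact
consistency needs at least three non-collinear supports at every node —
with two point feet the force system cannot produce a moment about the
line joining them, and with none it cannot produce any wrench at all, so
trot and gallop truths would require actively shaped ballistic arcs.
Construction:

1. task space first: stance feet pinned to ground points, swing feet on
   C³ arcs (seventh-order smoothstep forward, sin⁴ lift of 5 cm), legs
   solved by closed-form two-link IK with a common leg-plane roll (which
   satisfies the revolute knee constraints identically);
2. the torso trajectory is shaped by a fixed point that matches the
   *net contact wrench* the kinematics demands (computed with the same
   chain-rule Newton–Euler terms and backward differences the estimator
   uses — matching discrete momenta instead leaves O(h·ω²) force gaps that
   peak during fast swings) to the wrench implied by the summed templates:
   fore–aft and vertical velocity absorb the force mismatch, lateral sway
   the roll-moment mismatch, and small torso pitch/yaw oscillations the
   pitch/yaw-moment mismatches. Secular moment biases, which no periodic
   motion can absorb — e.g. the nose-down moment of a net-braking template
   — are balanced by shifting the foot placements fore–aft/laterally
   relative to the hips, exactly as decelerating animals stand;
3. exact kinetics last: at every node a small QP recovers (τ, λ_c, λ_g)
   with the dynamics as *hard equalities* (solved in the null space of the
   force map, so w is machine-zero), minimising ‖τ‖² with a weak pull
   toward the template — the same tie-break the estimator's cost applies
   to the indeterminacy of multi-foot support. The template band is
   imposed on the QP and, where the exact wrench cannot be met inside it
   (a handful of support-transition nodes), escalated gradually (×1.5, ×2,
   ×4 …) so the truth deviates minimally instead of wandering to the
   unconstrained minimum-torque spread.

Observations are rendered through four synthetic fisheye cameras (two per
side at ~3 m, 1920×1080, f = 1400 px, mild equidistant distortion,
far-side confidence weight 0.6), with isotropic pixel noise, random
dropout, and a confidence score that decays with the drawn noise. The
truth kinematics are seed-independent; a given (parameters, seed) pair
regenerates bit-identically.

What the generator does *not* emulate: detector failure modes beyond
noise + dropout (no outliers, occlusion structure, or identity swaps);
soft tissue and marker movement; calibration error; rolling shutter;
flight phases and fast gaits. Passing the end-to-end tests therefore shows
the estimator recovers a *consistent* rigid-body gait through this camera
model — not that the full real-data pipeline is this accurate.

## Problem sizes and runtimes

The bundled trial assembles to ~3.4k variables before reduction (~1.5k
after), 392 joint-geometry equalities, 888 no-slip rows and 444 linear
force rows. A 60-iteration solve takes roughly two minutes on one CPU;
the noisy trial is run for 250 iterations. The acceptance script solves
the noise-free trial in both modes and the 2 px trial in sinusoidal mode.

## Known limitations

* Euler gimbal lock is avoided by construction, not handled.
* With several feet on the ground the force distribution is indeterminate;
  both the truth construction and the estimator resolve it by the same
  minimum-torque criterion, so recovered torques are comparable, but
  neither is a measurement.
* Under 2 px keypoint noise the *pointwise peak* of the vertical GRF is
  only weakly observable: converged solutions sit 10–20 % above the truth
  peak (at the template band's upper edge) even as mean force error,
  impulses and kinematics recover well. Peak force from noisy keypoints
  should be treated with that uncertainty in mind.
* The 17-link cheetah layout ships with placeholder morphometry (editable
  JSON); it is exercised structurally in the tests but the bundled
  benchmark gait uses the 9-link model.
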