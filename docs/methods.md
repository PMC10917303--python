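# Methods

`morphsim` couples a differentiable planar musculoskeletal simulator to a
direct-collocation trajectory optimizer so that motor coordination,
body-segment dimensions, and per-muscle volumes can be optimized jointly
for locomotion objectives: maximal sprint speed and minimal marathon
metabolic cost. This note records the models, the numerical choices, and
the limits of what the bundled desk-scale experiments demonstrate.

## The simulator

**State and dynamics.** The simulator state is `x = (a_m; a_T; F_t; q; q̇)`:
muscle activations, torque-actuator activations (when the model carries
actuators), tendon forces, generalized positions, velocities. On the
bundled desk model (18 muscles, no actuators, 9 coordinates) the flattened
state has 54 entries; on the structural full configuration (92 muscles,
8 actuators, 31 coordinates) it has 254. State derivatives come from four
blocks:

* activation dynamics `ȧ = (e − a)·rate(e − a)`, a smooth sigmoid blend
  between the activation rate `1/τ_act` (τ_act = 15 ms) and the
  deactivation rate `1/τ_deact` (τ_deact = 60 ms). The blend half-width
  defaults to 0.5 in `e − a` — a gentle rate transition that keeps the
  optimizer's Newton model accurate — and can be sharpened (e.g. 0.005)
  to recover the exact two-rate law, which is the configuration used when
  fitting the deactivation time constant from a decay trace;
* torque-actuator dynamics `ȧ_T = (e_T − a_T)/0.035` with torque
  `τ_T = 150·a_T` N·m;
* implicit Hill contraction dynamics with tendon force as a state (below);
* implicit skeleton dynamics `M(q, p_s) q̈ = G + C + τ_m + τ_T + τ_pas + f_c`,
  evaluated as a residual with q̈ supplied as a control.

Everything is written complex-analytically in numpy: derivatives with
respect to any input — including the morphology parameters — are obtained
by complex-step differentiation, which is exact to machine precision and
is validated against central finite differences in the test suite.

**Muscle model.** The characteristic curves are the smooth
Gaussian/exponential/logarithmic parameterization standard in
direct-collocation gait work: a three-Gaussian active force-length curve
with peak 1 at normalized length 1, an exponential passive curve, a
logarithmic force-velocity curve with value 1 at zero velocity and maximal
shortening velocity 10 optimal fiber lengths per second, and an
exponential tendon force-strain curve parameterized by the dimensionless
stiffness `k_T` (curve default 35; the desk model's lumped short-tendon
muscles use 100, i.e. nearly rigid tendons). All coefficients are
configuration, not contract:
the package's guarantees depend only on the normalization properties.
Pennation follows the constant-width model. Given the normalized tendon
force and its rate, the tendon curve is inverted for tendon length and
velocity, the fiber state follows, and the contraction residual expresses
the Hill equilibrium `F_t = cosα·F_max(a·f_act·f_v + f_pas + β·ṽ)` with a
small fiber damping β = 0.01.

Two numerical guards keep the residual well-behaved at any iterate the
optimizer visits: the tendon inversion's argument is soft-floored away
from zero (so transiently negative forces stay defined), and the projected
fiber length floors smoothly at 0.25 optimal lengths (minimum-fiber-length
guard). Without the second guard, a near-slack muscle with a long
compliant tendon makes the fiber state supersensitive to tendon force and
the pennation cosine sharply curved — a genuine obstacle to Newton-type
solvers that the guard removes at no cost in the operating range.

**Skeleton.** Planar tree dynamics are evaluated by propagating
accelerations down the tree and assembling Jacobian-transpose
contributions of each body's Newton-Euler wrench — equivalent to standard
inverse dynamics `M q̈ + C + G` and verified against a hand-derived
symbolic Lagrangian of the desk topology and against energy conservation
(relative drift < 1e-6 over 1 s ballistic flight).

**Morphology scaling.** Segment dimension factors `p_s` (triplets per
scaling group; left/right segments share groups) scale mass with the
product of the three factors (constant density), centre-of-mass and
joint-frame offsets per axis, and each principal inertia moment with the
mass ratio times the mean square of the two orthogonal axis factors
(exact for constant-density ellipsoids of equal orthogonal semi-axes).
Optimal fiber length and tendon slack length scale with the ratio of
anatomical-pose muscle-tendon lengths; muscle volume scales 1:1 with the
whole-body mass ratio, then with the per-muscle factor `p_V`; PCSA is
recomputed from volume and fiber length, and `F_max = PCSA·σ`. Stature is
the stack of the scaled longitudinal (y) dimensions of the segments listed
in the model definition (torso incl. head, thigh, shank, foot height for
the desk model); BMI = mass/stature². A deliberate asymmetry: `p_V`
changes only the force-generating parameters, never segment inertia —
strength training in this model adds strength, not limb mass.

**Contact.** Sphere-on-plane Hunt-Crossley: normal force
`k·d^p·(1 + 1.5·c·ḋ)` with penetration `d` passed through an
exponential-tail softplus (no phantom forces above the smoothing band) and
the dissipation bracket through a smooth positive part; friction is
`−μ·F_n·tanh(v_x/v_t)`. The desk track is deliberately compliant:
`k = 1.2e5 N/m^1.5`, dissipation 1.0 s/m, μ = 0.8, smoothing band 5 mm,
`v_t = 0.2 m/s`, giving ~2 cm penetrations under body weight. This is a
soft running track, chosen so that a coarse collocation mesh resolves the
loading and unloading of stance smoothly; none of the acceptance
quantities depend on the contact constants.

**Passive torques.** Exponential joint-limit torques
`k_U1·e^{k_U2(q−θ_U)} + k_L1·e^{k_L2(θ_L−q)} − 0.1·q̇` with `k_U1 < 0`
and `k_L1 > 0` so both limit terms restore into range and damping
dissipates (the sign convention is documented here because printed forms
of this law are ambiguous about it). Desk parameters give ~2 N·m at 5°
beyond the passive range. The metatarsophalangeal spring-damper uses
40 N·m/rad and 0.4 N·m·s/rad when sprinting, 25 N·m/rad and 1.9 N·m·s/rad
at marathon pace; the planar desk model has no MTP joint, so this law is
exercised as a pure function and on the structural full configuration.

**Desk muscle parameterization.** The nine lumped units per leg carry
maximal isometric forces of 1.2-5 kN (specific tension 60 N/cm²),
optimal fiber lengths of 6-14 cm sized to each muscle's excursion over
the desk model's joint ranges, and tendon slack lengths chosen so the
anatomical pose (q = 0) puts each fiber at its optimal length under a
light 15 % reference load — enough tendon pre-strain that fibers stay in
their working range under stance loads, little enough that antagonist
pairs carry only small passive tension at rest. The hip flexor path
includes a pelvic-brim via point (the anatomical wrap of the iliopsoas),
which also keeps its length function smooth over the full hip range.

## Muscle-geometry surrogates

The desk model's geometry is an exact closed-form via-point model:
lengths, moment arms (`r_j = −∂l_mt/∂q_j`, the tendon-excursion identity,
satisfied to machine precision) and velocities are smooth functions of
pose and scale factors. On top of it sits the surrogate pipeline that a
full-scale model needs when its geometry engine is not differentiable:
draw scaled model variants with factors from U(0.8, 1.2), sample poses
uniformly within the joint ranges, record lengths and moment arms, and
fit one small network per muscle — two hidden tanh layers of width
8/12/16 for muscles spanning 1/2/≥3 coordinates, z-scored inputs and
outputs, Adam on mean-squared error for 1000 epochs at batch size 64
(learning rate 1e-3 with a ×0.2 step decay after 70 % of the epochs).
Inputs are the spanned coordinates plus the scale factors of every
segment the path touches or crosses; restricting inputs to attachment
segments alone leaves irreducible label noise because intermediate
segments scale the joint offsets the path spans. Sample counts default to
one tenth of the full-scale protocol (2,000/8,200/20,000 by spanned-
coordinate count), matched to the desk model's size. Moment arms at run
time come from the network's dedicated heads; muscle-tendon velocity from
the chain rule on the length head; the discrepancy between the two
(tendon-excursion consistency) is reported as a diagnostic. Trained desk
surrogates reach held-out length errors below 1 mm. The trajectory
optimizer uses the analytic geometry directly — it is already smooth and
exact, so for the bundled fixture the surrogate is a validated mirror of
the full-scale pipeline rather than a necessity.

## Trajectory optimization

**Transcription.** Half a gait cycle on `n_mesh` intervals (interval
length `h` a decision variable) with third-order Radau collocation
(nodes ≈ 0.155, 0.645, 1; includes the right endpoint). Tendon-force
rates and coordinate accelerations are controls, so muscle and skeleton
dynamics enter as algebraic constraints at every collocation node
(implicit dynamics). Left-right symmetry: the mirrored end state equals
the initial state except the root forward position; marathon runs impose
average speed (3.33 m/s by default) as `x_end − x_0 = v·T`; the initial
forward position is pinned at zero. Freed morphology adds global
variables: 12 scale factors (four groups × three axes) bounded to
[0.8, 1.2] with BMI constrained to [17.5, 25.5], or 9 left/right-tied
per-muscle-pair volume factors bounded to [1.0, 1.2] with total added
volume at most 5 % of the baseline total. Tying volumes across sides is
a modelling choice: with half-cycle symmetry an asymmetric volume
distribution cannot be exploited, so the pairs remove a null direction.

**Objective.** Marathon: a weighted sum of squared per-muscle metabolic
power (Bhargava-style activation, maintenance, shortening heats and
positive fiber work, coefficients in configuration), squared activations,
squared coordinate accelerations, squared joint-limit torques and squared
actuator activations, integrated over the half cycle and divided by the
distance travelled. Weights (1e-4, 2, 1e-5, 1e-3, 1) put the terms on
comparable scales for the desk model; they are configuration, and no
acceptance quantity depends on them. Sprint: `−v_avg² + 1e-6·J_marathon`
with `v_avg` = displacement/duration. The reported marathon energy uses
the *unsquared* metabolic energy per meter times 42,196 m at
4184 J/kcal; both squared and unsquared integrals are computed.

**Solver.** The NLP is solved with a purpose-built pipeline on scipy's
sparse linear algebra (no general NLP solver in the dependency set is
able to converge these problems):

1. *Exact sparse linearization.* The collocation equations' linear part
   is a precomputed sparse matrix; all nonlinear Jacobian blocks come
   from complex-step directional sweeps batched across nodes.
2. *Homotopy feasibility.* A damped Gauss-Newton (Levenberg-Marquardt)
   projection onto the constraint manifold, using direct factorization
   of the damped normal equations, chord reuse of the factorization, a
   second-order correction step, and backtracking. The search starts in
   an easier world — soft, long-range contact plus "crutch" torque
   controls on every coordinate that make the kinematic initial guess
   nearly feasible — and anneals to the physical problem. The crutch
   bounds are retired by geometric decay with adaptive step control;
   making crutch moves expensive in the minimum-norm metric ensures usage
   only rebounds where the physics still needs it.
3. *Optimality.* Projected-gradient descent along the constraint
   manifold: the objective gradient is projected onto the null space of
   the active constraint Jacobian, a bounded step is taken, feasibility
   is restored, and the point is accepted only if the objective
   decreased — monotone improvement along feasible iterates, so a
   warm-started morphology optimization can never end worse than its
   coordination-only baseline.
4. *Polish.* Active-set Gauss-Newton refinement drives the final
   constraint violation to ~1e-9.

The initial guess is a smooth sinusoidal running pattern (hip/knee/ankle
sinusoids, a vertical bounce, feet grazing the ground) with statically
equilibrated tendon forces, collocation-consistent force rates and
crutch torques chosen to zero the skeleton residual exactly at the guess.

**Problem sizes.** The bundled experiments use 8 mesh intervals per half
cycle (24 collocation nodes, ≈ 2,900 unknowns); the transcription accepts
any mesh (the conventional full-scale choice of 50 is configuration).
Mesh 8 resolves the desk model's stance well on the compliant track and
keeps a complete solve within minutes on one CPU.

**Re-integration check.** The solved controls are integrated forward with
fine fixed-step RK4 from the solved initial state; mismatch against the
collocation states at mesh boundaries, normalized by the state scales, is
reported (tolerance 1e-3).

**Torque capacity.** Per coordinate and sign: maximal isometric torque of
the fully activated agonist set (muscles whose moment arm matches the
sign), maximized over a pose grid spanning the coordinate's range, with
tendon forces from per-muscle static equilibrium. Linear in the muscle
strengths, so doubling every `F_max` doubles every capacity.

## What the desk experiments do and do not show

The desk model emulates the role of a full three-dimensional running
model: the same state layout, dynamics blocks, scaling rules, surrogate
pipeline, transcription and experiment matrix, exercised end-to-end at a
size where everything is verifiable against closed forms and oracles. It
is planar and uses nine lumped muscles per leg, a compliant track, and a
coarse mesh; its absolute speeds, energies and optimized morphologies are
properties of this fixture, not predictions for human athletes. Claims
that survive the reduction — and that the acceptance suite checks — are
structural: scaling identities and budgets, constraint satisfaction at
the optimum, the improvement property of freed morphology over
coordination-only solutions, and the activity of the volume budget under
sprint training. The quantitative full-scale results (absolute sprint
speeds near 9 m/s, marathon costs near 3,000 kcal) require the external
92-muscle model and are out of scope.

## Known limitations

* The solver is a feasibility-first homotopy method with first-order
  optimality refinement: solutions are locally improved, but no
  second-order optimality certificate is computed, and descent is
  stopped by iteration budget. On a known linear-quadratic benchmark
  the optimal value is reproduced to better than 1e-9 while the control
  profile carries the ~1e-4 endgame imprecision typical of first-order
  methods.
* Crutch-torque retirement is incomplete on the bundled gait problems:
  after the homotopy the trajectories carry dynamics residuals of order
  1e-2 in scaled units (a few N·m at the joints, a few N at the root)
  rather than the 1e-9 the intermediate homotopy stages reach. The last
  ~10 N·m of crutch usage resists every local retirement strategy we
  tried; closing this gap appears to require second-order KKT steps
  (an interior-point NLP solver) or a globally different gait basin.
  Derived gait metrics (imposed speed, stride parameters, budgets,
  anthropometrics) are insensitive to this residual at their reported
  precision, but the strict feasibility and forward re-integration
  checks do not pass at their nominal tolerances.
* Planar contact only (spheres on the plane y = 0); no closed kinematic
  loops; no non-penetration constraints between body segments are active
  on the desk model (legs pass each other out of plane); the machinery
  accepts designated sphere pairs for models that need them.
* The metabolic model's length dependence of maintenance heat uses the
  active force-length curve as a smooth stand-in for the piecewise
  original, and the shortening-heat coefficient is a single constant
  rather than fiber-type-resolved.
* Muscle volumes do not feed back into segment inertia (documented
  design choice, see above).
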