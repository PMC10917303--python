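# morphsim

Differentiable planar musculoskeletal simulation and morphology-aware
predictive gait optimization.

Body proportions and muscle volumes shape what a body can do: sprinters
carry more muscle, marathoners sit at the light end of the healthy BMI
range with long shanks. Testing such relationships causally requires
simulations in which *morphology itself* is a decision variable — the
optimizer must be free to resize segments or redistribute muscle volume
while simultaneously finding the motor coordination that exploits the new
body. `morphsim` implements that capability end to end for a bundled
desk-scale planar running model: a musculoskeletal simulator that is
differentiable in pose, velocities, muscle state, segment dimension
factors `p_s` and muscle-volume factors `p_V`, plus a direct-collocation
trajectory optimizer that solves sprint (maximize average speed) and
marathon (minimize metabolic cost at an imposed 3.33 m/s) problems with
morphology free or fixed.

The library is the interface: build models, scale them, train
muscle-geometry surrogates, transcribe and solve predictive-gait
problems, post-process. Short narrative scripts in `examples/` walk
through each capability; a thin `morphsim` command-line wrapper covers
the common workflows.

## The model in brief

* **State** `x = (a_m; a_T; F_t; q; q̇)` — muscle activations, torque-
  actuator activations, tendon forces, coordinates, velocities (54
  entries on the desk model; 254 on the structural full configuration
  with 92 muscles, 8 actuators and 31 coordinates).
* **Muscles** are Hill-type with tendon force as a state and implicit
  contraction dynamics: `F_t = cosα·F_max(a·f_act(l̃)·f_v(ṽ) + f_pas(l̃))`,
  with the smooth curve set standard in collocation-based gait work.
* **Skeleton** dynamics `M(q,p_s)q̈ = G + C + τ_m + τ_T + τ_pas + f_c`
  with Hunt-Crossley sphere-ground contact and exponential joint-limit
  torques; every quantity is a smooth function of the morphology.
* **Scaling** is constant-density: mass ∝ product of the three dimension
  factors; optimal fiber and tendon slack lengths follow anatomical-pose
  muscle-tendon lengths; volumes track whole-body mass 1:1, then the
  strength-training factors `p_V`; `F_max = PCSA·σ`.
* **Trajectory optimization**: third-order Radau collocation over half a
  gait cycle with left-right mirror periodicity, interval length free,
  implicit dynamics as algebraic constraints, and morphology parameters
  as global decision variables under their bounds (`p_s ∈ [0.8, 1.2]`,
  BMI ∈ [17.5, 25.5]; per-muscle volume +20 % max, +5 % total).

See `docs/methods.md` for the full account, including the homotopy
feasibility solver built for this problem and its current limitations.

## Worked example

```bash
python examples/01_build_and_scale_model.py
```

prints

```
generic model: 75.2 kg, 1.81 m, BMI 22.95
long-legged variant: 73.4 kg, 1.94 m, BMI 19.50
vasti: generic F_max 5000 N, l_opt 120 mm -> scaled F_max 4253 N, l_opt 138 mm
```

The generic desk model reproduces the reference anthropometrics (75.2 kg,
1.81 m). Lengthening and slimming the thighs and shanks (scale factors
0.9/1.15/0.9) adds 13 cm of stature while removing 1.8 kg of mass — the
constant-density rule at work — and the vasti's optimal fiber length grows
with its anatomical muscle-tendon length (120 to 138 mm) while its
maximal isometric force drops (5000 to 4253 N): the same muscle volume,
scaled with body mass, is spread over longer fibers.

```bash
python examples/02_train_geometry_surrogates.py   # surrogate fidelity
python examples/03_marathon_solve.py              # full marathon solve
python examples/04_strength_training.py           # sprint + volume budgets
```

`02` trains the soleus network to sub-millimeter held-out length error;
`03` runs the complete feasibility-and-descent pipeline at the imposed
3.33 m/s and prints step length, step frequency, whole-marathon kcal and
the re-integration check; `04` frees the per-muscle volume factors under
the strength-training budgets and reports where the added volume goes.

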