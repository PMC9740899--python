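# liftsim

Model-based evaluation of heavy lifting tasks and shoulder-support
exoskeleton concepts, at desk scale.

Occupational lifting of heavy boxes to shoulder height loads the arms,
shoulders and lower back, and passive shoulder exoskeletons are a
candidate countermeasure. `liftsim` implements the two-stage workflow
used to design such a device:

* **Stage A — sequence ranking.** Six box-handling motion sequences
  (carrying, lifting and lowering a 21 kg box, two box geometries) are
  evaluated with a simplified rigid-body human model and an
  inverse-dynamics muscle-recruitment core. Thirteen biomechanical
  stress criteria are computed per sequence — time integrals of
  muscle-group activity envelopes (%·s) and peak joint forces (kN) at
  the knee, hip, L4/L5, glenohumeral joint, elbow and wrist. Each
  criterion awards points 1..6 by rank; the sequence with the highest
  summed score is the most strenuous and becomes the design load case.

* **Stage B — concept rating.** A shoulder-support exoskeleton with a
  hip belt, lateral load-bearing structures, a torque-generating joint
  beside each shoulder and upper-arm bracings is varied at three joint
  locations per side (4 hip x 2 middle x 4 arm-connection choices = 32
  variants). A kinematic feasibility screen removes variants without a
  prismatic middle joint or without a rotational arm-connection DOF
  (12 survive). Survivors are coupled to the human model through
  predictive contact elements (PCE: unilateral normal forces up to
  10 kN with friction cones, mu = 1) and simulated on the selected lift
  with the support torque tau(x) = 27.6381 + 0.5570 x − 0.0036 x² Nm
  (x = joint elevation angle in degrees). Concepts are rated on eight
  criteria — mean shoulder/back muscle activity, mean glenohumeral and
  L4/L5 joint force, and four parasitic arm-interface loads — with the
  lowest point total marking the highest relief potential.

The recruitment core solves, per frame, a convex program: minimize the
sum of cubed actuator and contact activities subject to generalized
Newton–Euler equilibrium, activity bounds and linearized friction
cones. Joint loads include the muscle-tension compression term
Σ|τ|/r along the bone, which is what makes them multi-kN.

Because laboratory motion capture is not distributable, the package
ships a synthetic-motion generator (minimum-jerk box trajectory, exact
hand–handle inverse kinematics, bilaterally symmetric, 100 Hz) and the
printed criterion tables of the laboratory study it emulates, so the
ranking arithmetic is exactly reproducible while the simulation core is
exercised end to end on synthetic input.

## Worked example

Rank the six recorded sequences from the bundled criterion table:

```
$ liftsim stage-a --from-table bundled
Stage A (sequence ranking)
--------------------------
  T1                         50.0
  T2                         63.0
  T3                         32.0
  T4                         39.0
  T5                         70.0
  T6                         19.0
  selected sequence: T5
```

T5 — the symmetric lift of the 21 kg box with both hands on its lateral
handles — collects 70 of a possible 78 points and is the most strenuous
sequence. Rating the six simulated exoskeleton concepts:

```
$ liftsim stage-b --from-table bundled
Stage B (concept rating)
------------------------
  H: R.cc–A: R.lm            25.0
  H: R.cc–A: R.cc            28.0
  H: R.cc–A: U.lm-cc         22.0
  H: U.cc-ap–A: R.lm         24.0
  H: U.cc-ap–A: R.cc         39.0
  H: U.cc-lm–A: R.cc         30.0
  selected concept: H: R.cc–A: U.lm-cc
```

Concept names read "H: hip joint – A: arm joint" (R revolute,
U universal, axes cc craniocaudal / lm lateromedial / ap
anteroposterior). Lower totals are better: the revolute-hip variant
with a universal lateromedial–craniocaudal arm joint rates best (22),
while the craniocaudal-only arm joint under a cc–ap universal hip rates
worst (39).

The same stages run in full simulation mode (`liftsim stage-a`,
`liftsim stage-b`) on the synthetic lift, and `liftsim synth` exports
synthetic marker trajectories (TRC-style or CSV). The library API
(`liftsim.stage_a`, `liftsim.stage_b`, `liftsim.run_sequence`, ...)
exposes every step individually.

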