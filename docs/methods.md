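# Methods

This note documents the models, the numerical choices and the
limitations of `liftsim`, in the package's own terms.

## Human model

The body is a rigid-body tree rooted at a 6-DOF floating pelvis with 31
generalized coordinates: 3-DOF lumbar (L4/L5), 2-DOF neck and, per
side, 3-DOF hip, 1-DOF knee and ankle, 3-DOF glenohumeral, 1-DOF elbow
and wrist. Segment masses are fixed fractions of body mass and lengths
fixed fractions of stature from a standard adult regression table
(Winter/Drillis–Contini type, `liftsim.config`); centre-of-mass offsets
and slender-rod inertias complete the inertial description. Defaults
describe a 1.76 m / 70.4 kg adult. Laterally acting joint axes are
mirrored between sides, so identical left/right coordinate values give
a bilaterally symmetric posture.

Muscles are torque-equivalent grouped actuators: each joint DOF carries
at least one agonist and one antagonist with a maximum torque (e.g.
lumbar extension 300 Nm, lumbar flexion 150 Nm, two redundant 120 Nm
actuators per glenohumeral flexion/abduction direction, elbow flexion
80 Nm, knee extension 250 Nm, hip extension 300 Nm, neck 40 Nm — all
configurable). An actuator's activity is delivered torque over maximum
torque. Actuators carry one of six group labels (arms, shoulders, neck,
lower back, abdomen, lower extremities), which partition the set.

A joint's reaction force is the inter-segmental resultant plus a
compression term Σ|τ|/r along the child segment's long axis, with
effective moment arms r of 0.05 m (lumbar, hip, knee, ankle) and
0.03 m (glenohumeral, elbow, wrist, neck). Without this term joint
loads would be a few hundred newtons; with it they are muscle-tension
dominated and reach the multi-kN range expected during heavy lifting.
The L4/L5 "compression" is the component of the lumbar reaction along
the thorax long axis.

## Synthetic motion

The study conditions are a symmetric lift of a 21 kg box
(0.44 x 0.26 x 0.14 m, lateral handles) from standing hand height onto
a 1.46 m platform, sampled at 100 Hz. The generator prescribes
leg/trunk angles (an initial squat of 20° hip / 30° knee flexion and
5° lumbar flexion releasing into upright stance with 3° extension,
minimum-jerk time scaling, feet planted by construction) and moves the
box centre along a minimum-jerk path from 0.25 m to 0.45 m ahead of the
pelvis while it rises. Arm coordinates are solved per frame by inverse
kinematics with the hand grip points pinned to the box handles
(equality-constrained SLSQP; residuals ~1e-12 m). The 2-dimensional
arm null space is resolved toward a physiological reach: shoulder
flexion along the shoulder-to-target direction, elbow flexion from the
two-link cosine rule, humeral rotation and wrist near neutral, plus a
small continuity term; both the previous frame's solution and this
prior seed the solver and the better converged branch is kept, which
prevents elbow-branch flips from propagating through the lift.

A prescribed out-of-sagittal shoulder-abduction wobble (5° peak at
mid-lift, amplitude jittered ±10 % by the seed) exercises lateromedial
load paths; a perfectly planar motion would make all lateromedial
interface loads trivially zero. Lowering sequences are time-reversed
lifts; carrying sequences hold the box while the legs march in
anti-phase, producing the flat-foot events the gait-cycle segmentation
detects. In the six-sequence ranking, lowers run 0.75x and carries
1.2x the lift duration so the time-integrated criteria can distinguish
otherwise statically identical sequences. Box A sequences use a
top-handle-plus-support grip (one hand above, one below), with the box
start height shifted so the lowest handle sits at standing hand height.

The generator emulates kinematic plausibility and reproducibility, not
human motor control: no dynamic co-contraction, no inter-subject
strategy differences, no marker noise or soft-tissue artefact.
Passing tests therefore demonstrate the workflow's mechanics and
comparative logic, not quantitative agreement with recorded motion.

## Recruitment core

Per frame, all unknown internal forces — actuator torques, ground
contact forces (three points per foot against the plane z = 0),
predictive-contact-element (PCE) forces and, in ideal-actuator mode,
the exo support torque — solve

minimize Σ_i a_i^p subject to A x = b, 0 ≤ a_i ≤ 1, friction cones,

with p = 3 by default (configurable to 2; p ≤ 1 is rejected because
strict convexity is what makes the optimum unique). Contact elements
enter the objective as auxiliary activities normal_force/F_max
(F_max = 10 kN), which makes well-within-cap contact forces nearly
cost-free. The equality constraints are generalized-force balance of
the human tree and, when coupled, the exoskeleton tree: gravity,
finite-differenced translational and rotational Newton–Euler terms
(central differences, one-sided at the endpoints, no filtering of the
noise-free synthetic motion) and the box load shared symmetrically
between both hands. Jacobians are evaluated by central differences of
the forward kinematics (step 1e-6; accuracy ~1e-9, ample for the 1e-6
equilibrium tolerance).

Friction is linearized as m half-plane constraints (m = 8) shrunk by
cos(pi/m), i.e. a polygon inscribed in the exact cone, so
|friction| ≤ mu * normal holds everywhere rather than approximately.
A HiGHS linear program provides a feasibility certificate and the warm
start; SLSQP with analytic gradients refines to the convex optimum.
Infeasibility (a generalized-force equation that no admissible force
set can balance) is reported with the offending coordinate named.
Friction components and the ideal torque are cost-free and therefore
determined only up to cone-interior ties; a quadratic regularization
(1e-8 against a 100 N reference) breaks ties deterministically without
influencing load routing. At degenerate LP vertices a small circulating
friction component can persist inside the cone; solutions remain
deterministic and equilibrium-exact.

## Exoskeleton coupling

The exo base (hip belt + back plate, 60 % of the 5.1 kg structure) is
kinematically slaved to the pelvis. Twelve hard constraints (six at the
hip and six at the back, as a literal reading of the interface would
have it) cannot coexist on one rigid base whenever the lumbar joint
moves, so the back interface is coupled kinetically only. Per side the
chain runs: hip-variation joint (posterolateral of the hip, 9 cm
lateral clearance, 6 cm posterior — the posterior offset keeps the
vertical hip axis laterally effective at every arm pose), lateral
structure up to the torque-generating joint (lateromedial axis, level
with and 6 cm lateral of the shoulder), then a two-part structure
through the middle-variation joint to the arm bracing, attached at the
lateral face of the bracing. With equal lateral clearances the distal
structure is parallel to the humerus, so the torque-joint angle equals
the arm elevation (0° = arm hanging) and the prismatic middle joint
absorbs the shoulder-to-pelvis distance changes that trunk motion
produces.

Per frame the bracing attachment point is driven hard (three
translational DOF, solved to ~1e-12 m by bounded least squares with
branch-keeping bounds and, for kinematically redundant chains, a
continuity-regularized pre-pass) and the three rotational DOF are soft
(orientation mismatch minimized, never enforced). Chains flagged by the
feasibility screen are refused with a kinematic-failure error naming
the conflicting drivers.

Kinetic coupling is exclusively through contact elements and the two
10 N/m springs (back plate to torque joint, attractive): 8 PCE per arm
bracing in two rings of four (±6 cm axially, radial normals toward the
humerus axis — two rings, because a single ring of radial normals
cannot transmit transverse torques through normal forces), 10 radial
PCE around the pelvis at the belt, and a plate/strap pair of opposed
unilateral elements at the thorax. The strap element is essential: the
support torque's reaction pitches the base backward, and without a
backward-acting path at the thorax that couple would load, rather than
relieve, the lumbar spine.

In ideal-actuator mode the torque joint is an unbounded zero-cost
variable and its per-frame (angle, torque) trace is the ideal target
curve; `fit_degree2` approximates it by ordinary least squares. The
fit reports the sampled curvature as-is — over a single up-phase the
concavity of the full support curve is not identifiable — while a
curve installed on a concept variant must be concave. In
prescribed-torque mode the configured polynomial is applied exactly.

## Statics of the concept space

Which variants can transmit the prescribed support torque is decided by
statics. A free (unactuated) exo DOF imposes a zero-generalized-force
condition; chains with a free pitch axis at both ends — a lateromedial
or spherical hip combined with a lateromedial or universal arm joint —
leave the support torque with no admissible reaction path, and the
recruitment program is provably infeasible for them (5 of the 12
screened-in variants). Two further variants complete but inflate the
mean glenohumeral load and are reported as biomechanically
unfavorable. The five variants that complete with strict glenohumeral
and L4/L5 reductions all use a revolute or cc-ap universal hip, or a
cc-lm hip with a locked-pitch arm joint. This failure taxonomy —
roughly half of the screened-in variants unable to produce a plausible
simulation — is an emergent property of the statics, and the pipeline
reports its own reason codes rather than claiming any specific
survivor set. Qualitative interface-load patterns also emerge
structurally: a free lateromedial arm axis zeroes the lateromedial
bracing torque, the prismatic middle joint keeps distoproximal forces
near the distal structure's own weight share, and azimuth-locked hips
raise lateromedial forces.

## Interface loads and criteria

Arm-interface forces are summed in a bracing frame re-evaluated per
frame from the humerus pose: distoproximal along the bone,
craniocaudal pointing caudally at 90° flexion, lateromedial toward the
sagittal plane on both sides (mirrored, so symmetric motions give
identical signed components left and right). Torques are taken about
the bracing centre at mid-humerus. Craniocaudal force and lateromedial
torque are supporting and averaged signed (with a recorded mirror flip
when the mean is negative); the other four components are parasitic
and averaged as absolute values, pooled over the frames of both sides;
standard deviations are over the same pooled samples.

Activity envelopes are pointwise maxima over a muscle group's
actuators (configurable to the mean for sensitivity checks), reported
in percent; cumulative stress is the trapezoidal time integral (%·s).
Peak joint forces take the per-frame bilateral average before the
maximum (configurable). Across-subject dispersion uses the sample
(n−1) standard deviation. The L4/L5 peak is compared against a 3.1 kN
lower-back guideline constant.

## Ranking

Points 1..n are assigned per criterion by ascending value. Ties (an
artifact of rounded table values) are resolved by a configurable
policy and every resolution is recorded in an audit list. Sequence
tables default to awarding more points to the alternative with the
larger dispersion — the unique simple policy that reproduces all six
printed sequence scores — while concept tables default to the opposite,
which reproduces the printed concept ratings including their single
tie; both defaults are calibrations to the bundled tables, recorded as
such, with no claim about intent. Criteria are unweighted by default;
a weight vector is accepted for sensitivity analysis. A
single-alternative table degenerates to one point per criterion.

## Problem sizes

The bundled-table stages run in milliseconds. Simulation-based tests
use 11-frame lifts at 5 Hz (quasi-static checks use 21 frames over
10 s), for which the per-frame convex programs (70–160 variables)
solve in ~0.1–0.5 s; the full 12-variant screening batch completes in
about two minutes on one CPU. The synthetic pipeline is deterministic;
the only stochastic inputs (posture jitter, wobble amplitude) take
explicit seeds.

## Known limitations

* Quasi-static emphasis: inertial terms are included but the synthetic
  motions are slow, so dynamic effects and co-contraction are absent;
  abdominal activity in particular stays near zero, and absolute
  magnitudes sit below those of recorded dynamic lifting.
* Torque-equivalent actuators cannot represent force–length–velocity
  muscle properties, wrapping, or ligaments.
* Interface stiffness is ideal-rigid through the contact elements;
  soft-tissue compliance, which in reality caps interface moments, is
  not modelled.
* The exo geometry (clearances, bracing position, PCE layout) is
  parameterized with documented defaults; absolute interface-load
  magnitudes move with these choices, comparative patterns are robust.
* Forward dynamics, force-dependent kinematics, fatigue and metabolic
  cost are out of scope.
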