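"""Whole-sequence simulation: statics, balance, determinism, invariants."""
import numpy as np
import pytest

from liftsim.motion import MotionTrajectory, TaskSpec, \
    generate_lift_trajectory
from liftsim.exo import attach_exo, variant_by_id
from liftsim.sim import fit_degree2, ideal_target_torque, run_sequence

GRAVITY = 9.81


@pytest.fixture(scope="module")
def static_traj(model):
    n = 5
    coords = np.tile(model.zero_coords(), (n, 1))
    box = np.zeros((n, 7))
    box[:, 3] = 1.0
    return MotionTrajectory(rate=10.0, times=np.arange(n) / 10.0,
                            coords=coords,
                            coord_labels=list(model.coord_names),
                            box_pose=box)


@pytest.fixture(scope="module")
def no_exo_solution(model, short_lift):
    return run_sequence(model, short_lift, mode="no_exo")


def _ground_z(frame):
    return sum(c["force"][2] for c in frame.contacts
               if c["interface"] == "ground")


class TestStatics:
    def test_standing_ground_forces_equal_body_weight(self, model,
                                                      static_traj):
        sol = run_sequence(model, static_traj, mode="no_exo")
        for f in sol.frames:
            assert _ground_z(f) == pytest.approx(70.4 * GRAVITY, abs=0.1)

    def test_standing_needs_no_muscle(self, model, static_traj):
        sol = run_sequence(model, static_traj, mode="no_exo")
        assert max(sol.frames[2].activities.values()) < 0.05

    def test_rerun_is_bit_identical(self, model, static_traj):
        a = run_sequence(model, static_traj, mode="no_exo")
        b = run_sequence(model, static_traj, mode="no_exo")
        for fa, fb in zip(a.frames, b.frames):
            assert fa.activities == fb.activities
            for ca, cb in zip(fa.contacts, fb.contacts):
                assert np.array_equal(ca["force"], cb["force"])


class TestQuasiStaticLift:
    def test_vertical_force_balance_within_2_percent(self, model, anthro,
                                                     lift_task):
        traj = generate_lift_trajectory(anthro, lift_task, duration=10.0,
                                        rate=2.0, seed=1, model=model)
        sol = run_sequence(model, traj, mode="no_exo")
        weight = (anthro.body_mass + lift_task.box_mass) * GRAVITY
        for f in sol.frames:
            assert abs(_ground_z(f) - weight) / weight < 0.02

    def test_equilibrium_residual_below_tolerance(self, no_exo_solution):
        for f in no_exo_solution.frames:
            assert f.equilibrium_residual < 1e-6

    def test_activities_within_bounds(self, no_exo_solution):
        for f in no_exo_solution.frames:
            for a in f.activities.values():
                assert -1e-9 <= a <= 1.0 + 1e-9

    def test_contact_caps_and_friction_cones(self, no_exo_solution):
        for f in no_exo_solution.frames:
            for c in f.contacts:
                assert -1e-9 <= c["N"] <= c["cap"] + 1e-9
                assert np.hypot(c["T1"], c["T2"]) <= \
                    c["mu"] * c["N"] + 1e-6

    def test_box_mass_monotonicity_of_peak_lumbar_compression(
            self, model, anthro):
        peaks = []
        for mass in (21.0, 30.0):
            task = TaskSpec(box_mass=mass)
            traj = generate_lift_trajectory(anthro, task, duration=2.0,
                                            rate=5.0, seed=1, model=model)
            sol = run_sequence(model, traj, mode="no_exo")
            comp = [abs(f.joint_reactions["lumbar"] @ f.spine_axis)
                    for f in sol.frames]
            peaks.append(max(comp))
        assert peaks[1] >= peaks[0]


@pytest.fixture(scope="module")
def coupled(model):
    return attach_exo(model, variant_by_id("H: R.cc–A: R.lm"))


@pytest.fixture(scope="module")
def ideal_solution(coupled, short_lift):
    return run_sequence(coupled, short_lift, mode="ideal_actuator")


class TestExoSequence:
    def test_ideal_target_torque_covers_lift_angle_range(
            self, ideal_solution):
        samples = ideal_target_torque(ideal_solution)
        for side in ("r", "l"):
            angles = samples[side][:, 0]
            assert len(angles) == len(ideal_solution.frames)
            assert angles.max() - angles.min() > 20.0

    def test_ideal_actuator_unloads_shoulder_flexors(self, model,
                                                     short_lift,
                                                     ideal_solution):
        base = run_sequence(model, short_lift, mode="no_exo")
        def flexor_peak(sol):
            acts = [sol.activity_trace(a.name)
                    for a in model.actuators
                    if a.coord == "gh_r_flexion" and a.direction > 0]
            return np.max(acts)
        assert flexor_peak(ideal_solution) < 0.5 * flexor_peak(base)

    def test_fitted_curve_approximates_ideal_samples(self, ideal_solution):
        samples = np.vstack([ideal_target_torque(ideal_solution)[s]
                             for s in ("r", "l")])
        spec = fit_degree2(samples)
        # the ideal support need rises with elevation and the quadratic
        # captures it to a fraction of the torque range
        assert spec.c1 > 0
        assert spec.residual < 0.25 * np.ptp(samples[:, 1])

    def test_prescribed_torque_follows_polynomial(self, coupled,
                                                  short_lift):
        sol = run_sequence(coupled, short_lift, mode="prescribed_torque")
        tj = coupled.variant.torque_joint
        for f in sol.frames:
            for side in ("r", "l"):
                x = f.torque_angle_deg[side]
                expected = tj.c0 + tj.c1 * x + tj.c2 * x**2
                assert f.torque_joint[side] == pytest.approx(expected,
                                                             abs=1e-9)

    def test_action_reaction_on_arm_interface(self, coupled, short_lift):
        """PCE forces on the human and exo are equal and opposite, so the
        coupled system's ground reaction still balances total weight."""
        sol = run_sequence(coupled, short_lift, mode="prescribed_torque")
        total = (70.4 + 21.0 + coupled.exo_mass) * GRAVITY
        mid = sol.frames[len(sol.frames) // 2]
        assert _ground_z(mid) == pytest.approx(total, rel=0.05)
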