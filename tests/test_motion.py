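"""Synthetic motion: generation, marker I/O, segmentation."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from liftsim.errors import (DegenerateTraceError, InfeasibleTaskError,
                            InvalidArgumentError, NoCycleError)
from liftsim.motion import (MarkerSet, TaskSpec, default_marker_set,
                            export_markers, generate_carry_trajectory,
                            generate_lift_trajectory, read_markers,
                            segment_gait_cycle, segment_lift_window)


@pytest.fixture(scope="module")
def full_lift(anthro, lift_task, model):
    return generate_lift_trajectory(anthro, lift_task, duration=3.0,
                                    rate=100.0, seed=1, model=model)


def _hand_position_oracle(model, coords, side):
    """Independent forward kinematics of the arm chain (scipy rotations)."""
    poses = {}
    for joint in model.tree.joints:
        p, R = (np.zeros(3), np.eye(3)) if joint.parent is None \
            else poses[joint.parent]
        p = p + R @ joint.offset
        start = model.tree.coord_index(joint.dofs[0].name)
        for k, dof in enumerate(joint.dofs):
            axis = np.asarray(dof.axis, float)
            if dof.kind == "trans":
                p = p + R @ (axis * coords[start + k])
            else:
                R = R @ Rotation.from_rotvec(axis * coords[start + k]
                                             ).as_matrix()
        poses[joint.child] = (p, R)
    seg, off = model.landmarks[f"hand_grip_{side}"]
    p, R = poses[seg]
    return p + R @ off


class TestLiftGeneration:
    def test_frame_count_and_sampling(self, full_lift):
        assert full_lift.n_frames == 301
        assert np.allclose(np.diff(full_lift.times), 0.01)

    def test_box_rises_monotonically_to_platform(self, full_lift):
        z = full_lift.box_pose[:, 2]
        assert np.all(np.diff(z) >= -1e-12)
        assert z.max() == pytest.approx(1.46, abs=1e-12)
        assert z[-1] == pytest.approx(1.46, abs=1e-12)

    def test_hands_track_handles_within_1mm(self, full_lift, model,
                                            lift_task):
        offs = lift_task.handle_offsets()
        for i in range(0, full_lift.n_frames, 20):
            for side in ("r", "l"):
                hand = _hand_position_oracle(model, full_lift.coords[i],
                                             side)
                target = full_lift.box_pose[i, :3] + offs[side]
                assert np.linalg.norm(hand - target) < 1e-3

    def test_final_hand_height_is_platform_height(self, full_lift, model):
        hand = _hand_position_oracle(model, full_lift.coords[-1], "r")
        assert abs(hand[2] - 1.46) < 1e-3

    def test_bilateral_symmetry(self, full_lift):
        labels = full_lift.coord_labels
        for name in labels:
            if "_r_" in name:
                i, j = labels.index(name), labels.index(
                    name.replace("_r_", "_l_"))
                assert np.max(np.abs(full_lift.coords[:, i]
                                     - full_lift.coords[:, j])) < 1e-9

    def test_determinism(self, anthro, lift_task, model):
        a = generate_lift_trajectory(anthro, lift_task, duration=1.0,
                                     rate=20.0, seed=7, model=model)
        b = generate_lift_trajectory(anthro, lift_task, duration=1.0,
                                     rate=20.0, seed=7, model=model)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.box_pose, b.box_pose)

    def test_unreachable_platform_reports_shortfall(self, anthro, model):
        task = TaskSpec(platform_height=2.6)
        with pytest.raises(InfeasibleTaskError) as err:
            generate_lift_trajectory(anthro, task, model=model)
        assert err.value.shortfall_m > 0

    @pytest.mark.parametrize("duration,rate", [(0.0, 100.0), (3.0, -1.0)])
    def test_invalid_arguments(self, anthro, lift_task, model, duration,
                               rate):
        with pytest.raises(InvalidArgumentError):
            generate_lift_trajectory(anthro, lift_task, duration=duration,
                                     rate=rate, model=model)


class TestMarkers:
    def test_round_trip_is_bit_exact(self, short_lift, model, lift_task,
                                     tmp_path):
        markers = default_marker_set(model, lift_task)
        for fmt, suffix in (("trc", "trc"), ("csv", "csv")):
            path = tmp_path / f"markers.{suffix}"
            export_markers(short_lift, markers, model, path=path, fmt=fmt)
            df = read_markers(str(path))
            from liftsim.motion import marker_positions
            ref = marker_positions(short_lift, markers, model)
            for col in ref.columns:
                assert np.array_equal(df[col].to_numpy(),
                                      ref[col].to_numpy()), (fmt, col)

    def test_static_root_marker_is_constant(self, model):
        import pandas as pd
        from liftsim.motion import MotionTrajectory, marker_positions
        n = 5
        coords = np.tile(model.zero_coords(), (n, 1))
        box = np.zeros((n, 7))
        box[:, 3] = 1.0
        traj = MotionTrajectory(rate=10.0, times=np.arange(n) / 10.0,
                                coords=coords,
                                coord_labels=list(model.coord_names),
                                box_pose=box)
        ms = MarkerSet({"sacrum": ("pelvis", np.zeros(3))})
        df = marker_positions(traj, ms, model)
        for ax in "xyz":
            assert df[f"sacrum_{ax}"].nunique() == 1

    def test_hand_marker_apex_matches_box_apex(self, full_lift, model,
                                               lift_task):
        from liftsim.motion import marker_positions
        markers = default_marker_set(model, lift_task)
        df = marker_positions(full_lift, markers, model)
        apex = df["hand_grip_r_z"].max()
        assert abs(apex - full_lift.box_pose[:, 2].max()) < 1e-3

    def test_unknown_segment_rejected(self, short_lift, model):
        ms = MarkerSet({"bad": ("femur", np.zeros(3))})
        from liftsim.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            export_markers(short_lift, ms, model)


class TestSegmentation:
    def test_half_sine_then_flat(self):
        z = np.concatenate([np.sin(np.linspace(0, np.pi / 2, 101)),
                            np.ones(50)])
        assert segment_lift_window(z, 100.0) == (0, 100)

    def test_known_apex_frame(self, full_lift):
        i_low, i_high = segment_lift_window(full_lift.box_pose[:, 2], 100.0)
        assert i_high == int(np.argmax(full_lift.box_pose[:, 2]))
        assert i_low <= i_high

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            segment_lift_window(np.ones(100), 100.0)

    def test_segmentation_is_idempotent(self, full_lift):
        z = full_lift.box_pose[:, 2]
        i0, i1 = segment_lift_window(z, 100.0)
        j0, j1 = segment_lift_window(z[i0:i1 + 1], 100.0)
        assert (j0, j1) == (0, i1 - i0)

    def test_gait_identical_traces_span_whole_window(self):
        heel = toe = np.linspace(0, 0.1, 50)
        assert segment_gait_cycle(heel, heel.copy(), 100.0) == (0, 49)

    def test_gait_injected_events(self):
        heel = np.full(200, 0.10)
        toe = np.zeros(200)
        heel[30] = 0.0
        heel[130] = 0.0
        assert segment_gait_cycle(heel, toe, 100.0) == (30, 130)

    def test_gait_no_events_raises(self):
        heel = np.full(50, 0.10)
        toe = np.zeros(50)
        with pytest.raises(NoCycleError):
            segment_gait_cycle(heel, toe, 100.0)

    def test_carry_trajectory_has_flatfoot_events(self, anthro, model):
        task = TaskSpec(sequence_type="carry")
        traj = generate_carry_trajectory(anthro, task, duration=2.0,
                                         rate=50.0, seed=3, model=model)
        from liftsim.motion import marker_positions
        ms = MarkerSet({
            "heel_r": model.landmarks["heel_r"],
            "toe_r": model.landmarks["toe_r"]})
        df = marker_positions(traj, ms, model)
        lo, hi = segment_gait_cycle(df["heel_r_z"], df["toe_r_z"], 50.0)
        assert 0 <= lo < hi < traj.n_frames
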