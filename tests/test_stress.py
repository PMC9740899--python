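"""Stress criteria: envelopes, integrals, joint forces, reductions."""
import numpy as np
import pytest

from liftsim.errors import (IncompleteTableError, InvalidArgumentError)
from liftsim.stress import (build_stress_table, group_envelope,
                            integrate_activity, reduction_percent,
                            resultant_joint_force)


class TestEnvelope:
    def test_single_member_is_identity(self, rng):
        tr = rng.random(50)
        assert np.allclose(group_envelope(tr[None, :]), 100 * tr)

    def test_pointwise_maximum_of_constants(self):
        env = group_envelope(np.array([[0.2] * 10, [0.5] * 10]))
        assert np.allclose(env, 50.0)

    def test_matches_per_frame_max_oracle(self, rng):
        acts = rng.random((10, 40))
        env = group_envelope(acts)
        oracle = np.array([100 * max(acts[m, i] for m in range(10))
                           for i in range(40)])
        assert np.array_equal(env, oracle)

    def test_envelope_dominates_members(self, rng):
        acts = rng.random((6, 30))
        env = group_envelope(acts)
        assert np.all(env[None, :] >= 100 * acts - 1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            group_envelope(np.zeros((0, 10)))


class TestIntegral:
    def test_constant_envelope(self):
        t = np.linspace(0, 1, 101)
        assert integrate_activity(np.full(101, 50.0), t) == pytest.approx(
            50.0)

    def test_linear_ramp_is_triangle_area(self):
        t = np.linspace(0, 1, 101)
        assert integrate_activity(np.linspace(0, 100, 101), t) == \
            pytest.approx(50.0)

    def test_against_fine_riemann_oracle(self, rng):
        t = np.linspace(0, 2, 201)
        env = 50 + 30 * np.sin(2 * np.pi * t) + 5 * rng.random(201)
        val = integrate_activity(env, t)
        fine_t = np.linspace(0, 2, 20001)
        fine = np.interp(fine_t, t, env)
        riemann = np.sum(fine[:-1]) * (fine_t[1] - fine_t[0])
        assert val == pytest.approx(riemann, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            integrate_activity(np.array([1.0]), np.array([0.0]))


class TestJointForce:
    def test_bilateral_average_of_constant_magnitudes(self):
        r = np.tile([1000.0, 0, 0], (5, 1))
        left = np.tile([0, 2000.0, 0], (5, 1))
        trace, jf_max, jf_mean = resultant_joint_force(
            {"r": r, "l": left}, "bilateral_average")
        assert np.allclose(trace, 1500.0)
        assert jf_max == pytest.approx(1.5)
        assert jf_mean == pytest.approx(1500.0)

    def test_pure_shear_has_zero_compression(self):
        vecs = np.tile([500.0, 300.0, 0.0], (4, 1))
        axes = np.tile([0.0, 0.0, 1.0], (4, 1))
        trace, jf_max, _ = resultant_joint_force(
            vecs, "single", spine_axes=axes, compressive=True)
        assert np.allclose(trace, 0.0)

    def test_matches_norm_and_projection_oracle(self, rng):
        vecs = rng.standard_normal((20, 3)) * 800
        axes = rng.standard_normal((20, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        trace, _, _ = resultant_joint_force(vecs, "single")
        assert np.array_equal(trace, np.linalg.norm(vecs, axis=1))
        ctrace, _, _ = resultant_joint_force(vecs, "single",
                                             spine_axes=axes,
                                             compressive=True)
        assert np.allclose(ctrace, np.abs(np.sum(vecs * axes, axis=1)),
                           atol=0)

    def test_missing_side_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resultant_joint_force({"r": np.zeros((3, 3))},
                                  "bilateral_average")


class TestReduction:
    def test_printed_glenohumeral_row(self):
        assert reduction_percent(1495.0, 461.3) == pytest.approx(69.14,
                                                                 abs=0.01)

    def test_printed_back_activity_row(self):
        assert reduction_percent(27.9, 10.3) == pytest.approx(63.08,
                                                              abs=0.01)

    def test_no_change_is_zero(self):
        assert reduction_percent(5.0, 5.0) == 0.0

    def test_monotone_in_gap(self):
        assert reduction_percent(100.0, 20.0) > reduction_percent(100.0,
                                                                  30.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidArgumentError):
            reduction_percent(0.0, 1.0)


class TestStressTable:
    def test_identical_subjects_have_zero_sd(self):
        report = build_stress_table(
            {"A": {"jf_max:l4l5": [2.5, 2.5, 2.5]}}, ["jf_max:l4l5"])
        assert report.values.loc["jf_max:l4l5", "A"] == pytest.approx(2.5)
        assert report.sds.loc["jf_max:l4l5", "A"] == pytest.approx(0.0)

    def test_sample_sd_convention(self):
        report = build_stress_table(
            {"A": {"jf_max:l4l5": [2.0, 2.6, 3.2]}}, ["jf_max:l4l5"])
        assert report.values.loc["jf_max:l4l5", "A"] == pytest.approx(2.6)
        # sample (n-1) standard deviation of {2.0, 2.6, 3.2} is 0.6
        assert report.sds.loc["jf_max:l4l5", "A"] == pytest.approx(0.6)

    def test_guideline_flag_above_3p1_kn(self):
        report = build_stress_table(
            {"A": {"jf_max:l4l5": 3.2}, "B": {"jf_max:l4l5": 2.0}},
            ["jf_max:l4l5"])
        assert report.guideline_exceeded["A"] is True
        assert report.guideline_exceeded["B"] is False

    def test_missing_cells_listed(self):
        with pytest.raises(IncompleteTableError) as err:
            build_stress_table({"A": {}}, ["jf_max:knee"])
        assert ("A", "jf_max:knee") in err.value.missing
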