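"""Exoskeleton concept space: catalog, screening, torque joint, springs."""
import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from liftsim.errors import InvalidArgumentError
from liftsim.exo import (SpringSpec, TorqueJointSpec, actuator_torque,
                         attach_exo, enumerate_variants, feasibility_screen,
                         spring_force, variant_by_id)


class TestCatalog:
    def test_exactly_32_variants_with_unique_ids(self):
        variants = enumerate_variants()
        assert len(variants) == 32
        assert len({v.id for v in variants}) == 32

    def test_table_acronym_variant_is_present(self):
        v = variant_by_id("H: R.cc–A: U.lm-cc")
        assert v.hip.kind == "revolute"
        assert v.hip.axes == ("craniocaudal",)
        assert v.middle.kind == "prismatic"
        assert v.arm.kind == "universal"
        assert v.arm.axes == ("lateromedial", "craniocaudal")

    def test_structure_mass_default(self):
        assert all(v.structure_mass == pytest.approx(5.1)
                   for v in enumerate_variants())


class TestScreen:
    def test_fixed_middle_fails_no_prismatic(self):
        v = variant_by_id("H: R.cc–M: F–A: R.lm")
        res = feasibility_screen(v)
        assert not res and res.reason == "no_prismatic"

    def test_fixed_arm_fails_arm_fixed(self):
        v = variant_by_id("H: R.cc–A: F")
        res = feasibility_screen(v)
        assert not res and res.reason == "arm_fixed"

    def test_twelve_variants_pass(self):
        passed = [v for v in enumerate_variants() if feasibility_screen(v)]
        assert len(passed) == 12
        # 4 hip choices x prismatic middle x 3 rotational arm joints
        assert all(v.middle.kind == "prismatic" for v in passed)
        assert all(v.arm.rotational_dof >= 1 for v in passed)


class TestTorqueJoint:
    def test_value_at_zero_degrees(self):
        assert actuator_torque(TorqueJointSpec(), 0.0) == pytest.approx(
            27.6381, abs=1e-12)

    def test_value_at_ten_degrees(self):
        assert actuator_torque(TorqueJointSpec(), 10.0) == pytest.approx(
            27.6381 + 5.570 - 0.36, abs=1e-12)

    def test_vertex_matches_numeric_maximization(self):
        spec = TorqueJointSpec()
        analytic = -spec.c1 / (2 * spec.c2)
        res = minimize_scalar(lambda x: -actuator_torque(spec, x),
                              bounds=(0, 150), method="bounded",
                              options={"xatol": 1e-10})
        assert analytic == pytest.approx(77.3611, abs=1e-3)
        # the curve is flat near the vertex (|c2| ~ 4e-3 Nm/deg^2), so the
        # numeric maximizer localizes it only to ~1e-2 deg
        assert res.x == pytest.approx(analytic, abs=0.05)

    def test_curve_symmetric_about_vertex(self):
        spec = TorqueJointSpec()
        vertex = -spec.c1 / (2 * spec.c2)
        for d in (5.0, 20.0, 40.0):
            assert actuator_torque(spec, vertex + d) == pytest.approx(
                actuator_torque(spec, vertex - d), abs=1e-9)

    def test_non_finite_angle_rejected(self):
        with pytest.raises(InvalidArgumentError):
            actuator_torque(TorqueJointSpec(), float("nan"))

    def test_convex_curve_rejected_on_a_concept(self):
        from liftsim.exo import ExoVariant, HIP_JOINTS, MIDDLE_JOINTS, \
            ARM_JOINTS
        convex = TorqueJointSpec(c2=0.001)
        assert not convex.is_concave
        with pytest.raises(InvalidArgumentError):
            ExoVariant(hip=HIP_JOINTS[0], middle=MIDDLE_JOINTS[1],
                       arm=ARM_JOINTS[1], torque_joint=convex)


class TestSpring:
    def test_magnitude_is_stiffness_times_distance(self):
        fa, fb = spring_force(SpringSpec(stiffness=10.0),
                              np.zeros(3), np.array([0.1, 0.0, 0.0]))
        assert np.linalg.norm(fa) == pytest.approx(1.0, abs=1e-12)
        assert fa[0] > 0          # attractive: pulls a toward b

    def test_coincident_endpoints_give_zero(self):
        fa, fb = spring_force(SpringSpec(), np.ones(3), np.ones(3))
        assert np.all(fa == 0) and np.all(fb == 0)

    def test_newtons_third_law(self, rng):
        pa, pb = rng.standard_normal(3), rng.standard_normal(3)
        fa, fb = spring_force(SpringSpec(), pa, pb)
        assert np.allclose(fa, -fb, atol=0)


class TestAttach:
    def test_dof_bookkeeping_grubler_tally(self, model):
        coupled = attach_exo(model, variant_by_id("H: R.cc–A: R.lm"))
        # per side: hip revolute + torque joint + prismatic + arm revolute
        assert coupled.exo_joint_dof_per_side == 4
        spherical = attach_exo(model, variant_by_id("H: S–A: U.lm-cc"))
        assert spherical.exo_joint_dof_per_side == 3 + 1 + 1 + 2

    def test_exo_mass_matches_structure_mass(self, model):
        coupled = attach_exo(model, variant_by_id("H: R.cc–A: R.lm"))
        assert coupled.exo_mass == pytest.approx(5.1, abs=1e-9)

    def test_infeasible_needs_override_and_is_flagged(self, model):
        v = variant_by_id("H: R.cc–M: F–A: R.lm")
        with pytest.raises(InvalidArgumentError):
            attach_exo(model, v)
        coupled = attach_exo(model, v, override=True)
        assert coupled.overconstrained
        assert coupled.screen_reason == "no_prismatic"

    def test_attach_detach_leaves_body_unchanged(self, model):
        before = {n: (s.mass, s.length) for n, s in model.segments.items()}
        coupled = attach_exo(model, variant_by_id("H: R.cc–A: R.cc"))
        restored = coupled.detach()
        assert restored is model
        after = {n: (s.mass, s.length) for n, s in model.segments.items()}
        assert before == after
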