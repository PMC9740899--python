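"""Recruitment core on toy problems, contact law, torque-curve fitting."""
import itertools

import numpy as np
import pytest

from liftsim.contacts import ContactElementSpec, element_geometry
from liftsim.errors import (ConfigurationError, KinematicFailureError,
                            RankDeficiencyError, RecruitmentInfeasibleError)
from liftsim.exo import attach_exo, variant_by_id
from liftsim.sim import (contact_force, fit_degree2, recruit_optimize,
                         solve_frame_kinematics)


def _single_joint(torques, required, power=3.0):
    """Recruitment of parallel actuators on one joint DOF."""
    n = len(torques)
    A = np.ones((1, n))
    x, info = recruit_optimize(
        A, np.array([required]), np.zeros(n), np.array(torques, float),
        np.array(torques, float), np.ones(n, dtype=bool), [],
        power=power)
    return x, info


class TestRecruitmentToys:
    def test_single_actuator_half_capacity(self):
        x, _ = _single_joint([80.0], 40.0)
        assert x[0] / 80.0 == pytest.approx(0.5, abs=1e-9)

    def test_two_identical_actuators_split_equally(self):
        x, _ = _single_joint([100.0, 100.0], 60.0)
        assert x[0] == pytest.approx(x[1], abs=1e-6)
        assert x.sum() == pytest.approx(60.0, abs=1e-8)

    @pytest.mark.parametrize("strengths,required", [
        ((80.0, 120.0, 200.0), 150.0),
        ((50.0, 50.0, 300.0), 90.0),
    ])
    def test_redundant_joint_matches_grid_oracle(self, strengths, required):
        x, _ = _single_joint(list(strengths), required)
        acts = x / np.array(strengths)

        # brute-force minimizer over the feasible polytope: coarse grid,
        # then a fine pass around the coarse optimum
        s = np.array(strengths)

        def grid_search(lo1, hi1, lo2, hi2, n):
            best, best_val = None, np.inf
            for a1 in np.linspace(lo1, hi1, n):
                for a2 in np.linspace(lo2, hi2, n):
                    a3 = (required - a1 * s[0] - a2 * s[1]) / s[2]
                    if not (0 <= a1 <= 1 and 0 <= a2 <= 1 and 0 <= a3 <= 1):
                        continue
                    val = a1**3 + a2**3 + a3**3
                    if val < best_val:
                        best_val, best = val, (a1, a2, a3)
            return best

        coarse = grid_search(0, 1, 0, 1, 201)
        h = 1.0 / 200
        best = grid_search(coarse[0] - h, coarse[0] + h,
                           coarse[1] - h, coarse[1] + h, 201)
        assert np.max(np.abs(acts - np.array(best))) < 1e-3

    def test_infeasible_demand_raises(self):
        with pytest.raises(RecruitmentInfeasibleError):
            _single_joint([80.0], 100.0)

    def test_quadratic_power_also_unique(self):
        x, _ = _single_joint([60.0, 120.0], 90.0, power=2.0)
        # analytic optimum of (t1/60)^2 + (t2/120)^2 s.t. t1+t2=90
        # d/dt: 2 t1/3600 = 2 t2/14400 -> t2 = 4 t1 -> t1 = 18, t2 = 72
        assert x[0] == pytest.approx(18.0, abs=1e-6)
        assert x[1] == pytest.approx(72.0, abs=1e-6)


class TestContactLaw:
    def _spec(self, **kw):
        base = dict(name="c", target_segment="t", target_offset=(0, 0, 0),
                    zone_segment="z", zone_center=(0, 0, 0),
                    zone_axis=(0, 0, 1), zone_radius=0.1,
                    zone_half_length=0.1)
        base.update(kw)
        return ContactElementSpec(**base)

    def test_zero_force_outside_zone(self):
        spec = self._spec()
        nrm, fric = contact_force(spec, np.array([0.5, 0, 0]), np.zeros(3),
                                  np.eye(3), normal_mag=500.0, t1_mag=100.0)
        assert np.all(nrm == 0) and np.all(fric == 0)

    def test_force_inside_zone_along_geometry(self):
        spec = self._spec(normal_mode="fixed", normal_axis=(1, 0, 0))
        nrm, fric = contact_force(spec, np.array([0.05, 0, 0]),
                                  np.zeros(3), np.eye(3), normal_mag=100.0)
        assert np.allclose(nrm, [100.0, 0, 0])

    def test_degenerate_zone_rejected(self):
        with pytest.raises(ConfigurationError):
            self._spec(zone_radius=0.0)

    def test_single_contact_supports_static_load(self):
        """One element carrying a 100 N load along its normal recruits
        exactly 100 N of normal force."""
        A = np.array([[1.0, 0.0, 0.0]])    # equilibrium along the normal
        x, _ = recruit_optimize(
            A, np.array([100.0]), np.array([0.0, -np.inf, -np.inf]),
            np.array([10000.0, np.inf, np.inf]),
            np.array([10000.0, 10000.0, 10000.0]),
            np.array([True, False, False]), [(0, 1, 2, 1.0)])
        assert x[0] == pytest.approx(100.0, abs=1e-6)
        # friction is indeterminate here (no tangential demand) but must
        # stay inside the exact cone
        assert np.hypot(x[1], x[2]) <= 1.0 * x[0] + 1e-9

    def test_friction_stays_inside_cone(self):
        """Tangential demand saturates at mu * normal (inscribed polygon)."""
        # equilibrium: normal carries 100 N, tangent t1 carries 60 N
        A = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        x, _ = recruit_optimize(
            A, np.array([100.0, 60.0]),
            np.array([0.0, -np.inf, -np.inf]),
            np.array([10000.0, np.inf, np.inf]),
            np.full(3, 10000.0), np.array([True, False, False]),
            [(0, 1, 2, 1.0)])
        assert np.hypot(x[1], x[2]) <= 1.0 * x[0] + 1e-9


class TestKinematics:
    def test_forcing_screened_out_variant_fails(self, model, short_lift):
        coupled = attach_exo(model, variant_by_id("H: R.cc–M: F–A: R.lm"),
                             override=True)
        with pytest.raises(KinematicFailureError):
            solve_frame_kinematics(coupled, short_lift.coords[0])

    def test_hard_drivers_satisfied_to_tolerance(self, model, short_lift):
        coupled = attach_exo(model, variant_by_id("H: R.cc–A: R.lm"))
        qe, soft = solve_frame_kinematics(coupled, short_lift.coords[5])
        poses = coupled.exo_tree.fk(qe)
        hp = model.fk(short_lift.coords[5])
        for side in ("r", "l"):
            brace = poses[f"exo_bracing_{side}"][0]
            target = model.point(f"bracing_attach_{side}", hp)
            assert np.linalg.norm(brace - target) < 1e-6

    def test_soft_rotational_mismatch_equals_imposed_angle(self, model):
        """A pure humeral axial rotation cannot be followed by a
        lateromedial-only arm joint; it lands in the soft residual."""
        coupled = attach_exo(model, variant_by_id("H: R.cc–A: R.lm"))
        delta = 0.2
        q = model.zero_coords()
        q[model.tree.coord_index("gh_r_rotation")] = delta
        _, soft = solve_frame_kinematics(coupled, q)
        assert np.linalg.norm(soft["r"]) == pytest.approx(delta, rel=0.1)


class TestTorqueFit:
    def test_exact_quadratic_recovered_to_1e9(self):
        ang = np.linspace(0, 90, 25)
        tau = 27.6381 + 0.5570 * ang - 0.0036 * ang**2
        spec = fit_degree2(np.column_stack([ang, tau]))
        assert spec.c0 == pytest.approx(27.6381, abs=1e-9)
        assert spec.c1 == pytest.approx(0.5570, abs=1e-9)
        assert spec.c2 == pytest.approx(-0.0036, abs=1e-9)
        assert spec.residual < 1e-9

    def test_constant_samples_give_flat_curve(self):
        ang = np.array([0.0, 30.0, 60.0, 90.0])
        spec = fit_degree2(np.column_stack([ang, np.full(4, 12.5)]))
        assert spec.c0 == pytest.approx(12.5, abs=1e-9)
        assert abs(spec.c1) < 1e-12 and abs(spec.c2) < 1e-12

    def test_rank_deficiency(self):
        samples = np.array([[10.0, 5.0], [10.0, 6.0], [20.0, 7.0]])
        with pytest.raises(RankDeficiencyError):
            fit_degree2(samples)

    def test_noisy_fit_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        ang = np.linspace(0, 100, 200)
        truth = np.array([27.6381, 0.5570, -0.0036])
        tau = truth[0] + truth[1] * ang + truth[2] * ang**2 \
            + rng.normal(0, 1.0, 200)
        spec = fit_degree2(np.column_stack([ang, tau]))
        # normal-equations oracle with standard errors
        V = np.column_stack([np.ones_like(ang), ang, ang**2])
        coef = np.linalg.solve(V.T @ V, V.T @ tau)
        resid = tau - V @ coef
        sigma2 = resid @ resid / (len(ang) - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(V.T @ V)))
        fitted = np.array([spec.c0, spec.c1, spec.c2])
        assert np.allclose(fitted, coef, atol=1e-9)
        assert np.all(np.abs(fitted - truth) < 3 * se)
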