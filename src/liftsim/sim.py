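"""Inverse-dynamics core: coupled kinematics and muscle recruitment.

Per frame the workflow solves two problems:

1. *Kinematics.*  The human coordinates come from the trajectory.  The
   exoskeleton base is slaved to the pelvis; the remaining exo joint
   coordinates are solved against drivers at the arm bracings -- the
   three translational DOF are hard (bracing centre coincides with the
   mid-humerus point to 1e-8 m) and the three rotational DOF are soft
   (orientation mismatch minimized, not enforced).

2. *Recruitment.*  All unknown internal forces -- torque-equivalent
   actuator torques, ground contact forces, predictive-contact-element
   (PCE) normal and friction forces and, in ideal-actuator mode, the
   exo support torque -- are found by minimizing the sum of activities
   to the power p (default 3) subject to generalized-force equilibrium
   of the human tree and (if present) the exo tree, activity bounds
   0..1, unilateral contact caps and linearized friction cones.
   Contact elements enter the objective as auxiliary activities
   normal_force / F_max, which makes the 10 kN caps nearly cost-free,
   as intended.  Equilibrium is assembled in generalized coordinates:
   segment gravity and Newton-Euler inertial terms (finite-differenced
   COM accelerations plus slender-rod rotational terms) on one side,
   Jacobian-transposed applied forces on the other.  The box load is
   shared symmetrically between both hands.

Friction cones are linearized as regular polygons inscribed in the
exact cone (half-plane constraints shrunk by cos(pi/m) for m facets),
so |friction| <= mu * normal holds everywhere, never just
approximately.  A linear program (HiGHS) provides a feasibility
certificate and warm start; SLSQP refines to the strictly convex
optimum, which is unique for p > 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, linprog, minimize

from . import config as cfgmod
from .body import BodyModel, KinematicTree
from .contacts import ContactElementSpec, GroundContactSpec, element_geometry
from .errors import (InvalidArgumentError, KinematicFailureError,
                     RankDeficiencyError, RecruitmentInfeasibleError)
from .exo import CoupledModel, TorqueJointSpec, actuator_torque, spring_force
from .motion import MotionTrajectory

MODES = ("no_exo", "ideal_actuator", "prescribed_torque")
_GVEC = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class KinematicDriver:
    """A constrained quantity with hard or soft priority."""

    name: str
    priority: str                       # "hard" or "soft"
    weight: float = 1.0                 # used for soft drivers only


@dataclass
class FrameSolution:
    """Per-frame recruitment result."""

    index: int
    time: float
    coords: np.ndarray
    exo_coords: np.ndarray | None
    activities: dict[str, float]
    actuator_torques: dict[str, float]          # signed, Nm
    contacts: list[dict]                         # per active element
    joint_reactions: dict[str, np.ndarray]       # incl. muscle compression
    joint_compressions: dict[str, float]
    spine_axis: np.ndarray
    torque_joint: dict[str, float] = field(default_factory=dict)  # side -> Nm
    torque_angle_deg: dict[str, float] = field(default_factory=dict)
    bracing_frames: dict = field(default_factory=dict)
    soft_residual: dict[str, np.ndarray] = field(default_factory=dict)
    equilibrium_residual: float = 0.0
    objective: float = 0.0


@dataclass
class SequenceSolution:
    frames: list[FrameSolution]
    mode: str
    times: np.ndarray

    def activity_trace(self, actuator: str) -> np.ndarray:
        return np.array([f.activities[actuator] for f in self.frames])

    def reaction_trace(self, joint: str) -> np.ndarray:
        return np.array([f.joint_reactions[joint] for f in self.frames])


# -- ground contact ---------------------------------------------------------

def ground_contacts(model: BodyModel, max_strength: float = 10000.0,
                    mu: float = 1.0) -> list[GroundContactSpec]:
    specs = []
    for side in ("r", "l"):
        for base in ("heel", "toe", "foot_mid"):
            seg, off = model.landmarks[f"{base}_{side}"]
            specs.append(GroundContactSpec(
                name=f"ground_{base}_{side}", target_segment=seg,
                target_offset=tuple(off), max_strength=max_strength,
                friction_mu=mu))
    return specs


def contact_force(spec: ContactElementSpec, target_pos, zone_pos, zone_R,
                  normal_mag: float = 0.0, t1_mag: float = 0.0,
                  t2_mag: float = 0.0):
    """World-frame (normal, friction) force of one element.

    Zero outside the zone regardless of the recruitment magnitudes.
    """
    inside, n, t1, t2 = element_geometry(spec, np.asarray(target_pos, float),
                                         np.asarray(zone_pos, float),
                                         np.asarray(zone_R, float))
    if not inside:
        return np.zeros(3), np.zeros(3)
    return normal_mag * n, t1_mag * t1 + t2_mag * t2


# -- kinematics -------------------------------------------------------------

def _rotation_residual(R_a: np.ndarray, R_b: np.ndarray) -> np.ndarray:
    """Rotation vector of R_a^T R_b (radians)."""
    R = R_a.T @ R_b
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    cos_t = max(-1.0, min(1.0, (np.trace(R) - 1.0) / 2.0))
    theta = math.acos(cos_t)
    s = np.linalg.norm(w)
    if s < 1e-12:
        return 0.5 * w
    return w * (theta / s)


def solve_frame_kinematics(coupled: CoupledModel, human_coords: np.ndarray,
                           previous: dict[str, np.ndarray] | None = None
                           ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Solve the exo joint coordinates for one frame.

    Returns the full exo coordinate vector and the per-side soft
    rotational residual (rotation vector, radians).  Raises
    :class:`KinematicFailureError` for overconstrained couplings.
    """
    if coupled.overconstrained:
        raise KinematicFailureError(
            f"variant {coupled.variant.id!r} is kinematically "
            f"overconstrained ({coupled.screen_reason})",
            conflicting_drivers=("arm_bracing_translation",
                                 coupled.screen_reason))
    body = coupled.body
    human_poses = body.fk(human_coords)
    base_pose = coupled.base_pose_from_pelvis(human_poses)
    tree = coupled.exo_tree
    hard_tol = coupled.config["solver"]["hard_tol"]

    joint_values = np.zeros(len(coupled.joint_coords))
    name_to_pos = {n: i for i, n in enumerate(coupled.joint_coords)}
    soft_res: dict[str, np.ndarray] = {}
    for side in ("r", "l"):
        target_p = body.point(f"bracing_attach_{side}", human_poses)
        target_R = human_poses[f"upper_arm_{side}"][1]
        idx = [name_to_pos[n] for n in coupled.side_dof[side]]
        # arm-connection rotations act at the bracing origin, so only the
        # hip/torque/middle coordinates move the hard (position) target
        n_arm = len(coupled.variant.arm.axes)
        pos_idx, arm_idx = idx[:len(idx) - n_arm], idx[len(idx) - n_arm:]
        if previous is not None and side in previous:
            x0 = previous[side].copy()
        else:
            x0 = np.full(len(idx), 0.01)

        def eval_side(x):
            jv = joint_values.copy()
            jv[idx] = x
            q = coupled.exo_coords_from(base_pose, jv)
            poses = tree.fk(q)
            p, R = poses[f"exo_bracing_{side}"]
            return p - target_p, _rotation_residual(R, target_R)

        def pos_res(xp):
            x = x0.copy()
            x[: len(pos_idx)] = xp
            pres, _ = eval_side(x)
            return pres

        # bounds keep rotations on the physical branch and the prismatic
        # extension at positive structure length
        lo = np.full(len(pos_idx), -2.5)
        hi = np.full(len(pos_idx), 2.5)
        has_prism = coupled.variant.middle.kind == "prismatic"
        if has_prism:
            lo[-1], hi[-1] = -0.9 * coupled.v_len, 0.6
        xp0 = np.clip(x0[: len(pos_idx)], lo + 1e-9, hi - 1e-9)
        redundant = len(pos_idx) > 3

        def solve_pos(start):
            if redundant:
                # continuity-regularized pass selects the branch, then an
                # unregularized polish drives the residual to round-off
                def reg_res(xp):
                    return np.concatenate([pos_res(xp),
                                           5e-3 * (xp - start)])
                pre = least_squares(reg_res, start, method="trf",
                                    bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
                start = pre.x
            return least_squares(pos_res, start, method="trf",
                                 bounds=(lo, hi), xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15)

        ls = solve_pos(xp0)
        x_sol = x0.copy()
        x_sol[: len(pos_idx)] = ls.x
        pres, _ = eval_side(x_sol)
        if np.linalg.norm(pres) > 1e-9:
            # multi-start on the torque-joint angle
            for th2 in (0.2, 0.6, 1.0, 1.5):
                alt = xp0.copy()
                alt[len(alt) - 1 - int(has_prism)] = th2
                ls2 = solve_pos(alt)
                if np.linalg.norm(ls2.fun) < np.linalg.norm(pres):
                    x_sol[: len(pos_idx)] = ls2.x
                    pres, _ = eval_side(x_sol)
                if np.linalg.norm(pres) <= 1e-9:
                    break
        if np.linalg.norm(pres) > 1e-6:
            raise KinematicFailureError(
                f"hard arm-bracing drivers unsatisfiable for "
                f"{coupled.variant.id!r} side {side} (residual "
                f"{np.linalg.norm(pres):.2e} m)",
                conflicting_drivers=(f"arm_bracing_translation_{side}",))

        if n_arm:
            def rot_obj(xa):
                x = x_sol.copy()
                x[len(pos_idx):] = xa
                _, rres = eval_side(x)
                return float(rres @ rres)

            ro = minimize(rot_obj, x_sol[len(pos_idx):], method="BFGS",
                          options={"maxiter": 200, "gtol": 1e-12})
            x_sol[len(pos_idx):] = ro.x
        if len(pos_idx) > 3:
            # redundant position DOF: co-optimize orientation on the
            # position-constraint manifold from the feasible start
            def objective(x):
                _, rres = eval_side(x)
                return (float(rres @ rres)
                        + 1e-3 * float((x - x_sol) @ (x - x_sol)))

            res = minimize(objective, x_sol, method="SLSQP",
                           constraints=[{"type": "eq",
                                         "fun": lambda x: eval_side(x)[0]}],
                           options={"maxiter": 200, "ftol": 1e-14})
            pres2, _ = eval_side(res.x)
            if np.linalg.norm(pres2) < 1e-7:
                x_sol = res.x
        pres, rres = eval_side(x_sol)
        joint_values[idx] = x_sol
        soft_res[side] = rres
    exo_coords = coupled.exo_coords_from(base_pose, joint_values)
    return exo_coords, soft_res


# -- jacobians --------------------------------------------------------------

def _tree_jacobians(tree: KinematicTree, q: np.ndarray,
                    points: list[tuple[str, np.ndarray]],
                    segments: list[str], h: float = 1e-6):
    """Positional Jacobians for points and angular Jacobians for segments."""
    npts, nseg, n = len(points), len(segments), tree.ndof
    Jp = np.zeros((npts, 3, n))
    Jw = np.zeros((nseg, 3, n))
    poses0 = tree.fk(q)
    R0 = [poses0[s][1] for s in segments]
    for j in range(n):
        dq = np.zeros(n)
        dq[j] = h
        pp = tree.fk(q + dq)
        pm = tree.fk(q - dq)
        for i, (s, off) in enumerate(points):
            a = pp[s][0] + pp[s][1] @ off
            b = pm[s][0] + pm[s][1] @ off
            Jp[i, :, j] = (a - b) / (2 * h)
        for i, s in enumerate(segments):
            W = (pp[s][1] - pm[s][1]) / (2 * h) @ R0[i].T
            Jw[i, :, j] = [W[2, 1] - W[1, 2], W[0, 2] - W[2, 0],
                           W[1, 0] - W[0, 1]]
    Jw *= 0.5
    return Jp, Jw


# -- recruitment core -------------------------------------------------------

def recruit_optimize(A_eq: np.ndarray, b_eq: np.ndarray,
                     lower: np.ndarray, upper: np.ndarray,
                     scale: np.ndarray, costed: np.ndarray,
                     cones: list[tuple[int, int, int, float]],
                     power: float = 3.0, facets: int = 8,
                     reg: float = 1e-8, x0: np.ndarray | None = None,
                     tol: float = 1e-6, row_names: list[str] | None = None):
    """Minimize sum of activities^p subject to equilibrium and cones.

    ``scale`` holds each variable's activity denominator; ``costed``
    marks variables entering the objective.  ``cones`` lists
    (i_normal, i_t1, i_t2, mu) friction triples; the cone is linearized
    as ``u_k . T <= mu cos(pi/m) N`` for m facet directions, an inscribed
    polygon, so the exact cone is never exceeded.  Returns (x, info).
    """
    n = A_eq.shape[1]
    rows = []
    shrink = math.cos(math.pi / facets)
    for iN, iT1, iT2, mu in cones:
        for k in range(facets):
            ang = 2 * math.pi * k / facets
            row = np.zeros(n)
            row[iN] = mu * shrink
            row[iT1] = -math.cos(ang)
            row[iT2] = -math.sin(ang)
            rows.append(row)
    G = np.array(rows) if rows else np.zeros((0, n))

    # feasibility + warm start via LP (minimize summed linear activities)
    c = np.where(costed, 1.0 / np.maximum(scale, 1e-12), 0.0)
    bounds = [(lo if np.isfinite(lo) else None,
               up if np.isfinite(up) else None)
              for lo, up in zip(lower, upper)]
    lp = linprog(c, A_ub=-G if len(G) else None,
                 b_ub=np.zeros(len(G)) if len(G) else None,
                 A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not lp.success:
        # confirm with the interior-point backend, then report which
        # generalized-force equation cannot be balanced
        lp2 = linprog(c, A_ub=-G if len(G) else None,
                      b_ub=np.zeros(len(G)) if len(G) else None,
                      A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                      method="highs-ipm")
        if lp2.success:
            lp = lp2
        else:
            from scipy.optimize import lsq_linear
            ls = lsq_linear(A_eq, b_eq,
                            bounds=(np.where(np.isfinite(lower), lower,
                                             -1e12),
                                    np.where(np.isfinite(upper), upper,
                                             1e12)))
            resid = A_eq @ ls.x - b_eq
            worst = int(np.argmax(np.abs(resid)))
            names = row_names or [f"equation {k}"
                                  for k in range(len(b_eq))]
            raise RecruitmentInfeasibleError(
                "equilibrium infeasible within actuator/contact bounds; "
                f"largest unbalanced generalized force at {names[worst]} "
                f"({resid[worst]:+.1f})")
    x_lp = lp.x
    if x0 is None:
        x0 = x_lp
    else:
        # keep the warm start only if it is feasible for this frame
        if (np.max(np.abs(A_eq @ x0 - b_eq)) > 1e-4
                or (len(G) and np.min(G @ x0) < -1e-6)
                or np.any(x0 < lower - 1e-9) or np.any(x0 > upper + 1e-9)):
            x0 = x_lp

    s = np.maximum(scale, 1e-12)
    w_cost = costed.astype(float)
    # tie-break regularization on cost-free variables (friction, ideal
    # torque) against a fixed 100 N/Nm reference so gratuitous forces
    # vanish without distorting genuinely needed ones
    reg_w = np.where(costed, 0.0, reg)
    s_reg = 100.0

    def fun(x):
        a = x / s
        r = x / s_reg
        return float(np.sum(w_cost * np.abs(a) ** power)
                     + np.sum(reg_w * r * r))

    def grad(x):
        a = x / s
        return (w_cost * power * np.sign(a) * np.abs(a) ** (power - 1) / s
                + 2 * reg_w * x / s_reg**2)

    cons = [{"type": "eq", "fun": lambda x: A_eq @ x - b_eq,
             "jac": lambda x: A_eq}]
    if len(G):
        cons.append({"type": "ineq", "fun": lambda x: G @ x,
                     "jac": lambda x: G})
    res = minimize(fun, x0, jac=grad, method="SLSQP",
                   bounds=list(zip(lower, upper)), constraints=cons,
                   options={"maxiter": 200, "ftol": 1e-12})
    x = res.x
    resid = float(np.max(np.abs(A_eq @ x - b_eq))) if len(b_eq) else 0.0
    if resid > tol or (len(G) and float(np.min(G @ x)) < -1e-6):
        # fall back to the LP point polished by a second SLSQP run
        res2 = minimize(fun, x_lp, jac=grad, method="SLSQP",
                        bounds=list(zip(lower, upper)), constraints=cons,
                        options={"maxiter": 300, "ftol": 1e-12})
        x2 = res2.x
        resid2 = float(np.max(np.abs(A_eq @ x2 - b_eq))) if len(b_eq) else 0.0
        if resid2 < resid:
            x, resid = x2, resid2
    if resid > 1e-4:
        raise RecruitmentInfeasibleError(
            f"recruitment solver left equilibrium residual {resid:.2e}")
    x = np.clip(x, lower, upper)
    return x, {"objective": fun(x), "residual": resid}


# -- frame problem assembly -------------------------------------------------

class _FrameProblem:
    """Index bookkeeping for one frame's recruitment variables."""

    def __init__(self):
        self.names: list[str] = []
        self.scale: list[float] = []
        self.costed: list[bool] = []
        self.lower: list[float] = []
        self.upper: list[float] = []
        self.cones: list[tuple[int, int, int, float]] = []

    def add(self, name, scale, costed, lo, up) -> int:
        self.names.append(name)
        self.scale.append(scale)
        self.costed.append(costed)
        self.lower.append(lo)
        self.upper.append(up)
        return len(self.names) - 1


def solve_recruitment(model, frame_ctx: dict, mode: str = "no_exo",
                      config: dict | None = None,
                      warm: np.ndarray | None = None) -> FrameSolution:
    """Solve one frame's recruitment problem.

    ``model`` is a :class:`BodyModel` (mode "no_exo") or a
    :class:`CoupledModel`; ``frame_ctx`` carries the kinematic state
    assembled by :func:`run_sequence`.
    """
    if mode not in MODES:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    coupled = model if isinstance(model, CoupledModel) else None
    body = coupled.body if coupled else model
    cfg = config or (coupled.config if coupled else cfgmod.default_config())
    scfg = cfg["solver"]
    g = cfg["gravity"]
    gvec = g * _GVEC

    q = frame_ctx["coords"]
    human_poses = frame_ctx["human_poses"]
    acc = frame_ctx["com_acc"]                 # segment -> (3,)
    omega = frame_ctx.get("omega", {})
    alpha = frame_ctx.get("alpha", {})
    box_mass = frame_ctx.get("box_mass", 0.0)
    box_acc = frame_ctx.get("box_acc", np.zeros(3))

    # ---- human tree points needing Jacobians
    h_points: list[tuple[str, np.ndarray]] = []
    h_point_id: dict[str, int] = {}

    def hpt(tag, seg, off):
        h_point_id[tag] = len(h_points)
        h_points.append((seg, np.asarray(off, float)))

    for seg, sp in body.segments.items():
        hpt(f"com:{seg}", seg, sp.com_offset)
    grounds = frame_ctx["ground_specs"]
    for gs in grounds:
        hpt(f"gnd:{gs.name}", gs.target_segment, gs.target_offset)
    for side in ("r", "l"):
        seg, off = body.landmarks[f"hand_grip_{side}"]
        hpt(f"hand:{side}", seg, off)
    active_pce: list[tuple[ContactElementSpec, np.ndarray, np.ndarray,
                           np.ndarray, np.ndarray]] = []
    exo_poses = frame_ctx.get("exo_poses")
    if coupled is not None and mode != "no_exo":
        for spec in coupled.pce:
            tp, tR = human_poses[spec.target_segment]
            target_pos = tp + tR @ np.asarray(spec.target_offset)
            zp, zR = exo_poses[spec.zone_segment]
            inside, nrm, t1, t2 = element_geometry(spec, target_pos, zp, zR)
            if inside:
                active_pce.append((spec, target_pos, nrm, t1, t2))
                hpt(f"pce:{spec.name}", spec.target_segment,
                    spec.target_offset)

    h_segs = list(body.segments)
    Jp_h, Jw_h = _tree_jacobians(body.tree, q, h_points, h_segs)
    nh = body.tree.ndof

    # ---- exo tree points
    ne = 0
    if coupled is not None and mode != "no_exo":
        e_points: list[tuple[str, np.ndarray]] = []
        e_point_id: dict[str, int] = {}

        def ept(tag, seg, off):
            e_point_id[tag] = len(e_points)
            e_points.append((seg, np.asarray(off, float)))

        for seg, sp in coupled.exo_segments.items():
            ept(f"com:{seg}", seg, sp.com_offset)
        for spec, target_pos, *_ in active_pce:
            zp, zR = exo_poses[spec.zone_segment]
            local = zR.T @ (target_pos - zp)
            ept(f"pce:{spec.name}", spec.zone_segment, local)
        for side, (a, b) in coupled.spring_points.items():
            ept(f"spr_a:{side}", a[0], a[1])
            ept(f"spr_b:{side}", b[0], b[1])
        qe = frame_ctx["exo_coords"]
        e_segs = list(coupled.exo_segments)
        Jp_e, Jw_e = _tree_jacobians(coupled.exo_tree, qe, e_points, e_segs)
        ne = coupled.exo_tree.ndof

    ntot = nh + ne
    b_vec = np.zeros(ntot)

    # inertial minus gravity terms, human
    for i, seg in enumerate(h_segs):
        sp = body.segments[seg]
        a_com = acc.get(seg, np.zeros(3))
        J = Jp_h[h_point_id[f"com:{seg}"]]
        b_vec[:nh] += J.T @ (sp.mass * (a_com - gvec))
        if seg in omega:
            _, R = human_poses[seg]
            Iw = R @ np.diag(sp.inertia) @ R.T
            tau = Iw @ alpha[seg] + np.cross(omega[seg], Iw @ omega[seg])
            b_vec[:nh] += Jw_h[i].T @ tau
    # box load shared symmetrically between both hands
    if box_mass > 0:
        f_box = 0.5 * box_mass * (box_acc - gvec)
        for side in ("r", "l"):
            J = Jp_h[h_point_id[f"hand:{side}"]]
            b_vec[:nh] += J.T @ f_box

    if ne:
        exo_acc = frame_ctx.get("exo_com_acc", {})
        exo_om = frame_ctx.get("exo_omega", {})
        exo_al = frame_ctx.get("exo_alpha", {})
        for i, seg in enumerate(e_segs):
            sp = coupled.exo_segments[seg]
            a_com = exo_acc.get(seg, np.zeros(3))
            J = Jp_e[e_point_id[f"com:{seg}"]]
            b_vec[nh:] += J.T @ (sp.mass * (a_com - gvec))
            if seg in exo_om:
                _, R = exo_poses[seg]
                Iw = R @ np.diag(sp.inertia) @ R.T
                tau = Iw @ exo_al[seg] + np.cross(exo_om[seg],
                                                  Iw @ exo_om[seg])
                b_vec[nh:] += Jw_e[i].T @ tau
        # springs (known applied forces -> move to b)
        spring_forces = {}
        for side, (pa_spec, pb_spec) in coupled.spring_points.items():
            pa = _world(exo_poses, *pa_spec)
            pb = _world(exo_poses, *pb_spec)
            fa, fb = spring_force(coupled.variant.spring, pa, pb)
            spring_forces[side] = (fa, fb)
            b_vec[nh:] -= Jp_e[e_point_id[f"spr_a:{side}"]].T @ fa
            b_vec[nh:] -= Jp_e[e_point_id[f"spr_b:{side}"]].T @ fb

    # ---- variables and equilibrium matrix
    prob = _FrameProblem()
    cols: list[np.ndarray] = []

    def col_for(vec_h=None, vec_e=None):
        col = np.zeros(ntot)
        if vec_h is not None:
            col[:nh] = vec_h
        if vec_e is not None:
            col[nh:] = vec_e
        cols.append(col)

    act_idx = {}
    for actn in body.actuators:
        i = prob.add(f"act:{actn.name}", actn.max_torque, True,
                     0.0, actn.max_torque)
        act_idx[actn.name] = i
        vec = np.zeros(nh)
        vec[body.tree.coord_index(actn.coord)] = actn.direction
        col_for(vec_h=vec)

    ground_info = []
    for gs in grounds:
        pos = _world(human_poses, gs.target_segment,
                     np.asarray(gs.target_offset))
        if pos[2] > gs.activation_height:
            continue
        nrm = np.array([0.0, 0.0, 1.0])
        t1 = np.array([1.0, 0.0, 0.0])
        t2 = np.array([0.0, 1.0, 0.0])
        J = Jp_h[h_point_id[f"gnd:{gs.name}"]]
        iN = prob.add(f"gndN:{gs.name}", gs.max_strength, True,
                      0.0, gs.max_strength)
        col_for(vec_h=J.T @ nrm)
        iT1 = prob.add(f"gndT1:{gs.name}", gs.max_strength, False,
                       -np.inf, np.inf)
        col_for(vec_h=J.T @ t1)
        iT2 = prob.add(f"gndT2:{gs.name}", gs.max_strength, False,
                       -np.inf, np.inf)
        col_for(vec_h=J.T @ t2)
        prob.cones.append((iN, iT1, iT2, gs.friction_mu))
        ground_info.append((gs, pos, nrm, t1, t2, iN, iT1, iT2))

    pce_info = []
    if ne:
        for spec, target_pos, nrm, t1, t2 in active_pce:
            Jh = Jp_h[h_point_id[f"pce:{spec.name}"]]
            Je = Jp_e[e_point_id[f"pce:{spec.name}"]]
            iN = prob.add(f"pceN:{spec.name}", spec.max_strength, True,
                          0.0, spec.max_strength)
            col_for(vec_h=Jh.T @ nrm, vec_e=-(Je.T @ nrm))
            iT1 = prob.add(f"pceT1:{spec.name}", spec.max_strength, False,
                           -np.inf, np.inf)
            col_for(vec_h=Jh.T @ t1, vec_e=-(Je.T @ t1))
            iT2 = prob.add(f"pceT2:{spec.name}", spec.max_strength, False,
                           -np.inf, np.inf)
            col_for(vec_h=Jh.T @ t2, vec_e=-(Je.T @ t2))
            prob.cones.append((iN, iT1, iT2, spec.friction_mu))
            pce_info.append((spec, target_pos, nrm, t1, t2, iN, iT1, iT2))

    torque_idx = {}
    if ne:
        for side in ("r", "l"):
            cidx = coupled.exo_tree.coord_index(coupled.torque_coord[side])
            if mode == "ideal_actuator":
                i = prob.add(f"exoM:{side}", 100.0, False, -np.inf, np.inf)
                vec = np.zeros(ne)
                vec[cidx] = 1.0
                col_for(vec_e=vec)
                torque_idx[side] = i
            else:  # prescribed torque: known applied generalized force
                angle = math.degrees(frame_ctx["exo_coords"][cidx])
                M = actuator_torque(coupled.variant.torque_joint, angle)
                b_vec[nh + cidx] -= M

    A = np.column_stack(cols)
    row_names = [f"human:{n}" for n in body.tree.coord_names]
    if ne:
        row_names += [f"exo:{n}" for n in coupled.exo_tree.coord_names]
    x, info = recruit_optimize(
        A, b_vec, np.array(prob.lower), np.array(prob.upper),
        np.array(prob.scale), np.array(prob.costed), prob.cones,
        power=scfg["recruitment_power"], facets=scfg["friction_facets"],
        reg=scfg["friction_regularization"], x0=warm,
        tol=scfg["equilibrium_tol"], row_names=row_names)

    # ---- unpack
    activities, torques = {}, {}
    for actn in body.actuators:
        tau = x[act_idx[actn.name]]
        activities[actn.name] = float(tau / actn.max_torque)
        torques[actn.name] = float(tau * actn.direction)

    contacts = []
    for gs, pos, nrm, t1, t2, iN, iT1, iT2 in ground_info:
        contacts.append({
            "name": gs.name, "interface": "ground", "side": "",
            "point": pos, "normal_dir": nrm,
            "N": float(x[iN]), "T1": float(x[iT1]), "T2": float(x[iT2]),
            "force": x[iN] * nrm + x[iT1] * t1 + x[iT2] * t2,
            "mu": gs.friction_mu, "cap": gs.max_strength,
            "segment": gs.target_segment,
        })
    for spec, pos, nrm, t1, t2, iN, iT1, iT2 in pce_info:
        contacts.append({
            "name": spec.name, "interface": spec.interface,
            "side": spec.side, "point": pos, "normal_dir": nrm,
            "N": float(x[iN]), "T1": float(x[iT1]), "T2": float(x[iT2]),
            "force": x[iN] * nrm + x[iT1] * t1 + x[iT2] * t2,
            "mu": spec.friction_mu, "cap": spec.max_strength,
            "segment": spec.target_segment,
        })

    tq, tq_ang = {}, {}
    if ne:
        for side in ("r", "l"):
            cidx = coupled.exo_tree.coord_index(coupled.torque_coord[side])
            ang = math.degrees(frame_ctx["exo_coords"][cidx])
            tq_ang[side] = ang
            if mode == "ideal_actuator":
                tq[side] = float(x[torque_idx[side]])
            else:
                tq[side] = float(actuator_torque(
                    coupled.variant.torque_joint, ang))

    reactions, compressions, spine_axis = _joint_reactions(
        body, human_poses, acc, gvec, contacts, box_mass, box_acc, torques)

    bracing_frames = {}
    if coupled is not None and mode != "no_exo":
        from .loads import BracingFrame
        for side in ("r", "l"):
            origin = body.point(f"mid_humerus_{side}", human_poses)
            R_h = human_poses[f"upper_arm_{side}"][1]
            bracing_frames[side] = BracingFrame.from_humerus(origin, R_h, side)

    return FrameSolution(
        index=frame_ctx.get("index", 0), time=frame_ctx.get("time", 0.0),
        coords=q, exo_coords=frame_ctx.get("exo_coords"),
        activities=activities, actuator_torques=torques, contacts=contacts,
        joint_reactions=reactions, joint_compressions=compressions,
        spine_axis=spine_axis, torque_joint=tq, torque_angle_deg=tq_ang,
        bracing_frames=bracing_frames,
        soft_residual=frame_ctx.get("soft_residual", {}),
        equilibrium_residual=info["residual"], objective=info["objective"])


def _world(poses, seg, off):
    p, R = poses[seg]
    return p + R @ np.asarray(off, float)


def _subtree_map(tree: KinematicTree) -> dict[str, list[str]]:
    children: dict[str, list[str]] = {}
    for j in tree.joints:
        if j.parent is not None:
            children.setdefault(j.parent, []).append(j.child)
    out = {}
    for j in tree.joints:
        stack, acc_ = [j.child], []
        while stack:
            s = stack.pop()
            acc_.append(s)
            stack.extend(children.get(s, []))
        out[j.name] = acc_
    return out


def _joint_reactions(body: BodyModel, poses, acc, gvec, contacts,
                     box_mass, box_acc, torques):
    """Inter-segmental joint forces plus muscle-compression contributions.

    The compression term sum(|tau|/moment arm) acts along the child
    segment's long axis, which is what makes joint loads multi-kN even
    though inter-segmental resultants alone are only a few hundred N.
    """
    subtrees = _subtree_map(body.tree)
    act_by_joint: dict[str, float] = {}
    for a in body.actuators:
        act_by_joint[a.joint] = (act_by_joint.get(a.joint, 0.0)
                                 + abs(torques[a.name]) / a.moment_arm)
    contact_by_seg: dict[str, np.ndarray] = {}
    for c in contacts:
        contact_by_seg[c["segment"]] = (
            contact_by_seg.get(c["segment"], np.zeros(3)) + c["force"])
    hand_force = 0.5 * box_mass * (gvec - box_acc)  # box weight on each hand

    reactions, compressions = {}, {}
    for joint in body.tree.joints:
        if joint.parent is None:
            continue
        F = np.zeros(3)
        for seg in subtrees[joint.name]:
            sp = body.segments[seg]
            F += sp.mass * (acc.get(seg, np.zeros(3)) - gvec)
            F -= contact_by_seg.get(seg, 0.0)
            if box_mass > 0 and seg.startswith("hand_"):
                F -= hand_force
        comp = act_by_joint.get(joint.name, 0.0)
        child_R = poses[joint.child][1]
        long_axis = child_R @ np.array([0.0, 0.0, 1.0])
        reactions[joint.name] = F + comp * long_axis
        compressions[joint.name] = comp
    spine_axis = poses["thorax"][1] @ np.array([0.0, 0.0, 1.0])
    return reactions, compressions, spine_axis


# -- sequence driver --------------------------------------------------------

def _finite_diff(arr: np.ndarray, dt: float, order: int) -> np.ndarray:
    """Central differences with one-sided endpoint copies."""
    n = len(arr)
    out = np.zeros_like(arr)
    if n < 3:
        return out
    if order == 1:
        out[1:-1] = (arr[2:] - arr[:-2]) / (2 * dt)
        out[0], out[-1] = out[1], out[-2]
    else:
        out[1:-1] = (arr[2:] - 2 * arr[1:-1] + arr[:-2]) / dt**2
        out[0], out[-1] = out[1], out[-2]
    return out


def run_sequence(model, traj: MotionTrajectory, mode: str = "no_exo",
                 config: dict | None = None,
                 frame_stride: int = 1) -> SequenceSolution:
    """Kinematics + recruitment for every frame of a trajectory.

    ``frame_stride`` sub-samples the trajectory (problem-size control
    for slow quasi-static motions); derivatives always use the full-rate
    neighbours, so sub-sampling does not distort accelerations.
    """
    if mode not in MODES:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    coupled = model if isinstance(model, CoupledModel) else None
    if coupled is None and mode != "no_exo":
        raise InvalidArgumentError(f"mode {mode!r} requires a CoupledModel")
    body = coupled.body if coupled else model
    cfg = config or (coupled.config if coupled else cfgmod.default_config())
    dt = 1.0 / traj.rate
    n = traj.n_frames

    # precompute all human poses and per-segment kinematic derivatives
    all_poses = [body.fk(traj.coords[i]) for i in range(n)]
    segs = list(body.segments)
    com_pos = {s: np.array([_world(all_poses[i], s,
                                   body.segments[s].com_offset)
                            for i in range(n)]) for s in segs}
    com_acc = {s: _finite_diff(com_pos[s], dt, 2) for s in segs}
    seg_R = {s: [all_poses[i][s][1] for i in range(n)] for s in segs}
    omega, alpha = {}, {}
    for s in segs:
        om = np.zeros((n, 3))
        for i in range(1, n - 1):
            W = (seg_R[s][i + 1] - seg_R[s][i - 1]) / (2 * dt) @ seg_R[s][i].T
            om[i] = 0.5 * np.array([W[2, 1] - W[1, 2], W[0, 2] - W[2, 0],
                                    W[1, 0] - W[0, 1]])
        if n >= 3:
            om[0], om[-1] = om[1], om[-2]
        omega[s] = om
        alpha[s] = _finite_diff(om, dt, 1)

    box_mass = traj.task.box_mass if traj.task else 0.0
    box_acc = _finite_diff(traj.box_pose[:, :3], dt, 2)

    grounds = ground_contacts(body)

    exo_coords_all = exo_soft_all = None
    exo_segs = None
    if coupled is not None and mode != "no_exo":
        exo_coords_all = np.zeros((n, coupled.exo_tree.ndof))
        exo_soft_all = []
        prev = None
        name_to_pos = {nme: i for i, nme in enumerate(coupled.joint_coords)}
        for i in range(n):
            try:
                qe, soft = solve_frame_kinematics(coupled, traj.coords[i],
                                                  previous=prev)
            except KinematicFailureError as err:
                raise KinematicFailureError(
                    f"frame {i}: {err}",
                    conflicting_drivers=err.conflicting_drivers) from err
            exo_coords_all[i] = qe
            exo_soft_all.append(soft)
            prev = {side: np.array([qe[coupled.exo_tree.coord_index(nm)]
                                    for nm in coupled.side_dof[side]])
                    for side in ("r", "l")}
        exo_segs = list(coupled.exo_segments)
        exo_poses_all = [coupled.exo_tree.fk(exo_coords_all[i])
                         for i in range(n)]
        exo_com_pos = {s: np.array([
            _world(exo_poses_all[i], s, coupled.exo_segments[s].com_offset)
            for i in range(n)]) for s in exo_segs}
        exo_com_acc = {s: _finite_diff(exo_com_pos[s], dt, 2)
                       for s in exo_segs}

    frames: list[FrameSolution] = []
    warm = None
    indices = list(range(0, n, frame_stride))
    for i in indices:
        ctx = {
            "index": i, "time": float(traj.times[i]),
            "coords": traj.coords[i], "human_poses": all_poses[i],
            "com_acc": {s: com_acc[s][i] for s in segs},
            "omega": {s: omega[s][i] for s in segs},
            "alpha": {s: alpha[s][i] for s in segs},
            "box_mass": box_mass, "box_acc": box_acc[i],
            "ground_specs": grounds,
        }
        if exo_coords_all is not None:
            ctx.update({
                "exo_coords": exo_coords_all[i],
                "exo_poses": exo_poses_all[i],
                "exo_com_acc": {s: exo_com_acc[s][i] for s in exo_segs},
                "soft_residual": exo_soft_all[i],
            })
        try:
            sol = solve_recruitment(model, ctx, mode=mode, config=cfg,
                                    warm=warm)
        except RecruitmentInfeasibleError as err:
            raise RecruitmentInfeasibleError(f"frame {i}: {err}") from err
        frames.append(sol)
    times = np.array([f.time for f in frames])
    return SequenceSolution(frames=frames, mode=mode, times=times)


# -- ideal target torque and its quadratic approximation --------------------

def ideal_target_torque(solution: SequenceSolution
                        ) -> dict[str, np.ndarray]:
    """(angle deg, torque Nm) samples per side from an ideal-actuator run."""
    if solution.mode != "ideal_actuator":
        raise InvalidArgumentError(
            "ideal_target_torque requires an ideal_actuator solution")
    out = {}
    for side in ("r", "l"):
        pairs = np.array([[f.torque_angle_deg[side], f.torque_joint[side]]
                          for f in solution.frames])
        out[side] = pairs
    return out


def fit_degree2(samples: np.ndarray) -> TorqueJointSpec:
    """Ordinary least-squares quadratic torque curve from (angle, torque).

    The fit reports the sampled curvature as-is; concavity is only
    identifiable when the samples span the curve's peak.
    """
    samples = np.asarray(samples, dtype=float)
    ang, tau = samples[:, 0], samples[:, 1]
    if len(np.unique(ang)) < 3:
        raise RankDeficiencyError(
            "need at least 3 distinct angles for a quadratic fit")
    V = np.column_stack([np.ones_like(ang), ang, ang**2])
    coef, *_ = np.linalg.lstsq(V, tau, rcond=None)
    resid = float(np.sqrt(np.mean((V @ coef - tau) ** 2)))
    return TorqueJointSpec(c0=float(coef[0]), c1=float(coef[1]),
                           c2=float(coef[2]), residual=resid)
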