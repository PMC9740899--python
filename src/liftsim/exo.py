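"""Exoskeleton concept space: joints, variants, screening, attachment.

The concept is a rigid hip-belt/back-plate base carrying, per side, a
lateral load-bearing structure up to a torque-generating joint near the
shoulder, from which a two-part structure leads through a middle
connection to an upper-arm bracing.  Three locations vary per side:

* hip connection  -- revolute (craniocaudal), universal (cc-ap or
  cc-lm) or spherical;
* middle connection -- fixed or prismatic (distoproximal translation);
* arm connection -- fixed, revolute (lateromedial or craniocaudal) or
  universal (lm-cc).

4 x 2 x 4 = 32 combinations.  The kinematic feasibility screen encodes
the two structural requirements found for this concept family: the
middle connection must be prismatic (the torque-joint-to-bracing
distance changes during shoulder flexion) and the arm connection needs
at least one rotational DOF (a rigid bracing cannot follow the humerus
orientation).  Exactly 12 variants survive.

The torque-generating joint applies a support torque given by a concave
degree-2 polynomial of its elevation angle; two soft springs (10 N/m)
pull the torque joints toward the back plate.  All exo joints are
ideal: frictionless, unbounded range, zero physical size.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import config as cfgmod
from .body import BodyModel, Dof, JointDef, KinematicTree, SegmentParam
from .contacts import ContactElementSpec
from .errors import InvalidArgumentError

ANATOMICAL_AXES = {
    "craniocaudal": (0.0, 0.0, 1.0),
    "anteroposterior": (1.0, 0.0, 0.0),
    "lateromedial": (0.0, 1.0, 0.0),
    "distoproximal": None,              # along the structure, set at attach
}

_KIND_AXIS_COUNT = {"fixed": 0, "revolute": 1, "prismatic": 1,
                    "universal": 2, "spherical": 3}


@dataclass(frozen=True)
class ExoJointSpec:
    location: str                       # hip_connection / middle_connection / arm_connection
    kind: str                           # fixed/revolute/prismatic/universal/spherical
    axes: tuple[str, ...] = ()

    def __post_init__(self):
        expected = _KIND_AXIS_COUNT[self.kind]
        if len(self.axes) != expected:
            raise InvalidArgumentError(
                f"{self.kind} joint needs {expected} axes, got {self.axes}")
        if self.kind == "universal" and self.axes[0] == self.axes[1]:
            raise InvalidArgumentError("universal joint axes must differ")

    @property
    def rotational_dof(self) -> int:
        return 0 if self.kind in ("fixed", "prismatic") else len(self.axes)

    @property
    def acronym(self) -> str:
        tags = {"craniocaudal": "cc", "anteroposterior": "ap",
                "lateromedial": "lm", "distoproximal": "dp"}
        kind_tag = {"revolute": "R", "universal": "U", "spherical": "S",
                    "prismatic": "P", "fixed": "F"}[self.kind]
        if self.kind in ("fixed",):
            return "F"
        if self.kind == "spherical":
            return "S"
        return f"{kind_tag}.{'-'.join(tags[a] for a in self.axes)}"


HIP_JOINTS = (
    ExoJointSpec("hip_connection", "revolute", ("craniocaudal",)),
    ExoJointSpec("hip_connection", "universal",
                 ("craniocaudal", "anteroposterior")),
    ExoJointSpec("hip_connection", "universal",
                 ("craniocaudal", "lateromedial")),
    ExoJointSpec("hip_connection", "spherical",
                 ("craniocaudal", "anteroposterior", "lateromedial")),
)
MIDDLE_JOINTS = (
    ExoJointSpec("middle_connection", "fixed"),
    ExoJointSpec("middle_connection", "prismatic", ("distoproximal",)),
)
ARM_JOINTS = (
    ExoJointSpec("arm_connection", "fixed"),
    ExoJointSpec("arm_connection", "revolute", ("lateromedial",)),
    ExoJointSpec("arm_connection", "revolute", ("craniocaudal",)),
    ExoJointSpec("arm_connection", "universal",
                 ("lateromedial", "craniocaudal")),
)


@dataclass(frozen=True)
class TorqueJointSpec:
    """Support torque polynomial tau(x) = c0 + c1 x + c2 x^2, x in degrees.

    The device's support curve is concave (c2 < 0); a spec produced by
    :func:`liftsim.sim.fit_degree2` reports whatever curvature the
    samples carry, so concavity is enforced where a curve is installed
    on a concept variant, not here.
    """

    c0: float = 27.6381                 # Nm
    c1: float = 0.5570                  # Nm / deg
    c2: float = -0.0036                 # Nm / deg^2
    residual: float = 0.0               # rms residual of the fit, Nm

    @property
    def is_concave(self) -> bool:
        return self.c2 < 0

    def __call__(self, angle_deg):
        return actuator_torque(self, angle_deg)


@dataclass(frozen=True)
class SpringSpec:
    stiffness: float = 10.0             # N/m, attractive


@dataclass(frozen=True)
class ExoVariant:
    hip: ExoJointSpec
    middle: ExoJointSpec
    arm: ExoJointSpec
    structure_mass: float = 5.1         # kg
    torque_joint: TorqueJointSpec = field(default_factory=TorqueJointSpec)
    spring: SpringSpec = field(default_factory=SpringSpec)

    def __post_init__(self):
        if not self.torque_joint.is_concave:
            raise InvalidArgumentError(
                "a concept's support-torque curve must be concave (c2 < 0)")

    @property
    def id(self) -> str:
        hip, arm = self.hip.acronym, self.arm.acronym
        if self.middle.kind == "prismatic":
            return f"H: {hip}–A: {arm}"
        return f"H: {hip}–M: F–A: {arm}"


def enumerate_variants(structure_mass: float = 5.1) -> list[ExoVariant]:
    """All 32 joint-configuration combinations, deterministic order."""
    variants = [
        ExoVariant(hip=h, middle=m, arm=a, structure_mass=structure_mass)
        for h, m, a in itertools.product(HIP_JOINTS, MIDDLE_JOINTS, ARM_JOINTS)
    ]
    ids = [v.id for v in variants]
    assert len(set(ids)) == len(ids)
    return variants


def variant_by_id(vid: str) -> ExoVariant:
    for v in enumerate_variants():
        if v.id == vid:
            return v
    raise InvalidArgumentError(f"unknown variant id {vid!r}")


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reason: str = ""

    def __bool__(self):
        return self.passed


def feasibility_screen(variant: ExoVariant) -> ScreenResult:
    """Kinematic feasibility rules for the concept family.

    The middle connection must provide the distoproximal translation
    (prismatic joint) and the arm connection at least one rotational
    DOF; otherwise the coupled human-exoskeleton chain is kinematically
    overconstrained for the lifting motion.
    """
    if variant.middle.kind != "prismatic":
        return ScreenResult(False, "no_prismatic")
    if variant.arm.rotational_dof == 0:
        return ScreenResult(False, "arm_fixed")
    return ScreenResult(True)


def actuator_torque(spec: TorqueJointSpec, angle_deg) -> float:
    """Support torque (Nm) of the torque-generating joint at an angle (deg)."""
    angle = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise InvalidArgumentError("torque-joint angle must be finite")
    out = spec.c0 + spec.c1 * angle + spec.c2 * angle**2
    return float(out) if out.ndim == 0 else out


def spring_force(spec: SpringSpec, p_a: np.ndarray, p_b: np.ndarray):
    """Attractive linear spring: forces on the bodies at p_a and p_b.

    Magnitude = stiffness x distance; equal and opposite; zero when the
    endpoints coincide (no defined direction).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    d = p_b - p_a
    dist = np.linalg.norm(d)
    if dist < 1e-12:
        z = np.zeros(3)
        return z, z.copy()
    f_on_a = spec.stiffness * d          # pulls a toward b
    return f_on_a, -f_on_a


# -- coupling ---------------------------------------------------------------

class CoupledModel:
    """Human body plus one exoskeleton variant.

    The exo is a second kinematic tree whose base (hip belt + back
    plate) is kinematically slaved to the pelvis; its joint coordinates
    are solved per frame against hard translational and soft rotational
    drivers at the arm bracings.  Kinetic coupling is exclusively
    through the contact elements and springs.
    """

    def __init__(self, body: BodyModel, variant: ExoVariant,
                 config: dict | None = None, override: bool = False):
        screen = feasibility_screen(variant)
        if not screen and not override:
            raise InvalidArgumentError(
                f"variant {variant.id!r} fails the feasibility screen "
                f"({screen.reason}); pass override=True to attempt it")
        self.body = body
        self.variant = variant
        self.config = config or cfgmod.default_config()
        self.overconstrained = not screen.passed
        self.screen_reason = screen.reason
        self._build()

    def _build(self):
        cfg = self.config["exo"]
        body = self.body
        L = {k: v * body.anthro.stature for k, v in
             cfgmod.LENGTH_FRACTIONS.items()}
        hip_lat = L["hip_half_width"] + cfg["hip_joint_clearance"]
        sh_lat = L["shoulder_half_width"]
        tj_lat = sh_lat + cfg["torque_joint_clearance"]
        z_sh = L["pelvis"] + L["thorax"]         # shoulder height above pelvis
        z_tq = z_sh + cfg["torque_joint_height_offset"]
        z_brace = z_sh - cfg["bracing_humerus_fraction"] * L["upper_arm"]

        joints: list[JointDef] = [JointDef("exo_base", None, "exo_base",
                                           np.zeros(3), [
            Dof("exo_base_tx", "trans", (1, 0, 0)),
            Dof("exo_base_ty", "trans", (0, 1, 0)),
            Dof("exo_base_tz", "trans", (0, 0, 1)),
            Dof("exo_base_rx", "rot", (1, 0, 0)),
            Dof("exo_base_ry", "rot", (0, 1, 0)),
            Dof("exo_base_rz", "rot", (0, 0, 1)),
        ])]
        self.side_dof: dict[str, list[str]] = {}
        self.torque_coord: dict[str, str] = {}
        self.prismatic_coord: dict[str, str] = {}
        seg_params: dict[str, SegmentParam] = {}
        m_total = self.variant.structure_mass
        split = cfg["mass_split"]
        m_base = split["base"] * m_total
        m_side = split["side"] * m_total
        seg_params["exo_base"] = SegmentParam(
            "exo_base", m_base, 0.4, np.array([-0.05, 0.0, 0.25]),
            np.array([0.05, 0.05, 0.05]) * m_base)

        for side, sgn in (("r", -1.0), ("l", +1.0)):
            names: list[str] = []

            def mk_dofs(spec: ExoJointSpec, prefix: str, u_axis=None):
                dofs = []
                for k, axname in enumerate(spec.axes):
                    axis = (tuple(u_axis) if axname == "distoproximal"
                            else ANATOMICAL_AXES[axname])
                    kind = "trans" if spec.kind == "prismatic" else "rot"
                    dof = Dof(f"{prefix}_{k}", kind, axis)
                    dofs.append(dof)
                    names.append(dof.name)
                return dofs

            # hip connection: base -> lateral load-bearing structure;
            # the belt joint sits posterolateral so its vertical axis keeps
            # lateral authority over the arm structure at every pose
            post = cfg["hip_joint_posterior_offset"]
            hip_off = np.array([-post, sgn * hip_lat, 0.0])
            joints.append(JointDef(
                f"exo_hip_{side}", "exo_base", f"exo_upper_{side}", hip_off,
                mk_dofs(self.variant.hip, f"exo_hip_{side}")))
            # torque-generating joint just above the shoulder (lm axis)
            tj_off = np.array([post, sgn * (tj_lat - hip_lat), z_tq])
            tq_dof = Dof(f"exo_torque_{side}", "rot", (0.0, -1.0, 0.0))
            names.append(tq_dof.name)
            joints.append(JointDef(
                f"exo_torque_{side}", f"exo_upper_{side}", f"exo_varm_{side}",
                tj_off, [tq_dof]))
            self.torque_coord[side] = tq_dof.name
            # middle connection along the distoproximal structure axis;
            # the chain attaches at the lateral face of the arm bracing
            bc = cfg["bracing_lateral_clearance"]
            v_ref = np.array([0.0, sgn * (sh_lat + bc - tj_lat),
                              z_brace - z_tq])
            v_len = np.linalg.norm(v_ref)
            u = v_ref / v_len
            mid_dofs = mk_dofs(self.variant.middle, f"exo_mid_{side}", u)
            self.v_len = v_len
            if self.variant.middle.kind == "prismatic":
                self.prismatic_coord[side] = mid_dofs[0].name
            joints.append(JointDef(
                f"exo_mid_{side}", f"exo_varm_{side}", f"exo_darm_{side}",
                v_ref, mid_dofs))
            # arm connection at the bracing centre
            joints.append(JointDef(
                f"exo_arm_{side}", f"exo_darm_{side}", f"exo_bracing_{side}",
                np.zeros(3), mk_dofs(self.variant.arm, f"exo_arm_{side}")))
            self.side_dof[side] = names

            upper_len = float(np.linalg.norm(tj_off))
            seg_params[f"exo_upper_{side}"] = SegmentParam(
                f"exo_upper_{side}", 0.5 * m_side, upper_len,
                0.5 * tj_off, np.array([0.02, 0.02, 0.002]) * m_side)
            seg_params[f"exo_varm_{side}"] = SegmentParam(
                f"exo_varm_{side}", 0.2 * m_side, v_len, 0.5 * v_ref,
                np.array([0.005, 0.005, 0.001]) * m_side)
            seg_params[f"exo_darm_{side}"] = SegmentParam(
                f"exo_darm_{side}", 0.15 * m_side, 0.05, np.zeros(3),
                np.array([0.002, 0.002, 0.001]) * m_side)
            seg_params[f"exo_bracing_{side}"] = SegmentParam(
                f"exo_bracing_{side}", 0.15 * m_side, 0.1, np.zeros(3),
                np.array([0.002, 0.002, 0.002]) * m_side)

        self.exo_tree = KinematicTree(joints)
        self.exo_segments = seg_params
        self.base_dof_names = [f"exo_base_{s}" for s in
                               ("tx", "ty", "tz", "rx", "ry", "rz")]
        self.joint_coords = [n for n in self.exo_tree.coord_names
                             if not n.startswith("exo_base_")]
        # spring endpoints: back plate point (base) <-> torque joint (varm)
        self.spring_points = {
            side: (("exo_base", np.array([-0.05, sgn * 0.10, z_sh])),
                   (f"exo_varm_{side}", np.zeros(3)))
            for side, sgn in (("r", -1.0), ("l", +1.0))}
        self._build_pce(z_brace)

    def _build_pce(self, z_brace: float):
        cfg = self.config["pce"]
        body = self.body
        L_ua = body.segments["upper_arm_r"].length
        frac = self.config["exo"]["bracing_humerus_fraction"]
        bc = self.config["exo"]["bracing_lateral_clearance"]
        r_arm = cfg["arm_radius"]
        elements: list[ContactElementSpec] = []
        n_arm = cfg["arm_count"]
        for side, sgn in (("r", -1.0), ("l", +1.0)):
            # two rings around the humerus so normal forces can transmit
            # transverse torques; friction carries axial force/torque
            for k in range(n_arm):
                phi = 2 * math.pi * k / n_arm
                ring = -1.0 if k % 2 == 0 else 1.0
                z_off = -frac * L_ua + ring * 0.06
                target = (r_arm * math.cos(phi), r_arm * math.sin(phi), z_off)
                elements.append(ContactElementSpec(
                    name=f"arm_{side}_{k}",
                    target_segment=f"upper_arm_{side}",
                    target_offset=target,
                    zone_segment=f"exo_bracing_{side}",
                    zone_center=(0.0, -sgn * bc, 0.0),
                    zone_axis=(0.0, 0.0, 1.0),
                    zone_radius=r_arm + 0.05,
                    zone_half_length=cfg["zone_half_length"] + 0.06,
                    max_strength=cfg["max_strength"],
                    friction_mu=cfg["friction_mu"],
                    normal_mode="radial", side=side, interface="arm"))
        n_hip = cfg["hip_count"]
        r_hip = cfg["hip_radius"]
        for k in range(n_hip):
            phi = 2 * math.pi * k / n_hip
            target = (r_hip * math.cos(phi), r_hip * math.sin(phi), 0.03)
            elements.append(ContactElementSpec(
                name=f"hip_{k}", target_segment="pelvis",
                target_offset=target,
                zone_segment="exo_base", zone_center=(0.0, 0.0, 0.03),
                zone_axis=(0.0, 0.0, 1.0), zone_radius=r_hip + 0.05,
                zone_half_length=0.15,
                max_strength=cfg["max_strength"],
                friction_mu=cfg["friction_mu"],
                normal_mode="radial", interface="hip"))
        # back plate: pushes the thorax forward; its straps pull it
        # backward -- together they transmit the support-torque reaction
        # couple into the trunk (plate/strap pair, both unilateral)
        z_back = 0.75 * body.segments["thorax"].length
        for name, axis in (("back_0", (1.0, 0.0, 0.0)),
                           ("back_strap", (-1.0, 0.0, 0.0))):
            elements.append(ContactElementSpec(
                name=name, target_segment="thorax",
                target_offset=(-0.10, 0.0, z_back),
                zone_segment="exo_base",
                zone_center=(-0.10, 0.0,
                             body.segments["pelvis"].length + z_back),
                zone_axis=(1.0, 0.0, 0.0), zone_radius=0.15,
                zone_half_length=0.10,
                max_strength=cfg["max_strength"],
                friction_mu=cfg["friction_mu"],
                normal_mode="fixed", normal_axis=axis,
                interface="back"))
        self.pce = elements

    # -- bookkeeping ---------------------------------------------------
    @property
    def exo_joint_dof_per_side(self) -> int:
        return len(self.side_dof["r"])

    @property
    def exo_mass(self) -> float:
        return sum(s.mass for s in self.exo_segments.values())

    def base_pose_from_pelvis(self, human_poses):
        """The exo base is kinematically slaved to the pelvis frame."""
        return human_poses["pelvis"]

    def exo_coords_from(self, base_pose, joint_values: np.ndarray
                        ) -> np.ndarray:
        """Full exo coordinate vector from base pose + joint coordinates."""
        p, R = base_pose
        q = np.zeros(self.exo_tree.ndof)
        # angles for R = Rx(rx) @ Ry(ry) @ Rz(rz), the tree's root order
        sy = max(-1.0, min(1.0, R[0, 2]))
        cy = math.sqrt(max(1.0 - sy * sy, 0.0))
        if cy > 1e-9:
            ry = math.asin(sy)
            rz = math.atan2(-R[0, 1], R[0, 0])
            rx = math.atan2(-R[1, 2], R[2, 2])
        else:                            # gimbal fallback, not hit in practice
            ry = math.copysign(math.pi / 2, sy)
            rz = 0.0
            rx = math.atan2(R[2, 1], R[1, 1])
        vals = [p[0], p[1], p[2], rx, ry, rz]
        for name, v in zip(self.base_dof_names, vals):
            q[self.exo_tree.coord_index(name)] = v
        for name, v in zip(self.joint_coords, joint_values):
            q[self.exo_tree.coord_index(name)] = v
        return q

    def detach(self) -> BodyModel:
        """The human model is never mutated; return it unchanged."""
        return self.body


def attach_exo(body: BodyModel, variant: ExoVariant,
               config: dict | None = None,
               override: bool = False) -> CoupledModel:
    """Couple an exoskeleton variant to the human model."""
    return CoupledModel(body, variant, config=config, override=override)
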