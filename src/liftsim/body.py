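"""Simplified 3D rigid-body human model.

The model is a kinematic tree rooted at the pelvis: 15 segments, 31
generalized coordinates (6-DOF floating root, 3-DOF lumbar L4/L5, 2-DOF
neck and, per side, 3-DOF hip, 1-DOF knee and ankle, 3-DOF glenohumeral,
1-DOF elbow and wrist).  Segment masses are fixed fractions of body mass
and lengths fixed fractions of stature from a standard adult regression
table; inertia uses a slender-rod approximation.

Muscles are abstracted as grouped, torque-equivalent actuators: each
joint DOF carries at least one agonist and one antagonist with a maximum
torque, and an actuator's activity is its delivered torque divided by
that maximum.  An effective moment arm per joint maps recruited torque
to a compressive joint-force contribution, which is what makes joint
loads muscle-tension dominated (multi-kN) rather than purely
inter-segmental.

Axis conventions: +X anterior, +Z up, +Y toward the left; the right
side lies at negative Y.  Laterally acting DOF axes are mirrored between
sides so that identical left/right coordinate values produce a
bilaterally symmetric posture.  Angles are radians, lengths metres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as cfgmod
from .errors import ConfigurationError, InvalidArgumentError

SIDES = ("r", "l")


@dataclass(frozen=True)
class Anthropometry:
    """Subject stature (m) and body mass (kg)."""

    stature: float = 1.76
    body_mass: float = 70.4

    def __post_init__(self):
        if not (1.4 <= self.stature <= 2.2):
            raise InvalidArgumentError(f"stature {self.stature} m outside [1.4, 2.2]")
        if not (40.0 <= self.body_mass <= 150.0):
            raise InvalidArgumentError(
                f"body mass {self.body_mass} kg outside [40, 150]"
            )


@dataclass
class SegmentParam:
    name: str
    mass: float
    length: float
    com_offset: np.ndarray          # local frame, from segment origin
    inertia: np.ndarray             # principal, about the COM, local frame

    def __post_init__(self):
        if self.mass < 0:
            raise InvalidArgumentError(f"segment {self.name}: negative mass")
        if np.any(np.asarray(self.inertia) < 0):
            raise InvalidArgumentError(f"segment {self.name}: negative inertia")


@dataclass(frozen=True)
class Dof:
    name: str                       # full coordinate name, e.g. "gh_r_flexion"
    kind: str                       # "rot" or "trans"
    axis: tuple[float, float, float]


@dataclass
class JointDef:
    name: str
    parent: str | None              # parent segment, None = world
    child: str
    offset: np.ndarray              # joint centre in the parent frame
    dofs: list[Dof] = field(default_factory=list)


@dataclass(frozen=True)
class ActuatorDef:
    name: str
    joint: str
    coord: str                      # generalized coordinate acted on
    direction: int                  # +1 or -1 along the DOF axis
    max_torque: float
    moment_arm: float
    group: str

    def __post_init__(self):
        if self.max_torque <= 0:
            raise InvalidArgumentError(f"{self.name}: max torque must be > 0")
        if self.moment_arm <= 0:
            raise InvalidArgumentError(f"{self.name}: moment arm must be > 0")


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


class KinematicTree:
    """Generic rigid-body tree with mixed rotational/translational DOF."""

    def __init__(self, joints: list[JointDef]):
        self.joints = joints
        self.coord_names: list[str] = []
        self._slices: list[tuple[JointDef, int]] = []
        for joint in joints:
            self._slices.append((joint, len(self.coord_names)))
            self.coord_names.extend(dof.name for dof in joint.dofs)
        self.ndof = len(self.coord_names)
        self.segment_names = [j.child for j in joints]
        self._index = {n: i for i, n in enumerate(self.coord_names)}

    def coord_index(self, name: str) -> int:
        return self._index[name]

    def fk(self, coords: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Pose (origin position, rotation matrix) of every segment frame."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.ndof,):
            raise InvalidArgumentError(
                f"coordinate vector length {coords.shape} != ({self.ndof},)"
            )
        poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for joint, start in self._slices:
            if joint.parent is None:
                p, R = np.zeros(3), np.eye(3)
            else:
                p, R = poses[joint.parent]
            p = p + R @ joint.offset
            for k, dof in enumerate(joint.dofs):
                q = coords[start + k]
                axis = np.asarray(dof.axis)
                if dof.kind == "trans":
                    p = p + R @ (axis * q)
                else:
                    R = R @ _rot(axis, q)
            poses[joint.child] = (p, R)
        return poses


class BodyModel:
    """Segments, joints, grouped redundant actuators and landmarks."""

    def __init__(
        self,
        anthro: Anthropometry,
        tree: KinematicTree,
        segments: dict[str, SegmentParam],
        actuators: list[ActuatorDef],
        landmarks: dict[str, tuple[str, np.ndarray]],
    ):
        self.anthro = anthro
        self.tree = tree
        self.segments = segments
        self.actuators = actuators
        self.landmarks = landmarks
        self.total_mass = anthro.body_mass
        mass_sum = sum(s.mass for s in segments.values())
        if abs(mass_sum - self.total_mass) > 1e-9:
            raise ConfigurationError(
                f"segment masses sum to {mass_sum} kg != body mass {self.total_mass}"
            )
        self.groups = {g: [a for a in actuators if a.group == g]
                       for g in cfgmod.MUSCLE_GROUPS}

    # -- kinematics ----------------------------------------------------
    @property
    def ndof(self) -> int:
        return self.tree.ndof

    @property
    def coord_names(self) -> list[str]:
        return self.tree.coord_names

    def zero_coords(self) -> np.ndarray:
        return np.zeros(self.ndof)

    def fk(self, coords: np.ndarray):
        return self.tree.fk(coords)

    def point(self, name: str, poses) -> np.ndarray:
        seg, local = self.landmarks[name]
        p, R = poses[seg]
        return p + R @ local

    @property
    def standing_hand_height(self) -> float:
        poses = self.fk(self.zero_coords())
        return float(self.point("hand_grip_r", poses)[2])

    @property
    def standing_shoulder_height(self) -> float:
        poses = self.fk(self.zero_coords())
        p, R = poses["upper_arm_r"]
        return float(p[2])

    @property
    def arm_length(self) -> float:
        s = self.segments
        return (s["upper_arm_r"].length + s["forearm_r"].length
                + s["hand_r"].length)


def group_members(model: BodyModel, group: str) -> list[ActuatorDef]:
    """All actuators (both sides) carrying the group label."""
    if group not in model.groups:
        raise InvalidArgumentError(
            f"unknown muscle group {group!r}; valid: {sorted(model.groups)}"
        )
    return list(model.groups[group])


# ---------------------------------------------------------------------------

def _dof(joint: str, dofname: str, axis) -> Dof:
    return Dof(f"{joint}_{dofname}", "rot", tuple(float(a) for a in axis))


def build_body(anthro: Anthropometry, config: dict | None = None) -> BodyModel:
    """Anthropometrically scaled body model from the fraction tables."""
    cfg = config or cfgmod.default_config()
    H = anthro.stature
    M = anthro.body_mass
    mf, lf, cf = cfgmod.MASS_FRACTIONS, cfgmod.LENGTH_FRACTIONS, cfgmod.COM_FRACTIONS

    mass_sum = sum(mf[n] * (2 if n in cfgmod._BILATERAL else 1) for n in mf)
    if abs(mass_sum - 1.0) > 1e-6:
        raise ConfigurationError(f"mass fractions sum to {mass_sum}, expected 1")

    L = {k: v * H for k, v in lf.items()}
    hip_height = L["ankle_height"] + L["shank"] + L["thigh"]

    joints: list[JointDef] = [
        JointDef("root", None, "pelvis", np.array([0.0, 0.0, hip_height]), [
            Dof("root_tx", "trans", (1, 0, 0)),
            Dof("root_ty", "trans", (0, 1, 0)),
            Dof("root_tz", "trans", (0, 0, 1)),
            Dof("root_rx", "rot", (1, 0, 0)),
            Dof("root_ry", "rot", (0, 1, 0)),
            Dof("root_rz", "rot", (0, 0, 1)),
        ]),
        # for upward-pointing segments the forward-flexion axis is +y
        JointDef("lumbar", "pelvis", "thorax", np.array([0.0, 0.0, L["pelvis"]]), [
            _dof("lumbar", "flexion", (0, 1, 0)),
            _dof("lumbar", "lateral", (1, 0, 0)),
            _dof("lumbar", "axial", (0, 0, 1)),
        ]),
        JointDef("neck", "thorax", "head", np.array([0.0, 0.0, L["thorax"]]), [
            _dof("neck", "flexion", (0, 1, 0)),
            _dof("neck", "lateral", (1, 0, 0)),
        ]),
    ]
    for side in SIDES:
        sgn = -1.0 if side == "r" else +1.0
        joints += [
            JointDef(f"hip_{side}", "pelvis", f"thigh_{side}",
                     np.array([0.0, sgn * L["hip_half_width"], 0.0]), [
                _dof(f"hip_{side}", "flexion", (0, -1, 0)),
                _dof(f"hip_{side}", "abduction", (sgn, 0, 0)),
                _dof(f"hip_{side}", "rotation", (0, 0, -sgn)),
            ]),
            JointDef(f"knee_{side}", f"thigh_{side}", f"shank_{side}",
                     np.array([0.0, 0.0, -L["thigh"]]), [
                _dof(f"knee_{side}", "flexion", (0, 1, 0)),
            ]),
            JointDef(f"ankle_{side}", f"shank_{side}", f"foot_{side}",
                     np.array([0.0, 0.0, -L["shank"]]), [
                _dof(f"ankle_{side}", "flexion", (0, -1, 0)),
            ]),
            JointDef(f"gh_{side}", "thorax", f"upper_arm_{side}",
                     np.array([0.0, sgn * L["shoulder_half_width"], L["thorax"]]), [
                _dof(f"gh_{side}", "flexion", (0, -1, 0)),
                _dof(f"gh_{side}", "abduction", (sgn, 0, 0)),
                _dof(f"gh_{side}", "rotation", (0, 0, -sgn)),
            ]),
            JointDef(f"elbow_{side}", f"upper_arm_{side}", f"forearm_{side}",
                     np.array([0.0, 0.0, -L["upper_arm"]]), [
                _dof(f"elbow_{side}", "flexion", (0, -1, 0)),
            ]),
            JointDef(f"wrist_{side}", f"forearm_{side}", f"hand_{side}",
                     np.array([0.0, 0.0, -L["forearm"]]), [
                _dof(f"wrist_{side}", "flexion", (0, -1, 0)),
            ]),
        ]

    tree = KinematicTree(joints)

    def rod_inertia(mass: float, length: float, long_axis: int) -> np.ndarray:
        it = mass * length * length / 12.0
        inertia = np.array([it, it, it])
        inertia[long_axis] = 1e-4 * it if it > 0 else 0.0
        return inertia

    def seg(name: str, key: str, com_dir: np.ndarray, long_axis: int = 2
            ) -> SegmentParam:
        mass, length = mf[key] * M, L[key]
        return SegmentParam(name, mass, length,
                            com_dir * cf[key] * length,
                            rod_inertia(mass, length, long_axis))

    up, down = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])
    segments = {
        "pelvis": seg("pelvis", "pelvis", up),
        "thorax": seg("thorax", "thorax", up),
        "head": seg("head", "head", up),
    }
    for side in SIDES:
        segments[f"thigh_{side}"] = seg(f"thigh_{side}", "thigh", down)
        segments[f"shank_{side}"] = seg(f"shank_{side}", "shank", down)
        foot = SegmentParam(
            f"foot_{side}", mf["foot"] * M, L["foot"],
            np.array([0.25 * L["foot"], 0.0, -0.5 * L["ankle_height"]]),
            rod_inertia(mf["foot"] * M, L["foot"], 0))
        segments[f"foot_{side}"] = foot
        segments[f"upper_arm_{side}"] = seg(f"upper_arm_{side}", "upper_arm", down)
        segments[f"forearm_{side}"] = seg(f"forearm_{side}", "forearm", down)
        segments[f"hand_{side}"] = seg(f"hand_{side}", "hand", down)

    landmarks: dict[str, tuple[str, np.ndarray]] = {}
    for side in SIDES:
        landmarks[f"hand_grip_{side}"] = (f"hand_{side}",
                                          np.array([0.0, 0.0, -L["hand"]]))
        landmarks[f"heel_{side}"] = (
            f"foot_{side}", np.array([-0.25 * L["foot"], 0.0, -L["ankle_height"]]))
        landmarks[f"toe_{side}"] = (
            f"foot_{side}", np.array([0.75 * L["foot"], 0.0, -L["ankle_height"]]))
        landmarks[f"foot_mid_{side}"] = (
            f"foot_{side}", np.array([0.25 * L["foot"], 0.0, -L["ankle_height"]]))
        z_brace = -cfg["exo"]["bracing_humerus_fraction"] * L["upper_arm"]
        landmarks[f"mid_humerus_{side}"] = (
            f"upper_arm_{side}", np.array([0.0, 0.0, z_brace]))
        sgn_side = -1.0 if side == "r" else 1.0
        landmarks[f"bracing_attach_{side}"] = (
            f"upper_arm_{side}",
            np.array([0.0, sgn_side * cfg["exo"]["bracing_lateral_clearance"],
                      z_brace]))
        landmarks[f"shoulder_{side}"] = (f"upper_arm_{side}", np.zeros(3))
    landmarks["pelvis_origin"] = ("pelvis", np.zeros(3))
    landmarks["lumbar_origin"] = ("thorax", np.zeros(3))
    landmarks["thorax_top"] = ("thorax", np.array([0.0, 0.0, L["thorax"]]))

    actuators: list[ActuatorDef] = []
    for jbase, dofname, direction, tmax, count, group in cfgmod.ACTUATOR_TABLE:
        sides = SIDES if jbase in ("hip", "knee", "ankle", "gh", "elbow", "wrist") \
            else (None,)
        for side in sides:
            jname = jbase if side is None else f"{jbase}_{side}"
            coord = f"{jname}_{dofname}"
            for k in range(count):
                suffix = "" if count == 1 else f"_{k + 1}"
                dirtag = "p" if direction > 0 else "n"
                actuators.append(ActuatorDef(
                    name=f"{coord}_{dirtag}{suffix}",
                    joint=jname, coord=coord, direction=direction,
                    max_torque=tmax,
                    moment_arm=cfgmod.MOMENT_ARMS[jbase],
                    group=group))

    coord_set = set(tree.coord_names)
    for act in actuators:
        if act.coord not in coord_set:
            raise ConfigurationError(f"actuator {act.name} targets unknown "
                                     f"coordinate {act.coord}")
    # every joint DOF must be spanned by an antagonistic pair
    for name in tree.coord_names:
        if name.startswith("root_"):
            continue
        dirs = {a.direction for a in actuators if a.coord == name}
        if dirs != {+1, -1}:
            raise ConfigurationError(f"coordinate {name} lacks an "
                                     "agonist/antagonist pair")

    return BodyModel(anthro, tree, segments, actuators, landmarks)


def forward_kinematics(model: BodyModel, coords: np.ndarray):
    """Per-segment poses; thin wrapper kept as the module's public FK entry."""
    return model.fk(coords)


def point_jacobian(tree: KinematicTree, coords: np.ndarray,
                   points: list[tuple[str, np.ndarray]],
                   h: float = 1e-6) -> np.ndarray:
    """d(point)/d(coords) by central differences, shape (npts, 3, ndof).

    Used to map Cartesian forces at attachment points into generalized
    forces (J^T F); accuracy ~1e-9 m is ample for the 1e-6 N equilibrium
    tolerance of the recruitment solver.
    """
    coords = np.asarray(coords, dtype=float)
    npts = len(points)
    J = np.zeros((npts, 3, tree.ndof))

    def positions(q):
        poses = tree.fk(q)
        return np.array([poses[s][0] + poses[s][1] @ off for s, off in points])

    for j in range(tree.ndof):
        dq = np.zeros(tree.ndof)
        dq[j] = h
        J[:, :, j] = (positions(coords + dq) - positions(coords - dq)) / (2 * h)
    return J
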