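"""Synthetic lifting/carrying motion generation and sequence segmentation.

The study conditions emulated here are a bilaterally symmetric lift of a
21 kg box from standing hand height onto a 1.46 m platform, sampled at
100 Hz.  The generator is joint-angle parameterized: leg/trunk angles
follow prescribed minimum-jerk profiles (a slight initial squat
releasing into upright stance), the root pose is solved so the feet stay
planted, and the arm chain is solved frame-by-frame by inverse
kinematics so the hand grip points coincide with the box handles
exactly.  A small out-of-sagittal shoulder-abduction wobble (5 deg peak
by default) is prescribed so lateromedial load paths are exercised; a
perfectly planar motion would make all lateromedial interface loads
trivially zero.  This is a kinematically plausible, reproducible input
-- not a biomechanical motion prediction.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import config as cfgmod
from .body import Anthropometry, BodyModel, build_body, _rot
from .errors import (ConfigurationError, DegenerateTraceError,
                     InfeasibleTaskError, InvalidArgumentError, NoCycleError)

GRIP_MODES = ("top_handle_plus_support", "two_lateral_handles")
SEQUENCE_TYPES = ("carry", "lift", "lower")


@dataclass(frozen=True)
class TaskSpec:
    """Box handling task: geometry, grip and sequence type."""

    box_mass: float = 21.0
    box_dims: tuple[float, float, float] = (0.44, 0.26, 0.14)
    platform_height: float = 1.46
    grip_mode: str = "two_lateral_handles"
    sequence_type: str = "lift"

    def __post_init__(self):
        if self.box_mass <= 0:
            raise InvalidArgumentError("box_mass must be > 0")
        if self.platform_height <= 0:
            raise InvalidArgumentError("platform_height must be > 0")
        if any(d <= 0 for d in self.box_dims):
            raise InvalidArgumentError("box dimensions must all be > 0")
        if self.grip_mode not in GRIP_MODES:
            raise InvalidArgumentError(f"unknown grip mode {self.grip_mode!r}")
        if self.sequence_type not in SEQUENCE_TYPES:
            raise InvalidArgumentError(
                f"unknown sequence type {self.sequence_type!r}")

    def handle_offsets(self) -> dict[str, np.ndarray]:
        """Hand attachment points relative to the box centre (box frame)."""
        length, _depth, height = self.box_dims
        if self.grip_mode == "two_lateral_handles":
            return {"r": np.array([0.0, -length / 2, 0.0]),
                    "l": np.array([0.0, +length / 2, 0.0])}
        # one hand on the top handle, the other supporting from below
        return {"r": np.array([0.0, -0.05, height / 2 + 0.03]),
                "l": np.array([0.0, +0.05, -height / 2])}


@dataclass
class MotionTrajectory:
    """Time-stamped generalized coordinates plus the load pose."""

    rate: float
    times: np.ndarray                  # (n,)
    coords: np.ndarray                 # (n, ndof)
    coord_labels: list[str]
    box_pose: np.ndarray               # (n, 7): x y z qw qx qy qz
    symmetric: bool = True
    task: TaskSpec | None = None
    anthro: Anthropometry | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise InvalidArgumentError("times must be strictly increasing "
                                       "and uniform")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=self.coord_labels)
        df.insert(0, "time", self.times)
        for j, col in enumerate(["box_x", "box_y", "box_z", "box_qw",
                                 "box_qx", "box_qy", "box_qz"]):
            df[col] = self.box_pose[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MarkerSet:
    """Named markers attached to model segments (or the box) with local offsets."""

    attachments: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.attachments)


def default_marker_set(model: BodyModel,
                       task: TaskSpec | None = None) -> MarkerSet:
    """Reduced synthetic marker protocol.

    Heels, toes and hands (segmentation and hand-path checks), one
    marker per major segment, and four box corners.
    """
    att: dict[str, tuple[str, np.ndarray]] = {}
    for side in ("r", "l"):
        for base in ("heel", "toe", "hand_grip"):
            seg, off = model.landmarks[f"{base}_{side}"]
            att[f"{base}_{side}"] = (seg, off.copy())
        for seg_base in ("upper_arm", "forearm", "thigh", "shank"):
            seg = f"{seg_base}_{side}"
            att[f"{seg}_marker"] = (seg, model.segments[seg].com_offset.copy())
    for seg in ("pelvis", "thorax", "head"):
        att[f"{seg}_marker"] = (seg, model.segments[seg].com_offset.copy())
    dims = (task or TaskSpec()).box_dims
    hx, hy, hz = dims[1] / 2, dims[0] / 2, dims[2] / 2
    for i, (sx, sy) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)]):
        att[f"box_corner_{i + 1}"] = ("box", np.array([sx * hx, sy * hy, hz]))
    return MarkerSet(att)


def min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk time scaling s(tau) on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _arm_chain_fk(p_sh, R_sh, q, lengths, sgn):
    """Hand-grip position of one arm given shoulder pose and 5 arm angles."""
    l_ua, l_fa, l_h = lengths
    flex, abd, rot, elb, wri = q
    R = R_sh @ _rot(np.array([0.0, -1.0, 0.0]), flex)
    R = R @ _rot(np.array([sgn, 0.0, 0.0]), abd)
    R = R @ _rot(np.array([0.0, 0.0, -sgn]), rot)
    p_el = p_sh + R @ np.array([0.0, 0.0, -l_ua])
    R = R @ _rot(np.array([0.0, -1.0, 0.0]), elb)
    p_wr = p_el + R @ np.array([0.0, 0.0, -l_fa])
    R = R @ _rot(np.array([0.0, -1.0, 0.0]), wri)
    return p_wr + R @ np.array([0.0, 0.0, -l_h])


def _solve_arm_ik(p_sh, R_sh, target, lengths, sgn, abd_pref, q0):
    """Arm IK: exact hand-target equality, physiological null space.

    The hard constraint pins the grip point; the redundancy is resolved
    toward a natural reach: shoulder flexion along the shoulder-target
    direction, elbow flexion from the two-link cosine geometry, and the
    prescribed abduction wobble.
    """
    rel = target - p_sh
    dist = np.linalg.norm(rel)
    arm = sum(lengths)
    flex_pref = np.arctan2(rel[0], -rel[2]) if dist > 1e-9 else 0.0
    elbow_pref = 2.0 * np.arccos(min(1.0, dist / arm))
    # cross-body targets need an ab/adduction bias of the right sign;
    # the lateral angle must stay small for targets above the shoulder
    if dist > 1e-9:
        abd_pref = abd_pref + np.arcsin(
            np.clip(sgn * rel[1] / dist, -1.0, 1.0))

    def objective(q):
        # rotation and wrist stay near neutral unless the target demands
        # them; continuity keeps the null space from drifting
        return ((q[1] - abd_pref) ** 2
                + 0.5 * (q[0] - flex_pref) ** 2
                + 0.02 * (q[3] - elbow_pref) ** 2
                + 0.5 * q[2] ** 2 + 0.5 * q[4] ** 2
                + 0.02 * np.sum((q - q0) ** 2))

    def constraint(q):
        return _arm_chain_fk(p_sh, R_sh, q, lengths, sgn) - target

    # try the warm start and the physiological prior; keep the better
    # converged branch (warm starts alone can carry an elbow flip
    # through the lift, prior starts alone can shoot to far branches)
    prior = np.array([flex_pref, abd_pref, 0.0, elbow_pref, 0.0])
    best_x, best_obj, best_err = None, np.inf, np.inf
    for start in (q0, prior):
        res = minimize(objective, start, method="SLSQP",
                       constraints=[{"type": "eq", "fun": constraint}],
                       options={"maxiter": 300, "ftol": 1e-14})
        err = np.linalg.norm(constraint(res.x))
        if err < 5e-4 and objective(res.x) < best_obj:
            best_x, best_obj = res.x, objective(res.x)
        best_err = min(best_err, err)
    if best_x is None:
        raise InfeasibleTaskError(
            f"arm inverse kinematics residual {best_err * 1000:.2f} mm "
            f"exceeds 0.5 mm", shortfall_m=best_err)
    return best_x


def _leg_trunk_coords(model: BodyModel, hip, knee, lumbar):
    """Coordinate vector with prescribed symmetric leg/trunk angles and a
    root pose keeping the right ankle at its standing location."""
    tree = model.tree
    q = np.zeros(tree.ndof)
    ankle = knee - hip  # keeps the foot sole horizontal
    for side in ("r", "l"):
        q[tree.coord_index(f"hip_{side}_flexion")] = hip
        q[tree.coord_index(f"knee_{side}_flexion")] = knee
        q[tree.coord_index(f"ankle_{side}_flexion")] = ankle
    q[tree.coord_index("lumbar_flexion")] = lumbar
    poses = tree.fk(q)
    ankle_now = poses["foot_r"][0]
    poses0 = tree.fk(np.zeros(tree.ndof))
    ankle_ref = poses0["foot_r"][0]
    q[tree.coord_index("root_tx")] = ankle_ref[0] - ankle_now[0]
    q[tree.coord_index("root_tz")] = ankle_ref[2] - ankle_now[2]
    return q


def generate_lift_trajectory(anthro: Anthropometry, task: TaskSpec,
                             duration: float = 3.0, rate: float = 100.0,
                             seed: int = 0, config: dict | None = None,
                             model: BodyModel | None = None
                             ) -> MotionTrajectory:
    """Symmetric lift of the box from standing hand height to the platform."""
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be > 0")
    if task.sequence_type != "lift":
        raise InvalidArgumentError("task.sequence_type must be 'lift'")
    cfg = config or cfgmod.default_config()
    model = model or build_body(anthro, cfg)
    mcfg = cfg["motion"]
    rng = np.random.default_rng(seed)

    tree = model.tree
    z_sh = model.standing_shoulder_height
    arm = model.arm_length
    z0 = model.standing_hand_height
    z1 = task.platform_height

    x1 = mcfg["box_end_forward"]
    max_reach_z = z_sh + np.sqrt(max((0.98 * arm) ** 2 - x1**2, 0.0))
    if z1 > max_reach_z:
        raise InfeasibleTaskError(
            f"platform at {z1:.2f} m unreachable; shortfall "
            f"{z1 - max_reach_z:.3f} m", shortfall_m=z1 - max_reach_z)

    jitter = 1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=4)
    hip0 = np.deg2rad(mcfg["squat_hip_deg"] * jitter[0])
    knee0 = np.deg2rad(mcfg["squat_knee_deg"] * jitter[1])
    lum0 = np.deg2rad(mcfg["lumbar_start_deg"] * jitter[2])
    lum1 = np.deg2rad(mcfg["lumbar_end_deg"])
    wobble_amp = np.deg2rad(mcfg["wobble_deg"] * jitter[3])

    # reach-limited start: box at standing hand height, slightly forward
    q_sq = _leg_trunk_coords(model, hip0, knee0, lum0)
    z_sh0 = model.point("shoulder_r", tree.fk(q_sq))[2]
    dz0 = z_sh0 - z0
    x0_max = np.sqrt(max((0.96 * arm) ** 2 - dz0**2, 1e-8))
    x0 = min(mcfg["box_start_forward"], x0_max)

    n = int(round(duration * rate)) + 1
    times = np.arange(n) / rate
    hold = mcfg["hold_fraction"] * duration
    tau = np.where(times <= hold, 0.0, (times - hold) / max(duration - hold, 1e-9))
    s = min_jerk(tau)

    handles = task.handle_offsets()
    # the lowest handle starts at standing hand height (for lateral
    # handles this is the box centre itself)
    z_shift = -min(off[2] for off in handles.values())
    box_centres = np.column_stack([
        x0 + s * (x1 - x0), np.zeros(n),
        (z0 + z_shift) + s * (z1 - (z0 + z_shift))])

    coords = np.zeros((n, tree.ndof))
    box_pose = np.zeros((n, 7))
    box_pose[:, :3] = box_centres
    box_pose[:, 3] = 1.0

    lengths = (model.segments["upper_arm_r"].length,
               model.segments["forearm_r"].length,
               model.segments["hand_r"].length)
    arm_coord_idx = {
        side: [tree.coord_index(f"{j}_{side}{d}") for j, d in
               [("gh", "_flexion"), ("gh", "_abduction"), ("gh", "_rotation"),
                ("elbow", "_flexion"), ("wrist", "_flexion")]]
        for side in ("r", "l")}

    q_arm_prev = {"r": np.zeros(5), "l": np.zeros(5)}
    for i in range(n):
        hip = hip0 * (1 - s[i])
        knee = knee0 * (1 - s[i])
        lum = lum0 + s[i] * (lum1 - lum0)
        q = _leg_trunk_coords(model, hip, knee, lum)
        poses = tree.fk(q)
        abd_pref = wobble_amp * np.sin(np.pi * s[i])
        for side, sgn in (("r", -1.0), ("l", +1.0)):
            p_sh = model.point(f"shoulder_{side}", poses)
            R_sh = poses["thorax"][1]
            target = box_centres[i] + handles[side]
            qa = _solve_arm_ik(p_sh, R_sh, target, lengths, sgn,
                               abd_pref, q_arm_prev[side])
            q_arm_prev[side] = qa
            q[arm_coord_idx[side]] = qa
            if task.grip_mode == "two_lateral_handles":
                break  # mirror instead of solving the left side
        if task.grip_mode == "two_lateral_handles":
            q[arm_coord_idx["l"]] = q[arm_coord_idx["r"]]
            q_arm_prev["l"] = q_arm_prev["r"]
        coords[i] = q

    symmetric = task.grip_mode == "two_lateral_handles"
    return MotionTrajectory(rate=rate, times=times, coords=coords,
                            coord_labels=list(tree.coord_names),
                            box_pose=box_pose, symmetric=symmetric,
                            task=task, anthro=anthro)


def generate_lower_trajectory(anthro: Anthropometry, task: TaskSpec,
                              duration: float = 3.0, rate: float = 100.0,
                              seed: int = 0, config: dict | None = None,
                              model: BodyModel | None = None
                              ) -> MotionTrajectory:
    """Lowering sequence: the time-reversed lift."""
    lift_task = TaskSpec(task.box_mass, task.box_dims, task.platform_height,
                         task.grip_mode, "lift")
    traj = generate_lift_trajectory(anthro, lift_task, duration, rate, seed,
                                    config, model)
    traj.coords = traj.coords[::-1].copy()
    traj.box_pose = traj.box_pose[::-1].copy()
    traj.task = task
    return traj


def generate_carry_trajectory(anthro: Anthropometry, task: TaskSpec,
                              duration: float = 3.0, rate: float = 100.0,
                              seed: int = 0, config: dict | None = None,
                              model: BodyModel | None = None,
                              step_frequency: float = 1.0
                              ) -> MotionTrajectory:
    """Carrying the box at standing height with a marching gait pattern.

    Legs swing in anti-phase; the arms keep the initial lift posture so
    the box travels with the trunk.  Flat-foot instants (leg vertical)
    provide the events the gait-cycle segmentation detects.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be > 0")
    cfg = config or cfgmod.default_config()
    model = model or build_body(anthro, cfg)
    lift_task = TaskSpec(task.box_mass, task.box_dims, task.platform_height,
                         task.grip_mode, "lift")
    base = generate_lift_trajectory(anthro, lift_task, duration=1.0,
                                    rate=rate, seed=seed, config=cfg,
                                    model=model)
    q0 = base.coords[0].copy()

    tree = model.tree
    n = int(round(duration * rate)) + 1
    times = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    amp = np.deg2rad(12.0 * (1 + 0.1 * rng.uniform(-1, 1)))
    knee_amp = np.deg2rad(15.0)
    omega = 2 * np.pi * step_frequency

    coords = np.tile(q0, (n, 1))
    for i, t in enumerate(times):
        ph = omega * t
        for side, sign in (("r", 1.0), ("l", -1.0)):
            swing = sign * np.sin(ph)
            coords[i, tree.coord_index(f"hip_{side}_flexion")] = amp * swing
            coords[i, tree.coord_index(f"knee_{side}_flexion")] = (
                knee_amp * max(sign * np.sin(ph), 0.0))
        coords[i, tree.coord_index("root_tz")] = (
            q0[tree.coord_index("root_tz")] - 0.01 * (1 - np.cos(2 * ph)) / 2)

    # box follows the hands
    box_pose = np.zeros((n, 7))
    box_pose[:, 3] = 1.0
    for i in range(n):
        poses = tree.fk(coords[i])
        grips = [model.point(f"hand_grip_{s}", poses) for s in ("r", "l")]
        box_pose[i, :3] = 0.5 * (grips[0] + grips[1])
    return MotionTrajectory(rate=rate, times=times, coords=coords,
                            coord_labels=list(tree.coord_names),
                            box_pose=box_pose, symmetric=False,
                            task=task, anthro=anthro)


# -- marker export / import -------------------------------------------------

def marker_positions(traj: MotionTrajectory, markers: MarkerSet,
                     model: BodyModel) -> pd.DataFrame:
    """World positions of every marker at every frame (columns name_x/y/z)."""
    for name, (seg, _off) in markers.attachments.items():
        if seg != "box" and seg not in model.segments:
            raise ConfigurationError(
                f"marker {name!r} attached to unknown segment {seg!r}")
    data = {}
    n = traj.n_frames
    pos = {name: np.zeros((n, 3)) for name in markers.names}
    for i in range(n):
        poses = model.fk(traj.coords[i])
        box_c = traj.box_pose[i, :3]
        for name, (seg, off) in markers.attachments.items():
            if seg == "box":
                pos[name][i] = box_c + off  # box orientation held identity
            else:
                p, R = poses[seg]
                pos[name][i] = p + R @ off
    data["frame"] = np.arange(1, n + 1)
    data["time"] = traj.times
    for name in markers.names:
        for j, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = pos[name][:, j]
    return pd.DataFrame(data)


def export_markers(traj: MotionTrajectory, markers: MarkerSet,
                   model: BodyModel, path=None, fmt: str = "trc") -> str:
    """Write marker trajectories as TRC-style TSV or plain CSV.

    Floats are written with shortest round-trip repr, so a write/read
    cycle reproduces the values bit-for-bit.
    """
    df = marker_positions(traj, markers, model)
    names = markers.names
    if fmt == "csv":
        buf = io.StringIO()
        buf.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            buf.write(",".join(repr(float(v)) if i else str(int(v))
                               for i, v in enumerate(row)) + "\n")
        text = buf.getvalue()
    elif fmt == "trc":
        buf = io.StringIO()
        buf.write("DataRate\tNumFrames\tNumMarkers\tUnits\n")
        buf.write(f"{traj.rate!r}\t{traj.n_frames}\t{len(names)}\tm\n")
        buf.write("Frame\tTime\t" + "\t\t\t".join(names) + "\n")
        buf.write("\t\t" + "\t".join(
            f"X{k + 1}\tY{k + 1}\tZ{k + 1}" for k in range(len(names))) + "\n")
        for i in range(traj.n_frames):
            row = [str(i + 1), repr(float(traj.times[i]))]
            for name in names:
                row += [repr(float(df[f"{name}_{ax}"].iloc[i]))
                        for ax in "xyz"]
            buf.write("\t".join(row) + "\n")
        text = buf.getvalue()
    else:
        raise InvalidArgumentError(f"unknown marker format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_markers(path_or_text: str, fmt: str | None = None) -> pd.DataFrame:
    """Read a marker table written by :func:`export_markers`."""
    if "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
        if fmt is None:
            fmt = "trc" if path_or_text.endswith(".trc") else None
    if fmt is None:
        fmt = "trc" if text.startswith("DataRate") else "csv"
    lines = text.strip("\n").split("\n")
    if fmt == "csv":
        header = lines[0].split(",")
        rows = [[float(v) for v in ln.split(",")] for ln in lines[1:]]
        df = pd.DataFrame(rows, columns=header)
        df["frame"] = df["frame"].astype(int)
        return df
    names = [s for s in lines[2].split("\t")[2:] if s]
    data = {"frame": [], "time": []}
    for name in names:
        for ax in "xyz":
            data[f"{name}_{ax}"] = []
    for ln in lines[4:]:
        vals = ln.split("\t")
        data["frame"].append(int(vals[0]))
        data["time"].append(float(vals[1]))
        for k, name in enumerate(names):
            for j, ax in enumerate("xyz"):
                data[f"{name}_{ax}"].append(float(vals[2 + 3 * k + j]))
    return pd.DataFrame(data)


# -- segmentation -----------------------------------------------------------

def segment_lift_window(vertical_trace, rate: float) -> tuple[int, int]:
    """Frames of the lowest point preceding the highest point of the load.

    Mirrors event detection on the vertical velocity of the box markers:
    the returned frames are the global minimum before, and the global
    maximum of, the vertical trace.
    """
    z = np.asarray(vertical_trace, dtype=float)
    if len(z) < 3:
        raise InvalidArgumentError("trace must have at least 3 frames")
    if np.ptp(z) < 1e-12:
        raise DegenerateTraceError("constant vertical trace carries no lift")
    i_high = int(np.argmax(z))
    i_low = int(np.argmin(z[: i_high + 1]))
    return i_low, i_high


def segment_gait_cycle(heel_z, toe_z, rate: float,
                       tol: float = 0.005) -> tuple[int, int]:
    """One full gait cycle between two flat-foot events.

    A flat-foot event is a run of frames with |heel_z - toe_z| < tol;
    the cycle spans from the centre of the first run to the centre of
    the last run.
    """
    heel = np.asarray(heel_z, dtype=float)
    toe = np.asarray(toe_z, dtype=float)
    if heel.shape != toe.shape or len(heel) < 3:
        raise InvalidArgumentError("heel and toe traces must have equal "
                                   "length >= 3")
    flat = np.abs(heel - toe) < tol
    if not flat.any():
        raise NoCycleError("no flat-foot events within tolerance")
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8),
                                                   [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))
    if len(runs) == 1:
        lo, hi = runs[0]
        if lo == 0 and hi == len(heel) - 1:
            return 0, len(heel) - 1
        raise NoCycleError("only one flat-foot event; no full cycle")
    first = (runs[0][0] + runs[0][1]) // 2
    last = (runs[-1][0] + runs[-1][1]) // 2
    return int(first), int(last)
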