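"""Arm-bracing interface loads: decomposition and summaries.

Contact forces at the upper-arm bracing are expressed in an anatomical
frame fixed to the bracing centre: the distoproximal axis runs along
the humerus (distal to proximal), the craniocaudal axis points caudally
when the shoulder is flexed 90 degrees, and the lateromedial axis points
toward the sagittal plane at zero abduction.  Components are classified
as *supporting* (craniocaudal force, lateromedial torque -- they help
lift the arm) or *parasitic* (distoproximal and lateromedial force,
distoproximal and craniocaudal torque -- shear, pinching, discomfort).

Summaries pool the frames of both arm interfaces: parasitic components
are averaged as absolute values; supporting components keep their sign,
with a recorded mirror flip applied when the signed mean is negative so
reported values read positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

FORCE_COMPONENTS = ("force_distoproximal", "force_craniocaudal",
                    "force_lateromedial")
TORQUE_COMPONENTS = ("torque_distoproximal", "torque_craniocaudal",
                     "torque_lateromedial")
COMPONENTS = FORCE_COMPONENTS + TORQUE_COMPONENTS

SUPPORTING = ("force_craniocaudal", "torque_lateromedial")
PARASITIC = ("force_distoproximal", "force_lateromedial",
             "torque_distoproximal", "torque_craniocaudal")


@dataclass
class BracingFrame:
    """Anatomical triad at the bracing centre, re-evaluated per frame."""

    origin: np.ndarray
    distoproximal: np.ndarray
    craniocaudal: np.ndarray
    lateromedial: np.ndarray

    @classmethod
    def from_humerus(cls, origin: np.ndarray, R_humerus: np.ndarray,
                     side: str) -> "BracingFrame":
        """Axes from the humerus pose.

        Lateromedial points toward the sagittal plane on both sides
        (mirror symmetric), so a symmetric motion yields identical
        signed components left and right.
        """
        sgn = -1.0 if side == "r" else +1.0
        dp = R_humerus @ np.array([0.0, 0.0, 1.0])
        cc = R_humerus @ np.array([-1.0, 0.0, 0.0])
        lm = R_humerus @ np.array([0.0, -sgn, 0.0])
        return cls(origin=np.asarray(origin, float), distoproximal=dp,
                   craniocaudal=cc, lateromedial=lm)

    def axes(self) -> dict[str, np.ndarray]:
        return {"distoproximal": self.distoproximal,
                "craniocaudal": self.craniocaudal,
                "lateromedial": self.lateromedial}


@dataclass
class InterfaceLoadTrace:
    """Per-frame six-component loads of one arm interface."""

    side: str
    components: pd.DataFrame            # columns = COMPONENTS

    def __post_init__(self):
        missing = [c for c in COMPONENTS if c not in self.components]
        if missing:
            raise InvalidArgumentError(f"trace missing components {missing}")


@dataclass
class LoadSummary:
    mean: dict[str, float]
    sd: dict[str, float]
    flipped: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in COMPONENTS:
            rows.append({
                "component": comp,
                "class": "supporting" if comp in SUPPORTING else "parasitic",
                "mean": self.mean[comp], "sd": self.sd[comp],
                "mirrored": self.flipped.get(comp, False)})
        return pd.DataFrame(rows)


def classify_components() -> dict[str, tuple[str, ...]]:
    """Fixed supporting/parasitic classification of the six components."""
    return {"supporting": SUPPORTING, "parasitic": PARASITIC}


def decompose_loads(forces: np.ndarray, points: np.ndarray,
                    frame: BracingFrame) -> dict[str, float]:
    """Project summed contact forces/torques onto the bracing axes.

    ``forces``/``points`` are (n, 3) world-frame arrays; torques are
    taken about the bracing origin.
    """
    forces = np.atleast_2d(np.asarray(forces, float))
    points = np.atleast_2d(np.asarray(points, float))
    if forces.shape != points.shape:
        raise InvalidArgumentError(
            f"force/point count mismatch: {forces.shape} vs {points.shape}")
    F = forces.sum(axis=0)
    T = np.cross(points - frame.origin, forces).sum(axis=0)
    out = {}
    for name, axis in frame.axes().items():
        out[f"force_{name}"] = float(F @ axis)
        out[f"torque_{name}"] = float(T @ axis)
    return out


def trace_from_solution(solution, side: str) -> InterfaceLoadTrace:
    """Interface-load trace of one side from a solved sequence."""
    rows = []
    for fs in solution.frames:
        arm_contacts = [c for c in fs.contacts
                        if c["interface"] == "arm" and c["side"] == side]
        if not arm_contacts:
            rows.append({c: 0.0 for c in COMPONENTS})
            continue
        frame = fs.bracing_frames[side]
        forces = np.array([c["force"] for c in arm_contacts])
        points = np.array([c["point"] for c in arm_contacts])
        rows.append(decompose_loads(forces, points, frame))
    return InterfaceLoadTrace(side=side, components=pd.DataFrame(rows))


def summarize_loads(trace: InterfaceLoadTrace,
                    other: InterfaceLoadTrace) -> LoadSummary:
    """Pool both sides' frames; absolute means for parasitic components,
    signed (mirrored-positive) means for supporting components."""
    if len(trace.components) != len(other.components):
        raise InvalidArgumentError("traces must have equal length")
    if len(trace.components) == 0:
        raise InvalidArgumentError("empty traces")
    mean, sd, flipped = {}, {}, {}
    for comp in COMPONENTS:
        pooled = np.concatenate([trace.components[comp].to_numpy(),
                                 other.components[comp].to_numpy()])
        if comp in PARASITIC:
            pooled = np.abs(pooled)
            flip = False
        else:
            flip = bool(pooled.mean() < 0)
            if flip:
                pooled = -pooled
        mean[comp] = float(pooled.mean())
        sd[comp] = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
        flipped[comp] = flip
    return LoadSummary(mean=mean, sd=sd, flipped=flipped)
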