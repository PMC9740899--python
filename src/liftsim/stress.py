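"""Biomechanical stress criteria.

Cumulative muscle stress is the time integral (percent-seconds) of a
muscle group's activity envelope -- the pointwise maximum over the
group's actuators, left and right pooled.  Peak joint stress is the
maximum over the motion of the resultant joint force (bilateral joints
averaged between sides per frame); the L4/L5 value is the magnitude of
the compressive component along the spine axis, compared against the
3.1 kN lower-back guideline limit.  Relief of an exoskeleton condition
is expressed as a reduction percentage against the unsupported
baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncompleteTableError, InvalidArgumentError

CRITERION_KINDS = ("ma_integral", "jf_max", "ma_mean", "jf_mean",
                   "interface_force", "interface_torque")


@dataclass(frozen=True)
class StressCriterion:
    kind: str
    target: str                       # muscle group, joint, or load component

    def __post_init__(self):
        if self.kind not in CRITERION_KINDS:
            raise InvalidArgumentError(f"unknown criterion kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.target}"

    @property
    def units(self) -> str:
        return {"ma_integral": "%s", "jf_max": "kN", "ma_mean": "%",
                "jf_mean": "N", "interface_force": "N",
                "interface_torque": "Nm"}[self.kind]


@dataclass
class StressReport:
    """Criteria x alternatives matrix with optional dispersions."""

    values: pd.DataFrame              # index = criterion labels
    sds: pd.DataFrame | None = None
    guideline_l45_kn: float = 3.1
    guideline_exceeded: dict[str, bool] = field(default_factory=dict)


def group_envelope(activities: np.ndarray, times=None,
                   kind: str = "max") -> np.ndarray:
    """Envelope (%) across member actuator traces, shape (members, frames)."""
    act = np.atleast_2d(np.asarray(activities, float))
    if act.shape[0] == 0:
        raise InvalidArgumentError("empty group has no envelope")
    env = act.max(axis=0) if kind == "max" else act.mean(axis=0)
    return 100.0 * env


def integrate_activity(envelope_pct: np.ndarray, times: np.ndarray) -> float:
    """Trapezoidal time integral of an envelope, units %*s."""
    env = np.asarray(envelope_pct, float)
    t = np.asarray(times, float)
    if len(env) < 2 or len(t) != len(env):
        raise InvalidArgumentError("need >= 2 frames with matching times")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * max(dt[0], 1e-12):
        raise InvalidArgumentError("non-uniform sampling")
    return float(np.trapezoid(env, t))


def resultant_joint_force(reactions, pairing: str = "bilateral_average",
                          spine_axes=None, compressive: bool = False):
    """Per-frame joint-force magnitude trace with max (kN) and mean (N).

    ``reactions``: (frames, 3) array for a single joint, or a dict
    {"r": ..., "l": ...} for bilateral averaging.  With ``compressive``
    the value is |projection on the spine axis| instead of the norm.
    """
    def magnitude(vecs):
        vecs = np.asarray(vecs, float)
        if not np.all(np.isfinite(vecs)):
            raise InvalidArgumentError("non-finite reaction vectors")
        if compressive:
            axes = np.asarray(spine_axes, float)
            return np.abs(np.sum(vecs * axes, axis=1))
        return np.linalg.norm(vecs, axis=1)

    if pairing == "bilateral_average":
        if not isinstance(reactions, dict) or set(reactions) != {"r", "l"}:
            raise InvalidArgumentError(
                "bilateral_average needs both 'r' and 'l' reaction traces")
        trace = 0.5 * (magnitude(reactions["r"]) + magnitude(reactions["l"]))
    elif pairing == "single":
        trace = magnitude(reactions)
    else:
        raise InvalidArgumentError(f"unknown pairing {pairing!r}")
    return trace, float(trace.max() / 1000.0), float(trace.mean())


def reduction_percent(baseline: float, treated: float) -> float:
    """Percent reduction 100 (1 - treated/baseline)."""
    if baseline <= 0:
        raise InvalidArgumentError("baseline must be > 0")
    return 100.0 * (1.0 - treated / baseline)


def build_stress_table(results: dict[str, dict[str, list[float] | float]],
                       criteria: list[str],
                       guideline_l45_kn: float = 3.1) -> StressReport:
    """Assemble a criteria x alternatives report.

    ``results[alternative][criterion]`` is a scalar or a per-subject
    list (mean and sample sd computed over subjects).
    """
    alternatives = list(results)
    missing = [(alt, c) for alt in alternatives for c in criteria
               if c not in results[alt]]
    if missing:
        raise IncompleteTableError(
            f"missing cells: {missing}", missing=missing)
    values = pd.DataFrame(index=criteria, columns=alternatives, dtype=float)
    sds = pd.DataFrame(index=criteria, columns=alternatives, dtype=float)
    any_sd = False
    for alt in alternatives:
        for c in criteria:
            v = results[alt][c]
            if np.ndim(v) > 0:
                v = np.asarray(v, float)
                values.loc[c, alt] = v.mean()
                if len(v) >= 2:
                    sds.loc[c, alt] = v.std(ddof=1)
                    any_sd = True
            else:
                values.loc[c, alt] = float(v)
    exceeded = {}
    for c in criteria:
        if "l4l5" in c.lower() and "jf_max" in c:
            for alt in alternatives:
                exceeded[alt] = bool(values.loc[c, alt] > guideline_l45_kn)
    return StressReport(values=values, sds=sds if any_sd else None,
                        guideline_l45_kn=guideline_l45_kn,
                        guideline_exceeded=exceeded)
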