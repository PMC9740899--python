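"""Predictive contact elements (PCE) and ground contact geometry.

A PCE pairs a target point on one body with a cylindrical contact zone
on another.  While the target sits inside the zone, a recruitment
variable generates a unilateral normal force (0..F_max) along the
element's normal direction and a friction force bounded by mu times the
normal inside a linearized cone.  Outside the zone the element is
force-free.  Ground contact uses the same law with a plane zone.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class ContactElementSpec:
    """One predictive contact element.

    ``normal_mode`` is either ``"radial"`` (normal points from the target
    toward the cylinder axis, re-evaluated per frame) or ``"fixed"``
    (normal is ``normal_axis`` expressed in the zone frame).
    """

    name: str
    target_segment: str                 # human segment carrying the point
    target_offset: tuple[float, float, float]
    zone_segment: str                   # exo segment carrying the cylinder
    zone_center: tuple[float, float, float]
    zone_axis: tuple[float, float, float]
    zone_radius: float
    zone_half_length: float
    max_strength: float = 10000.0
    friction_mu: float = 1.0
    normal_mode: str = "radial"
    normal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    side: str = ""                      # "r"/"l" for arm elements, else ""
    interface: str = ""                 # "arm", "hip", "back", "ground"

    def __post_init__(self):
        if self.zone_radius <= 0 or self.zone_half_length <= 0:
            raise ConfigurationError(
                f"PCE {self.name}: degenerate zone (radius/half-length <= 0)")
        if self.max_strength <= 0:
            raise ConfigurationError(f"PCE {self.name}: max strength <= 0")


@dataclass(frozen=True)
class GroundContactSpec:
    """Foot target point against the ground plane (z = 0)."""

    name: str
    target_segment: str
    target_offset: tuple[float, float, float]
    max_strength: float = 10000.0
    friction_mu: float = 1.0
    activation_height: float = 0.01     # m, point must be this close to ground


def element_geometry(spec: ContactElementSpec, target_pos: np.ndarray,
                     zone_pos: np.ndarray, zone_R: np.ndarray):
    """Per-frame contact geometry.

    Returns ``(inside, normal, t1, t2)`` with the world-frame normal and
    two tangent directions, or ``inside = False`` when the target lies
    outside the cylinder.
    """
    axis = zone_R @ np.asarray(spec.zone_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = zone_pos + zone_R @ np.asarray(spec.zone_center, dtype=float)
    rel = target_pos - center
    axial = float(rel @ axis)
    radial_vec = rel - axial * axis
    radial = float(np.linalg.norm(radial_vec))
    inside = (abs(axial) <= spec.zone_half_length
              and radial <= spec.zone_radius)
    if not inside:
        return False, None, None, None
    if spec.normal_mode == "radial":
        if radial > 1e-9:
            normal = -radial_vec / radial          # push toward the axis
        else:
            normal = zone_R @ np.asarray(spec.normal_axis, dtype=float)
    else:
        normal = zone_R @ np.asarray(spec.normal_axis, dtype=float)
    normal = normal / np.linalg.norm(normal)
    t1 = np.cross(normal, axis)
    n1 = np.linalg.norm(t1)
    if n1 < 1e-9:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(normal @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(normal, helper)
        n1 = np.linalg.norm(t1)
    t1 = t1 / n1
    t2 = np.cross(normal, t1)
    return True, normal, t1, t2
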