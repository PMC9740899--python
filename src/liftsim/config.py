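"""Default configuration tables and config file handling.

All tunable numbers of the workflow live here: anthropometric mass and
length fractions (a standard adult regression table of the
Winter/Drillis-Contini type), torque-equivalent actuator strengths,
effective moment arms for joint-compression mapping, exoskeleton
geometry, contact-element placement and solver settings.  A user config
(YAML, arbitrarily nested) is deep-merged over these defaults.
"""
from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

# Mass fractions of total body mass per segment (bilateral segments listed
# once; applied to each side).  Sums to 1 exactly.
MASS_FRACTIONS = {
    "pelvis": 0.142,
    "thorax": 0.355,
    "head": 0.081,
    "upper_arm": 0.028,
    "forearm": 0.016,
    "hand": 0.006,
    "thigh": 0.100,
    "shank": 0.0465,
    "foot": 0.0145,
}

# Segment lengths as fractions of stature.
LENGTH_FRACTIONS = {
    "pelvis": 0.098,      # hip line to L4/L5
    "thorax": 0.190,      # L4/L5 to shoulder line
    "head": 0.182,
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.054,        # wrist to grip centre
    "thigh": 0.245,
    "shank": 0.246,
    "foot": 0.152,
    "ankle_height": 0.039,
    "shoulder_half_width": 0.1225,
    "hip_half_width": 0.050,
}

# Centre-of-mass position as fraction of segment length from the proximal end.
COM_FRACTIONS = {
    "pelvis": 0.5,
    "thorax": 0.5,
    "head": 0.5,
    "upper_arm": 0.436,
    "forearm": 0.430,
    "hand": 0.5,
    "thigh": 0.433,
    "shank": 0.433,
    "foot": 0.5,
}

# Torque-equivalent actuator strengths in Nm, keyed by (joint, dof, direction).
# Directions: +1 acts in the positive sense of the DOF axis, -1 opposite.
# "count" allows redundant parallel actuators on one (dof, direction).
ACTUATOR_TABLE = [
    # joint,   dof,        dir, max Nm, count, group
    ("lumbar", "flexion", +1, 150.0, 1, "abdomen"),
    ("lumbar", "flexion", -1, 300.0, 1, "lower_back"),   # extension
    ("lumbar", "lateral", +1, 150.0, 1, "lower_back"),
    ("lumbar", "lateral", -1, 150.0, 1, "lower_back"),
    ("lumbar", "axial",   +1, 100.0, 1, "lower_back"),
    ("lumbar", "axial",   -1, 100.0, 1, "lower_back"),
    ("neck",   "flexion", +1, 40.0, 1, "neck"),
    ("neck",   "flexion", -1, 40.0, 1, "neck"),
    ("neck",   "lateral", +1, 40.0, 1, "neck"),
    ("neck",   "lateral", -1, 40.0, 1, "neck"),
    ("gh",     "flexion", +1, 120.0, 2, "shoulders"),
    ("gh",     "flexion", -1, 100.0, 1, "shoulders"),
    ("gh",     "abduction", +1, 120.0, 2, "shoulders"),
    ("gh",     "abduction", -1, 100.0, 1, "shoulders"),
    ("gh",     "rotation", +1, 60.0, 1, "shoulders"),
    ("gh",     "rotation", -1, 60.0, 1, "shoulders"),
    ("elbow",  "flexion", +1, 80.0, 1, "arms"),
    ("elbow",  "flexion", -1, 60.0, 1, "arms"),
    ("wrist",  "flexion", +1, 40.0, 1, "arms"),
    ("wrist",  "flexion", -1, 40.0, 1, "arms"),
    ("hip",    "flexion", +1, 150.0, 1, "lower_extremities"),
    ("hip",    "flexion", -1, 300.0, 1, "lower_extremities"),  # extension
    ("hip",    "abduction", +1, 120.0, 1, "lower_extremities"),
    ("hip",    "abduction", -1, 120.0, 1, "lower_extremities"),
    ("hip",    "rotation", +1, 60.0, 1, "lower_extremities"),
    ("hip",    "rotation", -1, 60.0, 1, "lower_extremities"),
    ("knee",   "flexion", +1, 120.0, 1, "lower_extremities"),
    ("knee",   "flexion", -1, 250.0, 1, "lower_extremities"),  # extension
    ("ankle",  "flexion", +1, 60.0, 1, "lower_extremities"),   # dorsiflexion
    ("ankle",  "flexion", -1, 200.0, 1, "lower_extremities"),  # plantarflexion
]

MUSCLE_GROUPS = (
    "arms", "shoulders", "neck", "lower_back", "abdomen", "lower_extremities",
)

# Effective moment arms (m) mapping actuator torque to joint compression.
MOMENT_ARMS = {
    "lumbar": 0.05,
    "gh": 0.03,
    "elbow": 0.03,
    "wrist": 0.03,
    "hip": 0.05,
    "knee": 0.05,
    "ankle": 0.05,
    "neck": 0.03,
}

DEFAULTS: dict[str, Any] = {
    "gravity": 9.81,
    "vertical_axis": "z",
    "anthropometry": {"stature": 1.76, "body_mass": 70.4},
    "task": {
        "box_mass": 21.0,
        "box_dims": [0.44, 0.26, 0.14],   # length (across body), depth, height
        "platform_height": 1.46,
        "grip_mode": "two_lateral_handles",
        "sequence_type": "lift",
    },
    "motion": {
        "rate": 100.0,
        "duration": 3.0,
        "hold_fraction": 0.1,
        "wobble_deg": 5.0,         # peak out-of-sagittal shoulder abduction
        "box_start_forward": 0.25,  # m, box centre ahead of the pelvis
        "box_end_forward": 0.45,    # arms reach out to place the box
        "flatfoot_tol": 0.005,     # m, gait-event tolerance
        "squat_hip_deg": 20.0,
        "squat_knee_deg": 30.0,
        "lumbar_start_deg": 5.0,
        "lumbar_end_deg": -3.0,
    },
    "exo": {
        "structure_mass": 5.1,
        "spring_stiffness": 10.0,
        "torque_poly": [27.6381, 0.5570, -0.0036],  # c0 Nm, c1 Nm/deg, c2 Nm/deg^2
        # lateral clearances (m) of the exo joints outward of the body
        "hip_joint_clearance": 0.09,      # outward of the hip joint line
        "hip_joint_posterior_offset": 0.06,  # belt joints sit posterolateral
        "torque_joint_clearance": 0.06,   # outward of the shoulder
        # at shoulder height the distal structure stays parallel to the
        # humerus: the prismatic axis tracks the arm and the joint angle
        # equals the arm elevation
        "torque_joint_height_offset": 0.0,
        # the structure attaches at the lateral face of the arm bracing;
        # equal clearances keep the prismatic axis vertical at reference
        "bracing_lateral_clearance": 0.06,
        "mass_split": {"base": 0.6, "side": 0.2},  # of structure mass
        "bracing_humerus_fraction": 0.5,  # bracing centre along the humerus
    },
    "pce": {
        "max_strength": 10000.0,
        "friction_mu": 1.0,
        "arm_count": 8,
        "hip_count": 10,
        "back_count": 1,
        "arm_radius": 0.05,
        "hip_radius": 0.12,
        "zone_half_length": 0.08,
    },
    "solver": {
        "recruitment_power": 3,
        "friction_facets": 8,
        "soft_weight": 1.0e3,
        "hard_tol": 1.0e-8,
        "equilibrium_tol": 1.0e-6,
        # tie-break only: large enough for determinism in flat directions,
        # small enough never to influence load routing
        "friction_regularization": 1.0e-8,
        "envelope": "max",            # or "mean", sensitivity only
    },
    "ranking": {
        "sequence_tie_policy": "by_dispersion_more_points_to_larger_sd",
        "concept_tie_policy": "by_dispersion_more_points_to_smaller_sd",
        "weights": None,
    },
    "guideline_l45_kn": 3.1,
}


def default_config() -> dict[str, Any]:
    """A deep copy of the built-in default configuration."""
    return copy.deepcopy(DEFAULTS)


def _deep_merge(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if (
            key in base
            and isinstance(base[key], dict)
            and isinstance(value, Mapping)
        ):
            _deep_merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def load_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Merge a YAML config file and/or an override mapping over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path!r} is not a mapping")
        _deep_merge(cfg, data)
    if overrides:
        _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    """Reject configurations that would make the solvers ill-posed."""
    p = cfg["solver"]["recruitment_power"]
    if p <= 1:
        raise ConfigurationError(
            f"recruitment_power must be > 1 for a unique optimum, got {p}"
        )
    mass_sum = sum(
        frac * (2 if name in _BILATERAL else 1)
        for name, frac in MASS_FRACTIONS.items()
    )
    if abs(mass_sum - 1.0) > 1e-6:
        raise ConfigurationError(
            f"segment mass fractions sum to {mass_sum}, expected 1"
        )
    c2 = cfg["exo"]["torque_poly"][2]
    if c2 >= 0:
        raise ConfigurationError("torque polynomial must be concave (c2 < 0)")


_BILATERAL = {"upper_arm", "forearm", "hand", "thigh", "shank", "foot"}
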