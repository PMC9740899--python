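"""Two-stage workflow orchestration.

Stage A ranks motion sequences by musculoskeletal stress without an
exoskeleton and selects the most strenuous one.  Stage B couples the
selected lifting motion to exoskeleton joint-configuration variants,
screens kinematic feasibility, simulates the survivors with the
prescribed support-torque curve and rates them by relief and parasitic
interface loads.  Both stages also run in a ``from_table`` mode that
skips simulation and applies the ranking arithmetic to a supplied (or
the bundled) criteria table.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfgmod
from . import datasets
from .body import Anthropometry, BodyModel, build_body, group_members
from .errors import (IncompleteTableError, KinematicFailureError,
                     LiftsimError, RecruitmentInfeasibleError)
from .exo import (ExoVariant, attach_exo, enumerate_variants,
                  feasibility_screen)
from .loads import summarize_loads, trace_from_solution
from .motion import (MotionTrajectory, TaskSpec, generate_carry_trajectory,
                     generate_lift_trajectory, generate_lower_trajectory)
from .rank import RankingTable
from .sim import SequenceSolution, run_sequence
from .stress import (group_envelope, integrate_activity, reduction_percent,
                     resultant_joint_force)

SEQUENCE_CRITERIA = [
    "ma_integral:whole_body", "ma_integral:lower_extremities",
    "ma_integral:abdomen", "ma_integral:lower_back", "ma_integral:neck",
    "ma_integral:shoulders", "ma_integral:arms",
    "jf_max:knee", "jf_max:hip", "jf_max:glenohumeral", "jf_max:elbow",
    "jf_max:wrist", "jf_max:l4l5",
]
CONCEPT_CRITERIA = [
    "ma_mean:shoulders", "ma_mean:lower_back",
    "jf_mean:glenohumeral", "jf_mean:l4l5",
    "interface_force:distoproximal", "interface_force:lateromedial",
    "interface_torque:distoproximal", "interface_torque:craniocaudal",
]

BILATERAL_JOINTS = ("knee", "hip", "gh", "elbow", "wrist")
_JOINT_LABEL = {"knee": "knee", "hip": "hip", "gh": "glenohumeral",
                "elbow": "elbow", "wrist": "wrist"}


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256

    def register(self, path: Path):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def save(self, path: Path):
        payload = {"config": self.config, "seeds": self.seeds,
                   "version": self.version, "stages": self.stages,
                   "outputs": self.outputs}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=str))


# -- criteria from solved sequences -----------------------------------------

def _envelope_pct(solution: SequenceSolution, members) -> np.ndarray:
    traces = np.array([solution.activity_trace(a.name) for a in members])
    return group_envelope(traces)


def sequence_criteria(solution: SequenceSolution, model: BodyModel
                      ) -> dict[str, float]:
    """The 13 per-sequence stress criteria from a no-exo solution."""
    times = solution.times
    out: dict[str, float] = {}
    for group in cfgmod.MUSCLE_GROUPS:
        env = _envelope_pct(solution, group_members(model, group))
        out[f"ma_integral:{group}"] = integrate_activity(env, times)
    env_all = _envelope_pct(solution, model.actuators)
    out["ma_integral:whole_body"] = integrate_activity(env_all, times)
    for joint in BILATERAL_JOINTS:
        reactions = {s: solution.reaction_trace(f"{joint}_{s}")
                     for s in ("r", "l")}
        _, jf_max, _ = resultant_joint_force(reactions, "bilateral_average")
        out[f"jf_max:{_JOINT_LABEL[joint]}"] = jf_max
    lum = solution.reaction_trace("lumbar")
    axes = np.array([f.spine_axis for f in solution.frames])
    _, jf_max, _ = resultant_joint_force(lum, "single", spine_axes=axes,
                                         compressive=True)
    out["jf_max:l4l5"] = jf_max
    return out


def concept_criteria(solution: SequenceSolution, model: BodyModel
                     ) -> dict[str, float]:
    """The 8 concept-rating criteria from an exo-coupled solution."""
    out: dict[str, float] = {}
    for group, label in (("shoulders", "shoulders"),
                         ("lower_back", "lower_back")):
        env = _envelope_pct(solution, group_members(model, group))
        out[f"ma_mean:{label}"] = float(env.mean())
    gh = {s: solution.reaction_trace(f"gh_{s}") for s in ("r", "l")}
    _, _, jf_mean = resultant_joint_force(gh, "bilateral_average")
    out["jf_mean:glenohumeral"] = jf_mean
    lum = solution.reaction_trace("lumbar")
    axes = np.array([f.spine_axis for f in solution.frames])
    _, _, jf_mean = resultant_joint_force(lum, "single", spine_axes=axes,
                                          compressive=True)
    out["jf_mean:l4l5"] = jf_mean
    if solution.frames and solution.frames[0].bracing_frames:
        summary = summarize_loads(trace_from_solution(solution, "r"),
                                  trace_from_solution(solution, "l"))
        out["interface_force:distoproximal"] = summary.mean[
            "force_distoproximal"]
        out["interface_force:lateromedial"] = summary.mean[
            "force_lateromedial"]
        out["interface_torque:distoproximal"] = summary.mean[
            "torque_distoproximal"]
        out["interface_torque:craniocaudal"] = summary.mean[
            "torque_craniocaudal"]
    return out


# -- stage A ----------------------------------------------------------------

def default_tasks() -> dict[str, TaskSpec]:
    """The six emulated sequences: carry/lift/lower of box A and box B."""
    box_a = ((0.45, 0.25, 0.27), "top_handle_plus_support")
    box_b = ((0.44, 0.26, 0.14), "two_lateral_handles")
    seqs = {}
    for name, (dims, grip), kind in [
            ("T1", box_a, "carry"), ("T2", box_a, "lift"),
            ("T3", box_a, "lower"), ("T4", box_b, "carry"),
            ("T5", box_b, "lift"), ("T6", box_b, "lower")]:
        seqs[name] = TaskSpec(21.0, dims, 1.46, grip, kind)
    return seqs


# lowering is quicker and carrying slower than the lift itself, so the
# cumulative (time-integrated) stress criteria can distinguish them
DURATION_FACTORS = {"carry": 1.2, "lift": 1.0, "lower": 0.75}


def _generate(task: TaskSpec, anthro, duration, rate, seed, cfg, model):
    gen = {"lift": generate_lift_trajectory,
           "lower": generate_lower_trajectory,
           "carry": generate_carry_trajectory}[task.sequence_type]
    duration = duration * DURATION_FACTORS[task.sequence_type]
    return gen(anthro, task, duration=duration, rate=rate, seed=seed,
               config=cfg, model=model)


def stage_a(config: dict | None = None, from_table=None, seed: int = 0,
            tasks: dict[str, TaskSpec] | None = None,
            duration: float = 2.0, rate: float = 10.0,
            frame_stride: int = 1) -> dict:
    """Rank motion sequences; report the most strenuous one.

    ``from_table`` may be "bundled", a (means, sds) tuple, or a path to
    a CSV with criteria rows and sequence columns.
    """
    cfg = config or cfgmod.default_config()
    if from_table is not None:
        means, sds = _resolve_table(from_table, datasets.sequence_table)
        table = RankingTable(
            values=means, sds=sds, direction="max_is_selected",
            tie_policy=cfg["ranking"]["sequence_tie_policy"],
            weights=cfg["ranking"]["weights"]).rank()
        return {"mode": "from_table", "table": table,
                "scores": table.scores, "selected": table.selected}

    anthro = Anthropometry(**cfg["anthropometry"])
    model = build_body(anthro, cfg)
    tasks = tasks or default_tasks()
    values, failures = {}, {}
    for name, task in tasks.items():
        try:
            traj = _generate(task, anthro, duration, rate, seed, cfg, model)
            sol = run_sequence(model, traj, mode="no_exo", config=cfg,
                               frame_stride=frame_stride)
            values[name] = sequence_criteria(sol, model)
        except LiftsimError as err:
            raise type(err)(f"sequence {name}: {err}") from err
    frame = pd.DataFrame(values)
    missing = frame.isna()
    if missing.any().any():
        raise IncompleteTableError("criteria table has missing cells")
    table = RankingTable(values=frame, direction="max_is_selected",
                         tie_policy="stable_order",
                         weights=cfg["ranking"]["weights"]).rank()
    return {"mode": "simulate", "criteria": frame, "table": table,
            "scores": table.scores, "selected": table.selected,
            "failures": failures}


# -- stage B ----------------------------------------------------------------

def stage_b(config: dict | None = None, from_table=None, seed: int = 0,
            variants: list[ExoVariant] | None = None,
            duration: float = 2.0, rate: float = 10.0,
            frame_stride: int = 1, run_ideal: bool = False) -> dict:
    """Screen and rate exoskeleton concepts on the selected lift."""
    cfg = config or cfgmod.default_config()
    if from_table is not None:
        values, sds = _resolve_table(from_table, datasets.concept_table)
        table = RankingTable(
            values=values, sds=sds, direction="min_is_selected",
            tie_policy=cfg["ranking"]["concept_tie_policy"],
            weights=cfg["ranking"]["weights"]).rank()
        return {"mode": "from_table", "table": table,
                "scores": table.scores, "selected": table.selected}

    catalog = variants if variants is not None else enumerate_variants(
        cfg["exo"]["structure_mass"])
    screen = {v.id: feasibility_screen(v) for v in catalog}
    passed = [v for v in catalog if screen[v.id].passed]

    anthro = Anthropometry(**cfg["anthropometry"])
    model = build_body(anthro, cfg)
    task = default_tasks()["T5"]
    traj = generate_lift_trajectory(anthro, task, duration=duration,
                                    rate=rate, seed=seed, config=cfg,
                                    model=model)
    baseline = run_sequence(model, traj, mode="no_exo", config=cfg,
                            frame_stride=frame_stride)
    base_crit = concept_criteria(baseline, model)

    ideal = None
    if run_ideal and passed:
        coupled = attach_exo(model, passed[0], cfg)
        ideal = run_sequence(coupled, traj, mode="ideal_actuator",
                             config=cfg, frame_stride=frame_stride)

    results, failures = {}, {}
    for variant in passed:
        try:
            coupled = attach_exo(model, variant, cfg)
            sol = run_sequence(coupled, traj, mode="prescribed_torque",
                               config=cfg, frame_stride=frame_stride)
            results[variant.id] = concept_criteria(sol, model)
        except (KinematicFailureError, RecruitmentInfeasibleError) as err:
            failures[variant.id] = f"{type(err).__name__}: {err}"
    if not results:
        raise IncompleteTableError("no concept produced a complete result")
    frame = pd.DataFrame(results)[list(results)]
    table = RankingTable(values=frame.loc[CONCEPT_CRITERIA],
                         direction="min_is_selected",
                         tie_policy="stable_order",
                         weights=cfg["ranking"]["weights"]).rank()
    reductions = {
        vid: {c: reduction_percent(base_crit[c], res[c])
              for c in ("ma_mean:shoulders", "ma_mean:lower_back",
                        "jf_mean:glenohumeral", "jf_mean:l4l5")}
        for vid, res in results.items()}
    return {"mode": "simulate", "criteria": frame, "table": table,
            "scores": table.scores, "selected": table.selected,
            "screen": {k: (s.passed, s.reason) for k, s in screen.items()},
            "baseline": base_crit, "reductions": reductions,
            "failures": failures, "ideal": ideal}


def _resolve_table(from_table, bundled):
    if isinstance(from_table, str) and from_table == "bundled":
        return bundled()
    if isinstance(from_table, tuple):
        return from_table
    means = pd.read_csv(from_table, index_col=0)
    sd_path = Path(str(from_table)).with_suffix(".sds.csv")
    sds = pd.read_csv(sd_path, index_col=0) if sd_path.exists() else None
    return means, sds


# -- report -----------------------------------------------------------------

def report(stage_a_result: dict | None, stage_b_result: dict | None,
           manifest: RunManifest | None = None) -> str:
    """Human-readable summary of completed stage outputs."""
    lines = ["liftsim run report", "=" * 40]
    missing = []
    for label, result, noun in (("Stage A (sequence ranking)",
                                 stage_a_result, "sequence"),
                                ("Stage B (concept rating)",
                                 stage_b_result, "concept")):
        lines.append("")
        lines.append(label)
        lines.append("-" * len(label))
        if result is None:
            lines.append("missing")
            missing.append(label)
            continue
        scores = result["scores"]
        for alt, score in scores.items():
            lines.append(f"  {alt:<24s} {score:6.1f}")
        lines.append(f"  selected {noun}: {result['selected']}")
        if result.get("failures"):
            for vid, reason in result["failures"].items():
                lines.append(f"  failed: {vid}: {reason}")
    if manifest is not None:
        lines.append("")
        lines.append(f"outputs: {len(manifest.outputs)} files")
    return "\n".join(lines) + "\n"
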