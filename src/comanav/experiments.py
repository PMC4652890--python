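"""Reproducible experiment orchestration.

An :class:`ExperimentSpec` bundles an environment description, a simulation
configuration and a starting-position set; :func:`run_experiment` executes
every start, writes trajectory and control logs plus a machine-readable
summary, and (when a goal and enough obstacles exist) the route analysis.
All randomness flows from a single master seed through named, independent
sub-streams (texture, placement, per-trajectory segment jitter, goal noise),
and every output carries the spec hash, so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import environments as envs
from .environments import Environment
from .routes import (cluster_routes, delaunay_mesh, efficiency_metrics,
                     linkage_to_json, route_dendrogram, trajectory_sequence)
from .simulate import SimulationConfig, Simulator, start_positions

__all__ = ["ExperimentSpec", "run_experiment", "subseed", "PRESETS",
           "make_preset"]


def subseed(master_seed: int, role: str) -> int:
    """Derive an independent, documented sub-seed (< 2^31) for a named role.

    Same (master, role) always gives the same seed; different roles give
    statistically independent streams.
    """
    digest = hashlib.sha256(role.encode()).digest()
    role_key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(master_seed), role_key])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentSpec:
    """Fully serializable description of one experiment."""

    name: str
    environment_yaml: str
    sim: SimulationConfig
    n_starts: int = 4
    start_mode: str = "grid"
    master_seed: int = 0
    analyze_routes: bool = True

    def spec_hash(self) -> str:
        doc = {"name": self.name, "environment": self.environment_yaml,
               "sim": {k: (v if not hasattr(v, "__dict__") else asdict(v))
                       for k, v in asdict(self.sim).items()},
               "n_starts": self.n_starts, "start_mode": self.start_mode,
               "master_seed": self.master_seed}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_experiment(spec: ExperimentSpec, out_dir: str | Path | None = None
                   ) -> dict:
    """Run all starts of an experiment; optionally write the output bundle.

    Returns the summary dict (crash / goal / dead-end counts, route count,
    efficiency statistics, spec hash).  When ``out_dir`` is given, writes
    ``trajectory_<i>.csv``, ``control_<i>.csv``, ``routes.csv``,
    ``distance_matrix.csv``, ``linkage.json`` and ``summary.json``.
    """
    try:
        env = envs.environment_from_yaml(spec.environment_yaml)
    except (KeyError, TypeError, ValueError, yaml.YAMLError) as err:
        raise ValueError(f"invalid experiment spec: {err}") from err
    if spec.n_starts < 1:
        raise ValueError("invalid experiment spec: need at least one start")

    sim_cfg = replace(spec.sim,
                      seed=subseed(spec.master_seed, "segment-directions"))
    simulator = Simulator(env, sim_cfg)
    starts = start_positions(env, spec.n_starts, mode=spec.start_mode)
    trajectories = []
    for i, (x, y, heading) in enumerate(starts):
        seed = subseed(spec.master_seed, f"segment-directions/{i}")
        trajectories.append(simulator.run((x, y), heading, seed=seed))

    outcomes = [{"timeout": "dead-end"}.get(t.outcome, t.outcome)
                for t in trajectories]
    summary: dict = {
        "name": spec.name,
        "spec_hash": spec.spec_hash(),
        "master_seed": spec.master_seed,
        "n_starts": len(starts),
        "crashes": outcomes.count("crash"),
        "goals": outcomes.count("goal"),
        "dead_ends": outcomes.count("dead-end"),
    }

    route_artifacts = {}
    if spec.analyze_routes and len(env.obstacles) >= 3 and env.goal is not None:
        mesh = delaunay_mesh(np.array([ob.center for ob in env.obstacles]))
        seqs = [trajectory_sequence(t, mesh, i)
                for i, t in enumerate(trajectories)]
        goal_seqs = [s for s, o in zip(seqs, outcomes) if o == "goal"]
        routeset = cluster_routes(goal_seqs) if goal_seqs else None
        report = efficiency_metrics(trajectories, env, env.goal,
                                    inflation=sim_cfg.collision_radius)
        summary["n_routes"] = routeset.n_routes if routeset else 0
        eff = report["efficiency"].dropna()
        summary["efficiency_min"] = float(eff.min()) if len(eff) else None
        summary["efficiency_mean"] = float(eff.mean()) if len(eff) else None
        summary["reliability_pct_crash"] = float(
            100.0 * summary["crashes"] / summary["n_starts"])
        route_artifacts = {"mesh": mesh, "sequences": seqs,
                           "routeset": routeset, "report": report}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "environment.yaml").write_text(spec.environment_yaml)
        for i, tr in enumerate(trajectories):
            df = tr.to_dataframe()
            df.insert(0, "spec_hash", spec.spec_hash())
            df.to_csv(out / f"trajectory_{i}.csv", index=False)
            tr.control_log().to_csv(out / f"control_{i}.csv", index=False)
        if route_artifacts.get("routeset"):
            rs = route_artifacts["routeset"]
            rows = [{"route": rid, "members": len(rs.members[rid]),
                     "sequence": " ".join(map(str, rs.routes[rid]))}
                    for rid in rs.routes]
            import pandas as pd
            pd.DataFrame(rows).to_csv(out / "routes.csv", index=False)
            if rs.n_routes >= 2:
                (out / "linkage.json").write_text(
                    linkage_to_json(route_dendrogram(rs)))
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    summary["trajectories"] = trajectories
    summary.update(route_artifacts)
    return summary


# ---------------------------------------------------------------------------
# experiment presets mirroring the published simulation designs
# ---------------------------------------------------------------------------

def make_preset(name: str, master_seed: int = 0, **overrides) -> ExperimentSpec:
    """Named experiment presets.

    ``box-textures`` — 40 cm cubic box, detector-based agent, four starts,
    10 s, gain 2 / threshold 4 (run once per wall texture).
    ``clutter-goal`` — 35-obstacle cluttered corridor with the goal at the
    far end, detector-based agent, gain 2 / threshold 4.
    ``clutter-goal-geometric`` — same but with ground-truth flow (fast).
    """
    tex_seed = subseed(master_seed, "texture")
    if name.startswith("box"):
        texel = float(overrides.pop("texel_size_mm", 1.0))
        tex = envs.make_random_checkerboard(
            texel, (400.0, 400.0), tex_seed)
        env = envs.make_cubic_box(wall_texture=tex, seed=tex_seed)
        sim = SimulationConfig(flow_source="emd", g=2.0, n0=4.0,
                               max_time_s=10.0, **overrides)
        return ExperimentSpec(name=f"box-{texel:g}mm",
                              environment_yaml=envs.environment_to_yaml(env),
                              sim=sim, n_starts=4, master_seed=master_seed)
    if name.startswith("clutter"):
        geometric = name.endswith("geometric")
        n_starts = int(overrides.pop("n_starts", 4))
        env = envs.make_cluttered_environment(
            seed=subseed(master_seed, "placement"),
            texel_size_mm=float(overrides.pop("texel_size_mm", 1.0)))
        env = env.with_goal((0.9 * env.width, env.depth / 2.0))
        sim = SimulationConfig(
            flow_source="geometric" if geometric else "emd",
            g=2.0, n0=4.0, goal=env.goal, max_time_s=60.0,
            flight_height=0.1, **overrides)
        return ExperimentSpec(name=name,
                              environment_yaml=envs.environment_to_yaml(env),
                              sim=sim, n_starts=n_starts,
                              start_mode="band", master_seed=master_seed)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("box-textures", "clutter-goal", "clutter-goal-geometric")
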