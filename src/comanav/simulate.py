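"""Closed-loop saccadic flight.

The agent alternates 50 ms translational intersaccades (50 one-millisecond
segments whose motion directions jitter around the heading with an 18 deg SD,
heading itself unchanged) with saccadic yaw turns whose amplitude is the
steering command computed from the flow integrated during the intersaccade.
Speed is 0.1 m/s throughout; the agent keeps translating along the
instantaneous heading during saccades, and the motion-detector filters keep
running, so saccadic history contaminates early intersaccadic responses just
as it does in the modeled insect.

Flight is confined to a constant height (mid-height of the arena by default).
A run ends on collision (surface distance below the collision radius), on
reaching the goal, or at the simulated-time limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._raycast import surface_distance
from .control import (ControlOutput, SquaredFlowAccumulator,
                      control_from_integrated, wrap_deg)
from .emd import EMD, EMDParams
from .environments import Environment
from .retina import Eye, Pose, RetinaGeometry

__all__ = [
    "SimulationConfig",
    "SaccadeProfile",
    "Trajectory",
    "Simulator",
    "simulate",
    "make_saccade_profile",
    "detect_collision",
    "start_positions",
]

PHASE_INTERSACCADE = 0
PHASE_SACCADE = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Closed-loop parameters.

    ``flow_source`` selects the sensing pathway: ``"geometric"`` uses
    ground-truth optic flow integrated over the whole 50 ms intersaccade;
    ``"emd"`` runs the motion-detector front end every millisecond and
    integrates only the last ``emd_window_ms`` of each intersaccade (the
    earlier part is contaminated by the preceding saccade).

    ``goal`` is a world (x, y) position or ``None`` for keep-straight mode
    (goal direction fixed to zero).  ``nearness_refresh_ticks`` controls how
    often the geometric pathway re-casts the ground-truth nearness map within
    an intersaccade (the agent moves 0.1 mm per tick, so modest striding is
    indistinguishable; 1 = every tick).
    """

    dt_ms: float = 1.0
    intersaccade_ms: float = 50.0
    segment_sd_deg: float = 18.0
    speed: float = 0.1
    flow_source: str = "geometric"
    g: float = 2.0
    n0: float = 4.0
    goal: tuple[float, float] | None = None
    goal_sigma_deg: float = 0.0
    collision_radius: float = 0.01
    goal_radius: float = 0.05
    max_time_s: float = 10.0
    seed: int = 0
    flight_height: float | None = None
    supersample: int = 2
    emd_window_ms: float = 5.0
    nearness_refresh_ticks: int = 1
    emd_params: EMDParams = field(default_factory=EMDParams)

    def __post_init__(self) -> None:
        if self.flow_source not in ("geometric", "emd"):
            raise ValueError("flow_source must be 'geometric' or 'emd'")
        if self.segment_sd_deg < 0:
            raise ValueError("segment direction SD must be >= 0")
        n = self.intersaccade_ms / self.dt_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("durations must be multiples of dt")


@dataclass(frozen=True)
class SaccadeProfile:
    """Per-tick yaw-velocity samples of one saccade (Gaussian profile).

    The samples follow a Gaussian centered at mid-duration (sigma = D/6,
    truncated at +/-3 sigma) and are renormalized so that the integrated turn
    equals the amplitude exactly.
    """

    amplitude_deg: float
    duration_ms: float
    yaw_deg_per_s: np.ndarray


def make_saccade_profile(gamma_deg: float, dt_ms: float = 1.0) -> SaccadeProfile:
    """Saccade template: duration D = max(10, 30 + 20 |gamma| / 90) ms.

    The affine duration rule spans the 10-80 ms range reported for fly
    saccades; the velocity profile is the Gaussian template renormalized so
    that sum(yaw * dt) == gamma to machine precision.
    """
    if abs(gamma_deg) > 180.0 + 1e-9:
        raise ValueError("saccade amplitude must satisfy |gamma| <= 180 deg")
    duration = max(10.0, 30.0 + 20.0 * abs(gamma_deg) / 90.0)
    n = max(1, int(round(duration / dt_ms)))
    duration = n * dt_ms          # realized duration on the tick grid
    t = (np.arange(n) + 0.5) * dt_ms
    sigma = duration / 6.0
    shape = np.exp(-0.5 * ((t - duration / 2.0) / sigma) ** 2)
    dt_s = dt_ms * 1e-3
    total = shape.sum() * dt_s
    yaw = shape * (gamma_deg / total) if gamma_deg != 0.0 else np.zeros(n)
    return SaccadeProfile(amplitude_deg=float(gamma_deg),
                          duration_ms=n * dt_ms, yaw_deg_per_s=yaw)


def detect_collision(env: Environment, position: np.ndarray,
                     radius: float = 0.01) -> bool:
    """True iff the distance to the nearest surface is strictly below radius."""
    return surface_distance(env, position) < radius


@dataclass
class Trajectory:
    """Timestamped pose history of one run plus its per-saccade decisions."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray
    phase: np.ndarray
    outcome: str                    # "goal" | "crash" | "timeout"
    saccades: list[ControlOutput]
    seed: int
    events: list[dict] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms, "x_m": self.x, "y_m": self.y,
            "heading_deg": self.heading_deg,
            "phase": np.where(self.phase == PHASE_SACCADE,
                              "saccade", "intersaccade"),
        })

    def control_log(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_row() for s in self.saccades])


class Simulator:
    """Closed-loop simulator bound to one environment and configuration."""

    def __init__(self, env: Environment, config: SimulationConfig):
        self.env = env
        self.config = config
        self.geometry = RetinaGeometry()
        self.eye = Eye(env, self.geometry, supersample=config.supersample)
        height = (env.height / 2.0 if config.flight_height is None
                  else config.flight_height)
        self.flight_height = height
        self._sin_eps = np.sin(self.geometry.eps_rad)[:, None]
        self._phi = self.geometry.phi_rad[None, :]

    # -- flow sensing -------------------------------------------------------

    def _planar_flow(self, mu: np.ndarray, speed: float, delta_rad: float
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form translational flow for motion direction delta (agent
        frame): OF_phi = v mu sin(phi - delta), OF_eps = v mu sin(eps)
        cos(phi - delta)."""
        rel = self._phi - delta_rad
        vmu = speed * mu
        return vmu * np.sin(rel), vmu * self._sin_eps * np.cos(rel)

    # -- main loop ----------------------------------------------------------

    def run(self, start_xy: tuple[float, float], start_heading_deg: float,
            seed: int | None = None) -> Trajectory:
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        dt_s = cfg.dt_ms * 1e-3
        n_seg = int(round(cfg.intersaccade_ms / cfg.dt_ms))
        emd_window = int(round(cfg.emd_window_ms / cfg.dt_ms))
        max_ticks = int(round(cfg.max_time_s * 1e3 / cfg.dt_ms))

        pos = np.array([start_xy[0], start_xy[1], self.flight_height])
        heading = float(wrap_deg(start_heading_deg))
        if detect_collision(self.env, pos, cfg.collision_radius):
            raise ValueError("start pose is already in collision")

        emd = EMD(cfg.emd_params) if cfg.flow_source == "emd" else None
        acc = SquaredFlowAccumulator(cfg.flow_source)

        t_ms, xs, ys, hs, ph = [], [], [], [], []
        saccades: list[ControlOutput] = []
        events: list[dict] = []
        outcome = "timeout"
        tick = 0

        def record(phase: int) -> None:
            t_ms.append(tick * cfg.dt_ms)
            xs.append(pos[0])
            ys.append(pos[1])
            hs.append(heading)
            ph.append(phase)

        def check_end() -> str | None:
            if detect_collision(self.env, pos, cfg.collision_radius):
                return "crash"
            if cfg.goal is not None:
                if np.hypot(pos[0] - cfg.goal[0],
                            pos[1] - cfg.goal[1]) < cfg.goal_radius:
                    return "goal"
            return None

        record(PHASE_INTERSACCADE)
        mu = None
        done = False
        while tick < max_ticks and not done:
            # ---- intersaccade: pure translation with jittered direction ----
            acc.reset()
            for i in range(n_seg):
                if tick >= max_ticks:
                    break
                delta = rng.normal(0.0, cfg.segment_sd_deg)
                move = np.deg2rad(heading + delta)
                pos[0] += cfg.speed * dt_s * np.cos(move)
                pos[1] += cfg.speed * dt_s * np.sin(move)
                tick += 1
                record(PHASE_INTERSACCADE)
                end = check_end()
                if end:
                    outcome = end
                    events.append({"t_ms": tick * cfg.dt_ms, "event": end})
                    done = True
                    break
                pose = Pose(position=pos.copy(), heading_deg=heading)
                if cfg.flow_source == "geometric":
                    if mu is None or i % cfg.nearness_refresh_ticks == 0:
                        mu = self.eye.nearness(pose)
                    of_phi, of_eps = self._planar_flow(
                        mu, cfg.speed, np.deg2rad(delta))
                    acc.add_geometric(of_phi, of_eps)
                else:
                    img = self.eye.render(pose)
                    rh, rv = emd.step(img)
                    if i >= n_seg - emd_window:
                        acc.add_emd(rh, rv)
            if done or tick >= max_ticks:
                break
            mu = None  # the map is stale after the saccade

            # ---- decide ----------------------------------------------------
            if cfg.goal is not None:
                bearing = np.degrees(np.arctan2(cfg.goal[1] - pos[1],
                                                cfg.goal[0] - pos[0]))
                alpha = wrap_deg(bearing - heading)
            else:
                alpha = 0.0
            ctrl = control_from_integrated(
                acc.result(), g=cfg.g, n0=cfg.n0, alpha_deg=alpha,
                sigma_deg=cfg.goal_sigma_deg, rng=rng,
                geometry=self.geometry, time_ms=tick * cfg.dt_ms)
            saccades.append(ctrl)

            # ---- saccade: yaw turn, translation continues ------------------
            profile = make_saccade_profile(ctrl.gamma_deg, cfg.dt_ms)
            for yaw in profile.yaw_deg_per_s:
                if tick >= max_ticks:
                    break
                heading = float(wrap_deg(heading + yaw * dt_s))
                move = np.deg2rad(heading)
                pos[0] += cfg.speed * dt_s * np.cos(move)
                pos[1] += cfg.speed * dt_s * np.sin(move)
                tick += 1
                record(PHASE_SACCADE)
                end = check_end()
                if end:
                    outcome = end
                    events.append({"t_ms": tick * cfg.dt_ms, "event": end})
                    done = True
                    break
                if emd is not None:
                    pose = Pose(position=pos.copy(), heading_deg=heading)
                    emd.step(self.eye.render(pose))

        return Trajectory(
            t_ms=np.asarray(t_ms), x=np.asarray(xs), y=np.asarray(ys),
            heading_deg=np.asarray(hs), phase=np.asarray(ph, dtype=np.int8),
            outcome=outcome, saccades=saccades, seed=seed, events=events)


def simulate(env: Environment, config: SimulationConfig,
             start_xy: tuple[float, float],
             start_heading_deg: float = 0.0) -> Trajectory:
    """One closed-loop run (builds a fresh :class:`Simulator`)."""
    return Simulator(env, config).run(start_xy, start_heading_deg)


def open_loop_control(
    env: Environment,
    start_xy: tuple[float, float],
    heading_deg: float,
    config: SimulationConfig | None = None,
    n_intersaccades: int = 3,
    emd_full_window: bool = True,
    average_intersaccades: int = 1,
) -> tuple[ControlOutput, ControlOutput]:
    """Open-loop probe: translate through ``n_intersaccades`` jittered
    intersaccades (no saccades) and return the steering decision that each
    sensing pathway would take, as ``(emd, geometric)``.

    Without saccades there is no rotational contamination of the detector
    filters, so the detector pathway integrates the full final intersaccade
    by default (set ``emd_full_window=False`` for the closed-loop 5 ms
    window).  ``average_intersaccades`` pools the integrated squared flow of
    that many final intersaccades (the agent moves only 5 mm per
    intersaccade, so this estimates the expected steering signal at the
    position).  This realizes the translating-parallel-to-a-wall
    measurements of the open-loop nearness/COMANV analyses.
    """
    from .retina import RetinaGeometry as _RG  # local alias for clarity

    cfg = config or SimulationConfig()
    geometry = _RG()
    eye = Eye(env, geometry, supersample=cfg.supersample)
    height = env.height / 2.0 if cfg.flight_height is None else cfg.flight_height
    rng = np.random.default_rng(cfg.seed)
    emd = EMD(cfg.emd_params)
    acc_e = SquaredFlowAccumulator("emd")
    acc_g = SquaredFlowAccumulator("geometric")
    n_seg = int(round(cfg.intersaccade_ms / cfg.dt_ms))
    emd_window = n_seg if emd_full_window else int(round(cfg.emd_window_ms
                                                         / cfg.dt_ms))
    dt_s = cfg.dt_ms * 1e-3
    phi = geometry.phi_rad[None, :]
    sin_eps = np.sin(geometry.eps_rad)[:, None]
    pos = np.array([start_xy[0], start_xy[1], height])

    first_pooled = n_intersaccades - max(1, average_intersaccades)
    for k in range(n_intersaccades):
        if k <= first_pooled:
            acc_e.reset()
            acc_g.reset()
        for i in range(n_seg):
            delta = rng.normal(0.0, cfg.segment_sd_deg)
            move = np.deg2rad(heading_deg + delta)
            pos[0] += cfg.speed * dt_s * np.cos(move)
            pos[1] += cfg.speed * dt_s * np.sin(move)
            pose = Pose(position=pos.copy(), heading_deg=heading_deg)
            rh, rv = emd.step(eye.render(pose))
            if i >= n_seg - emd_window:
                acc_e.add_emd(rh, rv)
            mu = eye.nearness(pose)
            rel = phi - np.deg2rad(delta)
            acc_g.add_geometric(cfg.speed * mu * np.sin(rel),
                                cfg.speed * mu * sin_eps * np.cos(rel))
    out_e = control_from_integrated(acc_e.result(), g=cfg.g, n0=cfg.n0,
                                    geometry=geometry)
    out_g = control_from_integrated(acc_g.result(), g=cfg.g, n0=cfg.n0,
                                    geometry=geometry)
    return out_e, out_g


def start_positions(
    env: Environment,
    n: int,
    margin_frac: float = 0.2,
    clearance: float = 0.05,
    mode: str = "grid",
) -> list[tuple[float, float, float]]:
    """Canonical starting sets: (x, y, heading_deg) tuples.

    ``mode="grid"`` spreads starts over the arena interior (shrunk by
    ``margin_frac`` per side) on a near-square grid, headings toward the goal
    if one is set, else toward the arena center.  ``mode="band"`` places the
    starts in the entry band at low x (for corridor runs toward a far goal).
    ``n == 4`` in a box uses the four diagonal quarter positions.  Positions
    closer than ``clearance`` to a surface are nudged to the nearest free
    grid point.
    """
    w, d = env.width, env.depth
    cx, cy = env.center

    def heading_from(x: float, y: float) -> float:
        tx, ty = env.goal if env.goal is not None else (cx, cy)
        if abs(tx - x) < 1e-12 and abs(ty - y) < 1e-12:
            return 0.0
        return float(np.degrees(np.arctan2(ty - y, tx - x)))

    pts: list[tuple[float, float]] = []
    if mode == "band":
        x0 = margin_frac * w / 2.0 + 0.05 * w
        ys = np.linspace(margin_frac * d, d * (1 - margin_frac), n)
        pts = [(x0, float(y)) for y in ys]
    elif n == 4 and abs(w - d) < 1e-9:
        off = 0.25 * w
        pts = [(cx - off, cy - off), (cx + off, cy - off),
               (cx + off, cy + off), (cx - off, cy + off)]
    else:
        nx = max(1, int(np.ceil(np.sqrt(n * w / d))))
        ny = int(np.ceil(n / nx))
        gx = np.linspace(margin_frac * w, w * (1 - margin_frac), nx)
        gy = np.linspace(margin_frac * d, d * (1 - margin_frac), ny)
        pts = [(float(x), float(y)) for y in gy for x in gx][:n]

    out = []
    for x, y in pts:
        p = np.array([x, y, env.height / 2.0])
        if surface_distance(env, p) < clearance:
            # nudge radially until clear of the nearest obstacle
            for r in np.linspace(clearance, 4 * clearance, 8):
                for a in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                    q = p + np.array([r * np.cos(a), r * np.sin(a), 0.0])
                    if (env.contains(q[0], q[1], margin=clearance)
                            and surface_distance(env, q) >= clearance):
                        p = q
                        break
                else:
                    continue
                break
        out.append((float(p[0]), float(p[1]), heading_from(p[0], p[1])))
    return out
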