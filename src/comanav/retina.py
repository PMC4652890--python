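"""Spherical eye sampling and geometric optic flow.

The eye samples the full sphere on a cylindrical-projection grid: 91 elevation
rows (-90..+90 deg, 2 deg spacing, 0 deg = equator) by 181 azimuth columns
(-180..+180 deg, 2 deg spacing; the two endpoint columns are the same physical
direction and are kept for grid regularity).  Azimuth 0 is the agent's
heading; positive azimuth is counter-clockwise seen from above.

Rendering casts central rays on a supersampled grid, applies the Gaussian
spatial low-pass of the photoreceptor lattice (sigma = 2 deg, truncated at
2 sigma) in image space and subsamples to the receptor grid.  Ground-truth
nearness (inverse ray distance) and the geometric optic flow computed from it
serve as the texture-independent benchmark for the motion-detector pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._raycast import CompiledScene, cast_grid, cast_ray, surface_distance
from .environments import Environment

__all__ = [
    "RetinaGeometry",
    "Pose",
    "Eye",
    "render",
    "nearness_truth",
    "geometric_flow",
    "cast_ray",
    "surface_distance",
    "save_map_csv",
    "save_map_png",
]

N_ROWS = 91
N_COLS = 181
SPACING_DEG = 2.0
BLUR_SIGMA_DEG = 2.0


@dataclass(frozen=True)
class RetinaGeometry:
    """Receptor directions and local flow bases on the spherical eye."""

    eps_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(-90.0, 90.0, N_ROWS))
    phi_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(-180.0, 180.0, N_COLS))

    @property
    def eps_rad(self) -> np.ndarray:
        return np.deg2rad(self.eps_deg)

    @property
    def phi_rad(self) -> np.ndarray:
        return np.deg2rad(self.phi_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.eps_deg.size, self.phi_deg.size)

    def directions(self) -> np.ndarray:
        """Unit viewing directions in the agent frame, shape (rows, cols, 3).

        Agent frame: x forward (heading), y left, z up.
        """
        eps = self.eps_rad[:, None]
        phi = self.phi_rad[None, :]
        return np.stack(
            [np.cos(eps) * np.cos(phi),
             np.cos(eps) * np.sin(phi),
             np.broadcast_to(np.sin(eps), (self.eps_deg.size, self.phi_deg.size))],
            axis=-1,
        )

    def basis_phi(self) -> np.ndarray:
        """Unit vector along increasing azimuth, shape (rows, cols, 3).

        Defined by continuity at the poles (where azimuth is degenerate).
        """
        phi = self.phi_rad[None, :]
        e = np.stack(
            [-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
        return np.broadcast_to(e, (*self.shape, 3)).copy()

    def basis_eps(self) -> np.ndarray:
        """Unit vector along increasing elevation, shape (rows, cols, 3)."""
        eps = self.eps_rad[:, None]
        phi = self.phi_rad[None, :]
        return np.stack(
            [-np.sin(eps) * np.cos(phi),
             -np.sin(eps) * np.sin(phi),
             np.broadcast_to(np.cos(eps), self.shape)],
            axis=-1,
        )


@dataclass(frozen=True)
class Pose:
    """Agent state: planar position at fixed flight height, heading and motion.

    ``heading_deg`` is the gaze/body direction (world frame, CCW from +x seen
    from above).  ``velocity`` is the world-frame linear velocity (m/s); flight
    is confined to the plane of constant ``position[2]``.  ``yaw_rate_deg``
    is the angular velocity about the vertical axis.
    """

    position: np.ndarray
    heading_deg: float
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    yaw_rate_deg: float = 0.0
    time_ms: float = 0.0

    @property
    def speed(self) -> float:
        return float(np.linalg.norm(self.velocity))


class Eye:
    """Renderer bound to one environment.

    Precompiles the scene and the angular grid so that per-tick rendering only
    rotates the azimuth table by the current heading and casts rays.
    ``supersample`` rays are cast per receptor spacing in each direction before
    the 2 deg Gaussian blur (the spec of the photoreceptor lattice) and
    subsampling; 2 is a good speed/fidelity compromise for closed-loop runs,
    4 is used for open-loop maps.
    """

    def __init__(self, env: Environment, geometry: RetinaGeometry | None = None,
                 supersample: int = 2):
        if supersample < 1:
            raise ValueError("supersample must be >= 1")
        self.env = env
        self.geometry = geometry or RetinaGeometry()
        self.supersample = int(supersample)
        self.scene = CompiledScene.from_environment(env)

        s = self.supersample
        step = SPACING_DEG / s
        self._fine_eps = np.deg2rad(np.arange(-90.0, 90.0 + step / 2, step))
        self._fine_phi = np.deg2rad(np.arange(-180.0, 180.0 + step / 2, step))
        self._cos_eps = np.cos(self._fine_eps)
        self._sin_eps = np.sin(self._fine_eps)
        # receptor-grid trig (supersample 1) for nearness ground truth
        g = self.geometry
        self._cos_eps1 = np.cos(g.eps_rad)
        self._sin_eps1 = np.sin(g.eps_rad)

    def render(self, pose: Pose) -> np.ndarray:
        """Brightness image on the receptor grid, shape (91, 181), in [0, 1]."""
        s = self.supersample
        phi_w = self._fine_phi + np.deg2rad(pose.heading_deg)
        _, bright = cast_grid(
            self.scene, pose.position,
            self._cos_eps, self._sin_eps, np.cos(phi_w), np.sin(phi_w),
            want_brightness=True, phi=phi_w,
        )
        if s > 1:
            # the duplicated +/-180 deg column would bias the wrap filter
            core = bright[:, :-1]
            core = gaussian_filter1d(core, sigma=float(s), axis=1,
                                     mode="wrap", truncate=2.0)
            core = gaussian_filter1d(core, sigma=float(s), axis=0,
                                     mode="nearest", truncate=2.0)
            bright = np.concatenate([core, core[:, :1]], axis=1)
            img = bright[::s, ::s]
        else:
            core = bright[:, :-1]
            core = gaussian_filter1d(core, sigma=1.0, axis=1,
                                     mode="wrap", truncate=2.0)
            core = gaussian_filter1d(core, sigma=1.0, axis=0,
                                     mode="nearest", truncate=2.0)
            img = np.concatenate([core, core[:, :1]], axis=1)
        return np.clip(img, 0.0, 1.0)

    def nearness(self, pose: Pose) -> np.ndarray:
        """Ground-truth nearness mu = 1/distance (1/m) per receptor direction.

        Central rays only, no blur.  Directions that escape an open
        environment get mu = 0.
        """
        phi_w = self.geometry.phi_rad + np.deg2rad(pose.heading_deg)
        dist, _ = cast_grid(
            self.scene, pose.position,
            self._cos_eps1, self._sin_eps1, np.cos(phi_w), np.sin(phi_w),
            want_brightness=False, phi=phi_w,
        )
        with np.errstate(divide="ignore"):
            mu = 1.0 / dist
        mu[~np.isfinite(mu) | (dist > 1e29)] = 0.0
        return mu


def save_map_csv(values: np.ndarray, path) -> None:
    """Write a retinal map (brightness, nearness, flow component) as a CSV
    matrix: rows are elevations from -90 to +90 deg, columns azimuths from
    -180 to +180 deg."""
    np.savetxt(path, np.asarray(values), delimiter=",", fmt="%.8g")


def save_map_png(values: np.ndarray, path) -> None:
    """Write a retinal map as an 8-bit gray-scale PNG, linearly rescaled to
    its own min/max (top row = +90 deg elevation)."""
    from PIL import Image

    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    img = np.round(255 * scaled[::-1]).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def render(env: Environment, pose: Pose,
           geometry: RetinaGeometry | None = None,
           supersample: int = 2) -> np.ndarray:
    """One-shot render; for repeated calls build an :class:`Eye` once."""
    return Eye(env, geometry, supersample).render(pose)


def nearness_truth(env: Environment, pose: Pose,
                   geometry: RetinaGeometry | None = None) -> np.ndarray:
    """One-shot ground-truth nearness map (see :meth:`Eye.nearness`)."""
    return Eye(env, geometry, supersample=1).nearness(pose)


def geometric_flow(
    nearness: np.ndarray,
    pose: Pose,
    geometry: RetinaGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optic flow (OF_phi, OF_eps) in rad/s from nearness and self-motion.

    For a viewing direction d, translation velocity t and yaw rotation w the
    apparent angular velocity of the image is

        flow = -mu * (t - (t . d) d) - w x d,

    projected on the local basis (e_phi, e_eps).  For pure planar translation
    at speed v in direction phi_t this reduces to
    OF_phi = v mu sin(phi - phi_t) (independent of elevation) and
    OF_eps = v mu sin(eps) cos(phi - phi_t).

    ``nearness`` and ``pose`` must refer to the same instant; the nearness map
    is taken in the agent frame of that pose (azimuth 0 = heading).
    """
    g = geometry or RetinaGeometry()
    if nearness.shape != g.shape:
        raise ValueError(f"nearness shape {nearness.shape} != grid {g.shape}")
    psi = np.deg2rad(pose.heading_deg)
    rot = np.array([[np.cos(psi), np.sin(psi), 0.0],
                    [-np.sin(psi), np.cos(psi), 0.0],
                    [0.0, 0.0, 1.0]])
    t = rot @ np.asarray(pose.velocity, dtype=float)   # velocity, agent frame
    w = np.array([0.0, 0.0, np.deg2rad(pose.yaw_rate_deg)])

    d = g.directions()
    td = d @ t
    trans = -(nearness[..., None] * (t[None, None, :] - td[..., None] * d))
    rotf = -np.cross(np.broadcast_to(w, d.shape), d)
    flow = trans + rotf
    of_phi = np.einsum("ijk,ijk->ij", flow, g.basis_phi())
    of_eps = np.einsum("ijk,ijk->ij", flow, g.basis_eps())
    return of_phi, of_eps
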