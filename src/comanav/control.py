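"""From integrated squared optic flow to the saccade command.

The pipeline implements the steering law of the model:

1. square the per-tick flow components (geometric, rad/s, or detector
   responses) and integrate them over the intersaccadic window;
2. invert the retinotopically modified norm,
   (v mu)^2 = OF_phi^2 + OF_eps^2 / sin^2(eps), to obtain the relative
   nearness v mu per viewing direction (the combination is independent of the
   viewing angle for planar translation on a spherical eye, and the
   mixed-direction integration removes the FOE/FOC singularities);
3. average the nearness map along the elevation -> azimuthal nearness profile;
4. sum the profile as polar vectors -> COMANV, the center-of-mass average
   nearness vector, which points toward the average direction of close
   objects;
5. CAD = direction opposite the COMANV, CAN = ||COMANV||;
6. saccade amplitude gamma = W * CAD + (1 - W) * (alpha + sigma), where
   W = 1 / (1 + (CAN / n0)^-g) is a sigmoid weight with gain g and
   threshold n0, alpha the goal direction and sigma an optional goal noise.

Angles are in degrees relative to the current heading, wrapped to
(-180, 180].  Relative nearness carries units of 1/s for the geometric
source; for the detector source it is in detector units mapped through a
single fixed calibration constant (see ``EMD_NEARNESS_GAIN``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .retina import N_COLS, N_ROWS, RetinaGeometry

__all__ = [
    "EMD_NEARNESS_GAIN",
    "IntegratedSquaredFlow",
    "SquaredFlowAccumulator",
    "RelativeNearnessMap",
    "ControlOutput",
    "nearness_from_integrated",
    "vertical_average",
    "comanv",
    "cad_can",
    "weight",
    "saccade_command",
    "wrap_deg",
    "control_from_integrated",
]

# Fixed calibration mapping detector responses onto the 1/s nearness scale.
# Correlator outputs are in arbitrary (brightness^2) units; this single
# constant anchors them so that the detector-based collision-avoidance
# necessity equals the geometric one at the reference operating point (head-on
# approach, 4 cm from the wall of the 1 mm-checkerboard 40 cm box), which
# puts the steering sigmoid's printed threshold (n0 = 4) at a physically
# sensible turning distance.  See docs/methods.md; not a per-texture fit.
EMD_NEARNESS_GAIN: float = 3000.0

# Elevation band (deg) around the equator excluded from the detector-based
# nearness map: the 1/sin^2(eps) inversion amplifies correlator opponent
# noise by >5 there, so those rows carry no usable signal.  Detector/
# geometric steering agreement is flat for widths of ~25-32 deg and degrades
# quickly below 20 deg.
EMD_EXCLUSION_BAND_DEG: float = 25.0


def wrap_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class IntegratedSquaredFlow:
    """Time-averaged squared flow components on the receptor grid."""

    s_phi: np.ndarray          # (91, 181) mean squared azimuthal component
    s_eps: np.ndarray          # (91, 181) mean squared elevational component
    n_ticks: int
    source: str                # "geometric" | "emd"


class SquaredFlowAccumulator:
    """Accumulate squared flow over an integration window.

    Geometric flow fields already live on the receptor grid.  Detector
    responses live between receptors (91 x 180 horizontal, 90 x 181 vertical)
    and are re-gridded by averaging the squared responses of the two flanking
    detectors (a single flanking detector at the pole rows).
    """

    def __init__(self, source: str = "geometric",
                 shape: tuple[int, int] = (N_ROWS, N_COLS)):
        if source not in ("geometric", "emd"):
            raise ValueError("source must be 'geometric' or 'emd'")
        self.source = source
        self.shape = shape
        self.reset()

    def reset(self) -> None:
        self._s_phi = np.zeros(self.shape)
        self._s_eps = np.zeros(self.shape)
        self._n = 0

    def add_geometric(self, of_phi: np.ndarray, of_eps: np.ndarray) -> None:
        if of_phi.shape != self.shape or of_eps.shape != self.shape:
            raise ValueError("flow field shape mismatch")
        self._s_phi += of_phi**2
        self._s_eps += of_eps**2
        self._n += 1

    def add_emd(self, horizontal: np.ndarray, vertical: np.ndarray) -> None:
        nrows, ncols = self.shape
        nuniq = ncols - 1
        if horizontal.shape != (nrows, nuniq) or vertical.shape != (nrows - 1, ncols):
            raise ValueError("detector array shape mismatch")
        sq_h = horizontal**2
        # receptor column j is flanked by detectors (j-1) mod 180 and j
        reg_h = 0.5 * (np.roll(sq_h, 1, axis=1) + sq_h)
        reg_h = np.concatenate([reg_h, reg_h[:, :1]], axis=1)
        sq_v = vertical**2
        reg_v = np.empty(self.shape)
        reg_v[1:-1] = 0.5 * (sq_v[:-1] + sq_v[1:])
        reg_v[0] = sq_v[0]
        reg_v[-1] = sq_v[-1]
        self._s_phi += reg_h
        self._s_eps += reg_v
        self._n += 1

    def add(self, component_phi: np.ndarray, component_eps: np.ndarray) -> None:
        if self.source == "geometric":
            self.add_geometric(component_phi, component_eps)
        else:
            self.add_emd(component_phi, component_eps)

    def result(self) -> IntegratedSquaredFlow:
        if self._n == 0:
            raise ValueError("empty integration window")
        return IntegratedSquaredFlow(
            s_phi=self._s_phi / self._n,
            s_eps=self._s_eps / self._n,
            n_ticks=self._n,
            source=self.source,
        )


@dataclass
class RelativeNearnessMap:
    """Relative nearness v mu per viewing direction, with a validity mask.

    ``valid_rows`` is False at the pole rows (degenerate azimuth).  The
    equatorial row, where the inversion is singular, is filled by averaging
    the estimates at +/-2 deg elevation (configurable to exclusion).
    """

    values: np.ndarray
    valid_rows: np.ndarray
    source: str


def nearness_from_integrated(
    isf: IntegratedSquaredFlow,
    geometry: RetinaGeometry | None = None,
    equator: str = "interpolate",
    emd_gain: float | None = None,
    emd_band_deg: float | None = None,
) -> RelativeNearnessMap:
    """Invert the retinotopically modified norm on time-averaged squared flow.

    v mu = sqrt(S_phi + S_eps / sin^2 eps), evaluated per direction.  The
    geometric source uses the formula everywhere except the singular
    equatorial row, which is interpolated from the +/-2 deg rows (``equator``
    = ``"interpolate"``, default) or excluded.  The detector source
    additionally masks the rows within ``emd_band_deg`` of the equator
    (default :data:`EMD_EXCLUSION_BAND_DEG`), where the inversion amplifies
    opponent noise beyond any signal, and is scaled by the fixed calibration
    ``emd_gain`` (default :data:`EMD_NEARNESS_GAIN`).
    """
    g = geometry or RetinaGeometry()
    if isf.s_phi.shape != g.shape:
        raise ValueError("integrated flow grid does not match the retina grid")
    sin_eps = np.sin(g.eps_rad)[:, None]
    nrows = g.shape[0]
    i_eq = int(np.argmin(np.abs(g.eps_deg)))

    valid = np.ones(nrows, dtype=bool)
    valid[0] = valid[-1] = False  # poles

    with np.errstate(divide="ignore", invalid="ignore"):
        vmu = np.sqrt(isf.s_phi + isf.s_eps / sin_eps**2)
    if equator == "interpolate":
        vmu[i_eq] = 0.5 * (vmu[i_eq - 1] + vmu[i_eq + 1])
    elif equator == "exclude":
        vmu[i_eq] = 0.0
        valid[i_eq] = False
    else:
        raise ValueError("equator must be 'interpolate' or 'exclude'")
    vmu[0] = 0.0
    vmu[-1] = 0.0

    if isf.source == "emd":
        band = EMD_EXCLUSION_BAND_DEG if emd_band_deg is None else emd_band_deg
        valid &= np.abs(g.eps_deg) >= band
        vmu[~valid] = 0.0
        gain = EMD_NEARNESS_GAIN if emd_gain is None else emd_gain
        vmu = vmu * gain
    return RelativeNearnessMap(values=vmu, valid_rows=valid, source=isf.source)


def vertical_average(nearness: RelativeNearnessMap) -> np.ndarray:
    """Elevation-average of the nearness map: one value per azimuth bin.

    Returns 180 bins (the duplicated +/-180 deg endpoint column is dropped),
    each the mean of the valid elevation rows of that column.
    """
    rows = nearness.valid_rows
    if not rows.any():
        raise ValueError("no valid elevation rows to average")
    return nearness.values[rows, :-1].mean(axis=0)


def comanv(profile: np.ndarray,
           geometry: RetinaGeometry | None = None) -> np.ndarray:
    """Center-of-mass average nearness vector (agent frame, x forward).

    The vector sum of the per-azimuth nearness vectors value * (cos phi,
    sin phi), weighted by the bin width (i.e. the Riemann integral over
    azimuth in radians).  The integral form is independent of the azimuthal
    resolution and keeps the norm on the 1/s scale of the relative nearness,
    where the printed operating thresholds of the steering sigmoid
    (n0 = 1.6, 3.2, 4) fall at physically sensible wall distances.
    """
    g = geometry or RetinaGeometry()
    phi = g.phi_rad[:-1]
    if profile.shape != phi.shape:
        raise ValueError(f"expected {phi.size} azimuth bins")
    dphi = 2.0 * np.pi / phi.size
    return np.array([np.sum(profile * np.cos(phi)) * dphi,
                     np.sum(profile * np.sin(phi)) * dphi])


def cad_can(comanv_vec: np.ndarray) -> tuple[float, float]:
    """Collision-avoidance direction (deg, opposite the COMANV) and necessity
    (its norm).  A zero vector yields CAD = 0 with CAN = 0 (the weight then
    vanishes, so the value is never acted upon)."""
    can = float(np.hypot(comanv_vec[0], comanv_vec[1]))
    if can == 0.0:
        return 0.0, 0.0
    cad = wrap_deg(np.degrees(np.arctan2(comanv_vec[1], comanv_vec[0])) + 180.0)
    return float(cad), can


def weight(can: float, g: float, n0: float) -> float:
    """Sigmoid weight W = 1 / (1 + (CAN/n0)^-g); W(0) = 0, W(n0) = 1/2."""
    if g <= 0 or n0 <= 0:
        raise ValueError("gain and threshold must be positive")
    if can <= 0.0:
        return 0.0
    return float(1.0 / (1.0 + (can / n0) ** (-g)))


def saccade_command(
    cad: float,
    w: float,
    alpha: float = 0.0,
    sigma_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Saccade amplitude gamma = W * CAD + (1 - W) * wrap(alpha + sigma).

    ``alpha`` is the goal direction relative to the heading (0 = keep
    straight); ``sigma_deg`` is the SD of an optional zero-mean Gaussian goal
    noise (0 disables it).  The avoidance term turns the agent away from
    obstacles: CAD already points opposite the COMANV.
    """
    noise = 0.0
    if sigma_deg > 0.0:
        if rng is None:
            raise ValueError("goal-direction noise requires an rng")
        noise = rng.normal(0.0, sigma_deg)
    return float(w * cad + (1.0 - w) * wrap_deg(alpha + noise))


@dataclass
class ControlOutput:
    """One saccade decision: the COMANV and everything derived from it."""

    comanv: np.ndarray
    cad_deg: float
    can: float
    w: float
    gamma_deg: float
    alpha_deg: float = 0.0
    g: float = 2.0
    n0: float = 4.0
    time_ms: float = 0.0

    def as_row(self) -> dict:
        return {
            "t_ms": self.time_ms,
            "comanv_x": float(self.comanv[0]),
            "comanv_y": float(self.comanv[1]),
            "cad_deg": self.cad_deg,
            "can": self.can,
            "w": self.w,
            "alpha_deg": self.alpha_deg,
            "gamma_deg": self.gamma_deg,
        }


def control_from_integrated(
    isf: IntegratedSquaredFlow,
    g: float = 2.0,
    n0: float = 4.0,
    alpha_deg: float = 0.0,
    sigma_deg: float = 0.0,
    rng: np.random.Generator | None = None,
    geometry: RetinaGeometry | None = None,
    time_ms: float = 0.0,
) -> ControlOutput:
    """Full decision chain: integrated squared flow -> saccade amplitude."""
    nearness = nearness_from_integrated(isf, geometry)
    profile = vertical_average(nearness)
    vec = comanv(profile, geometry)
    cad, can = cad_can(vec)
    w = weight(can, g, n0)
    gamma = saccade_command(cad, w, alpha_deg, sigma_deg, rng)
    return ControlOutput(comanv=vec, cad_deg=cad, can=can, w=w,
                         gamma_deg=gamma, alpha_deg=alpha_deg,
                         g=g, n0=n0, time_ms=time_ms)
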