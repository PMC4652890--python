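"""Correlation-type elementary motion detectors (Reichardt-Hassenstein).

The front end runs at 1 kHz on the 91 x 181 brightness image:

1. photoreceptor stage — first-order temporal low-pass (tau = 8 ms, unity DC
   gain), a pluggable stand-in for the measured band-pass kernel of fly
   second-order interneurons;
2. high-pass stage — first-order high-pass, tau = 20 ms, removing the DC
   component;
3. correlator — for each pair of neighboring receptors (A, B) the response is
   LP35(A) * B - LP35(B) * A computed on the high-passed signals, i.e. two
   mirror-symmetric subunits whose outputs are subtracted.  The 35 ms
   low-pass acts as the delay of the detector.

Horizontal detectors pair azimuth neighbors (periodic across +/-180 deg, the
duplicated endpoint column is not double-counted); positive response means
motion toward increasing azimuth.  Vertical detectors pair elevation
neighbors; positive means motion toward increasing elevation.  Responses are
in arbitrary units, quadratic in input contrast.

All filters use exact exponential (zero-order-hold) updates, so the time
constants do not depend on the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .retina import N_COLS, N_ROWS

__all__ = ["EMDParams", "FilterState", "EMD"]


@dataclass(frozen=True)
class EMDParams:
    """Time constants (s) of the detector chain and the simulation step."""

    tau_lp: float = 35e-3   # correlator delay low-pass
    tau_hp: float = 20e-3   # DC-removing high-pass
    tau_pr: float = 8e-3    # photoreceptor low-pass; 0 bypasses the stage
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.tau_lp, self.tau_hp, self.dt) <= 0 or self.tau_pr < 0:
            raise ValueError("time constants and dt must be positive")


class FilterState:
    """Internal states of the three temporal stages on the receptor grid."""

    def __init__(self, shape: tuple[int, int] = (N_ROWS, N_COLS)):
        self.shape = shape
        self.pr = np.zeros(shape)
        self.hp_mem = np.zeros(shape)   # low-pass memory of the high-pass stage
        self.lp = np.zeros(shape)
        self.primed = False             # first sample initializes the PR stage

    def reset(self) -> None:
        self.pr[:] = 0.0
        self.hp_mem[:] = 0.0
        self.lp[:] = 0.0
        self.primed = False


class EMD:
    """Streaming detector array: consume one image per tick, emit responses."""

    def __init__(self, params: EMDParams | None = None,
                 shape: tuple[int, int] = (N_ROWS, N_COLS)):
        self.params = params or EMDParams()
        self.state = FilterState(shape)
        p = self.params
        self._a_pr = np.exp(-p.dt / p.tau_pr) if p.tau_pr > 0 else 0.0
        self._a_hp = np.exp(-p.dt / p.tau_hp)
        self._a_lp = np.exp(-p.dt / p.tau_lp)

    def reset(self) -> None:
        self.state.reset()

    # -- individual stages (exposed for testing and for custom chains) -----

    def photoreceptor_stage(self, image: np.ndarray) -> np.ndarray:
        """First-order low-pass with unity DC gain (ZOH-exact update).

        The state starts at the first sample rather than at zero so that a
        static scene produces no spurious onset transient.
        """
        st = self.state
        if image.shape != st.shape:
            raise ValueError(f"image shape {image.shape} != {st.shape}")
        if self.params.tau_pr == 0:
            return np.asarray(image, dtype=float).copy()
        if not st.primed:
            st.pr[:] = image
            st.primed = True
        else:
            st.pr += (1.0 - self._a_pr) * (image - st.pr)
        return st.pr.copy()

    def highpass_stage(self, filtered: np.ndarray) -> np.ndarray:
        """Exact first-order high-pass: x minus a one-sample-delayed low-pass.

        A step passes through at full height on the tick it arrives and then
        decays to zero with tau = 20 ms; constants decay to zero exactly.
        """
        st = self.state
        if filtered.shape != st.shape:
            raise ValueError(f"image shape {filtered.shape} != {st.shape}")
        out = filtered - st.hp_mem
        st.hp_mem += (1.0 - self._a_hp) * (filtered - st.hp_mem)
        return out

    def correlate(self, detrended: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Advance the 35 ms delay filter and correlate neighbor pairs.

        Returns ``(horizontal, vertical)`` responses with shapes
        (rows, cols-1) and (rows-1, cols): horizontal detectors live between
        azimuth-adjacent receptors on the 180 unique columns (periodic),
        vertical detectors between elevation-adjacent receptors.
        """
        st = self.state
        st.lp += (1.0 - self._a_lp) * (detrended - st.lp)
        h = detrended
        l = st.lp
        nrows, ncols = st.shape
        nuniq = ncols - 1  # drop the duplicated +/-180 deg endpoint column
        hu = h[:, :nuniq]
        lu = l[:, :nuniq]
        h_next = np.roll(hu, -1, axis=1)
        l_next = np.roll(lu, -1, axis=1)
        horizontal = lu * h_next - l_next * hu
        vertical = l[:-1, :] * h[1:, :] - l[1:, :] * h[:-1, :]
        return horizontal, vertical

    def step(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full chain for one 1 ms tick: image -> (horizontal, vertical)."""
        x = self.photoreceptor_stage(image)
        x = self.highpass_stage(x)
        return self.correlate(x)


def grating_mean_response(
    temporal_freq_hz: float,
    wavelength_deg: float,
    contrast: float = 1.0,
    spacing_deg: float = 2.0,
    params: EMDParams | None = None,
) -> float:
    """Closed-form time-averaged steady-state response to a drifting sine
    grating, for first-order photoreceptor/high-pass/low-pass stages.

    For receptor signals A sin(wt + a_j) the mean of
    LP(s1) s2 - LP(s2) s1 is  A^2 |L(w)| sin(-arg L(w)) sin(a2 - a1), with
    A = contrast * |P(w)| * |H(w)| and a2 - a1 the spatial phase step between
    neighboring receptors.  Positive for motion toward increasing azimuth.
    """
    p = params or EMDParams()
    w = 2.0 * np.pi * temporal_freq_hz
    P = 1.0 if p.tau_pr == 0 else 1.0 / np.hypot(1.0, w * p.tau_pr)
    H = (w * p.tau_hp) / np.hypot(1.0, w * p.tau_hp)
    Lmag = 1.0 / np.hypot(1.0, w * p.tau_lp)
    sin_argL = (w * p.tau_lp) / np.hypot(1.0, w * p.tau_lp)
    A = contrast * P * H
    dphase = 2.0 * np.pi * spacing_deg / wavelength_deg
    return float(A * A * Lmag * sin_argL * np.sin(dphase))
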