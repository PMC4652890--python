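"""Temporal-frequency tuning of the motion-detector front end.

A sine grating drifting across the retina probes the correlator: its mean
steady-state response depends on the temporal frequency v/lambda (not on
velocity itself), peaks at an intermediate frequency set by the filter time
constants, and scales with the square of the pattern contrast.  The
simulated responses are compared against the closed-form steady state.
"""

import numpy as np

from comanav.emd import EMD, grating_mean_response


def simulate(tf_hz, wavelength_deg=20.0, amplitude=0.5, n_ms=1400):
    emd = EMD(shape=(3, 181))
    phis = np.linspace(-180.0, 180.0, 181)
    resp = []
    for n in range(n_ms):
        img = 0.5 + amplitude * np.sin(
            2 * np.pi * (tf_hz * n * 1e-3 - phis / wavelength_deg))
        rh, _ = emd.step(np.tile(img, (3, 1)))
        if n >= 1000:
            resp.append(rh.mean())
    return float(np.mean(resp))


print(f"{'tf (Hz)':>8} {'simulated':>12} {'closed form':>12}")
vals = []
for tf in [0.5, 1, 2, 4, 8, 12, 16, 24]:
    sim = simulate(tf)
    ref = grating_mean_response(tf, 20.0, contrast=0.5)
    vals.append((tf, sim))
    print(f"{tf:>8} {sim:>12.3e} {ref:>12.3e}")
peak = max(vals, key=lambda p: p[1])
print(f"\npeak response near {peak[0]} Hz — the detector reports temporal "
      "frequency, not angular velocity")
lo, hi = simulate(4, amplitude=0.2), simulate(4, amplitude=0.4)
print(f"doubling contrast multiplies the response by {hi / lo:.2f} "
      "(quadratic contrast dependence)")
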