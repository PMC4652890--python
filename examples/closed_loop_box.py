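"""Closed-loop collision avoidance in the 40 cm box, detector-based.

One agent flies for 10 simulated seconds in a box papered with a 1 mm random
checkerboard, steering purely from motion-detector responses (gain 2,
threshold 4).  It alternates 50 ms translations with saccadic turns and must
never touch a wall.
"""

import numpy as np

from comanav import make_cubic_box, make_random_checkerboard
from comanav.simulate import SimulationConfig, Simulator

tex = make_random_checkerboard(1.0, (400.0, 400.0), seed=7)
env = make_cubic_box(wall_texture=tex)
cfg = SimulationConfig(flow_source="emd", g=2.0, n0=4.0, max_time_s=10.0)

tr = Simulator(env, cfg).run((0.1, 0.1), 45.0, seed=101)
wall_margin = min(tr.x.min(), tr.y.min(), 0.4 - tr.x.max(), 0.4 - tr.y.max())
turns = [s.gamma_deg for s in tr.saccades]
print(f"outcome            : {tr.outcome} after {tr.t_ms[-1]/1e3:.1f} s")
print(f"path length        : {tr.path_length():.2f} m")
print(f"closest wall pass  : {wall_margin*100:.1f} cm")
print(f"saccades           : {len(turns)}, median |turn| "
      f"{np.median(np.abs(turns)):.1f} deg, largest {np.max(np.abs(turns)):.0f} deg")
print(f"peak CAN observed  : {max(s.can for s in tr.saccades):.1f} "
      f"(threshold n0 = {cfg.n0})")
print("\nThe agent turns away whenever the integrated flow signals a nearby "
      "wall;\nwith a 1 mm texture the detector-based nearness is reliable "
      "enough that no\ncollision occurs within the run.")
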