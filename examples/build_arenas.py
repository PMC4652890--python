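"""Build the standard arenas: textured boxes and a cluttered corridor.

Prints the geometry of each environment and round-trips one through the YAML
description format.
"""

from comanav import (environment_from_yaml, make_cluttered_environment,
                     make_cubic_box, make_object_box, make_one_over_f_texture,
                     make_random_checkerboard)
from comanav.environments import environment_to_yaml

checker = make_random_checkerboard(1.0, (400.0, 400.0), seed=7)
pink = make_one_over_f_texture((400.0, 400.0), seed=7)
print(f"1 mm checkerboard: {checker.grid.shape[1]}x{checker.grid.shape[0]} "
      f"texels, mean brightness {checker.grid.mean():.3f}")
print(f"1/f texture: range [{pink.grid.min():.2f}, {pink.grid.max():.2f}]")

box = make_cubic_box(wall_texture=checker)
print(f"\ncubic box: {box.width*100:.0f} cm edge, "
      f"{len(box.obstacles)} obstacles")

bars = make_object_box(4, checker)
print(f"object box: {len(bars.obstacles)} camouflaged bars of "
      f"{bars.obstacles[0].base_edge*100:.0f} cm base at "
      f"{[tuple(round(c, 2) for c in ob.center) for ob in bars.obstacles]}")

clutter = make_cluttered_environment(seed=11)
edges = sorted({round(ob.base_edge * 1e3) for ob in clutter.obstacles})
print(f"cluttered corridor: {clutter.width}x{clutter.depth}x{clutter.height} m,"
      f" {len(clutter.obstacles)} obstacles with base edges {edges} mm,"
      f" heights 5x the base edge")

text = environment_to_yaml(clutter)
back = environment_from_yaml(text)
print(f"\nYAML round trip: {len(text.splitlines())} lines, "
      f"{len(back.obstacles)} obstacles restored identically: "
      f"{[o.center for o in back.obstacles] == [o.center for o in clutter.obstacles]}")
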