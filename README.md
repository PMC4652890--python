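# comanav

Closed-loop simulation of insect-inspired collision avoidance from
translational optic flow on a spherical eye.

Flying insects separate rotation from translation behaviorally: they fly in
straight 50 ms bursts (intersaccades) punctuated by rapid yaw turns
(saccades).  The optic flow experienced during the translations carries the
depth structure of the surroundings, entangled with the viewing geometry.
`comanav` implements a model agent that untangles it using only local
properties of a spherical eye, steers away from obstacles, and — when given
a goal direction — threads cluttered environments along a small number of
repeatable routes.

The pipeline, per intersaccade:

1. **Relative nearness from flow.**  For planar translation, the flow
   components at elevation ε and azimuth φ satisfy
   `(vμ)² = OF_φ² + OF_ε²/sin²ε` — a retinotopically modified norm that is
   independent of the motion direction (v = speed, μ = inverse distance).
   Squared flow is integrated over the 50 jittered sub-translations of an
   intersaccade, which removes the focus-of-expansion/contraction blind
   spots of any single translation.
2. **COMANV.**  The nearness map is averaged along elevation and summed
   over azimuth as polar vectors, yielding the Center-Of-Mass Average
   Nearness Vector, which points toward the average direction of close
   surfaces.  Its reversed argument is the collision-avoidance direction
   (CAD); its norm the collision-avoidance necessity (CAN, units 1/s).
3. **Saccade command.**  `γ = W·CAD + (1−W)·(α+σ)` with the sigmoid weight
   `W = 1/(1+(CAN/n₀)^(−g))` blending avoidance against a goal direction α
   (gain g = 2, threshold n₀ = 4 for the detector-based agent).

Flow is measured either geometrically (ground truth from ray distances — a
texture-independent benchmark) or by an array of correlation-type
elementary motion detectors (Reichardt–Hassenstein: 20 ms high-pass, 35 ms
delay low-pass, mirror-opponent multiplication) fed by a ray-cast panoramic
rendering (91 × 181 receptors at 2° spacing, 2° Gaussian blur).  Detector
responses depend on texture contrast and spatial structure, not just image
velocity — the point of the model is that steering survives this.

Goal-directed trajectories are clustered into routes via the sequence of
Delaunay cells (triangles of neighboring obstacle centers) they cross, with
route similarity the number of cells not shared, and performance measured
as reliability (% crashes) and path efficiency against a visibility-graph
shortest path.

## Worked example

A detector-based agent in a 40 cm box papered with a 1 mm random
checkerboard (`python examples/closed_loop_box.py`):

```
outcome            : timeout after 10.0 s
path length        : 1.00 m
closest wall pass  : 4.2 cm
saccades           : 122, median |turn| 8.9 deg, largest 26 deg
peak CAN observed  : 6.6 (threshold n0 = 4.0)
```

The agent flies 10 simulated seconds without ever touching a wall: the CAN
stays below threshold in the open interior (small corrective turns toward
the goal direction, here "straight ahead") and crosses it on wall
approaches, where large saccades away from the COMANV take over.

Other examples, one per capability (`python examples/<name>.py`):
`build_arenas` (textures, boxes, the 35-obstacle cluttered corridor),
`nearness_from_flow` (the constant-distance surround recovered to 0.5 1/s
exactly, FOE removed), `detector_tuning` (grating responses vs the
closed-form correlator steady state), `open_loop_steering` (CAN growth on
wall approach; detector vs geometric CAD agreement), `routes_in_clutter`
(many starts → few routes, with efficiency metrics).

A thin CLI wraps the same calls:

```bash
comanav make-env --kind clutter --texel-mm 1 --seed 11 arena.yaml
comanav simulate --env arena.yaml --mode emd --gain 2 --threshold 4 \
        --goal 1.8,0.5 --max-time 60 --starts 4 --seed 1 --out out/
comanav routes --env arena.yaml --trajectories out/
```

## Layout

```
src/comanav/
  environments.py   arenas and procedural textures (YAML / PNG round trips)
  retina.py         spherical-eye geometry, rendering, geometric flow
  _raycast.py       numba ray-casting kernel
  emd.py            correlation-type motion-detector front end
  control.py        nearness inversion, COMANV, CAD/CAN, saccade command
  simulate.py       closed-loop saccade/intersaccade flight
  routes.py         Delaunay cell sequences, route clustering, efficiency
  experiments.py    seeding, presets, experiment bundles
  cli.py            thin command-line front end
docs/methods.md     model assumptions, parameters, numerical choices
examples/           one narrative script per capability
```
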