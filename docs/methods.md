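# Methods

`comanav` simulates an insect-like flying agent that avoids collisions using
only the apparent motion of the world on a spherical eye.  This note
documents the model, the numerical choices, and what the synthetic test
environments do and do not establish.

## Model overview

Flight alternates two behavioral phases, mirroring the saccadic gaze
strategy of flies and bees:

* **Intersaccade** — 50 ms of pure translation at 0.1 m/s.  The path is
  composed of 50 one-millisecond segments whose motion directions are drawn
  from a normal distribution around the heading (SD 18 deg); the heading
  itself does not change.  During this phase the agent gathers optic flow.
* **Saccade** — a rapid yaw turn whose amplitude is computed from the flow
  gathered during the preceding intersaccade.  Translation continues at
  0.1 m/s along the instantaneous heading during the turn.

All motion is confined to a horizontal plane at fixed flight height
(mid-height of the arena by default; 100 mm in the cluttered corridors).

### From flow to relative nearness

For translation in the horizontal ("null-elevation") plane of a spherical
eye, the two flow components in a viewing direction with elevation eps and
azimuth phi are

    OF_phi = v * mu * sin(phi - phi_t)
    OF_eps = v * mu * sin(eps) * cos(phi - phi_t)

with v the speed, mu the inverse distance to the surface seen in that
direction and phi_t the motion direction.  The combination

    (v mu)^2 = OF_phi^2 + OF_eps^2 / sin^2(eps)

is independent of phi_t: it recovers the *relative nearness* v*mu (units
1/s) from the flow alone.  A single translation still has two blind
directions — the foci of expansion and contraction, where the flow
vanishes regardless of nearness — so the squared flow components are
integrated over the whole jittered intersaccade; with mixed motion
directions the expectation of the right-hand side is v^2 mu^2 in every
direction and the singularities disappear.

The inversion is singular on the equator (sin eps = 0).  The equatorial row
of the nearness map is filled by averaging the estimates at +/-2 deg; the
pole rows, where azimuth is degenerate, are excluded throughout.

### Steering: COMANV, CAD, CAN

The nearness map is averaged along the elevation, giving one value per
azimuth.  These values, read as polar vectors, are summed over azimuth
(a Riemann integral, `sum(value * (cos phi, sin phi)) * dphi`), producing
the **COMANV** — the center-of-mass average nearness vector, which points
toward the average direction of close surfaces.  Its argument reversed by
180 deg is the collision-avoidance direction (**CAD**); its norm is the
collision-avoidance necessity (**CAN**, units 1/s).  The integral
normalization is independent of the azimuthal resolution, and it places the
operating thresholds of the steering law (below) at physically sensible
distances: in the 40 cm box the geometric CAN is about 7.0, 2.4, 1.3 and
0.5 at 2, 4, 6 and 10 cm from a wall.

The saccade amplitude blends avoidance and goal pursuit:

    gamma = W * CAD + (1 - W) * (alpha + sigma)
    W     = 1 / (1 + (CAN / n0)^-g)

where alpha is the goal direction relative to the heading (0 in arenas
without a goal), sigma an optional zero-mean Gaussian goal noise (off by
default), n0 the threshold (W(n0) = 1/2) and g the gain of the sigmoid.
Defaults are g = 2 and n0 = 4 for the detector-based agent; g = 2 with
n0 = 1.6-3.2 are the reference operating points for the geometric agent in
the box.

The saccade follows a Gaussian yaw-velocity template with duration
D = max(10, 30 + 20*|gamma|/90) ms (spanning the 10-80 ms range of fly
saccades; configurable), renormalized so the integrated turn equals gamma
exactly.

### Motion-detector pathway

The biologically plausible flow estimate comes from correlation-type
elementary motion detectors running at 1 kHz on the rendered brightness
image:

1. photoreceptor stage: first-order temporal low-pass, tau = 8 ms, unity DC
   gain.  This is a deliberately simple stand-in for the measured band-pass
   kernel of fly second-order interneurons, which is not published in a
   closed form; the kernel is pluggable (`EMDParams.tau_pr`, 0 bypasses it).
2. high-pass, tau = 20 ms, removing the mean luminance;
3. correlator: for each azimuth- or elevation-adjacent receptor pair the
   delayed (35 ms low-pass) signal of one receptor is multiplied with the
   undelayed signal of its neighbor, in two mirror-symmetric subunits whose
   outputs are subtracted.  Responses are quadratic in contrast and tuned to
   temporal frequency, not velocity.

All filters use exact exponential (zero-order-hold) updates, so time
constants are independent of the 1 ms step.  Filters keep running during
saccades; the rotational flow of a saccade therefore contaminates the early
intersaccade, and the closed-loop agent integrates only the last 5 ms of
each intersaccade when steering from detector responses.  Open-loop probes
(`open_loop_control`), which contain no saccades, integrate the full 50 ms.

Two empirically necessary choices specific to the detector pathway:

* **Equatorial exclusion band.**  The vertical detector channel carries
  opponent noise of the same order as the horizontal signal (vertically
  adjacent receptors see partly decorrelated texture).  Dividing it by
  sin^2(eps) amplifies that noise ~800-fold two degrees off the equator,
  which reverses the COMANV (~150 deg CAD errors).  Rows within 25 deg of
  the equator are therefore excluded from the detector-based nearness
  average (`EMD_EXCLUSION_BAND_DEG`; steering agreement is flat for widths
  of 25-32 deg and degrades quickly below 20).  With the band excluded,
  detector CADs agree with geometric CADs to ~6-10 deg on average
  (full-window integration, COMANV averaged over a few jittered probes)
  when translating parallel to a wall at mid distances.  The geometric
  pathway uses the exact formula everywhere.
* **Calibration.**  Correlator outputs are in arbitrary brightness^2 units.
  One fixed constant (`EMD_NEARNESS_GAIN` = 3000) maps them onto the 1/s
  scale; it was set once by equating detector-based and geometric CAN at a
  single reference operating point (head-on approach, 4 cm from the wall of
  the 1 mm-checkerboard box, measured ratio 2946, rounded).  It is not
  adjusted per texture — texture-dependent response differences are part of
  the modeled biology.

### Rendering

Arenas are axis-aligned boxes with textured walls, floor, ceiling and
vertical bar obstacles.  The eye samples brightness on a cylindrical-
projection grid of 91 elevation rows x 181 azimuth columns (2 deg spacing;
the +/-180 deg columns are the same physical direction, kept for grid
regularity and never double-counted).  Rendering casts one central ray per
cell of a grid refined `supersample`-fold, applies the 2 deg Gaussian
spatial low-pass of the photoreceptor lattice in image space (truncated at
2 sigma; azimuth wraps), and subsamples to the receptor grid.  Textures are
looked up nearest-texel, preserving the hard edges the detectors respond
to.  Surfaces that share a texture tile it from distinct fixed anchors
(coprime texel strides per face and per obstacle): opposing walls carrying
pixel-identical patterns would otherwise bias the COMANV, which is exactly
a left-right/front-back difference signal.  `supersample=2` is the single
operating point of the detector pathway — the calibration constant and the
behavioral results are tied to it (receptor values converge as
1/supersample; at supersample 4 a further doubling changes values by <2%
RMS).  Ground-truth nearness (inverse central-ray distance, no blur) and
the geometric flow derived from it form the texture-independent benchmark
pathway.

## Environments (what the synthetic data emulate)

* 40 cm cubic box (the classic fly flight arena), walls papered with random
  black/white checkerboards (1, 4, 8 or 35 mm texels), a 1/f random
  texture, or a user-supplied grayscale image; floor and ceiling default to
  dark/bright 8 mm irregular patterns.  A 3.9 m tall variant exercises the
  apparent-size dependence of the CAN.
* Object boxes: 1, 2 or 4 camouflaged vertical bars (3 x 3 cm base, full
  box height) at the center / diagonal positions (diagonals at 25% of the
  edge from center).
* Cluttered corridor: 2000 x 1000 x 400 mm with 35 obstacles (five each of
  80/72/56/48/40 mm base edge and ten of 64 mm; a second roster swaps the
  72/64 mm counts), each five times as tall as wide, placed uniformly in
  the box shrunk by 10% per side with at least 60 mm edge-to-edge
  clearance (a stand-in for the unquantified "homogeneity" selection of the
  original arenas).  A wall-less variant is available.

These environments reproduce the geometry and texture statistics of the
modeled experiments, not their exact random instances: obstacle placements
and texture samples are seed-dependent, so route identities and counts are
reproducible per seed but not comparable to any published instance.  The
natural-grass photograph used in some of the original arenas is not
redistributable; the 1/f texture (or any user image) stands in for it.
Passing tests therefore establish the mechanisms — nearness recovery,
texture-robust steering, route convergence — under matched statistics, not
pixel-level reproduction.

## Route analysis

Obstacle centers are Delaunay-triangulated; a trajectory maps to the
sequence of triangles it crosses (consecutive duplicates collapsed; points
outside the convex hull emit a reserved "outside" token so wall-hugging
detours still differentiate routes).  Revisits are removed by deleting the
subsequence between the first and last occurrence of a repeated cell,
iterated to convergence (the result is idempotent).  The outside token is
exempt from this suppression — it marks excursions, not a revisitable
region; without the exemption a run that starts and ends beyond the hull
would collapse to the bare marker.  Trajectories with
identical simplified sequences form a route.  Route similarity is the
number of cells not shared (symmetric set difference, a pseudo-metric);
dendrograms use average-linkage agglomerative clustering on that distance,
and routes pooled from runs over different textures can be compared in one
tree.

Performance of goal-directed runs: *reliability* is the percentage of
trajectories that crash before reaching the goal; *efficiency* of each
goal-reaching trajectory is the shortest collision-free path length divided
by the realized path length.  The shortest path comes from a visibility
graph over obstacle corners inflated by the collision radius; a
maximal-clearance baseline along the Voronoi skeleton of the obstacle
centers (wall-mirrored sites) is reported alongside.

## Numerical and design choices

* Units: meters and seconds internally; constructors accept millimeters
  where the experimental literature quotes them.  Angles in degrees at the
  API surface, radians internally.
* Collision: surface distance < 1 cm (strict); goal: within 5 cm.  Both
  configurable.
* The geometric pathway can re-cast the ground-truth nearness map every
  `nearness_refresh_ticks` milliseconds within an intersaccade (the agent
  moves 0.1 mm per tick, so strides up to ~10 are indistinguishable; long
  closed-loop studies use 10).
* Zero COMANV: CAD is reported as 0 with CAN = 0; the weight is then 0, so
  the convention is never acted on.
* Seeding: a single master seed feeds named, independent sub-streams
  (texture, placement, per-trajectory segment jitter, goal noise) derived
  via hashed `SeedSequence` keys; end-to-end reruns are bit-identical.
* Start sets: canonical grids over the arena interior (the four diagonal
  quarter positions in boxes; an entry band for corridor runs), standing in
  for unpublished start coordinates.

## Known limitations

* The detector-based agent does not reproduce the published *failure* on
  coarse (35 mm) checkerboards: in this implementation its CADs remain
  usable and its CAN is inflated by the high contrast, so it turns early
  and never crashes, whereas the original agent crashed.  That failure mode
  depended on the original (unpublished) renderer's texture response; see
  the equatorial-exclusion discussion above.
* Speed, altitude and intersaccade duration are constant; non-planar
  motion adds a nearness error that grows with the vertical velocity
  component and is not corrected.
* The photoreceptor kernel is a first-order low-pass stand-in, not the
  measured fly kernel.
* Pixel-identical reproduction of published figures and route counts is
  out of scope (unpublished arena instances and textures).
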