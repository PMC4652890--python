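"""Textured virtual flight arenas.

Environments are closed (or open-topped-by-configuration) axis-aligned boxes
whose walls, floor and ceiling carry gray-scale textures, optionally containing
vertical box obstacles.  They emulate the classic insect flight arenas: a 40 cm
cubic box, boxes with a few camouflaged bars, and a 2000 x 1000 x 400 mm
cluttered corridor with 35 randomly placed obstacles.

All geometry is axis-aligned and held in meters internally; constructors accept
millimeters where the experimental literature quotes millimeters.  Texture
generation is a pure function of (kind, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "Texture",
    "BoxObstacle",
    "Environment",
    "make_random_checkerboard",
    "make_one_over_f_texture",
    "make_texture_from_image",
    "make_cubic_box",
    "make_object_box",
    "make_cluttered_environment",
    "CLUTTER_ROSTERS",
    "save_texture_png",
    "load_texture_png",
    "environment_to_yaml",
    "environment_from_yaml",
]


@dataclass(frozen=True)
class Texture:
    """A gray-scale texture tiled onto a surface.

    ``grid`` holds brightness values in [0, 1] with shape (n_v, n_u); one cell
    covers ``texel_size_mm`` of physical surface.  ``kind`` records how the
    texture was generated and ``seed`` the RNG seed used, so that equal
    (kind, seed, shape) always means an identical grid.
    """

    grid: np.ndarray
    texel_size_mm: float
    kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 2:
            raise ValueError("texture grid must be 2-D")
        if self.texel_size_mm <= 0:
            raise ValueError("texel_size_mm must be positive")
        if g.size and (g.min() < -1e-12 or g.max() > 1 + 1e-12):
            raise ValueError("texture values must lie in [0, 1]")
        object.__setattr__(self, "grid", np.clip(g, 0.0, 1.0))

    @property
    def texel_size_m(self) -> float:
        return self.texel_size_mm * 1e-3


@dataclass(frozen=True)
class BoxObstacle:
    """A vertical bar with a square base standing on the floor.

    ``center`` is the (x, y) position of the base center in meters,
    ``base_edge`` the side of the square base and ``height`` the vertical
    extent, both in meters.
    """

    center: tuple[float, float]
    base_edge: float
    height: float
    texture: Texture

    def __post_init__(self) -> None:
        if self.base_edge <= 0 or self.height <= 0:
            raise ValueError("obstacle dimensions must be positive")


@dataclass(frozen=True)
class Environment:
    """An axis-aligned arena: outer box, surface textures and obstacles.

    The outer box spans [0, width] x [0, depth] x [0, height].  ``walls=False``
    removes the outer box surfaces entirely (open variant): rays that escape
    see a uniform ``background`` brightness at infinite distance.
    """

    width: float
    depth: float
    height: float
    wall_texture: Texture
    floor_texture: Texture
    ceiling_texture: Texture
    obstacles: tuple[BoxObstacle, ...] = ()
    walls: bool = True
    goal: tuple[float, float] | None = None
    background: float = 0.5
    name: str = "environment"

    def __post_init__(self) -> None:
        if min(self.width, self.depth, self.height) <= 0:
            raise ValueError("box dimensions must be positive")
        for ob in self.obstacles:
            x, y = ob.center
            h = ob.base_edge / 2.0
            if not (h <= x <= self.width - h and h <= y <= self.depth - h):
                raise ValueError("obstacle must lie strictly inside the box")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.depth / 2.0)

    def with_goal(self, goal: tuple[float, float] | None) -> "Environment":
        return replace(self, goal=goal)

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        """True if the 2-D point is inside the outer box (shrunk by margin)."""
        return (margin <= x <= self.width - margin
                and margin <= y <= self.depth - margin)


# ---------------------------------------------------------------------------
# texture generators
# ---------------------------------------------------------------------------

def make_random_checkerboard(
    texel_size_mm: float,
    extent_mm: tuple[float, float],
    seed: int,
    levels: tuple[float, float] = (0.0, 1.0),
) -> Texture:
    """Random black-and-white checkerboard: each texel independently takes one
    of two brightness ``levels`` with probability 1/2.

    ``extent_mm`` is (width, height) of the covered surface; the grid has
    ceil(extent / texel) cells per side so the surface is fully tiled.
    """
    if texel_size_mm <= 0:
        raise ValueError("texel_size_mm must be positive")
    w_mm, h_mm = extent_mm
    if w_mm < texel_size_mm or h_mm < texel_size_mm:
        raise ValueError("extent must cover at least one texel per dimension")
    nu = int(np.ceil(w_mm / texel_size_mm))
    nv = int(np.ceil(h_mm / texel_size_mm))
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(nv, nu))
    lo, hi = levels
    grid = np.where(bits == 0, lo, hi).astype(np.float64)
    return Texture(grid=grid, texel_size_mm=texel_size_mm,
                   kind="checkerboard", seed=seed)


def make_one_over_f_texture(
    extent_mm: tuple[float, float],
    seed: int,
    texel_size_mm: float = 1.0,
) -> Texture:
    """Random gray-scale field with an approximately 1/f amplitude spectrum.

    Built in the Fourier domain: white Gaussian phases with amplitude
    proportional to 1/|f|, inverse-transformed and linearly rescaled to [0, 1].
    """
    if texel_size_mm <= 0:
        raise ValueError("texel_size_mm must be positive")
    w_mm, h_mm = extent_mm
    if w_mm < texel_size_mm or h_mm < texel_size_mm:
        raise ValueError("extent must cover at least one texel per dimension")
    nu = int(np.ceil(w_mm / texel_size_mm))
    nv = int(np.ceil(h_mm / texel_size_mm))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((nv, nu))
    spec = np.fft.rfft2(white)
    fy = np.fft.fftfreq(nv)[:, None]
    fx = np.fft.rfftfreq(nu)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC; mean is set by the rescale below
    field_ = np.fft.irfft2(spec / f, s=(nv, nu))
    lo, hi = field_.min(), field_.max()
    grid = (field_ - lo) / (hi - lo) if hi > lo else np.full_like(field_, 0.5)
    return Texture(grid=grid, texel_size_mm=texel_size_mm,
                   kind="one_over_f", seed=seed)


def make_texture_from_image(path: str | Path, texel_size_mm: float = 1.0) -> Texture:
    """Load a user-supplied gray-scale image (e.g. PNG) as a texture."""
    img = Image.open(path).convert("L")
    grid = np.asarray(img, dtype=np.float64) / 255.0
    return Texture(grid=grid, texel_size_mm=texel_size_mm, kind="image")


def save_texture_png(texture: Texture, path: str | Path) -> None:
    """Write the texture as an 8-bit gray-scale PNG plus a sidecar ``.txt``
    recording texel_size_mm, kind and seed."""
    path = Path(path)
    arr = np.round(texture.grid * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".txt")
    sidecar.write_text(
        f"texel_size_mm: {texture.texel_size_mm}\n"
        f"kind: {texture.kind}\nseed: {texture.seed}\n"
    )


def load_texture_png(path: str | Path) -> Texture:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".txt")
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    img = Image.open(path).convert("L")
    grid = np.asarray(img, dtype=np.float64) / 255.0
    return Texture(
        grid=grid,
        texel_size_mm=float(meta.get("texel_size_mm", 1.0)),
        kind=str(meta.get("kind", "image")),
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# arena constructors
# ---------------------------------------------------------------------------

def _default_floor(edge_mm: float, seed: int) -> Texture:
    # dark irregular floor: 8 mm checkerboard with levels {0, 0.5}
    return make_random_checkerboard(8.0, (edge_mm, edge_mm), seed, levels=(0.0, 0.5))


def _default_ceiling(edge_mm: float, seed: int) -> Texture:
    # bright irregular ceiling: 8 mm checkerboard with levels {0.5, 1}
    return make_random_checkerboard(8.0, (edge_mm, edge_mm), seed, levels=(0.5, 1.0))


def make_cubic_box(
    edge: float = 0.4,
    wall_texture: Texture | None = None,
    floor_texture: Texture | None = None,
    ceiling_texture: Texture | None = None,
    height: float | None = None,
    seed: int = 0,
) -> Environment:
    """Cubic flight arena (default edge 0.4 m, i.e. the 40 cm box).

    ``height`` overrides the vertical extent for the tall-wall variants
    (e.g. a 3.9 m high box on a 0.4 m base).
    """
    height = edge if height is None else height
    edge_mm, height_mm = edge * 1e3, height * 1e3
    if wall_texture is None:
        wall_texture = make_random_checkerboard(8.0, (edge_mm, height_mm), seed)
    if floor_texture is None:
        floor_texture = _default_floor(edge_mm, seed + 1)
    if ceiling_texture is None:
        ceiling_texture = _default_ceiling(edge_mm, seed + 2)
    return Environment(width=edge, depth=edge, height=height,
                       wall_texture=wall_texture, floor_texture=floor_texture,
                       ceiling_texture=ceiling_texture, name="cubic_box")


def make_object_box(
    n_objects: int,
    texture: Texture,
    edge: float = 0.4,
    object_edge: float = 0.03,
    seed: int = 0,
) -> Environment:
    """Cubic box containing 0, 1, 2 or 4 camouflaged vertical bars.

    Bars have a 3 cm square base and the full box height (40 cm); they carry
    the same texture as the walls.  Layout: one bar at the center; two on one
    diagonal; four on both diagonals, offset by 25% of the edge from center.
    """
    if n_objects not in (0, 1, 2, 4):
        raise ValueError("n_objects must be one of 0, 1, 2, 4")
    env = make_cubic_box(edge=edge, wall_texture=texture, seed=seed)
    cx, cy = edge / 2.0, edge / 2.0
    off = 0.25 * edge
    if n_objects == 0:
        positions: list[tuple[float, float]] = []
    elif n_objects == 1:
        positions = [(cx, cy)]
    elif n_objects == 2:
        positions = [(cx - off, cy - off), (cx + off, cy + off)]
    else:
        positions = [(cx - off, cy - off), (cx + off, cy + off),
                     (cx - off, cy + off), (cx + off, cy - off)]
    obstacles = tuple(
        BoxObstacle(center=p, base_edge=object_edge, height=edge, texture=texture)
        for p in positions
    )
    return replace(env, obstacles=obstacles, name=f"object_box_{n_objects}")


# Obstacle-size rosters for the cluttered corridor: (base edge mm, count).
CLUTTER_ROSTERS: dict[str, tuple[tuple[float, int], ...]] = {
    "first": ((80.0, 5), (72.0, 5), (64.0, 10), (56.0, 5), (48.0, 5), (40.0, 5)),
    "second": ((80.0, 5), (72.0, 10), (64.0, 5), (56.0, 5), (48.0, 5), (40.0, 5)),
}


def make_cluttered_environment(
    seed: int,
    texel_size_mm: float = 1.0,
    walls: bool = True,
    roster: str = "first",
    clearance_mm: float = 60.0,
    max_tries: int = 20000,
) -> Environment:
    """Cluttered corridor: a 2000 x 1000 x 400 mm box with 35 obstacles.

    Obstacle base edges follow the named ``roster``; every obstacle is five
    times as tall as its base edge.  Centers are sampled uniformly in the box
    shrunk by 10% per side and rejection-sampled so that the edge-to-edge
    clearance between obstacles (and to the walls) is at least
    ``clearance_mm``.  ``walls=False`` yields the open variant (no outer
    surfaces).  All surfaces carry random checkerboards of ``texel_size_mm``.
    """
    if roster not in CLUTTER_ROSTERS:
        raise ValueError(f"unknown roster {roster!r}")
    w, d, h = 2.0, 1.0, 0.4
    rng = np.random.default_rng(seed)

    edges_m = [e * 1e-3 for e, n in CLUTTER_ROSTERS[roster] for _ in range(n)]
    # place the larger obstacles first: easier to satisfy the clearance rule
    edges_m.sort(reverse=True)
    clearance = clearance_mm * 1e-3
    margin_x, margin_y = 0.1 * w, 0.1 * d

    placed: list[tuple[float, float, float]] = []  # (x, y, half_edge)
    for e in edges_m:
        half = e / 2.0
        for _ in range(max_tries):
            x = rng.uniform(margin_x + half + clearance, w - margin_x - half - clearance)
            y = rng.uniform(margin_y + half + clearance, d - margin_y - half - clearance)
            ok = True
            for px, py, ph in placed:
                # edge-to-edge clearance under the Chebyshev metric (square bases)
                gap = max(abs(x - px), abs(y - py)) - (half + ph)
                if gap < clearance:
                    ok = False
                    break
            if ok:
                placed.append((x, y, half))
                break
        else:
            raise RuntimeError(
                f"obstacle placement failed after {max_tries} tries "
                f"(seed={seed}, edge={e * 1e3:.0f} mm)"
            )

    wall_tex = make_random_checkerboard(texel_size_mm, (w * 1e3, h * 1e3), seed + 101)
    floor_tex = make_random_checkerboard(texel_size_mm, (w * 1e3, d * 1e3), seed + 102)
    ceil_tex = make_random_checkerboard(texel_size_mm, (w * 1e3, d * 1e3), seed + 103)
    ob_tex = make_random_checkerboard(texel_size_mm, (400.0, 400.0), seed + 104)
    obstacles = tuple(
        BoxObstacle(center=(x, y), base_edge=2 * half, height=5 * 2 * half,
                    texture=ob_tex)
        for x, y, half in placed
    )
    return Environment(width=w, depth=d, height=h, wall_texture=wall_tex,
                       floor_texture=floor_tex, ceiling_texture=ceil_tex,
                       obstacles=obstacles, walls=walls,
                       name=f"clutter_{roster}_{texel_size_mm:g}mm")


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def _texture_spec(t: Texture) -> dict:
    if t.kind in ("checkerboard", "one_over_f") and t.seed is not None:
        nv, nu = t.grid.shape
        spec = {
            "kind": t.kind,
            "texel_size_mm": t.texel_size_mm,
            "extent_mm": [nu * t.texel_size_mm, nv * t.texel_size_mm],
            "seed": int(t.seed),
        }
        if t.kind == "checkerboard":
            levels = sorted(set(np.unique(t.grid).tolist()))
            if levels != [0.0, 1.0]:
                spec["levels"] = levels
        return spec
    raise ValueError(
        "only seeded procedural textures serialize to YAML; "
        "save image textures to PNG instead"
    )


def _texture_from_spec(spec: dict) -> Texture:
    kind = spec["kind"]
    extent = tuple(spec["extent_mm"])
    if kind == "checkerboard":
        levels = tuple(spec.get("levels", (0.0, 1.0)))
        return make_random_checkerboard(spec["texel_size_mm"], extent,
                                        spec["seed"], levels=levels)
    if kind == "one_over_f":
        return make_one_over_f_texture(extent, spec["seed"],
                                       texel_size_mm=spec["texel_size_mm"])
    raise ValueError(f"unknown texture kind {kind!r}")


def environment_to_yaml(env: Environment) -> str:
    """Serialize an environment (procedural textures only) to YAML text."""
    doc = {
        "name": env.name,
        "box_m": [env.width, env.depth, env.height],
        "walls": env.walls,
        "background": env.background,
        "goal_m": list(env.goal) if env.goal is not None else None,
        "wall_texture": _texture_spec(env.wall_texture),
        "floor_texture": _texture_spec(env.floor_texture),
        "ceiling_texture": _texture_spec(env.ceiling_texture),
        "obstacles": [
            {
                "center_m": list(ob.center),
                "base_edge_m": ob.base_edge,
                "height_m": ob.height,
                "texture": _texture_spec(ob.texture),
            }
            for ob in env.obstacles
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def environment_from_yaml(text: str) -> Environment:
    doc = yaml.safe_load(text)
    w, d, h = doc["box_m"]
    obstacles = tuple(
        BoxObstacle(center=tuple(ob["center_m"]), base_edge=ob["base_edge_m"],
                    height=ob["height_m"], texture=_texture_from_spec(ob["texture"]))
        for ob in doc.get("obstacles", [])
    )
    goal = doc.get("goal_m")
    return Environment(
        width=w, depth=d, height=h,
        wall_texture=_texture_from_spec(doc["wall_texture"]),
        floor_texture=_texture_from_spec(doc["floor_texture"]),
        ceiling_texture=_texture_from_spec(doc["ceiling_texture"]),
        obstacles=obstacles, walls=bool(doc.get("walls", True)),
        goal=tuple(goal) if goal is not None else None,
        background=float(doc.get("background", 0.5)),
        name=str(doc.get("name", "environment")),
    )
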