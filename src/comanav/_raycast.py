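"""Ray casting against axis-aligned textured arenas.

The scene is compiled once per environment into flat arrays (outer-box
dimensions, obstacle AABBs, a texture atlas) that a single monolithic numba
kernel consumes.  Rays are cast on a cylindrical-projection grid whose
columns share a world azimuth; obstacles are pre-binned by the azimuth
interval they subtend as seen from the eye, so each ray only tests the few
obstacles near its column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .environments import Environment

_EPS = 1e-12
_BIG = 1e30      # finite "no hit" sentinel so fastmath never sees inf


@dataclass(frozen=True)
class CompiledScene:
    """Flat-array form of an :class:`Environment` for the ray-cast kernel."""

    walls: bool
    size: np.ndarray          # (3,) box width, depth, height (m)
    background: float
    face_tex: np.ndarray      # (6,) texture index for x0,xW,y0,yD,floor,ceiling
    face_au: np.ndarray       # (6,) texel anchor offsets per face: faces that
    face_av: np.ndarray       #      share a texture tile it from different
    ob_cx: np.ndarray         #      anchors, so no two surfaces are clones
    ob_cy: np.ndarray
    ob_half: np.ndarray
    ob_h: np.ndarray
    ob_tex: np.ndarray
    ob_au: np.ndarray         # per-obstacle texel anchors (same rationale)
    ob_av: np.ndarray
    tex_offset: np.ndarray
    tex_nv: np.ndarray
    tex_nu: np.ndarray
    tex_texel: np.ndarray     # texel edge (m)
    atlas: np.ndarray         # flat float32 brightness values

    @staticmethod
    def from_environment(env: Environment) -> "CompiledScene":
        textures = [env.wall_texture, env.floor_texture, env.ceiling_texture]
        tex_index = {id(t): i for i, t in enumerate(textures)}
        ob_tex = []
        for ob in env.obstacles:
            if id(ob.texture) not in tex_index:
                tex_index[id(ob.texture)] = len(textures)
                textures.append(ob.texture)
            ob_tex.append(tex_index[id(ob.texture)])

        offsets, nvs, nus, texels, chunks = [], [], [], [], []
        pos = 0
        for t in textures:
            nv, nu = t.grid.shape
            offsets.append(pos)
            nvs.append(nv)
            nus.append(nu)
            texels.append(t.texel_size_m)
            chunks.append(np.ascontiguousarray(t.grid, dtype=np.float32).ravel())
            pos += nv * nu
        atlas = np.concatenate(chunks) if chunks else np.zeros(0, np.float32)

        nobs = len(env.obstacles)
        # fixed coprime strides decorrelate the anchors; face 0 is unshifted
        face_ids = np.arange(6)
        ob_ids = 6 + np.arange(max(nobs, 1))
        return CompiledScene(
            walls=env.walls,
            size=np.array([env.width, env.depth, env.height]),
            background=env.background,
            face_tex=np.array([0, 0, 0, 0, 1, 2], dtype=np.int64),
            face_au=(face_ids * 173).astype(np.int64),
            face_av=(face_ids * 97).astype(np.int64),
            ob_cx=np.array([ob.center[0] for ob in env.obstacles]),
            ob_cy=np.array([ob.center[1] for ob in env.obstacles]),
            ob_half=np.array([ob.base_edge / 2.0 for ob in env.obstacles]),
            ob_h=np.array([ob.height for ob in env.obstacles]),
            ob_tex=np.array(ob_tex, dtype=np.int64),
            ob_au=(ob_ids[:nobs] * 173).astype(np.int64),
            ob_av=(ob_ids[:nobs] * 97).astype(np.int64),
            tex_offset=np.array(offsets, dtype=np.int64),
            tex_nv=np.array(nvs, dtype=np.int64),
            tex_nu=np.array(nus, dtype=np.int64),
            tex_texel=np.array(texels),
            atlas=atlas,
        )


@njit(cache=True, fastmath=True)
def _cast_grid(ox, oy, oz, phi, cos_eps, sin_eps, cos_phi, sin_phi,
               walls, W, D, H, background, face_tex, face_au, face_av,
               ob_cx, ob_cy, ob_half, ob_h, ob_tex, ob_au, ob_av,
               tex_offset, tex_nv, tex_nu, tex_texel, atlas,
               want_brightness, dist, bright):
    """Cast the full elevation x azimuth grid from one eye position.

    For every ray the nearest hit among the outer-box faces (exit face, since
    the eye is inside) and the candidate obstacle AABBs is found, then the
    brightness is read from the hit surface's texture (nearest texel, tiled).
    Rays that escape an open environment get distance ``_BIG`` and the
    background brightness.
    """
    nrows = cos_eps.shape[0]
    ncols = cos_phi.shape[0]
    nobs = ob_cx.shape[0]

    # azimuth interval subtended by each obstacle, for per-column candidates
    theta = np.empty(nobs)
    delta = np.empty(nobs)
    for i in range(nobs):
        rx = ob_cx[i] - ox
        ry = ob_cy[i] - oy
        r = np.sqrt(rx * rx + ry * ry)
        rad = ob_half[i] * 1.4142135623730951
        theta[i] = np.arctan2(ry, rx)
        if r <= rad:
            delta[i] = np.pi  # eye inside the circumcircle: always a candidate
        else:
            delta[i] = np.arcsin(rad / r)

    cand = np.empty(max(nobs, 1), dtype=np.int64)
    for c in range(ncols):
        ncand = 0
        for i in range(nobs):
            dphi = phi[c] - theta[i]
            while dphi > np.pi:
                dphi -= 2.0 * np.pi
            while dphi < -np.pi:
                dphi += 2.0 * np.pi
            if abs(dphi) <= delta[i] + 0.03:
                cand[ncand] = i
                ncand += 1
        cp = cos_phi[c]
        sp = sin_phi[c]
        for r in range(nrows):
            dx = cos_eps[r] * cp
            dy = cos_eps[r] * sp
            dz = sin_eps[r]
            inv_dx = 1.0 / dx if abs(dx) > _EPS else _BIG
            inv_dy = 1.0 / dy if abs(dy) > _EPS else _BIG
            inv_dz = 1.0 / dz if abs(dz) > _EPS else _BIG

            best_t = _BIG
            kind = -1        # 0..5 outer face, 6 obstacle
            best_ob = -1
            best_face = -1   # obstacle face: 0 x-,1 x+,2 y-,3 y+,4 top
            if walls:
                tx = (((W if dx > 0.0 else 0.0) - ox) * inv_dx
                      if abs(dx) > _EPS else _BIG)
                ty = (((D if dy > 0.0 else 0.0) - oy) * inv_dy
                      if abs(dy) > _EPS else _BIG)
                tz = (((H if dz > 0.0 else 0.0) - oz) * inv_dz
                      if abs(dz) > _EPS else _BIG)
                if tx <= ty and tx <= tz:
                    best_t = tx
                    kind = 1 if dx > 0.0 else 0
                elif ty <= tz:
                    best_t = ty
                    kind = 3 if dy > 0.0 else 2
                else:
                    best_t = tz
                    kind = 5 if dz > 0.0 else 4

            for k in range(ncand):
                i = cand[k]
                t1 = (ob_cx[i] - ob_half[i] - ox) * inv_dx
                t2 = (ob_cx[i] + ob_half[i] - ox) * inv_dx
                if t1 > t2:
                    t1, t2 = t2, t1
                tmin = t1
                tmax = t2
                axis = 0
                t1 = (ob_cy[i] - ob_half[i] - oy) * inv_dy
                t2 = (ob_cy[i] + ob_half[i] - oy) * inv_dy
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                    axis = 1
                if t2 < tmax:
                    tmax = t2
                t1 = (0.0 - oz) * inv_dz
                t2 = (ob_h[i] - oz) * inv_dz
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                    axis = 2
                if t2 < tmax:
                    tmax = t2
                if tmax >= tmin and tmin > _EPS and tmin < best_t:
                    best_t = tmin
                    kind = 6
                    best_ob = i
                    if axis == 0:
                        best_face = 0 if dx > 0.0 else 1
                    elif axis == 1:
                        best_face = 2 if dy > 0.0 else 3
                    else:
                        best_face = 4

            if kind < 0:
                dist[r, c] = _BIG
                bright[r, c] = background
                continue
            dist[r, c] = best_t
            if not want_brightness:
                bright[r, c] = 0.0
                continue

            px = ox + best_t * dx
            py = oy + best_t * dy
            pz = oz + best_t * dz
            if kind < 6:
                tid = face_tex[kind]
                au = face_au[kind]
                av = face_av[kind]
                if kind <= 1:        # x = 0 / x = W walls
                    u, v = py, pz
                elif kind <= 3:      # y = 0 / y = D walls
                    u, v = px, pz
                else:                # floor / ceiling
                    u, v = px, py
            else:
                tid = ob_tex[best_ob]
                au = ob_au[best_ob]
                av = ob_av[best_ob]
                xlo = ob_cx[best_ob] - ob_half[best_ob]
                ylo = ob_cy[best_ob] - ob_half[best_ob]
                if best_face <= 1:
                    u, v = py - ylo, pz
                elif best_face <= 3:
                    u, v = px - xlo, pz
                else:
                    u, v = px - xlo, py - ylo
            nu = tex_nu[tid]
            nv = tex_nv[tid]
            iu = (int(np.floor(u / tex_texel[tid])) + au) % nu
            iv = (int(np.floor(v / tex_texel[tid])) + av) % nv
            if iu < 0:
                iu += nu
            if iv < 0:
                iv += nv
            bright[r, c] = atlas[tex_offset[tid] + iv * nu + iu]


def cast_grid(
    scene: CompiledScene,
    origin: np.ndarray,
    cos_eps: np.ndarray,
    sin_eps: np.ndarray,
    cos_phi: np.ndarray,
    sin_phi: np.ndarray,
    want_brightness: bool = True,
    phi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cast an (elevation x azimuth) grid of rays; returns (dist, brightness).

    ``phi`` (world azimuth per column, rad) may be supplied to avoid an
    arctan2 per column.  Distances of escaping rays (open environments) come
    back as a huge sentinel (> 1e29 m) with the background brightness.
    """
    nrows, ncols = cos_eps.shape[0], cos_phi.shape[0]
    dist = np.empty((nrows, ncols))
    bright = np.empty((nrows, ncols))
    W, D, H = scene.size
    if phi is None:
        phi = np.arctan2(sin_phi, cos_phi)
    _cast_grid(
        float(origin[0]), float(origin[1]), float(origin[2]),
        phi, cos_eps, sin_eps, cos_phi, sin_phi,
        scene.walls, W, D, H, scene.background,
        scene.face_tex, scene.face_au, scene.face_av,
        scene.ob_cx, scene.ob_cy, scene.ob_half, scene.ob_h, scene.ob_tex,
        scene.ob_au, scene.ob_av,
        scene.tex_offset, scene.tex_nv, scene.tex_nu, scene.tex_texel,
        scene.atlas, want_brightness, dist, bright,
    )
    return dist, bright


def cast_ray(
    scene: CompiledScene, origin: np.ndarray, direction: np.ndarray
) -> tuple[float, float]:
    """Cast a single ray; returns (distance, brightness).

    The direction need not be normalized.  Distance is ``inf`` (with the
    background brightness) only when the ray escapes an open environment.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be nonzero")
    d = d / n
    horiz = np.hypot(d[0], d[1])
    phi = np.array([np.arctan2(d[1], d[0])])
    dist, bright = cast_grid(
        scene, origin,
        cos_eps=np.array([horiz]), sin_eps=np.array([d[2]]),
        cos_phi=np.array([d[0] / horiz if horiz > 0 else 1.0]),
        sin_phi=np.array([d[1] / horiz if horiz > 0 else 0.0]),
        want_brightness=True, phi=phi,
    )
    t = float(dist[0, 0])
    return (t if t < _BIG * 0.5 else float("inf")), float(bright[0, 0])


def surface_distance(env: Environment, position: np.ndarray) -> float:
    """Shortest distance from a 3-D point to any surface of the environment."""
    x, y, z = position
    d = np.inf
    if env.walls:
        d = min(x, env.width - x, y, env.depth - y, z, env.height - z)
    for ob in env.obstacles:
        gx = max(abs(x - ob.center[0]) - ob.base_edge / 2.0, 0.0)
        gy = max(abs(y - ob.center[1]) - ob.base_edge / 2.0, 0.0)
        gz = max(z - ob.height, 0.0)
        d = min(d, np.sqrt(gx * gx + gy * gy + gz * gz))
    return float(d)
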