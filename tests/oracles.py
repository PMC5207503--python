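"""Independent brute-force oracles used by unit and acceptance tests.

The ray-cast oracle deliberately uses a different intersection formulation
from the package (plane intersection + barycentric inside test, dense over
all (pixel, triangle) pairs, no screen-space culling).
"""

import numpy as np

from vbsalab.camera import (CameraPlacement, Intrinsics, MISS_ID,
                            place_camera, resolve_look_at)
from vbsalab.mesh_core import Mesh


def brute_force_hit_ids(mesh: Mesh, intr: Intrinsics,
                        placement: CameraPlacement) -> np.ndarray:
    """Exhaustive nearest-intersection scan; returns an (H, W) face-id map."""
    look = resolve_look_at(placement, mesh)
    R, T = place_camera(placement, look)
    vc = mesh.vertices @ R.T + T
    H, W = intr.height, intr.width
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    yn = (ii + 0.5 - intr.oy) / (intr.f * intr.sy)
    xn = (jj + 0.5 - intr.ox - intr.f * intr.s_theta * yn) / (intr.f * intr.sx)
    d = np.stack([xn, yn, np.ones_like(xn)], -1).reshape(-1, 3)
    tri = vc[mesh.faces]
    best_t = np.full(len(d), np.inf)
    best_f = np.full(len(d), -1, dtype=np.int64)
    for k in range(len(tri)):
        a, b, c = tri[k]
        n = np.cross(b - a, c - a)
        denom = d @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a @ n) / denom
            pt = t[:, None] * d
            v0, v1, v2 = b - a, c - a, pt - a
            d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
            d20, d21 = v2 @ v0, v2 @ v1
            den = d00 * d11 - d01 * d01
            vv = (d11 * d20 - d01 * d21) / den
            ww = (d00 * d21 - d01 * d20) / den
        hit = ((np.abs(denom) > 1e-14) & (t > 1e-9)
               & (vv >= 0) & (ww >= 0) & (vv + ww <= 1))
        better = hit & ((t < best_t) | ((t == best_t) & (k < best_f)))
        best_t[better] = t[better]
        best_f[better] = k
    ids = np.full(len(d), MISS_ID, dtype=np.int64)
    ok = best_f >= 0
    ids[ok] = mesh.face_ids[best_f[ok]]
    return ids.reshape(H, W)


def random_triangle_soup(rng: np.random.Generator, n_triangles: int,
                         extent: float = 3.0) -> Mesh:
    v = rng.uniform(-extent, extent, size=(n_triangles * 3, 3))
    return Mesh(v, np.arange(n_triangles * 3).reshape(n_triangles, 3))


def fit_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS solve via the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)
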