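"""View body surface area (VBSA) three ways.

* ground truth: sum of the areas of the triangles hit by at least one ray,
  looked up in the *original* mesh by face id — no reconstruction involved;
* degraded: the same after random removal of visible triangles (depth-sensor
  hole simulation);
* reconstructed: area of a surface meshed directly off the organized
  single-view point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter

from .camera import MISS_ID, RayCastResult
from .mesh_core import Mesh, MeshError

__all__ = [
    "VbsaRecord",
    "vbsa_ground_truth",
    "simulate_holes",
    "reconstruct_organized",
    "smooth_and_decimate",
]


@dataclass
class VbsaRecord:
    """One (subject, view) VBSA measurement with its acquisition settings."""

    subject_id: str
    theta: float
    phi: float
    vbsa_gt: float               # dm^2
    wbsa: float                  # dm^2
    vbsa_holes: float | None = None
    vbsa_recon: float | None = None
    hole_fraction: float = 0.0
    distance_dm: float = 43.0
    width: int = 640
    height: int = 480
    noise: bool = False


def vbsa_ground_truth(mesh: Mesh, raycast_result: RayCastResult) -> float:
    """Sum of original-mesh areas over the visible-triangle-ID list (dm^2)."""
    ids = raycast_result.visible_ids
    if len(ids) == 0:
        return 0.0
    return mesh.area_of_ids(ids)


def simulate_holes(raycast_result: RayCastResult, p: float,
                   seed: int = 0) -> tuple[RayCastResult, float]:
    """Drop each visible triangle independently with probability p.

    Pixels whose hit triangle was dropped are blanked in the depth/point/ID
    maps, emulating sensor dropouts (IR interference, reflective surfaces).
    Returns the degraded acquisition and its VBSA.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("hole probability p must be in [0, 1]")
    if raycast_result.mesh is None:
        raise ValueError("raycast result carries no mesh")
    rng = np.random.default_rng(seed)
    ids = raycast_result.visible_ids
    keep = rng.random(len(ids)) >= p
    kept_ids = ids[keep]
    drop_set = set(int(i) for i in ids[~keep])

    hit_ids = raycast_result.hit_ids.copy()
    blank = np.isin(hit_ids, ids[~keep]) if drop_set else np.zeros(
        hit_ids.shape, dtype=bool)
    hit_ids[blank] = MISS_ID
    depth = raycast_result.depth.copy()
    depth[blank] = np.nan
    points = raycast_result.points.copy()
    points[blank] = np.nan

    degraded = replace(raycast_result, depth=depth, points=points,
                       hit_ids=hit_ids, visible_ids=kept_ids)
    vbsa = raycast_result.mesh.area_of_ids(kept_ids) if len(kept_ids) else 0.0
    return degraded, vbsa


def reconstruct_organized(raycast_result: RayCastResult,
                          depth_jump_threshold: float = 0.2) -> Mesh:
    """Mesh the organized point cloud on its pixel grid.

    Every 2x2 pixel quad whose four depths are finite and whose largest
    pairwise depth difference stays below ``depth_jump_threshold`` (dm)
    yields two triangles; larger jumps are treated as silhouette /
    depth-discontinuity boundaries and left unbridged.
    """
    if depth_jump_threshold <= 0:
        raise ValueError("depth_jump_threshold must be positive")
    depth = raycast_result.depth
    pts = raycast_result.points
    H, W = depth.shape
    d00 = depth[:-1, :-1]
    d01 = depth[:-1, 1:]
    d10 = depth[1:, :-1]
    d11 = depth[1:, 1:]
    stack = np.stack([d00, d01, d10, d11])
    finite = np.all(np.isfinite(stack), axis=0)
    filled = np.where(np.isfinite(stack), stack, 0.0)
    jump = filled.max(axis=0) - filled.min(axis=0)
    ok = finite & (jump < depth_jump_threshold)
    qi, qj = np.nonzero(ok)
    if len(qi) == 0:
        raise MeshError("no reconstructable quads in the view")
    lin = lambda i, j: i * W + j
    v00 = lin(qi, qj)
    v01 = lin(qi, qj + 1)
    v10 = lin(qi + 1, qj)
    v11 = lin(qi + 1, qj + 1)
    faces = np.concatenate([
        np.stack([v00, v01, v11], axis=1),
        np.stack([v00, v11, v10], axis=1),
    ])
    # compress vertex table to the used pixels
    used, inv = np.unique(faces, return_inverse=True)
    verts = pts.reshape(-1, 3)[used]
    return Mesh(verts, inv.reshape(faces.shape))


def smooth_and_decimate(raycast_result: RayCastResult,
                        voxel_size: float | None = None,
                        window: int = 3) -> RayCastResult:
    """Least-squares plane smoothing of depths, then voxel-grid thinning.

    Smoothing: for each pixel whose full ``window x window`` neighbourhood is
    finite, a plane Z = aX + bY + c is fit (ordinary least squares over the
    neighbourhood's 3D points) and the pixel's depth is moved along its own
    ray onto that plane — exact identity for noise-free planar input.

    Thinning: points are binned into cubic voxels of edge ``voxel_size`` (dm);
    in each voxel only the point nearest the voxel center is kept, the rest
    are blanked (organized layout preserved).  ``voxel_size`` of None/0 skips
    thinning.
    """
    depth = raycast_result.depth
    pts = raycast_result.points
    dirs = raycast_result.ray_dirs
    finite = np.isfinite(depth)

    X = np.where(finite, pts[..., 0], 0.0)
    Y = np.where(finite, pts[..., 1], 0.0)
    Zc = np.where(finite, pts[..., 2], 0.0)
    cnt = uniform_filter(finite.astype(float), window, mode="constant")
    full = cnt > 1.0 - 0.5 / window ** 2  # all window^2 samples finite

    def s(arr):
        return uniform_filter(arr, window, mode="constant") * window ** 2

    Sx, Sy, Sz = s(X), s(Y), s(Zc)
    Sxx, Syy, Sxy = s(X * X), s(Y * Y), s(X * Y)
    Sxz, Syz = s(X * Zc), s(Y * Zc)
    n = float(window ** 2)

    M = np.stack([
        np.stack([Sxx, Sxy, Sx], axis=-1),
        np.stack([Sxy, Syy, Sy], axis=-1),
        np.stack([Sx, Sy, np.full_like(Sx, n)], axis=-1),
    ], axis=-2)
    rhs = np.stack([Sxz, Syz, Sz], axis=-1)
    sel = full & finite
    new_depth = depth.copy()
    if np.any(sel):
        Msel = M[sel]
        ok = np.abs(np.linalg.det(Msel)) > 1e-12
        if np.any(ok):
            coef = np.linalg.solve(Msel[ok], rhs[sel][ok][..., None])[..., 0]
            a, b, c = coef[:, 0], coef[:, 1], coef[:, 2]
            xn = dirs[sel][ok][:, 0]
            ynrm = dirs[sel][ok][:, 1]
            denom = 1.0 - a * xn - b * ynrm
            good = np.abs(denom) > 1e-9
            z_new = np.where(good, c / np.where(good, denom, 1.0),
                             depth[sel][ok])
            tmp = new_depth[sel]
            okidx = np.flatnonzero(ok)
            tmp[okidx] = z_new
            new_depth[sel] = tmp

    out = replace(raycast_result, depth=new_depth)
    out.points = new_depth[..., None] * dirs

    if voxel_size and voxel_size > 0:
        p = out.points.reshape(-1, 3)
        d = out.depth.reshape(-1)
        fin = np.isfinite(d)
        idx = np.flatnonzero(fin)
        cells = np.floor(p[idx] / voxel_size).astype(np.int64)
        centers = (cells + 0.5) * voxel_size
        dist = np.linalg.norm(p[idx] - centers, axis=1)
        _, key = np.unique(cells, axis=0, return_inverse=True)
        order = np.lexsort((dist, key))
        first = np.ones(len(order), dtype=bool)
        first[1:] = key[order][1:] != key[order][:-1]
        keep = np.zeros(len(d), dtype=bool)
        keep[idx[order[first]]] = True
        d2 = np.where(keep, d, np.nan).reshape(out.depth.shape)
        out = replace(out, depth=d2)
        out.points = d2[..., None] * dirs
    return out
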