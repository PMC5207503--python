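"""Virtual 2.5-D depth camera.

Pinhole projection (intrinsic matrix K), polar camera placement around the
subject, per-pixel ray casting against a triangle mesh with triangle-ID
harvesting, and an optional axial/lateral sensor-noise model.

Conventions
-----------
* World frame: +y up, subject faces +z, subject's left toward +x; angles are
  azimuth theta (0 = frontal, 90 = subject's left side) and elevation phi
  (+90 = overhead), both in degrees; distances in decimeters.
* Camera frame: +z along the optical axis (into the scene), +x to image
  right, +y to image down; a pixel (row i, col j) has its center at
  continuous image coordinates (u, v) = (j + 0.5, i + 0.5).
* Depth is the camera-frame Z coordinate of the first ray-mesh intersection
  (dm); misses are NaN in the depth/point maps and -1 in the hit-ID map.

One ray is cast through every pixel center and only the nearest intersection
is kept.  The caster runs a watertight-style Möller-Trumbore test, restricted
per triangle to the conservative screen-space rectangle of its projection
(exact: a pixel-center ray can only hit a triangle over whose projection it
lies).  Equal-depth ties break to the lowest face id, so results are fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .mesh_core import Mesh

__all__ = [
    "Intrinsics",
    "CameraPlacement",
    "RayCastResult",
    "NoiseModel",
    "default_intrinsics",
    "project",
    "place_camera",
    "framing_distance",
    "max_stature",
    "raycast",
    "apply_noise",
    "nguyen_noise_model",
]

MISS_ID = -1


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics: K = [[f*sx, f*s_theta, ox], [0, f*sy, oy], [0, 0, 1]]."""

    f: float               # focal length (pixels once multiplied by sx/sy)
    sx: float = 1.0
    sy: float = 1.0
    s_theta: float = 0.0   # pixel skew
    ox: float = 0.0        # principal point (pixels)
    oy: float = 0.0
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.f <= 0 or self.sx <= 0 or self.sy <= 0:
            raise ValueError("f, sx, sy must be positive")
        if not (0 <= self.ox < self.width and 0 <= self.oy < self.height):
            raise ValueError("principal point outside image")

    @property
    def K(self) -> np.ndarray:
        return np.array([
            [self.f * self.sx, self.f * self.s_theta, self.ox],
            [0.0, self.f * self.sy, self.oy],
            [0.0, 0.0, 1.0],
        ])


def default_intrinsics(width: int = 640, height: int = 480,
                       fov_v_half_deg: float = 21.5) -> Intrinsics:
    """Kinect-for-Xbox-like stand-in: 640x480, 43 deg vertical FOV, no skew."""
    fy = (height / 2.0) / math.tan(math.radians(fov_v_half_deg))
    return Intrinsics(f=fy, ox=width / 2.0, oy=height / 2.0,
                      width=width, height=height)


@dataclass(frozen=True)
class CameraPlacement:
    """Polar placement of the camera about a look-at point.

    ``fov_v`` is the HALF vertical field of view psi in degrees, the angle
    that enters the framing relation maxStature = 2 tan(psi) D.
    """

    theta: float            # azimuth, degrees
    phi: float = 0.0        # elevation, degrees, in [-90, 90]
    distance: float = 43.0  # dm (4.3 m default)
    fov_v: float = 21.5     # half vertical FOV psi, degrees
    look_at: tuple[float, float, float] | None = None  # default: body center

    def __post_init__(self) -> None:
        if not -90.0 <= self.phi <= 90.0:
            raise ValueError("phi must be in [-90, 90] degrees")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def framing_distance(max_stature_dm: float, fov_v_half_deg: float) -> float:
    """Distance at which a subject of the given stature just fills the frame."""
    if not 0.0 < fov_v_half_deg < 90.0:
        raise ValueError("half FOV must be in (0, 90) degrees")
    if max_stature_dm <= 0:
        raise ValueError("stature must be positive")
    return max_stature_dm / (2.0 * math.tan(math.radians(fov_v_half_deg)))


def max_stature(distance_dm: float, fov_v_half_deg: float) -> float:
    """Tallest subject that fits vertically: maxStature = 2 tan(psi) D."""
    if not 0.0 < fov_v_half_deg < 90.0:
        raise ValueError("half FOV must be in (0, 90) degrees")
    if distance_dm <= 0:
        raise ValueError("distance must be positive")
    return 2.0 * math.tan(math.radians(fov_v_half_deg)) * distance_dm


def project(points, intrinsics: Intrinsics) -> np.ndarray:
    """Perspective projection of camera-frame points to pixel coordinates.

    x = f X / Z, y = f Y / Z, then through K:
    u = f sx x' + f s_theta y' + ox, v = f sy y' + oy  with (x', y') = (X/Z, Y/Z).
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    Z = p[:, 2]
    if np.any(Z <= 0):
        raise ValueError("point behind camera (Z <= 0)")
    xn = p[:, 0] / Z
    yn = p[:, 1] / Z
    u = intrinsics.f * intrinsics.sx * xn + intrinsics.f * intrinsics.s_theta * yn + intrinsics.ox
    v = intrinsics.f * intrinsics.sy * yn + intrinsics.oy
    uv = np.stack([u, v], axis=1)
    return uv[0] if single else uv


def _camera_center(placement: CameraPlacement, look_at: np.ndarray) -> np.ndarray:
    th = math.radians(placement.theta)
    ph = math.radians(placement.phi)
    d = np.array([math.sin(th) * math.cos(ph),
                  math.sin(ph),
                  math.cos(th) * math.cos(ph)])
    return look_at + placement.distance * d


def resolve_look_at(placement: CameraPlacement, mesh: Mesh) -> np.ndarray:
    """Explicit look-at if given, else the body center at half stature."""
    if placement.look_at is not None:
        return np.asarray(placement.look_at, dtype=float)
    lo, hi = mesh.bounds()
    return np.array([0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1]),
                     0.5 * (lo[2] + hi[2])])


def place_camera(placement: CameraPlacement,
                 look_at=(0.0, 0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Extrinsics (R, T) of the rigid transform p_cam = R p_world + T.

    The camera center sits at C = look_at + D (sin(th)cos(ph), sin(ph),
    cos(th)cos(ph)); the optical axis points at the look-at point and the up
    vector keeps the image upright (world +y maps to image up).  At the
    elevation poles (|phi| = 90) the up reference degenerates and the
    subject's facing direction +z is used instead.
    """
    look_at = np.asarray(look_at, dtype=float)
    C = _camera_center(placement, look_at)
    z_c = look_at - C
    z_c = z_c / np.linalg.norm(z_c)
    up_ref = np.array([0.0, 1.0, 0.0])
    if abs(float(np.dot(z_c, up_ref))) > 0.999:
        up_ref = np.array([0.0, 0.0, 1.0])
    x_c = np.cross(z_c, up_ref)
    x_c = x_c / np.linalg.norm(x_c)
    y_c = np.cross(z_c, x_c)
    R = np.stack([x_c, y_c, z_c], axis=0)
    T = -R @ C
    return R, T


@dataclass
class RayCastResult:
    """Organized single-view acquisition.

    ``depth``/``points``/``hit_ids`` are H x W (x 3) maps in pixel layout;
    ``visible_ids`` is the deduplicated sorted list of face ids hit by at
    least one ray — the ground-truth visibility list.
    """

    depth: np.ndarray            # (H, W) dm, NaN = miss
    points: np.ndarray           # (H, W, 3) camera-frame, NaN = miss
    hit_ids: np.ndarray          # (H, W) int face_id, MISS_ID = miss
    visible_ids: np.ndarray      # sorted unique face ids
    intrinsics: Intrinsics
    placement: CameraPlacement
    mesh: Mesh | None = None     # source mesh (for area lookups downstream)

    @property
    def ray_dirs(self) -> np.ndarray:
        """(H, W, 3) unnormalized ray directions (x', y', 1) per pixel."""
        intr = self.intrinsics
        H, W = self.depth.shape
        jj, ii = np.meshgrid(np.arange(W), np.arange(H))
        u = jj + 0.5
        v = ii + 0.5
        yn = (v - intr.oy) / (intr.f * intr.sy)
        xn = (u - intr.ox - intr.f * intr.s_theta * yn) / (intr.f * intr.sx)
        return np.stack([xn, yn, np.ones_like(xn)], axis=-1)

    def face_normals_map(self) -> np.ndarray:
        """(H, W, 3) unit normal of the hit triangle per pixel (camera frame is
        NOT applied; normals are in the mesh/world coordinates of ``mesh``)."""
        if self.mesh is None:
            raise ValueError("result carries no mesh")
        tri = self.mesh.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
        id_to_idx = {int(fid): k for k, fid in enumerate(self.mesh.face_ids)}
        out = np.full(self.depth.shape + (3,), np.nan)
        hit = self.hit_ids != MISS_ID
        idx = np.array([id_to_idx[int(f)] for f in self.hit_ids[hit]], dtype=int)
        if len(idx):
            out[hit] = n[idx]
        return out


def raycast(mesh: Mesh, intrinsics: Intrinsics, placement: CameraPlacement,
            _pair_chunk: int = 4_000_000) -> RayCastResult:
    """Cast one ray per pixel center; keep the nearest intersection only.

    Raises if the camera lies inside the mesh bounding sphere (the pinhole
    model degenerates) or if any vertex falls behind the image plane.
    """
    look_at = resolve_look_at(placement, mesh)
    center, radius = mesh.bounding_sphere()
    C = _camera_center(placement, look_at)
    R, T = place_camera(placement, look_at)
    vc = mesh.vertices @ R.T + T          # camera-frame vertices
    if vc[:, 2].min() <= 1e-9:
        if np.linalg.norm(C - center) <= radius:
            raise ValueError("camera center inside the mesh bounding sphere")
        raise ValueError("mesh extends behind the camera")

    intr = intrinsics
    W, H = intr.width, intr.height
    fx, fy, fs = intr.f * intr.sx, intr.f * intr.sy, intr.f * intr.s_theta
    Z = vc[:, 2]
    yn = vc[:, 1] / Z
    u = fx * vc[:, 0] / Z + fs * yn + intr.ox
    v = fy * yn + intr.oy

    tri = mesh.faces
    u_tri = u[tri]
    v_tri = v[tri]
    eps = 1e-9
    j0 = np.maximum(0, np.ceil(u_tri.min(axis=1) - 0.5 - eps).astype(np.int64))
    j1 = np.minimum(W - 1, np.floor(u_tri.max(axis=1) - 0.5 + eps).astype(np.int64))
    i0 = np.maximum(0, np.ceil(v_tri.min(axis=1) - 0.5 - eps).astype(np.int64))
    i1 = np.minimum(H - 1, np.floor(v_tri.max(axis=1) - 0.5 + eps).astype(np.int64))
    wf = j1 - j0 + 1
    hf = i1 - i0 + 1
    counts = np.where((wf > 0) & (hf > 0), wf * hf, 0)

    npx = H * W
    best_t = np.full(npx, np.inf)
    best_face = np.full(npx, -1, dtype=np.int64)

    v0 = vc[tri[:, 0]]
    e1 = vc[tri[:, 1]] - v0
    e2 = vc[tri[:, 2]] - v0

    # enumerate candidate (pixel, triangle) pairs in bounded chunks
    active = np.flatnonzero(counts)
    cum = np.cumsum(counts[active])
    total = int(cum[-1]) if len(active) else 0
    starts = cum - counts[active]
    pos = 0
    while pos < total:
        end = min(total, pos + _pair_chunk)
        # faces overlapping the global pair range [pos, end)
        a = np.searchsorted(cum, pos, side="right")
        b = np.searchsorted(cum, end - 1, side="right") + 1
        fsel = active[a:b]
        local_start = np.maximum(starts[a:b], pos) - starts[a:b]
        local_end = np.minimum(cum[a:b], end) - starts[a:b]
        ncand = (local_end - local_start).astype(np.int64)
        face_rep = np.repeat(fsel, ncand)
        # local index within each face's candidate rectangle
        cstart = np.concatenate([[0], np.cumsum(ncand)[:-1]])
        local = (np.arange(end - pos) - np.repeat(cstart, ncand)
                 + np.repeat(local_start, ncand))
        wrep = np.repeat(wf[fsel], ncand)
        row = np.repeat(i0[fsel], ncand) + local // wrep
        col = np.repeat(j0[fsel], ncand) + local % wrep

        ypix = (row + 0.5 - intr.oy) / fy
        xpix = (col + 0.5 - intr.ox - fs * ypix) / fx
        d = np.stack([xpix, ypix, np.ones_like(xpix)], axis=1)

        V0 = v0[face_rep]
        E1 = e1[face_rep]
        E2 = e2[face_rep]
        pvec = np.cross(d, E2)
        det = np.einsum("ij,ij->i", E1, pvec)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = np.where(np.abs(det) > 1e-14, 1.0 / det, 0.0)
            tvec = -V0
            ub = np.einsum("ij,ij->i", tvec, pvec) * inv_det
            qvec = np.cross(tvec, E1)
            vb = np.einsum("ij,ij->i", d, qvec) * inv_det
            t = np.einsum("ij,ij->i", E2, qvec) * inv_det
        hit = ((np.abs(det) > 1e-14) & (ub >= 0.0) & (vb >= 0.0)
               & (ub + vb <= 1.0) & (t > 1e-9))
        if np.any(hit):
            lin = (row * W + col)[hit]
            th = t[hit]
            fh = face_rep[hit]
            # nearest-depth, then lowest-face-id reduction per pixel
            order = np.lexsort((fh, th, lin))
            lin, th, fh = lin[order], th[order], fh[order]
            first = np.ones(len(lin), dtype=bool)
            first[1:] = lin[1:] != lin[:-1]
            lin, th, fh = lin[first], th[first], fh[first]
            better = (th < best_t[lin]) | (
                (th == best_t[lin]) & (fh < best_face[lin]))
            best_t[lin[better]] = th[better]
            best_face[lin[better]] = fh[better]
        pos = end

    depth = best_t.reshape(H, W)
    hit_mask = np.isfinite(depth)
    depth = np.where(hit_mask, depth, np.nan)
    hit_idx = best_face.reshape(H, W)
    hit_ids = np.full((H, W), MISS_ID, dtype=np.int64)
    hit_ids[hit_mask] = mesh.face_ids[hit_idx[hit_mask]]
    visible_ids = np.unique(hit_ids[hit_mask])

    result = RayCastResult(depth, None, hit_ids, visible_ids, intr, placement,
                           mesh)
    result.points = depth[..., None] * result.ray_dirs
    return result


# ---------------------------------------------------------------------------
# sensor noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Axial + lateral Gaussian depth-sensor noise.

    ``axial_sigma(depth_dm, incidence_rad) -> dm`` perturbs each depth sample;
    ``lateral_sigma(depth_dm) -> pixels`` drives a pixel-offset resampling
    jitter.  A disabled model is the identity.  Noise corrupts the measured
    geometry only; the ground-truth visibility list is untouched.
    """

    axial_sigma: Callable[[np.ndarray, np.ndarray], np.ndarray]
    lateral_sigma: Callable[[np.ndarray], np.ndarray]
    enabled: bool = True
    seed: int = 0


def nguyen_noise_model(seed: int = 0, enabled: bool = True) -> NoiseModel:
    """Kinect-like noise: axial sd quadratic in depth plus a grazing-angle
    term, lateral sd roughly constant in pixels (coefficients in meters from
    the published Kinect characterization, converted to dm here)."""

    def axial(depth_dm, incidence_rad):
        z = np.asarray(depth_dm, float) / 10.0  # m
        th = np.clip(np.abs(np.asarray(incidence_rad, float)), 0.0,
                     math.pi / 2 - 1e-3)
        base = 0.0012 + 0.0019 * (z - 0.4) ** 2
        graze = 0.0001 / np.sqrt(np.maximum(z, 1e-6)) * (
            th ** 2 / (math.pi / 2 - th) ** 2)
        return 10.0 * (base + graze)  # dm

    def lateral(depth_dm):
        return np.full_like(np.asarray(depth_dm, float), 0.815)  # px

    return NoiseModel(axial, lateral, enabled=enabled, seed=seed)


def apply_noise(result: RayCastResult, noise_model: NoiseModel | None,
                placement: CameraPlacement | None = None) -> RayCastResult:
    """Perturb an acquisition with seeded axial/lateral sensor noise.

    Axial: depth += N(0, axial_sigma(depth, incidence)^2) per hit pixel.
    Lateral: each hit pixel re-reads its depth from a Gaussian-offset
    neighbour (sd = lateral_sigma(depth) pixels, rounded), when that
    neighbour is itself a hit.  ``hit_ids``/``visible_ids`` are unchanged.
    """
    if noise_model is None or not noise_model.enabled:
        return result
    rng = np.random.default_rng(noise_model.seed)
    H, W = result.depth.shape
    depth = result.depth.copy()
    hit = np.isfinite(depth)

    # incidence: angle between the (normalized) ray and the surface normal
    if result.mesh is not None:
        R, _ = place_camera(result.placement,
                            resolve_look_at(result.placement, result.mesh))
        normals_cam = result.face_normals_map() @ R.T
        dirs = result.ray_dirs
        dn = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
        cosang = np.abs(np.einsum("ijk,ijk->ij", dn, normals_cam))
        incidence = np.arccos(np.clip(cosang, 0.0, 1.0))
    else:
        incidence = np.zeros_like(depth)

    # lateral jitter first (resample geometry), then axial perturbation
    sig_l = noise_model.lateral_sigma(depth)
    offs = rng.normal(0.0, 1.0, size=(H, W, 2)) * sig_l[..., None]
    di = np.rint(offs[..., 0]).astype(int)
    dj = np.rint(offs[..., 1]).astype(int)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    si = np.clip(ii + di, 0, H - 1)
    sj = np.clip(jj + dj, 0, W - 1)
    src = depth[si, sj]
    take = hit & np.isfinite(src)
    depth_l = depth.copy()
    depth_l[take] = src[take]

    sig_a = noise_model.axial_sigma(depth_l, incidence)
    noise = rng.normal(0.0, 1.0, size=(H, W)) * np.where(
        np.isfinite(sig_a), sig_a, 0.0)
    depth_out = np.where(hit, depth_l + noise, np.nan)

    out = replace(result, depth=depth_out)
    out.points = depth_out[..., None] * result.ray_dirs
    return out
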