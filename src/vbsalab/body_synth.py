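"""Parametric synthetic humanoid bodies and virtual populations.

The generator is a parametric-primitive stand-in for a full anthropometric
modeller: head ellipsoid, torso as a vertically-varying elliptic tube whose
frontal half-width exceeds its depth, limbs as capsules/tapered tubes, arms
slightly bent forward and inward (the default standing pose).  It is not meant
to be anatomically faithful — its purpose is to provide bodies whose size and
shape are *controllable* so that the whole-body / view surface-area (WBSA /
VBSA) relationship can be studied with exact ground truth.

Two population schemes are provided:

* a "random" population with every shape parameter drawn i.i.d. uniformly
  from configurable ranges (deliberately heavy on extreme bodies), and
* an "NHANES-style" population: a set of base subjects, each replicated with
  k variations that perturb only girth (weight proxy) and the muscle/fat
  balance, with stature, age and gender fixed per subject.

Lengths inside meshes are decimeters; the parameter/measurement interface is
in the field's customary units (cm for lengths, kg for the weight proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import ellipe

from .mesh_core import Mesh, total_area

__all__ = [
    "BodyParams",
    "SubjectRecord",
    "DEFAULT_PARAM_RANGES",
    "make_body",
    "measure_subject",
    "du_bois",
    "sample_random_population",
    "sample_nhanes_base",
    "sample_nhanes_style_population",
    "population_to_frame",
]

# Uniform sampling ranges for the random population: statures span small
# children to very tall adults, girth spans emaciated to obese, producing a
# wide, heavy-tailed WBSA spread including subjects rare in real populations.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "stature": (120.0, 220.0),   # cm
    "girth": (0.7, 1.5),         # cross-section scale (weight proxy)
    "muscle_fat": (0.0, 1.0),    # 0 = fat, 1 = lean/muscular
    "gender_shape": (0.0, 1.0),  # 0 = male-typical, 1 = female-typical blend
    "age": (5.0, 80.0),          # years
}

KID_AGE_MAX = 15.0  # kid/adult split (years)


@dataclass(frozen=True)
class BodyParams:
    """Macro shape parameters of one synthetic subject."""

    stature: float          # cm
    girth: float = 1.0      # dimensionless torso/limb cross-section scale
    muscle_fat: float = 0.5  # in [0, 1]; low = fat waist, high = lean + thicker limbs
    gender_shape: float = 0.5  # in [0, 1]; blends shoulder/hip/bust proportions
    age: float = 30.0       # years

    def validate(self) -> None:
        if not self.stature > 0:
            raise ValueError("stature must be positive")
        if not self.girth > 0:
            raise ValueError("girth must be positive")
        if not 0.0 <= self.muscle_fat <= 1.0:
            raise ValueError("muscle_fat must be in [0, 1]")
        if not 0.0 <= self.gender_shape <= 1.0:
            raise ValueError("gender_shape must be in [0, 1]")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass
class SubjectRecord:
    """One subject: parameters, measurements (cm / kg), WBSA and group labels."""

    subject_id: str
    params: BodyParams
    wbsa: float                      # dm^2, total mesh area
    measurements: dict[str, float] = field(default_factory=dict)
    sex: str = ""                    # "male" / "female"
    age_group: str = ""              # "kid" / "adult"
    stature_group: str = ""          # "small" / "normal" / "big"


def _group_labels(params: BodyParams, small_max_cm: float = 140.0,
                  normal_max_cm: float = 200.0) -> tuple[str, str, str]:
    sex = "female" if params.gender_shape >= 0.5 else "male"
    age_group = "kid" if params.age <= KID_AGE_MAX else "adult"
    if params.stature <= small_max_cm:
        stature_group = "small"
    elif params.stature <= normal_max_cm:
        stature_group = "normal"
    else:
        stature_group = "big"
    return sex, age_group, stature_group


# ---------------------------------------------------------------------------
# geometry plan: all key dimensions in dm, derived deterministically from params
# ---------------------------------------------------------------------------

@dataclass
class _BodyPlan:
    H: float                 # stature, dm
    leg_top: float           # hip height
    torso_top: float         # shoulder height
    neck_top: float
    torso_h: np.ndarray      # ring heights, hip..shoulder
    torso_a: np.ndarray      # frontal half-widths at rings
    torso_b: np.ndarray      # sagittal half-depths at rings
    neck_r: float
    head_c: np.ndarray       # head ellipsoid center
    head_r: np.ndarray       # (rx, ry, rz)
    arm_r: float
    arm_p0: np.ndarray       # left-arm shoulder point (right arm mirrored in x)
    arm_p1: np.ndarray       # left-arm hand point
    leg_x: float             # leg axis |x| offset
    leg_h: np.ndarray        # leg ring heights (top..bottom)
    leg_r: np.ndarray        # leg ring radii
    # profile interpolators for measurements
    a_of_h: PchipInterpolator
    b_of_h: PchipInterpolator
    waist_y: float
    underbust_y: float
    bust_y: float
    hip_y: float


def _plan(params: BodyParams) -> _BodyPlan:
    params.validate()
    H = params.stature / 10.0          # dm
    g = params.girth
    m = params.muscle_fat
    w = params.gender_shape

    leg_top = 0.50 * H
    torso_top = leg_top + 0.31 * H
    neck_top = torso_top + 0.03 * H
    head_ry = 0.08 * H                 # head top at neck_top + 2*ry = H

    # torso profile control points (heights absolute, half-widths in dm)
    hip_y = leg_top + 0.02 * H
    waist_y = leg_top + 0.09 * H
    underbust_y = leg_top + 0.19 * H
    bust_y = leg_top + 0.235 * H
    shoulder_y = torso_top
    waist_f = 0.80 + 0.45 * (1.0 - m)          # fat bulges the waist
    a_ctrl_y = np.array([leg_top, hip_y, waist_y, underbust_y, bust_y, shoulder_y])
    a_ctrl = H * g * np.array([
        0.088 * (1 + 0.12 * w),                # pelvis base
        0.095 * (1 + 0.12 * w),                # hips
        0.075 * waist_f,                       # waist
        0.085,                                 # underbust
        0.088 * (1 + 0.04 * w),                # bust/chest
        0.112 * (1 + 0.10 * (1 - w)),          # shoulders
    ])
    # depth (sagittal) kept below frontal width; bust adds forward depth
    depth_ratio = np.array([0.66, 0.66, 0.64, 0.62, 0.62 * (1 + 0.22 * w), 0.55])
    b_ctrl = a_ctrl * depth_ratio
    a_of_h = PchipInterpolator(a_ctrl_y, a_ctrl)
    b_of_h = PchipInterpolator(a_ctrl_y, b_ctrl)
    torso_h = np.linspace(leg_top, torso_top, 16)
    torso_a = a_of_h(torso_h)
    torso_b = b_of_h(torso_h)

    neck_r = 0.030 * H * g * (1 - 0.08 * w)
    head_c = np.array([0.0, neck_top + head_ry, 0.0])
    head_r = np.array([0.062 * H, head_ry, 0.068 * H])

    # arms: capsules from shoulder, tilted forward and slightly inward so the
    # distal arm sits in front of the thigh (visible frontally, occluded from
    # the rear) — the pose behind the azimuth asymmetries of interest
    arm_r = 0.028 * H * g * (0.85 + 0.30 * m)
    x_sh = float(a_ctrl[-1]) + 0.8 * arm_r
    arm_len = 0.36 * H
    arm_p0 = np.array([x_sh, shoulder_y - 0.2 * arm_r, 0.0])
    arm_p1 = np.array([0.55 * x_sh,
                       shoulder_y - 0.92 * arm_len,
                       0.30 * arm_len])

    # legs: tapered vertical tubes, thigh -> ankle, flat soles at y = 0
    leg_f = 0.90 + 0.25 * (1.0 - m)
    leg_x = 0.052 * H * (1 + 0.06 * w)
    leg_h = np.linspace(leg_top + 0.02 * H, 0.0, 12)
    top_r = 0.047 * H * g * leg_f
    bot_r = 0.020 * H * g
    t = np.linspace(0.0, 1.0, 12)
    leg_r = top_r + (bot_r - top_r) * t ** 0.8

    return _BodyPlan(H, leg_top, torso_top, neck_top, torso_h, torso_a, torso_b,
                     neck_r, head_c, head_r, arm_r, arm_p0, arm_p1,
                     leg_x, leg_h, leg_r, a_of_h, b_of_h,
                     waist_y, underbust_y, bust_y, hip_y)


# -- primitive builders (vertex/face lists, local numbering) ----------------

def _ring_tube(heights, half_w, half_d, n_seg, x0=0.0, cap_bottom=True,
               cap_top=True):
    """Vertical tube through elliptic rings (half_w along x, half_d along z)."""
    heights = np.asarray(heights, float)
    half_w = np.broadcast_to(np.asarray(half_w, float), heights.shape)
    half_d = np.broadcast_to(np.asarray(half_d, float), heights.shape)
    ang = 2 * np.pi * np.arange(n_seg) / n_seg
    ca, sa = np.cos(ang), np.sin(ang)
    verts = []
    for y, a, b in zip(heights, half_w, half_d):
        ring = np.stack([x0 + a * ca, np.full(n_seg, y), b * sa], axis=1)
        verts.append(ring)
    verts = np.concatenate(verts, axis=0)
    faces = []
    for k in range(len(heights) - 1):
        base0, base1 = k * n_seg, (k + 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            faces.append([base0 + j, base0 + jn, base1 + jn])
            faces.append([base0 + j, base1 + jn, base1 + j])
    extra = []
    if cap_bottom:
        c0 = len(verts) + len(extra)
        extra.append([x0, heights[0], 0.0])
        for j in range(n_seg):
            faces.append([c0, (j + 1) % n_seg, j])
    if cap_top:
        c1 = len(verts) + len(extra)
        extra.append([x0, heights[-1], 0.0])
        base = (len(heights) - 1) * n_seg
        for j in range(n_seg):
            faces.append([c1, base + j, base + (j + 1) % n_seg])
    if extra:
        verts = np.vstack([verts, np.array(extra)])
    return verts, np.array(faces, dtype=np.int64)


def _uv_sphere(center, radii, n_lat, n_lon):
    """Ellipsoid as a UV sphere (poles + latitude rings)."""
    center = np.asarray(center, float)
    radii = np.asarray(radii, float)
    lat = np.pi * (np.arange(1, n_lat) / n_lat)  # exclude poles
    lon = 2 * np.pi * np.arange(n_lon) / n_lon
    verts = [center + radii * np.array([0.0, 1.0, 0.0])]  # top pole
    for la in lat:
        y = np.cos(la)
        r = np.sin(la)
        ring = np.stack([r * np.cos(lon), np.full(n_lon, y), r * np.sin(lon)],
                        axis=1)
        verts.extend(center + radii * ring)
    verts.append(center + radii * np.array([0.0, -1.0, 0.0]))  # bottom pole
    verts = np.array(verts)
    faces = []
    ring0 = 1
    for j in range(n_lon):
        faces.append([0, ring0 + (j + 1) % n_lon, ring0 + j])
    for k in range(n_lat - 2):
        a0, b0 = 1 + k * n_lon, 1 + (k + 1) * n_lon
        for j in range(n_lon):
            jn = (j + 1) % n_lon
            faces.append([a0 + j, a0 + jn, b0 + jn])
            faces.append([a0 + j, b0 + jn, b0 + j])
    bot = len(verts) - 1
    last = 1 + (n_lat - 2) * n_lon
    for j in range(n_lon):
        faces.append([bot, last + j, last + (j + 1) % n_lon])
    return verts, np.array(faces, dtype=np.int64)


def _capsule(p0, p1, radius, n_seg=14, n_len=8, n_cap=4):
    """Capsule (cylinder + hemispherical caps) from p0 to p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    # build along +y in local frame then rotate
    lat_top = 0.5 * np.pi * np.arange(n_cap) / n_cap            # top cap rows
    lat_bot = 0.5 * np.pi * (np.arange(n_cap) / n_cap)[::-1]
    rows = []
    rows.append((length + radius, 0.0, True))                    # top pole
    for la in lat_top[1:][::-1]:
        rows.append((length + radius * np.cos(la), radius * np.sin(la), False))
    for t in np.linspace(1.0, 0.0, n_len):
        rows.append((length * t, radius, False))
    for la in lat_bot[1:]:
        rows.append((-radius * np.cos(la), radius * np.sin(la), False))
    rows.append((-radius, 0.0, True))                            # bottom pole
    lon = 2 * np.pi * np.arange(n_seg) / n_seg
    cl, sl = np.cos(lon), np.sin(lon)
    verts = []
    ring_start = []
    for y, r, is_pole in rows:
        ring_start.append(len(verts))
        if is_pole:
            verts.append(np.array([0.0, y, 0.0]))
        else:
            verts.extend(np.stack([r * cl, np.full(n_seg, y), r * sl], axis=1))
    verts = np.array(verts)
    faces = []
    for j in range(n_seg):  # top pole fan
        faces.append([0, ring_start[1] + (j + 1) % n_seg, ring_start[1] + j])
    for k in range(1, len(rows) - 2):
        a0, b0 = ring_start[k], ring_start[k + 1]
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            faces.append([a0 + j, a0 + jn, b0 + jn])
            faces.append([a0 + j, b0 + jn, b0 + j])
    bot = len(verts) - 1
    last = ring_start[-2]
    for j in range(n_seg):
        faces.append([bot, last + j, last + (j + 1) % n_seg])
    faces = np.array(faces, dtype=np.int64)

    # rotate local +y onto the capsule axis, translate to p0
    d = axis / length
    y_axis = np.array([0.0, 1.0, 0.0])
    v = np.cross(y_axis, d)
    c = float(np.dot(y_axis, d))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return verts @ R.T + p0, faces


def make_body(params: BodyParams) -> Mesh:
    """Deterministic humanoid mesh for the given parameters.

    The mesh stands on the floor (y = 0), faces +z, with its left side toward
    +x; its bounding-box height equals the requested stature exactly (head top
    at stature, soles at 0).  Identical parameters produce identical meshes.
    """
    plan = _plan(params)
    parts = []
    parts.append(_ring_tube(plan.torso_h, plan.torso_a, plan.torso_b, 24))
    neck_h = np.linspace(plan.torso_top - 0.01 * plan.H, plan.neck_top + 0.01 * plan.H, 3)
    parts.append(_ring_tube(neck_h, plan.neck_r, plan.neck_r, 14))
    parts.append(_uv_sphere(plan.head_c, plan.head_r, 12, 16))
    mirror = np.array([-1.0, 1.0, 1.0])
    parts.append(_capsule(plan.arm_p0, plan.arm_p1, plan.arm_r))
    parts.append(_capsule(plan.arm_p0 * mirror, plan.arm_p1 * mirror, plan.arm_r))
    for sgn in (+1.0, -1.0):
        parts.append(_ring_tube(plan.leg_h, plan.leg_r, plan.leg_r, 16,
                                x0=sgn * plan.leg_x))
    verts_all, faces_all, off = [], [], 0
    for v, f in parts:
        verts_all.append(v)
        faces_all.append(f + off)
        off += len(v)
    return Mesh(np.concatenate(verts_all), np.concatenate(faces_all))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E."""
    if a < b:
        a, b = b, a
    if a == 0:
        return 0.0
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(m))


def _volume_proxy(plan: _BodyPlan) -> float:
    """Approximate body volume (dm^3 = liters) from the parametric solids."""
    h = np.linspace(plan.leg_top, plan.torso_top, 200)
    torso = np.trapezoid(np.pi * plan.a_of_h(h) * plan.b_of_h(h), h)
    head = 4.0 / 3.0 * np.pi * float(np.prod(plan.head_r))
    neck = np.pi * plan.neck_r ** 2 * (plan.neck_top - plan.torso_top)
    arm_len = float(np.linalg.norm(plan.arm_p1 - plan.arm_p0))
    arms = 2 * (np.pi * plan.arm_r ** 2 * arm_len
                + 4.0 / 3.0 * np.pi * plan.arm_r ** 3)
    legs = 2 * abs(np.trapezoid(np.pi * plan.leg_r ** 2, plan.leg_h))
    return float(torso + head + neck + arms + legs)


BODY_DENSITY_KG_PER_L = 1.0  # weight proxy: roughly the density of a human body


def measure_subject(mesh: Mesh, params: BodyParams) -> dict[str, float]:
    """NHANES-style measurements (cm / kg) of a generated body.

    Circumferences are planar cross-section perimeters of the parametric
    solids at the named heights (exact ellipse perimeters, not mesh slices);
    stature is read off the mesh bounding box; the weight proxy is the
    parametric volume times a nominal 1 kg/L body density.
    """
    plan = _plan(params)
    lo, hi = mesh.bounds()
    for y in (plan.waist_y, plan.bust_y, plan.underbust_y, plan.hip_y):
        if not (lo[1] - 1e-9 <= y <= hi[1] + 1e-9):
            raise ValueError(f"section height {y} dm outside body extent")

    def circ(y: float) -> float:  # cm
        return 10.0 * _ellipse_perimeter(float(plan.a_of_h(y)), float(plan.b_of_h(y)))

    return {
        "stature_cm": 10.0 * float(hi[1] - lo[1]),
        "waist_circ_cm": circ(plan.waist_y),
        "hip_circ_cm": circ(plan.hip_y),
        "bust_circ_cm": circ(plan.bust_y),
        "underbust_circ_cm": circ(plan.underbust_y),
        "neck_circ_cm": 10.0 * 2.0 * np.pi * plan.neck_r,
        "frontchest_cm": 10.0 * 2.0 * float(plan.a_of_h(plan.bust_y)),
        "weight_kg": BODY_DENSITY_KG_PER_L * _volume_proxy(plan),
    }


def du_bois(weight: float, stature: float) -> float:
    """Classical height-weight body-surface-area estimate (m^2).

    WBSA = 0.007184 * W^0.425 * H^0.725 with W in kg and H in cm.
    """
    if weight <= 0 or stature <= 0:
        raise ValueError("weight and stature must be positive")
    return 0.007184 * weight ** 0.425 * stature ** 0.725


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _build_record(subject_id: str, params: BodyParams,
                  small_max_cm: float = 140.0) -> tuple[SubjectRecord, Mesh]:
    mesh = make_body(params)
    wbsa = total_area(mesh).wbsa
    meas = measure_subject(mesh, params)
    sex, age_group, stature_group = _group_labels(params, small_max_cm)
    rec = SubjectRecord(subject_id, params, wbsa, meas, sex, age_group,
                        stature_group)
    return rec, mesh


def sample_random_population(
    n: int,
    seed: int,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    small_max_cm: float = 140.0,
) -> tuple[list[SubjectRecord], list[Mesh]]:
    """i.i.d. uniform population over the configured parameter ranges.

    Uniform (not normal) sampling is deliberate: it over-represents extreme
    body shapes, which are exactly the subjects that stress a WBSA predictor.
    Fully reproducible from (n, seed, ranges).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draws = {name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in ranges.items()}
    records, meshes = [], []
    for i in range(n):
        params = BodyParams(
            stature=float(draws["stature"][i]),
            girth=float(draws["girth"][i]),
            muscle_fat=float(draws["muscle_fat"][i]),
            gender_shape=float(draws["gender_shape"][i]),
            age=float(draws["age"][i]),
        )
        rec, mesh = _build_record(f"rand{i:05d}", params, small_max_cm)
        records.append(rec)
        meshes.append(mesh)
    return records, meshes


def sample_nhanes_base(n_base: int, seed: int,
                       param_ranges: dict[str, tuple[float, float]] | None = None
                       ) -> list[BodyParams]:
    """Draw the fixed per-subject parameters of an NHANES-style base table."""
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_base):
        out.append(BodyParams(
            stature=float(rng.uniform(*ranges["stature"])),
            girth=1.0,
            muscle_fat=float(rng.uniform(*ranges["muscle_fat"])),
            gender_shape=float(rng.uniform(*ranges["gender_shape"])),
            age=float(rng.uniform(*ranges["age"])),
        ))
    return out


def sample_nhanes_style_population(
    base_subjects: list[BodyParams],
    k_variations: int,
    seed: int = 0,
    girth_range: tuple[float, float] = (0.80, 1.30),
    include_originals: bool = False,
    small_max_cm: float = 140.0,
    build_meshes: bool = False,
) -> list[SubjectRecord] | tuple[list[SubjectRecord], list[Mesh]]:
    """Base subjects plus k variations each, varying girth and muscle/fat only.

    Each base subject is replicated over a near-square grid of (girth factor,
    muscle_fat) values — a fat-to-skinny family of the same individual —
    while stature, age and gender stay fixed.  Output size is
    ``len(base) * k`` (plus the originals when requested).
    """
    if k_variations < 1:
        raise ValueError("k_variations must be >= 1")
    if not base_subjects:
        raise ValueError("base_subjects is empty")
    mlo, mhi = 0.0, 1.0
    if k_variations == 1:
        grid = [(1.0, None)]  # identity variation: the base subject itself
    else:
        ng = int(math.ceil(math.sqrt(k_variations)))
        gf = np.linspace(girth_range[0], girth_range[1], ng)
        mf = np.linspace(mlo, mhi, ng)
        grid = [(float(gf[i]), float(mf[j]))
                for i in range(ng) for j in range(ng)][:k_variations]
    records: list[SubjectRecord] = []
    meshes: list[Mesh] = []

    def emit(sid: str, params: BodyParams) -> None:
        rec, mesh = _build_record(sid, params, small_max_cm)
        if build_meshes:
            meshes.append(mesh)
        records.append(rec)

    for b, base in enumerate(base_subjects):
        base.validate()
        if include_originals:
            emit(f"nh{b:04d}_base", base)
        for v, (gfac, mval) in enumerate(grid):
            params = replace(
                base,
                girth=base.girth * gfac,
                muscle_fat=base.muscle_fat if mval is None else mval,
            )
            emit(f"nh{b:04d}_v{v:03d}", params)
    if build_meshes:
        return records, meshes
    return records


def population_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """NHANES-style table: one row per subject, measurements as columns."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.params.age,
            "gender": r.sex,
            "age_group": r.age_group,
            "stature_group": r.stature_group,
            "girth": r.params.girth,
            "muscle_fat": r.params.muscle_fat,
            "gender_shape": r.params.gender_shape,
            "wbsa_dm2": r.wbsa,
        }
        row.update(r.measurements)
        rows.append(row)
    return pd.DataFrame(rows)
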