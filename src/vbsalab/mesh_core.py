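"""Triangle-mesh container, OBJ I/O and triangle-level geometry.

The canonical length unit throughout the package is the **decimeter** (dm), so
that surface areas come out in dm^2, the unit in which whole-body surface area
(WBSA) is conventionally reported.  Every triangle carries a stable integer
identifier (``face_id``); visibility analysis is done purely in terms of these
identifiers, so they must survive I/O round-trips and subdivision must map new
triangles back to their parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "AreaReport",
    "MeshError",
    "ObjParseError",
    "read_obj",
    "write_obj",
    "triangle_area",
    "total_area",
    "subdivide",
    "scale_mesh",
]


class MeshError(ValueError):
    """Raised for structurally invalid meshes (empty, bad indices...)."""


class ObjParseError(MeshError):
    """Raised on malformed OBJ records; carries the offending line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


@dataclass
class Mesh:
    """Triangle mesh with stable per-triangle identifiers.

    Attributes
    ----------
    vertices : (V, 3) float array, decimeters.
    faces : (F, 3) int array of vertex indices (0-based).
    face_ids : (F,) int array, unique identifier per triangle.
    parent_ids : optional (F,) int array mapping each triangle to the
        ``face_id`` of the triangle it was subdivided from.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    parent_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.face_ids is None:
            self.face_ids = np.arange(len(self.faces), dtype=np.int64)
        else:
            self.face_ids = np.asarray(self.face_ids, dtype=np.int64)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if len(self.faces) == 0:
            raise MeshError("mesh has zero faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face vertex index out of range")
        if len(self.face_ids) != len(self.faces):
            raise MeshError("face_ids length mismatch")
        if len(np.unique(self.face_ids)) != len(self.face_ids):
            raise MeshError("face_ids are not unique")
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise MeshError("degenerate face with repeated vertex index")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        """Per-triangle areas (dm^2), ordered like ``faces``."""
        tri = self.triangles()
        u = tri[:, 1] - tri[:, 0]
        v = tri[:, 2] - tri[:, 0]
        return 0.5 * np.linalg.norm(np.cross(u, v), axis=1)

    def area_of_ids(self, ids: np.ndarray) -> float:
        """Sum of areas of the triangles with the given face_ids."""
        ids = np.asarray(ids, dtype=np.int64)
        order = np.argsort(self.face_ids)
        pos = np.searchsorted(self.face_ids[order], ids)
        if np.any(pos >= len(order)) or np.any(
            self.face_ids[order][np.clip(pos, 0, len(order) - 1)] != ids
        ):
            raise MeshError("unknown face_id in id list")
        return float(self.face_areas()[order[pos]].sum())

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def bounding_sphere(self) -> tuple[np.ndarray, float]:
        lo, hi = self.bounds()
        center = 0.5 * (lo + hi)
        radius = float(np.linalg.norm(self.vertices - center, axis=1).max())
        return center, radius


@dataclass
class AreaReport:
    """Total surface area plus the per-triangle breakdown (dm^2)."""

    wbsa: float
    per_face_area: dict[int, float]


def triangle_area(u, v) -> float:
    """Area of the triangle spanned by edge vectors ``u`` and ``v``.

    A = 0.5 * |u x v| — half the parallelogram magnitude.  Degenerate
    (collinear) edges give 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(u, v)))


def total_area(mesh: Mesh) -> AreaReport:
    """WBSA of a mesh: the plain sum of its per-triangle areas."""
    areas = mesh.face_areas()
    return AreaReport(
        wbsa=float(areas.sum()),
        per_face_area={int(fid): float(a) for fid, a in zip(mesh.face_ids, areas)},
    )


def scale_mesh(mesh: Mesh, s: float) -> Mesh:
    """Isotropic scaling about the origin; areas scale by s^2."""
    return Mesh(mesh.vertices * float(s), mesh.faces.copy(),
                mesh.face_ids.copy(),
                None if mesh.parent_ids is None else mesh.parent_ids.copy())


def subdivide(mesh: Mesh, levels: int) -> Mesh:
    """Flat midpoint (1 -> 4) subdivision.

    No smoothing is applied, so total area is conserved exactly (up to
    floating-point accumulation).  New triangles get fresh sequential
    face_ids; ``parent_ids`` records, for every output triangle, the face_id
    of the *input* triangle it descends from (composed across levels).
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if levels == 0:
        return Mesh(mesh.vertices.copy(), mesh.faces.copy(), mesh.face_ids.copy(),
                    mesh.face_ids.copy())

    vertices = mesh.vertices
    faces = mesh.faces
    parents = mesh.face_ids
    for _ in range(levels):
        edges = np.concatenate(
            [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
        )
        edges_sorted = np.sort(edges, axis=1)
        uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
        midpoints = 0.5 * (vertices[uniq[:, 0]] + vertices[uniq[:, 1]])
        mid_idx = len(vertices) + inverse.reshape(3, -1).T  # (F, 3): m01, m12, m20
        vertices = np.vstack([vertices, midpoints])
        v0, v1, v2 = faces.T
        m01, m12, m20 = mid_idx.T
        faces = np.concatenate(
            [
                np.stack([v0, m01, m20], axis=1),
                np.stack([m01, v1, m12], axis=1),
                np.stack([m20, m12, v2], axis=1),
                np.stack([m01, m12, m20], axis=1),
            ],
            axis=0,
        )
        parents = np.tile(parents, 4)

    return Mesh(vertices, faces, np.arange(len(faces), dtype=np.int64), parents)


# -- OBJ I/O ---------------------------------------------------------------

def read_obj(path) -> Mesh:
    """Read a Wavefront OBJ (v/f records only; quads accepted).

    Quads are fan-split at the first vertex: (v0,v1,v2) + (v0,v2,v3).
    face_ids are assigned in file order (after splitting); OBJ's 1-based
    indices are converted to 0-based.  Malformed records raise
    :class:`ObjParseError` naming the line.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tag, *rest = line.split()
            if tag == "v":
                if len(rest) < 3:
                    raise ObjParseError("vertex record needs 3 coordinates", line_no)
                try:
                    vertices.append([float(x) for x in rest[:3]])
                except ValueError:
                    raise ObjParseError("non-numeric vertex coordinate", line_no)
            elif tag == "f":
                if len(rest) < 3 or len(rest) > 4:
                    raise ObjParseError(
                        f"face record with {len(rest)} vertices (3 or 4 supported)",
                        line_no,
                    )
                try:
                    # tolerate v/vt/vn references; only the vertex index is used
                    idx = [int(tok.split("/")[0]) for tok in rest]
                except ValueError:
                    raise ObjParseError("non-integer face index", line_no)
                idx = [i - 1 if i > 0 else len(vertices) + i for i in idx]
                if len(idx) == 3:
                    faces.append(idx)
                else:  # quad -> fixed fan split
                    faces.append([idx[0], idx[1], idx[2]])
                    faces.append([idx[0], idx[2], idx[3]])
    if not faces:
        raise MeshError(f"{path}: OBJ contains no faces")
    return Mesh(np.array(vertices), np.array(faces))


def write_obj(mesh: Mesh, path) -> None:
    """Write triangles-only OBJ (1-based indices), face order = face_id order."""
    order = np.argsort(mesh.face_ids)
    with open(path, "w") as fh:
        fh.write(f"# vbsalab mesh: {len(mesh.vertices)} vertices, "
                 f"{mesh.n_faces} triangles, units dm\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces[order]:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
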