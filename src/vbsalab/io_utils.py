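"""Plain-text writers/readers for acquisitions and configs.

Organized point clouds go to ASCII PLY with the row/column organization
retained in header comments and point order (row-major, misses written as
nan).  Depth maps go to CSV matrices; configs are flat ``key = value`` text.
"""

from __future__ import annotations

import numpy as np

from .camera import RayCastResult

__all__ = ["write_ply_organized", "write_depth_csv", "read_depth_csv",
           "write_config", "read_config"]


def write_ply_organized(result: RayCastResult, path) -> None:
    """ASCII PLY of the organized cloud; one vertex per pixel, row-major."""
    H, W = result.depth.shape
    pts = result.points.reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment organized point cloud rows {H} cols {W} row-major\n")
        fh.write("comment units decimeters, camera frame; nan = miss\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")


def write_depth_csv(result: RayCastResult, path) -> None:
    np.savetxt(path, result.depth, delimiter=",", fmt="%.9g")


def read_depth_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(cfg.items()):
            fh.write(f"{k} = {v}\n")


def read_config(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
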