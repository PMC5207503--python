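"""End-to-end sweep: population x camera-angle grid -> VBSA table -> fits.

The default angle grid is azimuth theta in {0, 30, 45, 60, 90, 120, 135,
150, 180} and elevation phi in {0, +-30, +-45, +-60, +-90} degrees, with the
two elevation poles run at theta = 0 only (azimuth is meaningless looking
straight down/up): 9 x 7 + 2 = 65 angle cells.  Azimuth covers one side only
because the synthetic subjects are left-right symmetric; a flag widens it.
Sweeps are resumable: angle cells already present in the output CSV are
skipped on rerun, and a manifest logs seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body_synth import SubjectRecord
from .camera import CameraPlacement, apply_noise, default_intrinsics, \
    nguyen_noise_model, raycast
from .mesh_core import Mesh
from .regression import AngleFit, fit_by_group, cross_validate, fits_to_frame
from .visibility import VbsaRecord, simulate_holes, vbsa_ground_truth

logger = logging.getLogger(__name__)

__all__ = ["SweepConfig", "default_angle_grid", "run_sweep", "report"]

DEFAULT_THETAS = (0.0, 30.0, 45.0, 60.0, 90.0, 120.0, 135.0, 150.0, 180.0)
DEFAULT_PHIS = (0.0, 30.0, -30.0, 45.0, -45.0, 60.0, -60.0, 90.0, -90.0)


@dataclass
class SweepConfig:
    theta_grid: tuple = DEFAULT_THETAS
    phi_grid: tuple = DEFAULT_PHIS
    distance: float = 43.0           # dm
    width: int = 640
    height: int = 480
    fov_v: float = 21.5              # half vertical FOV, degrees
    noise: bool = False
    hole_fraction: float = 0.0
    groups: tuple = ("all",)         # column names or "all"
    model_variants: tuple = ("vbsa",)  # "vbsa", "vbsa+stature"
    seed: int = 0
    k_folds: int = 10
    full_azimuth: bool = False       # mirror thetas to the right side too

    def __post_init__(self) -> None:
        if not self.theta_grid or not self.phi_grid:
            raise ValueError("angle grids must be non-empty")


def default_angle_grid(config: SweepConfig) -> list[tuple[float, float]]:
    """(theta, phi) cells; at phi = +-90 only theta = 0 is run."""
    thetas = list(config.theta_grid)
    if config.full_azimuth:
        thetas += [-t for t in thetas if 0.0 < abs(t) < 180.0]
    cells = []
    for phi in config.phi_grid:
        if abs(phi) == 90.0:
            cells.append((0.0, phi))
        else:
            for th in thetas:
                cells.append((th, phi))
    return cells


def _config_hash(config: SweepConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def run_sweep(records: list[SubjectRecord], meshes: list[Mesh],
              config: SweepConfig, out_dir=None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ray-cast every subject at every angle cell, then fit per cell.

    Returns (vbsa_table, fit_table).  With ``out_dir`` set, both tables are
    written as CSV, a manifest records seed/config/version, and angle cells
    already present in an existing vbsa CSV are not recomputed.
    """
    if len(records) != len(meshes):
        raise ValueError("records and meshes differ in length")
    intr = default_intrinsics(config.width, config.height, config.fov_v)
    cells = default_angle_grid(config)
    noise_model = nguyen_noise_model(seed=config.seed) if config.noise else None

    out_dir = Path(out_dir) if out_dir is not None else None
    vbsa_path = out_dir / "vbsa_records.csv" if out_dir else None
    done: set[tuple[float, float]] = set()
    old_rows: pd.DataFrame | None = None
    if vbsa_path is not None and vbsa_path.exists():
        old_rows = pd.read_csv(vbsa_path)
        done = set(zip(old_rows["theta"], old_rows["phi"]))
        logger.info("resuming sweep: %d angle cells already computed", len(done))

    rows = []
    for theta, phi in cells:
        if (theta, phi) in done:
            continue
        for rec, mesh in zip(records, meshes):
            if mesh is None:
                raise FileNotFoundError(
                    f"mesh for subject {rec.subject_id} is missing")
            placement = CameraPlacement(theta=theta, phi=phi,
                                        distance=config.distance,
                                        fov_v=config.fov_v)
            res = raycast(mesh, intr, placement)
            if noise_model is not None:
                res = apply_noise(res, noise_model, placement)
            gt = vbsa_ground_truth(mesh, res)
            vh = None
            if config.hole_fraction > 0:
                _, vh = simulate_holes(res, config.hole_fraction,
                                       seed=config.seed)
            rows.append(VbsaRecord(
                subject_id=rec.subject_id, theta=theta, phi=phi,
                vbsa_gt=gt, wbsa=rec.wbsa, vbsa_holes=vh,
                hole_fraction=config.hole_fraction,
                distance_dm=config.distance, width=config.width,
                height=config.height, noise=config.noise))
    new_tab = pd.DataFrame([asdict(r) for r in rows])
    vbsa_tab = (pd.concat([old_rows, new_tab], ignore_index=True)
                if old_rows is not None else new_tab)

    # attach subject metadata for grouping / extra predictors
    meta = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "sex": [r.sex for r in records],
        "age_group": [r.age_group for r in records],
        "stature_group": [r.stature_group for r in records],
        "stature_cm": [r.measurements.get("stature_cm", np.nan)
                       for r in records],
    })
    merged = vbsa_tab.merge(meta, on="subject_id", how="left")

    fits: list[AngleFit] = []
    for (theta, phi), sub in merged.groupby(["theta", "phi"], sort=True):
        for variant in config.model_variants:
            extra_cols = ["stature_cm"] if variant == "vbsa+stature" else None
            for grouping in config.groups:
                if grouping == "all":
                    extra = ({c: sub[c].to_numpy() for c in extra_cols}
                             if extra_cols else None)
                    f = cross_validate(sub["vbsa_gt"].to_numpy(),
                                       sub["wbsa"].to_numpy(), extra,
                                       k=min(config.k_folds, len(sub)),
                                       seed=config.seed, theta=theta, phi=phi,
                                       group=f"all[{variant}]")
                    fits.append(f)
                else:
                    gfits = fit_by_group(sub, grouping, vbsa_col="vbsa_gt",
                                         wbsa_col="wbsa",
                                         extra_cols=extra_cols,
                                         k=config.k_folds, seed=config.seed,
                                         theta=theta, phi=phi)
                    for g in gfits:
                        g.group = f"{g.group}[{variant}]"
                    fits.extend(gfits)
    fit_tab = fits_to_frame(fits)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        vbsa_tab.to_csv(vbsa_path, index=False)
        fit_tab.to_csv(out_dir / "angle_fits.csv", index=False)
        manifest = {
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "version": __version__,
            "n_subjects": len(records),
            "n_angle_cells": len(cells),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return vbsa_tab, fit_tab


def report(fit_table: pd.DataFrame, out_dir=None,
           du_bois_frame: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-angle coefficient/error curves: c1 and CV RMSE vs theta per phi.

    Returns the summary table and, with ``out_dir``, writes it as CSV plus
    matplotlib curve plots (one line per elevation).
    """
    if fit_table.empty:
        raise ValueError("empty fit table")
    cols = ["theta", "phi", "group", "c1", "c0", "cv_rmse", "cv_mape", "n"]
    summary = fit_table[[c for c in cols if c in fit_table.columns]].copy()
    summary = summary.sort_values(["group", "phi", "theta"]).reset_index(drop=True)
    if du_bois_frame is not None:
        summary = summary.merge(du_bois_frame, how="left",
                                on=[c for c in ("group",) if c in du_bois_frame])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "angle_summary.csv", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for metric in ("c1", "cv_rmse"):
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for (group, phi), sub in summary.groupby(["group", "phi"]):
                sub = sub.sort_values("theta")
                if len(sub) < 2:
                    continue
                ax.plot(sub["theta"], sub[metric], marker="o",
                        label=f"{group}, phi={phi:g}")
            ax.set_xlabel("azimuth theta (deg)")
            ax.set_ylabel(metric)
            ax.legend(fontsize=6)
            fig.tight_layout()
            fig.savefig(out_dir / f"{metric}_vs_theta.png", dpi=120)
            plt.close(fig)
    return summary
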