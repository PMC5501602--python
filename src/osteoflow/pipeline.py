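"""End-to-end pipeline orchestrator: simulate -> synthesize -> process -> ROC."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .flow_solver import FluidProps, PorousProps, mass_balance, refine_until_converged, solve_flow
from .geometry import (
    BioreactorGeometry,
    DomainLabel,
    FlowBoundaryCondition,
    build_geometry,
    inlet_velocity_from_flow_rate,
    rasterize,
)
from .io import sha256_of, write_field_vtk, write_mask, write_volume
from .roc_mapping import pool, roc_curve, superimpose
from .stress_field import sample_scaffold_volume, shear_stress
from .synthetic_data import (
    MineralizationLink,
    PhantomParams,
    ScanParams,
    gen_mineralization,
    gen_scaffold_phantom,
    simulate_uct_scan,
)
from .uct_pipeline import FilterParams, cylinder_mask, process_volume, timelapse_bvtv

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]

log = logging.getLogger("osteoflow")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # name -> path
    checksums: dict[str, str] = field(default_factory=dict)  # name -> sha256
    summary: dict = field(default_factory=dict)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version, "seed": self.seed,
             "outputs": self.outputs, "checksums": self.checksums,
             "summary": self.summary},
            indent=2, sort_keys=True))
        return path


def _solve_stage(cfg: PipelineConfig, geom: BioreactorGeometry):
    fluid = FluidProps(**cfg.fluid)
    porous = PorousProps(**cfg.porous)
    v = cfg.solver.inlet_velocity
    if v is None:
        v = inlet_velocity_from_flow_rate(float(cfg.solver.flow_rate), geom.tube_radius)
    bc = FlowBoundaryCondition(v, profile=cfg.solver.profile)
    opts = dict(include_inertia=cfg.solver.include_inertia,
                tol=cfg.solver.tol, max_iter=cfg.solver.max_iter)
    if cfg.solver.mode == "fixed":
        grid = rasterize(geom, cfg.solver.grid_spacing)
        sol = solve_flow(grid, fluid, porous, bc, **opts)
        report = None
    else:
        sol, report = refine_until_converged(
            geom, fluid, porous, bc,
            initial_spacing=cfg.solver.initial_spacing,
            criterion=cfg.solver.criterion,
            max_levels=cfg.solver.max_levels, **opts)
    return sol, report


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full chain and write every artifact plus a run manifest.

    Stages: CFD solve -> shear-stress field -> scaffold phantom ->
    stress-driven mineralization series -> simulated scans -> micro-CT
    processing + BV/TV morphometry -> pooled ROC.  A stage failure raises
    :class:`PipelineError` naming the stage; earlier artifacts remain on
    disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.to_dict(), __version__, cfg.seed)

    def record(name: str, path: Path):
        manifest.outputs[name] = str(path)
        manifest.checksums[name] = sha256_of(path)

    # ---- stage: simulate -------------------------------------------------
    try:
        geom = build_geometry(**cfg.geometry)
        sol, report = _solve_stage(cfg, geom)
        field_tau = shear_stress(sol)
        mb = mass_balance(sol)
        log.info("flow solved: max |u| = %.3e m/s, mass imbalance %.2e",
                 sol.max_speed(), mb.imbalance)
        record("shear_stress_vtk", write_field_vtk(
            field_tau.tau, sol.grid.dr, sol.grid.dz, out / "shear_stress_rz.vtk", "tau_Pa"))
        manifest.summary["max_velocity_m_per_s"] = sol.max_speed()
        manifest.summary["max_velocity_scaffold_m_per_s"] = sol.max_speed(DomainLabel.POROUS)
        manifest.summary["max_tau_scaffold_Pa"] = float(
            field_tau.tau[sol.grid.labels == DomainLabel.POROUS].max())
        manifest.summary["mass_imbalance"] = mb.imbalance
        if report is not None:
            manifest.summary["refinement_spacings_m"] = report.spacings
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # ---- stage: synthesize ----------------------------------------------
    try:
        s = cfg.synth
        ss_sample = sample_scaffold_volume(field_tau, s.voxel_size)
        phantom = PhantomParams(
            scaffold_radius=geom.scaffold_radius, scaffold_height=geom.scaffold_height,
            porosity=s.porosity, pore_diameter_range=(s.pore_diameter_min, s.pore_diameter_max),
            voxel_size=s.voxel_size, scaffold_density=s.scaffold_density, seed=cfg.seed)
        scaffold_vol, pores = gen_scaffold_phantom(phantom)
        link = MineralizationLink(kind=s.link_kind, lo=s.band_lo, hi=s.band_hi,
                                  rate=s.rate, bonus=s.bonus, noise=s.link_noise,
                                  seed=cfg.seed + 1)
        minerals = gen_mineralization(ss_sample, pores, link, s.weeks)
        scans = []
        for week, mask in minerals.items():
            scan = simulate_uct_scan(
                mask, ScanParams(psf_sigma=s.psf_sigma, noise_sd=s.noise_sd,
                                 mineral_density=s.mineral_density,
                                 seed=cfg.seed + 100 + week),
                background=scaffold_vol, week=week)
            scans.append(scan)
            record(f"scan_week{week}", write_volume(scan, out / f"scan_week{week}.mha"))
            record(f"mineral_week{week}", write_mask(mask, out / f"mineral_week{week}.mha"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synthesize", str(exc)) from exc

    # ---- stage: uct ------------------------------------------------------
    try:
        fp = FilterParams(sigma=cfg.uct.sigma, support=cfg.uct.support,
                          threshold=cfg.uct.threshold,
                          min_particle_size=cfg.uct.min_particle_size,
                          connectivity=cfg.uct.connectivity)
        shape = scans[0].data.shape
        tv = cylinder_mask(shape, s.voxel_size, geom.scaffold_radius, geom.scaffold_height)
        table = timelapse_bvtv(scans, tv, fp)
        table_path = out / "morphometry.csv"
        table.to_csv(table_path, index=False, lineterminator="\n")
        record("morphometry_csv", table_path)
        manifest.summary["bvtv_final_percent"] = float(table["BVTV_percent"].iloc[-1])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("uct", str(exc)) from exc

    # ---- stage: roc ------------------------------------------------------
    try:
        final_scan = scans[-1]
        mineral_mask = process_volume(final_scan, fp)
        paired = pool([superimpose(ss_sample, mineral_mask, tv, sample_id=0)])
        curve = roc_curve(paired)
        import pandas as pd

        roc_path = out / "roc.csv"
        pd.DataFrame({"threshold_Pa": curve.thresholds, "TPR": curve.tpr,
                      "FPR": curve.fpr}).to_csv(roc_path, index=False, lineterminator="\n")
        record("roc_csv", roc_path)
        summary = {
            "AUC": curve.auc,
            "tau_star_Pa": curve.tau_star,
            "TPR_star": curve.tpr_star,
            "FPR_star": curve.fpr_star,
            "P": paired.p,
            "N": paired.n_neg,
            "excluded_voxels": paired.n_excluded,
        }
        summary_path = out / "roc_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        record("roc_summary_json", summary_path)
        manifest.summary.update(summary)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("roc", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
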