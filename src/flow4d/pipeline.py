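"""End-to-end orchestration: simulate -> gate -> recon x2 -> segment ->
velocity -> PWV / WSS, with file artifacts per stage and a single report.

Stages write their outputs under the run directory so intermediates are
inspectable (and the raw data is reloadable for re-runs that skip the
simulation stage):

    raw.h5                    raw radial k-space (+ self-navigation)
    ground_truth/             phantom magnitude/lumen NIfTI + centerline CSV
    gating/                   beat times + per-projection phases (CSV)
    cine_hs_mag.nii.gz        HS/LT magnitude cine
    labels.nii.gz             HS segmentation; centerline.csv
    velocity_ls.nii.gz        decoded LS/HT velocity (cm/s)
    pwv.json, flow_curves.csv, pwv_fit.png
    wss/                      median curve + bulls-eye CSV, surface VTK
    report.json

Stages later than ``gate`` consume in-memory predecessors, so a partial
``stages`` list must keep each stage together with the reconstructions it
needs within one invocation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io
from .config import PhantomConfig, SequenceParams
from .errors import PipelineError
from .flowfield import decode_velocity, mask_velocity, median_filter_velocity
from .lumen import (extract_centerline, extract_surface, interpolate_labels,
                    segment_lumen)
from .phantom import build_dynamics, simulate_acquisition
from .pwv import place_planes, pwv_from_curves, through_plane_flow
from .recon import BinningScheme, ReconProfile, reconstruct_cine
from .selfnav import gate
from .wss import WssConfig, aggregate_wss, compute_wss

log = logging.getLogger("flow4d")


@dataclass
class PipelineConfig:
    """Serialisable description of one full phantom-to-report run."""

    phantom: dict = field(default_factory=dict)       # PhantomConfig kwargs
    full_scale: bool = False
    n_projections: int = 30_000
    n_phase_samples: int = 64
    sim_grid: float = 0.15                            # mm
    hs_matrix: int = 96
    ls_matrix: int = 64
    ls_frames: int = 200
    ls_width: float = 1.0 / 33.0
    reject_fraction: float = 0.20
    seg_threshold: float = 0.5
    seg_seeds: list = field(default_factory=lambda: [
        [-2.5, 0.0, 0.0], [0.0, 2.5, 0.0], [2.5, 0.0, 0.0]])
    n_planes: int = 50
    plane_exclusion_mm: float = 1.5
    wss_viscosity: float = 4.0
    stages: list = field(default_factory=lambda: [
        "simulate", "gate", "recon-hs", "recon-ls", "segment", "velocity",
        "pwv", "wss"])
    seed: int = 0

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def phantom_config(self) -> PhantomConfig:
        kw = dict(self.phantom)
        kw.setdefault("seed", self.seed)
        return PhantomConfig(**kw)

    def sequence(self) -> SequenceParams:
        if self.full_scale:
            return SequenceParams.table1()
        return SequenceParams.desk_scale(self.n_projections)

    def hs_profile(self) -> ReconProfile:
        if self.full_scale:
            return ReconProfile.hs_lt()
        return ReconProfile.hs_lt_desk(self.hs_matrix)

    def ls_profile(self) -> ReconProfile:
        if self.full_scale:
            return ReconProfile.ls_ht()
        return ReconProfile.ls_ht_desk(self.ls_matrix, self.ls_frames,
                                       self.ls_width)


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' requires {path.name}, which stage "
            f"'{stage}' did not produce — run '{stage}' first")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.stages)
    report: dict = {"seed": cfg.seed, "stages": stages}
    pcfg = cfg.phantom_config()
    seq = cfg.sequence()
    raw_path = outdir / "raw.h5"

    if "simulate" in stages:
        log.info("simulate: %d projections", seq.n_projections)
        dyn = build_dynamics(pcfg, cfg.n_phase_samples, cfg.sim_grid,
                             fov=seq.fov)
        acq = simulate_acquisition(dyn, seq, pcfg)
        io.save_raw(acq, raw_path)
        io.export_ground_truth(dyn, outdir / "ground_truth")
        report["simulate"] = {
            "n_spokes": acq.n_spokes,
            "scan_time_min": seq.scan_time_min,
            "velocity_aliasing": acq.velocity_aliasing,
            "pwv_true": pcfg.pwv_true,
        }
    else:
        _require(raw_path, "simulate", stages[0] if stages else "gate")
        acq = io.load_raw(raw_path)

    gating = None
    if "gate" in stages:
        log.info("gate: self-navigation")
        gating = gate(acq, cfg.reject_fraction)
        gating.to_csv(outdir / "gating")
        report["gate"] = {
            "n_beats": gating.n_beats,
            "mean_rr_ms": gating.mean_rr,
            "yield_percent": gating.yield_percent,
            "accepted_fraction": float(gating.accept_mask.mean()),
        }

    def need_gating():
        if gating is None:
            raise PipelineError(
                "stage requires gating output — run 'gate' first")
        return gating

    cine_hs = None
    if "recon-hs" in stages:
        g = need_gating()
        prof = cfg.hs_profile()
        log.info("recon-hs: matrix %d, %d frames", prof.matrix,
                 prof.binning.n_frames)
        cine_hs = reconstruct_cine(acq, g, prof)
        m = cine_hs.metrics
        io.save_nifti(np.moveaxis(cine_hs.magnitude(), 0, -1),
                      cine_hs.voxel, outdir / "cine_hs_mag.nii.gz",
                      "HS/LT magnitude")
        report["recon_hs"] = _metrics_dict(m)

    cine_ls = None
    vc = None
    if "recon-ls" in stages:
        g = need_gating()
        prof = cfg.ls_profile()
        log.info("recon-ls: matrix %d, %d frames", prof.matrix,
                 prof.binning.n_frames)
        cine_ls = reconstruct_cine(acq, g, prof)
        report["recon_ls"] = _metrics_dict(cine_ls.metrics)

    labels_hs = labels_ls = centerline = None
    if "segment" in stages:
        if cine_hs is None:
            raise PipelineError(
                "stage 'segment' requires the HS/LT cine — run 'recon-hs'")
        log.info("segment: %d seeds", len(cfg.seg_seeds))
        labels_hs = segment_lumen(cine_hs.magnitude(), cine_hs.voxel,
                                  cine_hs.origin,
                                  np.asarray(cfg.seg_seeds),
                                  cfg.seg_threshold,
                                  cine_hs.frame_phase_centers)
        io.save_nifti(np.moveaxis(labels_hs.labels, 0, -1), labels_hs.voxel,
                      outdir / "labels.nii.gz", "lumen labels (HS)")
        centerline = extract_centerline(
            labels_hs, 0, start_hint=np.asarray(cfg.seg_seeds[0], float)
            - np.array([0.0, 2.0, 0.0]))
        import pandas as pd

        pd.DataFrame(
            np.column_stack([centerline.points, centerline.arc_length]),
            columns=["x_mm", "y_mm", "z_mm", "s_mm"]).to_csv(
            outdir / "centerline.csv", index=False)
        report["segment"] = {
            "lumen_volume_mm3": [float(v) for v in labels_hs.volume_ml()],
            "centerline_length_mm": centerline.total_length,
        }

    if "velocity" in stages:
        if cine_ls is None or labels_hs is None:
            raise PipelineError(
                "stage 'velocity' requires recon-ls and segment outputs")
        log.info("velocity: decode + mask + median filter")
        vc = decode_velocity(cine_ls)
        labels_ls = interpolate_labels(
            labels_hs, vc.n_frames, target_voxel=vc.voxel,
            target_shape=vc.shape,
            target_phase_centers=vc.frame_phase_centers)
        vc = mask_velocity(vc, labels_ls.labels)
        vc = median_filter_velocity(vc, labels_ls.labels)
        io.save_nifti(np.moveaxis(vc.v, (0, 1), (-2, -1)), vc.voxel,
                      outdir / "velocity_ls.nii.gz",
                      "LS/HT velocity cm/s (x,y,z,frame,component)")

    if "pwv" in stages:
        if vc is None or centerline is None:
            raise PipelineError(
                "stage 'pwv' requires velocity and segment outputs")
        g = need_gating()
        L = centerline.total_length
        planes = place_planes(
            centerline, cfg.n_planes,
            exclusions=[(0.0, cfg.plane_exclusion_mm),
                        (L - cfg.plane_exclusion_mm, L)])
        log.info("pwv: %d planes", len(planes))
        curves = [through_plane_flow(vc, p, labels_ls, g.mean_rr)
                  for p in planes]
        fit, ups = pwv_from_curves(curves)
        _write_curves(curves, outdir / "flow_curves.csv")
        pwv_block = {
            "pwv_m_per_s": fit.pwv, "stderr_m_per_s": fit.stderr,
            "r_squared": fit.r_squared, "n_planes_used": fit.n_planes_used,
        }
        if "pwv_true" in report.get("simulate", {}):
            true = report["simulate"]["pwv_true"]
            if math.isfinite(true):
                pwv_block["recovery_error_percent"] = (
                    abs(fit.pwv - true) / true * 100.0)
        report["pwv"] = pwv_block
        io.write_json(pwv_block, outdir / "pwv.json")
        _plot_fit(curves, ups, fit, outdir / "pwv_fit.png")

    if "wss" in stages:
        if cine_hs is None or labels_hs is None or centerline is None:
            raise PipelineError(
                "stage 'wss' requires recon-hs and segment outputs")
        log.info("wss: gradients at the lumen surface")
        surface = extract_surface(labels_hs, centerline)
        vc_hs = decode_velocity(cine_hs)
        vc_hs = mask_velocity(vc_hs, labels_hs.labels)
        wcfg = WssConfig(viscosity=cfg.wss_viscosity)
        fieldw = compute_wss(vc_hs, surface, wcfg,
                             labels=labels_hs.labels[0])
        agg = aggregate_wss(fieldw, surface)
        wdir = outdir / "wss"
        wdir.mkdir(exist_ok=True)
        import pandas as pd

        pd.DataFrame({
            "frame_phase": agg["frame_phase_centers"],
            "median_wss": agg["median_curve"]}).to_csv(
            wdir / "median_wss.csv", index=False)
        agg["bullseye"].to_csv(wdir / "bullseye.csv", index=False)
        io.write_vtk_polydata(
            wdir / "wall_surface.vtk", surface.vertices, surface.faces,
            {"wss_mean": agg["vertex_mean"],
             "normal": surface.normals,
             "sector": surface.sector.astype(float)})
        report["wss"] = {
            "grand_mean_n_per_m2": agg["grand_mean"],
            "peak_median_wss": float(np.max(agg["median_curve"])),
            "n_vertices": len(surface.vertices),
            "flagged_fraction": float(fieldw.flagged.mean()),
        }

    io.write_json(report, outdir / "report.json")
    return report


def _metrics_dict(m) -> dict:
    return {
        "n_nyquist": m.n_nyquist,
        "mean_projections_per_frame": m.mean_projections_per_frame,
        "undersampling": m.undersampling,
        "temporal_blurring_ms": m.temporal_blurring_ms,
    }


def _write_curves(curves, path) -> None:
    import pandas as pd

    rows = []
    for c in curves:
        for t, q in zip(c.frame_times, c.q):
            rows.append({"plane_id": c.plane_id, "dx_mm": c.arc_distance,
                         "frame_time_ms": t, "q_ml_s": q})
    pd.DataFrame(rows).to_csv(path, index=False)


def _plot_fit(curves, ups, fit, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([c.arc_distance for c in curves])
    t = np.array([u.t_up if u.valid else np.nan for u in ups])
    T = curves[0].period
    dt = np.mod(t - t[np.isfinite(t)][0], T)
    dt[dt > T / 2] -= T
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(dt, x, "o", ms=3)
    tt = np.linspace(np.nanmin(dt), np.nanmax(dt), 10)
    ax.plot(tt, fit.pwv * tt + fit.intercept_ms * fit.pwv, "-")
    ax.set_xlabel("upstroke time dt (ms)")
    ax.set_ylabel("plane distance dx (mm)")
    ax.set_title(f"PWV = {fit.pwv:.2f} ± {fit.stderr:.2f} m/s, "
                 f"$R^2$ = {fit.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------------------------
# sensitivity sweep (frame rates / window widths / resolutions)
# ----------------------------------------------------------------------
def sensitivity_sweep(acq, gating, centerline, labels_hs,
                      frames: list[int], widths: list[float],
                      matrices: list[int], n_planes: int = 50,
                      exclusion_mm: float = 1.5,
                      fov_xy: float = 25.0):
    """PWV over a grid of (matrix, frames, width); one row per combination.

    Returns a DataFrame shaped like a resolution/frame-rate study table:
    resolution_um, frames, width, pwv, stderr, r2, us.  Combinations whose
    PWV cannot be evaluated carry NaN.  Duplicate grid points are
    deduplicated.
    """
    import pandas as pd

    from .errors import Flow4dError

    if not frames or not widths or not matrices:
        raise ValueError("empty sweep grid")
    combos = sorted({(m, f, w) for m in matrices for f in frames
                     for w in widths})
    L = centerline.total_length
    rows = []
    for m, f, w in combos:
        prof = ReconProfile(name=f"sweep-{m}-{f}", matrix=m,
                            binning=BinningScheme(f, w, 1.0 / f),
                            kr_max=m / (2.0 * fov_xy))
        row = {"resolution_um": fov_xy / m * 1000.0, "frames": f,
               "width": w, "pwv": np.nan, "stderr": np.nan, "r2": np.nan,
               "us": np.nan}
        try:
            cine = reconstruct_cine(acq, gating, prof)
            row["us"] = cine.metrics.undersampling
            vc = decode_velocity(cine)
            labs = interpolate_labels(
                labels_hs, max(f, labels_hs.n_frames),
                target_voxel=vc.voxel, target_shape=vc.shape,
                target_phase_centers=vc.frame_phase_centers)
            vc = mask_velocity(vc, labs.labels)
            planes = place_planes(centerline, n_planes,
                                  exclusions=[(0, exclusion_mm),
                                              (L - exclusion_mm, L)])
            curves = [through_plane_flow(vc, p, labs, gating.mean_rr)
                      for p in planes]
            fit, _ = pwv_from_curves(curves)
            row.update(pwv=fit.pwv, stderr=fit.stderr, r2=fit.r_squared)
        except Flow4dError as exc:
            log.warning("sweep point %s failed: %s", (m, f, w), exc)
        rows.append(row)
    return pd.DataFrame(rows)
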