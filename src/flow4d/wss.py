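"""Wall shear stress from wall-normal velocity gradients at the lumen surface.

At every surface vertex the velocity is probed at a few depths along the
inward normal; the normal component is removed from each sample and the
wall-tangential derivative is the least-squares slope of a line through
the origin (no-slip wall).  The shear vector is tau = mu * dv_t/dn,
tangential by construction.  Summaries: per-frame median |tau| over the
surface, per-vertex temporal means, and a bulls-eye table over
(region A/T/D x angular sector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import WssError
from .flowfield import VelocityCine
from .lumen import REGIONS, WallSurface


@dataclass(frozen=True)
class WssConfig:
    viscosity: float = 4.0                      # mPa*s (murine blood)
    probe_depths: tuple[float, ...] | None = None   # mm; None -> 1,2,3 voxels
    gradient_scheme: str = "linear-fit"         # or "two-point"

    def __post_init__(self):
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.probe_depths is not None:
            d = np.asarray(self.probe_depths, float)
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise ValueError("probe depths must be positive, increasing")
        if self.gradient_scheme not in ("linear-fit", "two-point"):
            raise ValueError("gradient scheme must be linear-fit/two-point")


@dataclass
class WssField:
    tau: np.ndarray              # (n_frames, nV, 3) N/m^2
    flagged: np.ndarray          # (nV,) probes left the lumen
    config: WssConfig
    frame_phase_centers: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)

    def median_curve(self) -> np.ndarray:
        """Per-frame median |tau| over non-flagged vertices."""
        ok = ~self.flagged
        if not ok.any():
            raise WssError("all vertices flagged")
        return np.median(self.magnitude[:, ok], axis=1)

    def vertex_mean(self) -> np.ndarray:
        """Temporal average of |tau| per vertex."""
        return self.magnitude.mean(axis=0)


def compute_wss(vc: VelocityCine, surface: WallSurface,
                cfg: WssConfig = WssConfig(),
                labels: np.ndarray | None = None) -> WssField:
    """Shear vectors at every vertex and frame.

    ``labels`` (3D, on the velocity grid) is used to flag vertices whose
    probe points leave the lumen; flagged vertices are excluded from
    aggregates but still carry values.
    """
    depths = (np.asarray(cfg.probe_depths, float)
              if cfg.probe_depths is not None
              else float(np.mean(vc.voxel)) * np.array([1.0, 2.0, 3.0]))
    if cfg.gradient_scheme == "two-point":
        depths = depths[:1]
    nV = len(surface.vertices)
    probes = (surface.vertices[None, :, :]
              + depths[:, None, None] * surface.normals[None, :, :])
    pidx = ((probes.reshape(-1, 3) - vc.origin) / vc.voxel).T

    flagged = np.zeros(nV, bool)
    if labels is not None:
        inlum = ndimage.map_coordinates(
            np.asarray(labels) > 0, pidx, order=0, mode="constant")
        flagged = ~inlum.reshape(len(depths), nV).all(axis=0)

    nhat = surface.normals
    tau = np.empty((vc.n_frames, nV, 3), dtype=np.float32)
    denom = float(np.sum(depths**2))
    for f in range(vc.n_frames):
        vs = np.stack([
            ndimage.map_coordinates(vc.v[f, c], pidx, order=1,
                                    mode="constant")
            for c in range(3)], axis=-1).reshape(len(depths), nV, 3)
        # remove the wall-normal component of each probe sample
        vn = np.einsum("dvc,vc->dv", vs, nhat)
        vt = vs - vn[:, :, None] * nhat[None, :, :]
        # least-squares slope through the origin over the probe depths,
        # cm/s per mm = 10 1/s;  tau = mu[mPa s] * 1e-3 * grad[1/s]
        slope = np.einsum("d,dvc->vc", depths, vt) / denom
        tau[f] = (cfg.viscosity * 1e-3 * slope * 10.0).astype(np.float32)
    return WssField(tau=tau, flagged=flagged, config=cfg,
                    frame_phase_centers=np.asarray(vc.frame_phase_centers))


def aggregate_wss(field: WssField, surface: WallSurface,
                  n_sectors: int | None = None) -> dict:
    """Median curve, temporal means, bulls-eye table and grand mean."""
    ok = ~field.flagged
    if not ok.any():
        raise WssError("all vertices flagged")
    tmean = field.vertex_mean()
    if n_sectors is None:
        n_sectors = int(surface.sector.max()) + 1
    rows = []
    for reg in REGIONS:
        for sec in range(n_sectors):
            m = ok & (surface.region == reg) & (surface.sector == sec)
            rows.append({
                "region": reg, "sector": sec,
                "mean_wss": float(tmean[m].mean()) if m.any() else np.nan,
                "n_vertices": int(m.sum())})
    table = pd.DataFrame(rows)
    return {
        "median_curve": field.median_curve(),
        "frame_phase_centers": field.frame_phase_centers,
        "vertex_mean": tmean,
        "bullseye": table,
        "grand_mean": float(tmean[ok].mean()),
    }
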