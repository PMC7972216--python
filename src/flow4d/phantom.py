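"""Digital murine aortic-arch phantom.

The phantom is a U-shaped tube lying in the mid-plane of the excitation
slab: two straight limbs (ascending / descending) joined by a half-torus.
It carries laminar flow with a parabolic axial profile whose volume flow is
a raised-cosine systolic pulse atop a diastolic baseline.  The pulse
propagates along the centerline as a pure delay at the configured true
pulse wave velocity, so that two cross-sections a distance dx apart see the
same waveform shifted by dt = dx / PWV (mm, ms, m/s).

The module also synthesises the raw scanner data: a slab-selective 3D
radial trajectory whose angular density is adjusted to the anisotropic
field of view, balanced 4-point velocity encoding, per-beat RR
variability, respiratory and cardiac modulation of the k-space-centre
(self-navigation) signal, and complex Gaussian noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (
    CARDIAC_NAV_FRACTION,
    PULSE_ONSET_PHASE,
    PhantomConfig,
    SequenceParams,
)
from .errors import GeometryError
from .nufft import nufft_forward

#: balanced 4-point (tetrahedral Hadamard) first-moment scheme; rows are the
#: signed encoder settings for (x, y, z).  phi_e = pi/(2*venc) * h_e . v
H_SCHEME = np.array(
    [[-1, -1, -1],
     [+1, +1, -1],
     [+1, -1, +1],
     [-1, +1, +1]], dtype=float)

GOLDEN = 0.6180339887498949        # conjugate golden ratio
PLASTIC2 = 0.7548776662466927      # second coordinate of the R2 sequence


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
class ArchTube:
    """U-bend centerline geometry and closest-point queries.

    Arc length ``s`` runs from the ascending inlet (s=0) through the bend to
    the descending outlet.  The tube axis lies in the z=0 plane.  Because
    the lumen is the set of points within ``radius`` of the (clamped)
    centerline, the open ends carry hemispherical caps; analyses exclude
    the end regions anyway.
    """

    def __init__(self, lumen_radius: float, curve_radius: float,
                 straight_length: float):
        self.radius = float(lumen_radius)
        self.curve_radius = float(curve_radius)
        self.straight_length = float(straight_length)

    @property
    def arc_length(self) -> float:
        return 2 * self.straight_length + math.pi * self.curve_radius

    def centerline(self, s: np.ndarray) -> np.ndarray:
        """Centerline points (N, 3) in mm at arc positions s."""
        s = np.atleast_1d(np.asarray(s, float))
        L, Rc = self.straight_length, self.curve_radius
        pts = np.empty((s.size, 3))
        pts[:, 2] = 0.0
        a = s <= L
        pts[a, 0] = -Rc
        pts[a, 1] = s[a] - L
        b = (s > L) & (s <= L + math.pi * Rc)
        phi = (s[b] - L) / Rc
        pts[b, 0] = -Rc * np.cos(phi)
        pts[b, 1] = Rc * np.sin(phi)
        c = s > L + math.pi * Rc
        pts[c, 0] = Rc
        pts[c, 1] = -(s[c] - L - math.pi * Rc)
        return pts

    def tangent(self, s: np.ndarray) -> np.ndarray:
        """Unit tangent (flow direction) at arc positions s."""
        s = np.atleast_1d(np.asarray(s, float))
        L, Rc = self.straight_length, self.curve_radius
        t = np.zeros((s.size, 3))
        a = s <= L
        t[a, 1] = 1.0
        b = (s > L) & (s <= L + math.pi * Rc)
        phi = (s[b] - L) / Rc
        t[b, 0] = np.sin(phi)
        t[b, 1] = np.cos(phi)
        c = s > L + math.pi * Rc
        t[c, 1] = -1.0
        return t

    def project(self, pts: np.ndarray):
        """Closest-point decomposition of arbitrary points.

        Returns ``(s, r, tangent)``: arc position of the closest centerline
        point, distance to the centerline, and the tangent there.
        """
        pts = np.atleast_2d(np.asarray(pts, float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        L, Rc = self.straight_length, self.curve_radius

        yc = np.clip(y, -L, 0.0)
        # ascending limb (x ~ -Rc)
        dA = np.sqrt((x + Rc) ** 2 + (y - yc) ** 2 + z**2)
        sA = yc + L
        # descending limb (x ~ +Rc)
        dD = np.sqrt((x - Rc) ** 2 + (y - yc) ** 2 + z**2)
        sD = L + math.pi * Rc - yc
        # arch (y >= 0): radial projection onto the half-circle
        rho = np.hypot(x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.arctan2(y, x)
        valid = (y >= 0) & (rho > 1e-12)
        dB = np.where(valid, np.sqrt((rho - Rc) ** 2 + z**2), np.inf)
        sB = np.where(valid, L + Rc * (math.pi - psi), 0.0)

        d = np.stack([dA, dB, dD])
        s_cand = np.stack([sA, sB, sD])
        best = np.argmin(d, axis=0)
        idx = np.arange(pts.shape[0])
        s = s_cand[best, idx]
        r = d[best, idx]
        return s, r, self.tangent(s)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        _, r, _ = self.project(pts)
        return r < self.radius

    def extent(self) -> np.ndarray:
        """Half-extents (x, y, z) of the tube including the lumen radius."""
        R, Rc, L = self.radius, self.curve_radius, self.straight_length
        return np.array([Rc + R, max(Rc + R, L + R), R])


# ----------------------------------------------------------------------
# waveform
# ----------------------------------------------------------------------
class PulseWaveform:
    """Raised-cosine systolic pulse propagating as a pure delay."""

    def __init__(self, cfg: PhantomConfig, onset: float = PULSE_ONSET_PHASE):
        self.cfg = cfg
        self.onset = onset

    def delay_phase(self, s) -> np.ndarray:
        """Propagation delay at arc position s, as a fraction of the cycle."""
        cfg = self.cfg
        if math.isinf(cfg.pwv_true):
            return np.zeros_like(np.asarray(s, float))
        return np.asarray(s, float) / (cfg.pwv_true * cfg.mean_rr)

    def normalized(self, u) -> np.ndarray:
        """Raised-cosine bump of unit height vs cycle fraction u (periodic)."""
        u = np.mod(np.asarray(u, float), 1.0)
        d = self.cfg.pulse_duration
        if d <= 0:
            return np.zeros_like(u)
        out = np.zeros_like(u)
        m = u < d
        out[m] = 0.5 * (1.0 - np.cos(2 * math.pi * u[m] / d))
        return out

    def q(self, s, p) -> np.ndarray:
        """Volume flow (ml/s) at arc position s and relative phase p."""
        cfg = self.cfg
        u = np.asarray(p, float) - self.onset - self.delay_phase(s)
        return cfg.baseline_flow + cfg.pulse_amplitude * self.normalized(u)


# ----------------------------------------------------------------------
# ground-truth dynamics
# ----------------------------------------------------------------------
@dataclass
class GroundTruthDynamics:
    """Sampled + analytic ground truth of the moving phantom.

    The dense magnitude volume is static (the wall does not move); the
    velocity field is stored sparsely on the lumen voxels for each of the
    ``phases`` cardiac-phase samples.  ``geometry`` and ``waveform`` expose
    the analytic field for oracle-style evaluation at arbitrary points.
    """

    config: PhantomConfig
    geometry: ArchTube
    waveform: PulseWaveform
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]   # mm, centred
    grid_spacing: float
    phases: np.ndarray                                 # (n_phase,)
    magnitude: np.ndarray                              # (nx, ny, nz) float32
    lumen_mask: np.ndarray                             # (nx, ny, nz) bool
    lumen_idx: np.ndarray                              # (n_lumen, 3) int
    velocity_lumen: np.ndarray                         # (n_phase, n_lumen, 3)
    centerline_true: np.ndarray                        # (n_cl, 4): x, y, z, s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape

    @property
    def voxel(self) -> np.ndarray:
        return np.full(3, self.grid_spacing)

    @property
    def origin(self) -> np.ndarray:
        return np.array([ax[0] for ax in self.axes])

    def flow(self, s, p):
        """True volume flow Q(s, p) in ml/s."""
        return self.waveform.q(s, p)

    def velocity_at(self, pts: np.ndarray, p: float) -> np.ndarray:
        """Analytic velocity (cm/s) at arbitrary points and phase p."""
        return _velocity_field(self.geometry, self.waveform, self.config,
                               pts, p)

    def velocity_volume(self, phase_index: int) -> np.ndarray:
        """Densify one phase sample to a (3, nx, ny, nz) volume (cm/s)."""
        out = np.zeros((3,) + self.shape, dtype=np.float32)
        i, j, k = self.lumen_idx.T
        for c in range(3):
            out[c, i, j, k] = self.velocity_lumen[phase_index, :, c]
        return out

    def peak_speed(self) -> float:
        if self.velocity_lumen.size == 0:
            return 0.0
        return float(np.linalg.norm(self.velocity_lumen, axis=2).max())


def _velocity_field(geom: ArchTube, wave: PulseWaveform, cfg: PhantomConfig,
                    pts: np.ndarray, p: float) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, float))
    s, r, tang = geom.project(pts)
    R = geom.radius
    inside = r < R
    q = wave.q(s, p)                            # ml/s
    # v_max = 2 Q / (pi R^2):  ml/s / mm^2 = 1e3 mm/s = 1e2 cm/s
    vmax = 2.0 * q / (math.pi * R**2) * 100.0   # cm/s
    prof = np.where(inside, 1.0 - (r / R) ** 2, 0.0)
    if cfg.profile_skew != 0.0:
        lateral = np.cross(tang, np.array([0.0, 0.0, 1.0]))
        cl = geom.centerline(s)
        d = pts - cl
        skew = 1.0 + cfg.profile_skew * np.einsum("ij,ij->i", d, lateral) / R
        prof = prof * np.clip(skew, 0.0, None)
    return (vmax * prof)[:, None] * tang


def build_dynamics(config: PhantomConfig, n_phase_samples: int = 64,
                   grid_spacing: float = 0.15,
                   fov: tuple[float, float, float] = (25.0, 25.0, 4.0),
                   ) -> GroundTruthDynamics:
    """Sample the analytic phantom onto a Cartesian grid.

    The grid spans the field of view with centred axes; lumen occupancy is
    anti-aliased over one grid spacing so that surfaces and magnitudes do
    not carry staircase artifacts.
    """
    if n_phase_samples < 50:
        raise ValueError("n_phase_samples must be >= 50")
    geom = ArchTube(config.lumen_radius, config.arch_curvature_radius,
                    config.straight_length)
    half = np.asarray(fov) / 2.0
    ext = geom.extent()
    for d, name in enumerate("xyz"):
        if ext[d] > half[d]:
            raise GeometryError(
                f"phantom extent {2 * ext[d]:.2f} mm exceeds the "
                f"{2 * half[d]:.2f} mm field of view along {name}")
    wave = PulseWaveform(config)

    axes = tuple(
        (np.arange(n) - n // 2) * grid_spacing
        for n in (int(round(fov[0] / grid_spacing)),
                  int(round(fov[1] / grid_spacing)),
                  int(round(fov[2] / grid_spacing))))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    s, r, tang = geom.project(pts)

    # anti-aliased occupancy and magnitude (blood = 1, tissue = 1/ratio)
    occ = np.clip((geom.radius - r) / grid_spacing + 0.5, 0.0, 1.0)
    bg = 1.0 / config.blood_tissue_signal_ratio
    mag = (bg + (1.0 - bg) * occ).reshape(X.shape).astype(np.float32)
    lumen = (r < geom.radius).reshape(X.shape)
    lumen_idx = np.argwhere(lumen)

    phases = (np.arange(n_phase_samples) + 0.0) / n_phase_samples
    lum_pts = pts[lumen.ravel()]
    vel = np.empty((n_phase_samples, lum_pts.shape[0], 3), dtype=np.float32)
    for ip, p in enumerate(phases):
        vel[ip] = _velocity_field(geom, wave, config, lum_pts, p)

    s_cl = np.linspace(0.0, geom.arc_length, 257)
    cl = np.column_stack([geom.centerline(s_cl), s_cl])

    return GroundTruthDynamics(
        config=config, geometry=geom, waveform=wave, axes=axes,
        grid_spacing=grid_spacing, phases=phases, magnitude=mag,
        lumen_mask=lumen, lumen_idx=lumen_idx, velocity_lumen=vel,
        centerline_true=cl)


def truth_velocity_cine(dyn: GroundTruthDynamics, n_frames: int = 200,
                        voxel: float = 0.25,
                        fov: tuple[float, float, float] = (25.0, 25.0, 4.0)):
    """Noise-free gridded velocity cine straight from the analytic phantom.

    Bypasses acquisition and reconstruction entirely; used as the oracle
    side of parameter-recovery checks.
    """
    from .flowfield import VelocityCine

    shape = tuple(int(round(f / voxel)) for f in fov)
    axes = [(np.arange(n) - n // 2) * voxel for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    _, r, _ = dyn.geometry.project(pts)
    lum = r < dyn.geometry.radius
    lum_pts = pts[lum]
    centers = np.arange(n_frames) / n_frames
    v = np.zeros((n_frames, 3) + shape, dtype=np.float32)
    flat = np.flatnonzero(lum)
    for f, p in enumerate(centers):
        vel = _velocity_field(dyn.geometry, dyn.waveform, dyn.config,
                              lum_pts, p)
        for c in range(3):
            v[f, c].ravel()[flat] = vel[:, c]
    return VelocityCine(
        v=v, voxel=np.full(3, voxel),
        origin=np.array([a[0] for a in axes]),
        frame_phase_centers=centers, venc=np.inf, mask_applied=True)


def truth_labels(dyn: GroundTruthDynamics, voxel: float = 0.25,
                 fov: tuple[float, float, float] = (25.0, 25.0, 4.0),
                 n_frames: int = 1):
    """Analytic lumen membership as a (static) label cine."""
    from .lumen import LabelCine

    shape = tuple(int(round(f / voxel)) for f in fov)
    axes = [(np.arange(n) - n // 2) * voxel for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    _, r, _ = dyn.geometry.project(pts)
    lab = (r < dyn.geometry.radius).reshape(shape).astype(np.uint8)
    return LabelCine(
        labels=np.repeat(lab[None], n_frames, axis=0),
        voxel=np.full(3, voxel), origin=np.array([a[0] for a in axes]),
        frame_phase_centers=np.arange(n_frames) / max(n_frames, 1))


def truth_centerline(dyn: GroundTruthDynamics):
    """Analytic centerline as a Centerline object."""
    from .lumen import Centerline

    s = dyn.centerline_true[:, 3]
    return Centerline(points=dyn.centerline_true[:, :3], arc_length=s,
                      tangents=dyn.geometry.tangent(s))


# ----------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------
def polar_density(dz: np.ndarray,
                  fov: tuple[float, float, float] = (25.0, 25.0, 4.0),
                  ) -> np.ndarray:
    """Relative angular density (per solid angle) of the slab-adapted scheme.

    For a thin-slab (anisotropic alias-free FOV) radial acquisition the
    transverse spoke spacing must resolve the object extent perpendicular
    to the spoke: rings of spokes are packed proportionally to
    ``W(c) = sqrt(c^2 + beta^2 (1 - c^2))`` with ``c`` the z-component of
    the direction and ``beta = fov_z / fov_xy`` — dense near the poles
    (where the transverse plane sees the full in-plane FOV), sparse near
    the slab plane.
    """
    beta = fov[2] / fov[0]
    c = np.asarray(dz, float)
    return np.sqrt(c**2 + beta**2 * (1.0 - c**2))


def generate_trajectory(n_projections: int,
                        fov: tuple[float, float, float] = (25.0, 25.0, 4.0),
                        ) -> np.ndarray:
    """Unit projection directions for the slab-adapted 3D radial scheme.

    A two-dimensional low-discrepancy (golden-ratio / R2) sequence spreads
    azimuths uniformly; the polar component covers the full sphere (the
    spatial resolution stays isotropic) with density adjusted to the
    anisotropic field of view (see :func:`polar_density`).  Deterministic
    in ``n_projections``; a single projection lies in the slab plane.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    i = np.arange(n_projections)
    phi = 2 * math.pi * np.mod(i * GOLDEN, 1.0)
    u = np.mod(0.5 + i * PLASTIC2, 1.0)
    cg = np.linspace(-1.0, 1.0, 4097)
    pdf = polar_density(cg, fov)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(cg))])
    cdf /= cdf[-1]
    dz = np.interp(u, cdf, cg)
    rho = np.sqrt(np.clip(1.0 - dz**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), dz])


# ----------------------------------------------------------------------
# acquisition container + simulator
# ----------------------------------------------------------------------
@dataclass
class RadialAcquisition:
    """Raw radial phase-contrast data (one spoke per TR).

    ``traj`` holds the unit direction of every stored spoke; four
    consecutive TRs share a direction and cycle through the balanced
    encoders.  ``k_radii`` gives the centre-out radial sample positions
    (cycles/mm) common to all spokes.
    """

    kspace: np.ndarray          # (n_spokes, n_readout) complex64
    traj: np.ndarray            # (n_spokes, 3) float64 unit vectors
    time_ms: np.ndarray         # (n_spokes,)
    encoder: np.ndarray         # (n_spokes,) int 0..3
    nav: np.ndarray             # (n_spokes,) float
    seq: SequenceParams
    phantom: dict = field(default_factory=dict)
    velocity_aliasing: bool = False

    @property
    def n_spokes(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_readout(self) -> int:
        return self.kspace.shape[1]

    @property
    def k_radii(self) -> np.ndarray:
        return np.arange(self.n_readout) * self.seq.delta_k


def _draw_beats(rng: np.random.Generator, cfg: PhantomConfig,
                total_ms: float) -> np.ndarray:
    beats = [0.0]
    t = 0.0
    while t < total_ms + 2 * cfg.mean_rr:
        rr = rng.normal(cfg.mean_rr, cfg.rr_sd)
        rr = max(rr, 0.3 * cfg.mean_rr)
        t += rr
        beats.append(t)
    return np.asarray(beats)


def cardiac_phases(time_ms: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Relative cardiac phase in [0, 1) of each timestamp."""
    idx = np.searchsorted(beat_times, time_ms, side="right") - 1
    idx = np.clip(idx, 0, len(beat_times) - 2)
    t0 = beat_times[idx]
    t1 = beat_times[idx + 1]
    return np.clip((time_ms - t0) / (t1 - t0), 0.0, 1.0 - 1e-9)


def simulate_acquisition(dynamics: GroundTruthDynamics, seq: SequenceParams,
                         config: PhantomConfig,
                         osf: float = 1.5, width: int = 5,
                         ) -> RadialAcquisition:
    """Synthesise the raw radial 4-point-encoded k-space data.

    Each TR acquires one centre-out spoke; the phantom state is quantised
    to the precomputed cardiac-phase samples of ``dynamics`` (quantisation
    error below half a phase sample).  Velocity maps to signal phase via
    the balanced scheme ``phi_e = pi/(2 venc) h_e . v``; the self-gating
    physiology enters as a multiplicative modulation of every spoke.
    """
    if not np.allclose([a[1] - a[0] for a in dynamics.axes],
                       dynamics.grid_spacing):
        raise ValueError("dynamics grid is not uniform")
    rng = np.random.default_rng(config.seed)
    n_spokes = seq.n_spokes
    dirs = generate_trajectory(seq.n_projections, seq.fov)
    spoke_dir = np.repeat(dirs, seq.n_encoders, axis=0)
    time_ms = np.arange(n_spokes) * seq.tr
    encoder = (np.arange(n_spokes) % seq.n_encoders).astype(np.int8)

    beat_times = _draw_beats(rng, config, seq.scan_time_ms)
    phase = cardiac_phases(time_ms, beat_times)
    n_phase = len(dynamics.phases)
    phase_idx = np.mod(np.round(phase * n_phase).astype(int), n_phase)

    # physiological modulation of every spoke (cardiac + respiratory)
    wave = dynamics.waveform
    if config.pulse_amplitude > 0:
        card = 1.0 + CARDIAC_NAV_FRACTION * wave.normalized(
            np.asarray(phase) - wave.onset)
    else:
        card = np.ones(n_spokes)
    resp = 1.0 + config.resp_motion_fraction * np.sin(
        2 * math.pi * time_ms / config.resp_period)
    modulation = (card * resp).astype(np.float64)

    peak = dynamics.peak_speed()
    aliasing = bool(peak >= seq.venc)
    if aliasing:
        warnings.warn(
            f"peak phantom speed {peak:.1f} cm/s reaches venc "
            f"{seq.venc:.1f} cm/s: velocity aliasing will occur")

    # per-axis angular frequencies: omega = 2 pi k voxel
    k_r = seq.k_radii()
    voxel = dynamics.grid_spacing
    background = dynamics.magnitude.astype(np.complex64)
    lum = dynamics.lumen_idx
    lum_mag = dynamics.magnitude[lum[:, 0], lum[:, 1], lum[:, 2]]
    phase_scale = math.pi / (2.0 * seq.venc)

    kspace = np.empty((n_spokes, seq.n_readout), dtype=np.complex64)
    order = np.lexsort((encoder, phase_idx))
    bounds = np.flatnonzero(np.diff(
        phase_idx[order] * seq.n_encoders + encoder[order])) + 1
    groups = np.split(order, bounds)
    for g in groups:
        ip = phase_idx[g[0]]
        e = int(encoder[g[0]])
        v = dynamics.velocity_lumen[ip]                 # (n_lumen, 3) cm/s
        phi = phase_scale * (v @ H_SCHEME[e])
        img = background.copy()
        img[lum[:, 0], lum[:, 1], lum[:, 2]] = (
            lum_mag * np.exp(1j * phi)).astype(np.complex64)
        pts = (2 * math.pi * voxel) * (
            k_r[None, :, None] * spoke_dir[g][:, None, :])
        samples = nufft_forward(img, pts.reshape(-1, 3), osf=osf, width=width)
        kspace[g] = samples.reshape(len(g), seq.n_readout)

    kspace *= modulation[:, None].astype(np.float32)

    nav_clean = np.abs(kspace[:, 0]).astype(np.float64)
    if config.noise_sd > 0:
        sd = config.noise_sd * float(
            np.sqrt(np.mean(np.abs(kspace) ** 2)))
        kspace += (sd * (rng.standard_normal(kspace.shape)
                         + 1j * rng.standard_normal(kspace.shape))
                   ).astype(np.complex64)
        nav = nav_clean + sd * rng.standard_normal(n_spokes)
    else:
        nav = nav_clean

    return RadialAcquisition(
        kspace=kspace, traj=spoke_dir, time_ms=time_ms.astype(float),
        encoder=encoder, nav=nav, seq=seq, phantom=config.to_dict(),
        velocity_aliasing=aliasing)
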