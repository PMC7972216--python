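"""Protocol and phantom configuration.

Units used throughout the package: lengths in mm, times in ms, velocities
in cm/s, volume flow in ml/s, spatial frequencies in cycles/mm, pulse wave
velocity in m/s (so that a transit delay in ms equals distance-in-mm divided
by PWV-in-m/s), dynamic viscosity in mPa*s and wall shear stress in N/m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


#: fraction of the cardiac cycle at which the systolic upstroke leaves the
#: baseline at the phantom inlet (gives every analysis plane a pre-systolic
#: quiescent segment).
PULSE_ONSET_PHASE = 0.10

#: amplitude of the pulsatile blood-volume modulation of the k-space centre
#: signal (the cardiac self-navigation contrast), relative to the DC signal.
CARDIAC_NAV_FRACTION = 0.08

#: fraction of readout points retained when cropping at k_r < 85/FOV with the
#: Table-1 protocol ("inner 64.5% of the original data points").
INNER_KSPACE_FRACTION = 0.645


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth description of the pulsatile aortic-arch phantom.

    The phantom is a U-shaped tube (two straight limbs joined by a
    half-torus) carrying a raised-cosine systolic flow pulse that propagates
    along the centerline at ``pwv_true``.
    """

    lumen_radius: float = 1.0            # mm
    arch_curvature_radius: float = 2.5   # mm, centre to centerline of the U-bend
    straight_length: float = 2.5         # mm, each limb
    peak_flow: float = 0.8               # ml/s at the systolic peak
    baseline_flow: float = 0.1           # ml/s diastolic baseline
    pulse_duration: float = 0.30         # fraction of the cardiac cycle
    pwv_true: float = 2.5                # m/s; math.inf disables propagation
    mean_rr: float = 100.0               # ms
    rr_sd: float = 4.0                   # ms, per-beat variability
    resp_period: float = 800.0           # ms
    resp_motion_fraction: float = 0.15   # navigator respiratory modulation
    blood_tissue_signal_ratio: float = 10.0
    noise_sd: float = 0.02               # fraction of RMS spoke amplitude
    profile_skew: float = 0.0            # lateral skew of the axial profile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be > 0")
        if self.pwv_true <= 0:
            raise ValueError("pwv_true must be > 0")
        if not 0 <= self.pulse_duration < 1:
            raise ValueError("pulse_duration must lie in [0, 1)")
        if not self.peak_flow >= self.baseline_flow >= 0:
            raise ValueError("need peak_flow >= baseline_flow >= 0")
        if self.mean_rr <= 0 or self.resp_period <= 0:
            raise ValueError("mean_rr and resp_period must be > 0")

    @property
    def pulse_amplitude(self) -> float:
        return self.peak_flow - self.baseline_flow

    def to_dict(self) -> dict:
        d = asdict(self)
        # HDF5 attributes cannot hold inf portably across readers; keep float
        return d


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition protocol of the slab-selective 3D radial 4-point PC scan.

    ``scan_time_ms`` is derived: one spoke per TR, each projection direction
    acquired once per velocity encoder, hence TR * n_projections * n_encoders.
    """

    tr: float = 3.0                      # ms
    te: float = 1.1                      # ms
    flip: float = 15.0                   # degrees
    n_readout: int = 140
    n_projections: int = 160_000         # directions (per encoder)
    n_encoders: int = 4
    venc: float = 125.0                  # cm/s
    fov: tuple[float, float, float] = (25.0, 25.0, 4.0)  # mm
    slab_thickness: float = 4.0          # mm
    kr_max: float = (85.0 / 25.0) / INNER_KSPACE_FRACTION  # cycles/mm, spoke end

    def __post_init__(self) -> None:
        if self.n_encoders != 4:
            raise ValueError("balanced 4-point encoding requires n_encoders = 4")
        if self.n_readout < 2 or self.n_projections < 1:
            raise ValueError("need n_readout >= 2 and n_projections >= 1")

    # -- derived protocol quantities -------------------------------------
    @property
    def scan_time_ms(self) -> float:
        return self.tr * self.n_projections * self.n_encoders

    @property
    def scan_time_min(self) -> float:
        return self.scan_time_ms / 60_000.0

    @property
    def n_spokes(self) -> int:
        """Total stored spokes (all encoders)."""
        return self.n_projections * self.n_encoders

    @property
    def slab_fraction(self) -> float:
        return self.slab_thickness / self.fov[0]

    @property
    def delta_k(self) -> float:
        """Radial sample spacing along a centre-out spoke (cycles/mm)."""
        return self.kr_max / (self.n_readout - 1)

    def k_radii(self):
        import numpy as np

        return np.arange(self.n_readout) * self.delta_k

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov"] = list(self.fov)
        return d

    # -- canonical protocols ---------------------------------------------
    @classmethod
    def table1(cls) -> "SequenceParams":
        """The in-vivo protocol (32 min scan, 100 um / 147 um resolutions)."""
        return cls()

    @classmethod
    def desk_scale(cls, n_projections: int = 30_000) -> "SequenceParams":
        """Laptop-scale protocol: same FOV/venc, matrix 96 (HS) / 64 (LS).

        The spoke end supports a 96 matrix over 25 mm; cropping at
        k_r < 64/(2*25) retains the inner 2/3 for the low-spatial recon.
        """
        return cls(
            n_readout=56,
            n_projections=n_projections,
            kr_max=96.0 / (2.0 * 25.0),
        )


def round_to_even(x: float) -> int:
    """Nearest even integer (>= 2)."""
    lo = 2 * math.floor(x / 2.0)
    hi = lo + 2
    ev = lo if (x - lo) <= (hi - x) else hi
    return max(ev, 2)


def slab_matrix(matrix: int, fov: tuple[float, float, float]) -> int:
    """Slab-direction matrix: in-plane matrix scaled by FOV anisotropy."""
    return round_to_even(matrix * fov[2] / fov[0])
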