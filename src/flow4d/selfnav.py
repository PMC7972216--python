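"""Self-navigation: k-space-centre signal, beat detection, gating, yield.

The magnitude of the first (k=0) readout sample of every spoke tracks the
pulsatile blood volume and the respiratory state.  Zero-phase band-pass
filters split it into a cardiac and a respiratory component; peak detection
on the cardiac component gives beat times, from which every projection is
assigned a relative cardiac phase p in [0, 1).  Respiratory gating rejects
the projections with the largest respiratory displacement.  The yield is
the number of detected heartbeats relative to the number expected from the
scan duration:  yield[%] = N * T_RR / T_scan * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import GatingError, NavigationError
from .phantom import RadialAcquisition, cardiac_phases

#: murine physiology defaults (Hz)
CARDIAC_BAND = (4.0, 15.0)
RESP_BAND = (0.5, 3.0)


@dataclass
class NavigatorSignal:
    values: np.ndarray          # raw DC magnitude per projection
    sampling_interval: float    # ms (= TR)
    cardiac: np.ndarray         # band-passed cardiac component
    resp: np.ndarray            # band-passed respiratory component
    cardiac_band: tuple[float, float] = CARDIAC_BAND
    resp_band: tuple[float, float] = RESP_BAND

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sampling_interval


@dataclass
class GatingTable:
    beat_times: np.ndarray      # ms, monotone
    rr_periods: np.ndarray      # ms (valid intervals only)
    mean_rr: float              # ms
    phase: np.ndarray           # per-projection relative phase, NaN if unusable
    accept_mask: np.ndarray     # respiratory accept, per projection
    n_beats: int
    n_beats_expected: float
    yield_percent: float
    scan_time_ms: float
    yield_over_100: bool = False

    def recompute_yield(self) -> float:
        return self.n_beats * self.mean_rr / self.scan_time_ms * 100.0

    def usable(self) -> np.ndarray:
        return self.accept_mask & np.isfinite(self.phase)

    def to_csv(self, outdir) -> None:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"beat_time_ms": self.beat_times}).to_csv(
            outdir / "beat_times.csv", index=False)
        pd.DataFrame({
            "phase": self.phase,
            "accepted": self.accept_mask.astype(int),
        }).to_csv(outdir / "projection_phase.csv", index=False)


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 3) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, x)


def extract_navigator(raw: RadialAcquisition,
                      cardiac_band: tuple[float, float] = CARDIAC_BAND,
                      resp_band: tuple[float, float] = RESP_BAND,
                      ) -> NavigatorSignal:
    """Navigator = DC-sample magnitude, detrended and band-split."""
    dc = np.abs(raw.kspace[:, 0]).astype(float)
    if dc.std() == 0:
        raise NavigationError("navigator signal is flat (sd = 0)")
    fs = 1000.0 / raw.seq.tr
    detrended = dc - np.mean(dc)
    return NavigatorSignal(
        values=dc, sampling_interval=raw.seq.tr,
        cardiac=_bandpass(detrended, cardiac_band, fs),
        resp=_bandpass(detrended, resp_band, fs),
        cardiac_band=cardiac_band, resp_band=resp_band)


def _dominant_frequency(x: np.ndarray, fs: float,
                        band: tuple[float, float]) -> float:
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any() or spec[m].max() == 0:
        raise GatingError("no spectral power in the cardiac band")
    return float(freqs[m][np.argmax(spec[m])])


def detect_beats(nav: NavigatorSignal,
                 accept_mask: np.ndarray | None = None,
                 min_beats: int = 10) -> GatingTable:
    """Peak detection on the cardiac component + phase assignment.

    RR intervals outside [0.5, 2] x median are treated as detection
    artifacts: they do not count as beats and projections inside them get
    phase NaN.
    """
    fs = nav.fs
    f_peak = _dominant_frequency(nav.cardiac, fs, nav.cardiac_band)
    min_dist = max(int(round(0.6 * fs / f_peak)), 1)
    peaks, _ = signal.find_peaks(nav.cardiac, distance=min_dist)
    if len(peaks) < min_beats:
        raise GatingError(
            f"only {len(peaks)} beats detected (< {min_beats})")
    # parabolic sub-sample refinement of each peak
    t_beats = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(nav.cardiac) - 1)
    y0 = nav.cardiac[peaks[inner] - 1]
    y1 = nav.cardiac[peaks[inner]]
    y2 = nav.cardiac[peaks[inner] + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / denom, 0.0)
    t_beats[inner] += np.clip(shift, -0.5, 0.5)
    beat_times = t_beats * nav.sampling_interval

    rr_all = np.diff(beat_times)
    med = np.median(rr_all)
    valid = (rr_all >= 0.5 * med) & (rr_all <= 2.0 * med)
    rr = rr_all[valid]
    if len(rr) < min_beats:
        raise GatingError("too few plausible RR intervals")
    mean_rr = float(np.mean(rr))

    t = nav.times
    phase = cardiac_phases(t, beat_times)
    # mark projections outside detected beats or in rejected intervals
    interval = np.searchsorted(beat_times, t, side="right") - 1
    bad = (interval < 0) | (interval >= len(rr_all))
    phase = np.where(bad, np.nan, phase)
    inval = np.flatnonzero(~valid)
    if inval.size:
        phase[np.isin(interval, inval)] = np.nan

    scan_time = len(nav.values) * nav.sampling_interval
    n_beats = int(valid.sum())
    n_expected = scan_time / mean_rr
    y = n_beats * mean_rr / scan_time * 100.0
    if accept_mask is None:
        accept_mask = np.ones(len(t), dtype=bool)
    return GatingTable(
        beat_times=beat_times, rr_periods=rr, mean_rr=mean_rr, phase=phase,
        accept_mask=np.asarray(accept_mask, bool), n_beats=n_beats,
        n_beats_expected=n_expected, yield_percent=y,
        scan_time_ms=scan_time, yield_over_100=bool(y > 100.0))


def respiratory_gate(nav: NavigatorSignal,
                     reject_fraction: float = 0.20) -> np.ndarray:
    """Accept-mask rejecting the largest respiratory displacements.

    Exactly ``round(reject_fraction * n)`` projections are rejected; ties in
    displacement magnitude are broken by projection index (stable order).
    """
    if not 0 <= reject_fraction < 1:
        raise ValueError("reject_fraction must lie in [0, 1)")
    disp = np.abs(nav.resp)
    n = len(disp)
    n_rej = int(round(reject_fraction * n))
    mask = np.ones(n, dtype=bool)
    if n_rej:
        order = np.argsort(disp, kind="stable")
        mask[order[n - n_rej:]] = False
    return mask


def gate(raw: RadialAcquisition, reject_fraction: float = 0.20,
         cardiac_band: tuple[float, float] = CARDIAC_BAND,
         resp_band: tuple[float, float] = RESP_BAND) -> GatingTable:
    """Full self-gating chain: navigator -> respiratory gate -> beats."""
    nav = extract_navigator(raw, cardiac_band, resp_band)
    mask = respiratory_gate(nav, reject_fraction)
    return detect_beats(nav, accept_mask=mask)
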