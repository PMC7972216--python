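"""Transit-time pulse wave velocity from multi-plane through-plane flow.

Through-plane flow Q(t) is measured at many centerline-perpendicular
planes.  For each plane the systolic upstroke time is the intersection of
a line fitted to the pre-systolic baseline and a line fitted to the early
systolic rise (the flow curve is linearly interpolated tenfold first).
Plotting plane distance dx against upstroke time dt, the global PWV is the
slope of the ordinary least-squares line, PWV = dx/dt, with the slope
standard error and R^2 as quality measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate as sinterp
from scipy import ndimage, stats

from .errors import PwvError
from .flowfield import VelocityCine
from .lumen import Centerline, LabelCine


@dataclass
class FlowPlane:
    plane_id: int
    arc_distance: float          # mm from the proximal (first) plane
    point: np.ndarray            # mm
    normal: np.ndarray           # unit, along the centerline tangent


@dataclass
class FlowCurve:
    plane_id: int
    arc_distance: float          # mm
    frame_times: np.ndarray      # ms
    q: np.ndarray                # ml/s
    period: float                # ms (cycle duration covered by the frames)


@dataclass
class UpstrokeResult:
    t_up: float                  # ms (within the cycle)
    baseline_fit: tuple[float, float]   # slope (ml/s per ms), intercept
    upstroke_fit: tuple[float, float]
    baseline_idx: np.ndarray
    upstroke_idx: np.ndarray
    valid: bool
    reason: str = ""


@dataclass
class PwvFit:
    pwv: float                   # m/s
    stderr: float                # m/s
    r_squared: float
    n_planes_used: int
    intercept_ms: float = 0.0


# ----------------------------------------------------------------------
# plane placement + flow integration
# ----------------------------------------------------------------------
def place_planes(centerline: Centerline, n_planes: int = 50,
                 exclusions: list[tuple[float, float]] | None = None,
                 min_planes: int = 4) -> list[FlowPlane]:
    """Equidistant analysis planes along the arc, minus excluded ranges."""
    L = centerline.total_length
    if L <= 0:
        raise PwvError("centerline has zero length")
    s = np.linspace(0.0, L, n_planes)
    if exclusions:
        keep = np.ones(n_planes, bool)
        for lo, hi in exclusions:
            keep &= ~((s >= lo) & (s <= hi))
        s = s[keep]
    if len(s) < min_planes:
        raise PwvError(
            f"only {len(s)} analysis planes survive (need >= {min_planes})")
    pts, tg = centerline.at(s)
    return [FlowPlane(plane_id=i, arc_distance=float(si - s[0]),
                      point=pts[i], normal=tg[i])
            for i, si in enumerate(s)]


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    up = np.array([0.0, 0.0, 1.0])
    if abs(n @ up) > 0.9:
        up = np.array([1.0, 0.0, 0.0])
    e1 = up - n * (n @ up)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def through_plane_flow(vc: VelocityCine, plane: FlowPlane,
                       labels: LabelCine, mean_rr_ms: float = 1.0,
                       half_width: float | None = None) -> FlowCurve:
    """Q(t) = sum over the lumen cross-section of (v . n) * pixel area.

    The velocity is resampled on an in-plane grid (spacing = in-plane
    voxel) by trilinear interpolation; lumen membership comes from the
    label cine (nearest frame / nearest voxel).
    """
    if labels.labels.shape[0] not in (1, vc.n_frames):
        raise PwvError("label cine frames do not match velocity cine")
    voxel = float(vc.voxel[0])
    if half_width is None:
        half_width = 0.45 * min(
            labels.shape[d] * labels.voxel[d] for d in range(3))
    e1, e2 = _plane_basis(plane.normal)
    g = np.arange(-half_width, half_width + 1e-9, voxel)
    ng = len(g)
    A, B = np.meshgrid(g, g, indexing="ij")
    pts = (plane.point[None, :] + A.ravel()[:, None] * e1[None, :]
           + B.ravel()[:, None] * e2[None, :])
    vidx = ((pts - vc.origin) / vc.voxel).T
    lidx = ((pts - labels.origin) / labels.voxel).T
    area = voxel * voxel                       # mm^2
    centre = np.argmin(A.ravel()**2 + B.ravel()**2)
    q = np.empty(vc.n_frames)
    any_lumen = False
    for f in range(vc.n_frames):
        lf = 0 if labels.labels.shape[0] == 1 else f
        inlum = ndimage.map_coordinates(labels.labels[lf], lidx, order=0,
                                        mode="constant") > 0
        # a plane may also cut obliquely through a neighbouring vessel
        # segment: keep only the cross-section connected to the plane centre
        lab2d, _ = ndimage.label(inlum.reshape(ng, ng))
        lc = lab2d.ravel()[centre]
        if lc == 0:
            near = np.flatnonzero(inlum)
            if near.size == 0:
                raise PwvError(
                    f"plane {plane.plane_id} has an empty lumen "
                    f"cross-section")
            rad2 = (A.ravel() - A.ravel()[centre])**2 + \
                (B.ravel() - B.ravel()[centre])**2
            lc = lab2d.ravel()[near[np.argmin(rad2[near])]]
        inlum = lab2d.ravel() == lc
        if not inlum.any():
            raise PwvError(
                f"plane {plane.plane_id} has an empty lumen cross-section")
        any_lumen = True
        vn = np.zeros(inlum.sum())
        for c in range(3):
            vn += plane.normal[c] * ndimage.map_coordinates(
                vc.v[f, c], vidx[:, inlum], order=1, mode="constant")
        # cm/s * mm^2 = 10 mm^3/s = 0.01 ml/s
        q[f] = vn.sum() * area * 0.01
    if not any_lumen:
        raise PwvError("plane does not intersect the lumen")
    period = float(mean_rr_ms)
    times = np.asarray(vc.frame_phase_centers, float) * period
    return FlowCurve(plane_id=plane.plane_id,
                     arc_distance=plane.arc_distance, frame_times=times,
                     q=q, period=period)


# ----------------------------------------------------------------------
# upstroke detection
# ----------------------------------------------------------------------
def resample_curve(curve: FlowCurve, n_out: int,
                   kind: str = "linear") -> FlowCurve:
    """Periodic resampling of a flow curve to n_out frames."""
    t = curve.frame_times
    qq = curve.q
    T = curve.period
    t_out = np.arange(n_out) / n_out * T
    if kind == "spline":
        spl = sinterp.CubicSpline(
            np.concatenate([t, [t[0] + T]]),
            np.concatenate([qq, [qq[0]]]), bc_type="periodic")
        q_out = spl(t_out)
    else:
        text = np.concatenate([t - T, t, t + T])
        qext = np.concatenate([qq, qq, qq])
        q_out = np.interp(t_out, text, qext)
    return FlowCurve(curve.plane_id, curve.arc_distance, t_out, q_out, T)


def detect_upstroke(curve: FlowCurve, baseline_quantile: float = 0.10,
                    rise: tuple[float, float] = (0.20, 0.80),
                    interp_factor: int = 10, min_frames: int = 40,
                    noise_factor: float = 4.0) -> UpstrokeResult:
    """Baseline/upstroke two-line intersection on the 10x interpolated curve.

    The curve is rolled circularly so the systolic peak sits at 40% of the
    window; baseline points are the pre-peak samples below
    ``baseline_quantile`` of the excursion, upstroke points the contiguous
    rising flank between the ``rise`` fractions.
    """
    n = len(curve.q)
    if n < min_frames:
        raise PwvError(
            f"upstroke detection needs >= {min_frames} frames, got {n}")
    T = curve.period
    nf = n * interp_factor
    tf = np.arange(nf) / nf * T
    text = np.concatenate([curve.frame_times - T, curve.frame_times,
                           curve.frame_times + T])
    qext = np.concatenate([curve.q] * 3)
    qf = np.interp(tf, text, qext)

    ipk = int(np.argmax(qf))
    shift = ipk - int(0.4 * nf)
    qr = np.roll(qf, -shift)
    t0 = tf[np.mod(shift, nf)]          # absolute time of rolled sample 0
    ipk = int(np.argmax(qr))

    qmin, qmax = float(qr.min()), float(qr.max())
    exc = qmax - qmin
    def invalid(reason):
        return UpstrokeResult(np.nan, (0, 0), (0, 0), np.array([]),
                              np.array([]), False, reason)
    if exc <= 0:
        return invalid("flat curve")
    lo = qmin + rise[0] * exc
    hi = qmin + rise[1] * exc
    # rising flank: walk down from the peak through the rise window ...
    a = ipk
    while a > 0 and qr[a] > hi:
        a -= 1
    b = a
    while b > 0 and qr[b] >= lo:
        b -= 1
    # ... and on to its foot: follow the strictly falling run so the
    # baseline fit stops where the rise begins (the first non-decreasing
    # sample — typically baseline noise — ends the walk)
    foot = b
    while foot > 0 and qr[foot - 1] < qr[foot]:
        foot -= 1
    base_thr = qmin + baseline_quantile * exc
    base_idx = np.flatnonzero((np.arange(nf) < foot) & (qr <= base_thr))
    if len(base_idx) < 3:
        return invalid("no pre-systolic baseline segment")
    # noise floor: excursion must stand out from baseline scatter
    noise = float(np.std(qr[base_idx]))
    if exc < noise_factor * noise:
        return invalid("excursion below the noise floor")
    up_idx = np.arange(b + 1, a + 1)
    if len(up_idx) < 2:
        return invalid("upstroke flank too short")
    tr = np.arange(nf) / nf * T
    m1, c1 = np.polyfit(tr[base_idx], qr[base_idx], 1)
    m2, c2 = np.polyfit(tr[up_idx], qr[up_idx], 1)
    if m2 <= m1:
        return invalid("upstroke slope does not exceed baseline slope")
    t_cross = (c1 - c2) / (m2 - m1)
    t_up = float(np.mod(t_cross + t0, T))
    return UpstrokeResult(t_up=t_up, baseline_fit=(m1, c1),
                          upstroke_fit=(m2, c2), baseline_idx=base_idx,
                          upstroke_idx=up_idx, valid=True)


# ----------------------------------------------------------------------
# the dx/dt fit
# ----------------------------------------------------------------------
def fit_pwv(upstroke_times_ms: np.ndarray, distances_mm: np.ndarray,
            period_ms: float | None = None, min_planes: int = 4) -> PwvFit:
    """OLS of plane distance (m) on upstroke time (s): PWV = slope.

    ``upstroke_times_ms`` may contain NaN for invalid planes (dropped).
    With ``period_ms`` given, times are unwrapped circularly relative to
    the first valid plane, so a seam crossing does not corrupt the fit.
    """
    t = np.asarray(upstroke_times_ms, float)
    x = np.asarray(distances_mm, float)
    ok = np.isfinite(t) & np.isfinite(x)
    t, x = t[ok], x[ok]
    if len(t) < min_planes:
        raise PwvError(
            f"only {len(t)} valid planes (need >= {min_planes})")
    if period_ms is not None:
        dt = np.mod(t - t[0], period_ms)
        dt[dt > period_ms / 2.0] -= period_ms
    else:
        dt = t - t[0]
    if np.ptp(dt) <= 0:
        raise PwvError("degenerate upstroke-time spread (all equal)")
    res = stats.linregress(dt / 1000.0, x / 1000.0)   # s, m
    return PwvFit(pwv=float(res.slope), stderr=float(res.stderr),
                  r_squared=float(res.rvalue**2), n_planes_used=len(t),
                  intercept_ms=float(res.intercept))


def pwv_from_curves(curves: list[FlowCurve],
                    subsample: int = 1, resample_kind: str | None = None,
                    **upstroke_kw) -> tuple[PwvFit, list[UpstrokeResult]]:
    """Upstroke detection on every plane + dx/dt fit.

    ``subsample`` keeps every k-th frame (frame-rate reduction experiments);
    with ``resample_kind`` the reduced curves are first re-interpolated to
    the original frame count (spline, as in the frame-rate sensitivity
    analysis).
    """
    ups = []
    for c in curves:
        cc = c
        if subsample > 1:
            cc = FlowCurve(c.plane_id, c.arc_distance,
                           c.frame_times[::subsample], c.q[::subsample],
                           c.period)
            if resample_kind:
                cc = resample_curve(cc, len(c.q), kind=resample_kind)
        try:
            ups.append(detect_upstroke(cc, **upstroke_kw))
        except PwvError:
            ups.append(UpstrokeResult(np.nan, (0, 0), (0, 0),
                                      np.array([]), np.array([]), False,
                                      "too few frames"))
    t_up = np.array([u.t_up if u.valid else np.nan for u in ups])
    x = np.array([c.arc_distance for c in curves])
    fit = fit_pwv(t_up, x, period_ms=curves[0].period)
    return fit, ups
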