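# flow4d — methods note

This note records the scientific model behind the package, the default
parameter choices and their rationale, the numerical decisions, and what a
green test does and does not establish.

## The measurement problem

Flow-sensitive 4D phase-contrast MRI of the murine aortic arch must serve
two antagonistic analyses from one acquisition: wall shear stress (WSS)
needs high *spatial* resolution to resolve the near-wall velocity
gradient, while transit-time pulse wave velocity (PWV) needs high
*temporal* resolution to time the systolic upstroke at many planes.  A
non-triggered (self-gated) 3D radial acquisition makes both available
retrospectively: the same raw spokes can be binned into

* **HS/LT** — all k-space, 20 non-overlapping selection windows
  (W = Δ = 1/20 of the cardiac cycle), used for segmentation and WSS;
* **LS/HT** — only the inner k-space (k_r below 85/FOV, the inner 64.5 %
  of readout points with the full protocol), 200 overlapping windows
  (W = 1/33, Δ = 1/200), used for PWV.

Key bookkeeping quantities (J = in-plane matrix, T̄_RR = mean cardiac
period, N̄_f = mean projections per frame):

* Nyquist projection count for the slab-selective radial scan:
  `N_Nyq ≈ π J² (4/25)` (≈1.45·10⁴ at J = 170, ≈3.14·10⁴ at J = 250);
* undersampling factor `us = N_Nyq / N̄_f`;
* self-gating yield `N·T̄_RR / T_scan · 100 %`;
* temporal blurring `δt = δp̄ · T̄_RR`, with δp̄ the mean in-window
  standard deviation of the binned relative phases (for phases uniform in
  a window of width W, δp̄ = W/√12).

## The phantom (stated world)

A U-shaped tube (two straight limbs joined by a half-torus, axis in the
slab mid-plane) carries laminar flow with a parabolic axial profile.  The
volume flow is a raised-cosine systolic bump atop a diastolic baseline
that propagates along the centerline as a pure delay:
`Q(s, p) = Q₀(p − s / (PWV · T̄_RR))`.  This is a kinematic phantom: flow
"conservation" holds per cross-section at each instant, but the wall is
rigid and the delayed waveform is imposed, not solved for.  The lumen is
the set of points within one radius of the clamped centerline, so the
open ends carry hemispherical caps (excluded from all analyses).

Defaults, chosen once:

| parameter | value | why |
|---|---|---|
| lumen radius | 1.0 mm | canonical value of all closed-form checks |
| bend radius / limb length | 2.5 / 2.5 mm | ~12.9 mm arch-like centerline inside the 25×25×4 mm³ FOV |
| peak / baseline flow | 0.8 / 0.1 ml/s | murine peak flows of 0.65–0.9 ml/s |
| pulse duration, onset | 0.30, 0.10 cycle | systole ≈ 1/3 of the cycle; the onset leaves a pre-systolic baseline at every plane |
| true PWV | 2.5 m/s | healthy-to-stiff murine range (1.7–2.6 m/s) |
| mean RR, RR sd | 100, 4 ms | ~600 bpm under anaesthesia, few-ms beat jitter |
| respiratory period, modulation | 800 ms, 0.15 | slow ventilation; amplitude modulation of the navigator |
| blood:tissue signal | 10 | inflow enhancement of the thin slab |
| k-space noise | 0.02 × RMS spoke amplitude | interpretation of "fraction of blood signal" in k-space |
| venc | 125 cm/s | protocol value; peak phantom speed ≈ 51 cm/s, no wrapping |

Desk scale: 30 000 projection directions (× 4 encoders, 6 min equivalent
scan), 56 readout points to a spoke end supporting a 96 matrix, HS matrix
96 / LS matrix 64, simulation grid 0.15 mm, 64 cardiac phase samples
(each TR mapped to the nearest sample; quantisation below half a sample).
The full 32-min protocol (140 points, 1.6·10⁵ projections, 100/147 µm)
is available behind `full_scale`.

What the phantom does **not** emulate: wall motion and compliance (the
delay is imposed, not a fluid–structure solution), branch vessels,
secondary/recirculating flow, off-resonance, eddy currents, coil
sensitivities, T1/T2 relaxation and flip-angle steady state.  A green
recovery test therefore establishes that the *post-processing chain* is
unbiased for a delayed laminar waveform at the stated sampling — not that
in-vivo accuracy would match.

## Acquisition model

One spoke per TR; four consecutive TRs share a direction and cycle
through the balanced tetrahedral encoding
h = (−1,−1,−1), (+1,+1,−1), (+1,−1,+1), (−1,+1,+1), with signal phase
`φ_e = π/(2·venc) · h_e·v`.  Velocity decodes as
`v = venc/(2π) · hᵀ·φ`; the columns of hᵀ sum to zero, so any common
phase offset cancels.  Velocities with |v|₂ < venc decode exactly (the
largest per-encoder phase is √3·π/2 < π); beyond that, components alias
by multiples of 2·venc and are flagged, not corrected.

The trajectory covers the full sphere (isotropic resolution) with polar
density `p(c) ∝ √(c² + β²(1−c²))`, β = slab/FOV = 4/25 — the
anisotropic-FOV adaptation: spokes near the pole are spaced against the
full in-plane FOV, spokes near the slab plane against the thin slab.  A
2-D golden-ratio (R2) sequence orders the directions so any selection
window sees well-spread coverage.

The navigator is the k-space-centre magnitude; physiology enters the
simulation as multiplicative spoke modulation — cardiac (amplitude 0.08,
proportional to the normalised inlet waveform; absent for a pulse-free
phantom) and respiratory (resp_motion_fraction, sinusoidal).  Note the
detected "beats" are navigator systolic peaks: beat times carry a
constant lag (~0.25 cycle here) relative to the underlying RR grid.
Every relative quantity (binning, upstroke differences, PWV) is invariant
to this lag.

## Reconstruction

Type-1/type-2 NUFFT by Kaiser–Bessel gridding (width 5, oversampling 1.5,
Beatty shape parameter, analytic deapodization); accuracy ≈3·10⁻⁴
relative against a direct non-uniform DFT.  The anisotropic image matrix
is (J, J, J·4/25 rounded to even) over the 25×25×4 mm³ FOV, i.e.
near-isotropic voxels.  Frequencies marginally beyond the grid Nyquist
wrap, exactly as a discrete Fourier model would.

**Density compensation** is computed per frame and encoder from the
actual spoke subset by Pipe–Menon iteration (10 iterations on a light
osf 1.25 / width 3 grid).  This matters: the spoke direction is
deterministically locked to acquisition time, so cardiac binning gives
every frame its own, slightly irregular angular coverage; a fixed
analytic k_r² weighting then leaves frame-dependent PSF distortions and a
DC pedestal that bias the flow-curve timing (PWV errors up to tens of
percent in controlled experiments).  The analytic weighting is retained
as an option (`dcf="analytic"`).

Zero-filling (k-space padding, sinc interpolation) implements the
half-voxel LS/HT output of the full protocol; the desk LS profile skips
it (the PWV stage resamples trilinearly anyway).

## PWV stage

≈50 equidistant centerline-perpendicular planes (ends excluded);
through-plane flow is the lumen-masked integral of v·n̂ on an in-plane
grid at voxel spacing, restricted to the cross-section connected to the
plane centre (an oblique plane near the bend can also cut the adjacent
limb).  Each curve is linearly interpolated tenfold; the upstroke time is
the intersection of a baseline line (pre-systolic points below the 10 %
quantile of the excursion, ending at the foot of the rising flank) and an
upstroke line (the contiguous flank between 20 % and 80 % of the
excursion).  The foot is found by walking down the strictly falling run
from the 20 % crossing, which makes the piecewise-linear case exact while
stopping at the first noise wiggle on measured curves.  Curves whose
excursion is below 4× the baseline scatter are invalid and dropped (≥4
valid planes required).  PWV is the OLS slope of distance (m) on upstroke
time (s), circularly unwrapped relative to the first plane; slope
standard error and R² are reported.

## WSS stage

Marching-cubes surface of the (Gaussian-smoothed) 0.5-occupancy level
with inward normals; vertices carry arc-length-tercile region tags
(ascending / top / descending, configurable break points) and 8 angular
sectors for the bulls-eye summary.  At each vertex the velocity is probed
at 1, 2, 3 voxels along the inward normal (trilinear), the wall-normal
component removed, and the tangential gradient taken as the least-squares
slope of a line **through the origin** (no-slip wall).  τ = μ·∂v_t/∂n
with μ = 4.0 mPa·s by default (typical murine whole-blood value; absolute
WSS scales linearly with it).  The no-slip constraint is essential to the
closed-form accuracy (an affine fit underestimates a parabolic wall
gradient by ~17 % at these depths) and implies that apparent slip — e.g.
a rigid-translation field — is reported as shear.  Vertices whose probes
leave the lumen are flagged and excluded from aggregates.  The Poiseuille
wall shear 4μQ/(πR³) is recovered within ~11 % at R/12 voxels (the
through-origin line under-reads a parabola by ~10 % at depths ≤ R/4; the
probing depth, not the surface, dominates the bias).

## Known limitations

* Voxelwise velocity accuracy at desk-scale undersampling (us ≈ 3–4) is
  streak-limited: mean in-lumen error is below 2 % of venc on a
  noise-free HS/LT reconstruction, but single-voxel errors reach several
  percent; integral quantities (flow curves) are what the pipeline relies
  on.
* Slope-error monotonicity across frame rates (50 → 100 → 200 frames) is
  not guaranteed: decimated-and-spline-resampled curves are smoother than
  the native 200-frame curve, and the 100-frame fit can show a smaller
  standard error than the 200-frame fit — the same inversion the original
  in-vivo frame-rate study reports.
* The two binning-direction comparisons (peak flow and peak median WSS,
  high vs low frame rate) are near-ties at desk projection counts: a
  W = 1/33 frame holds ~40 % fewer spokes than a W = 1/20 frame, and the
  resulting extra blur offsets the temporal sharpening that dominates at
  the full 1.6·10⁵-projection scale.
* Segmented lumen volume carries a small (+few %) dilation from
  thresholding the partial-volume edge at half the blood level.
* Self-gating assumes a single dominant cardiac band (4–15 Hz) and
  quantile-based respiratory rejection (default 20 %); arrhythmia and
  drift beyond RR outlier removal (0.5–2 × median) are out of scope.
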