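# flow4d

**Pulse wave velocity and 3D wall shear stress from a single self-gated
radial 4D flow acquisition — with a digital murine aortic-arch phantom.**

Quantifying aortic stiffening (via pulse wave velocity, PWV) and the
haemodynamic stress on the vessel wall (wall shear stress, WSS) in mice
normally takes two MRI measurements, because PWV needs high temporal and
WSS high spatial resolution.  A self-gated (non-triggered) 3D radial
phase-contrast acquisition removes that trade-off: the raw spokes carry
their own cardiac/respiratory timing, so the *same* k-space data can be
reconstructed retrospectively at two operating points,

* **HS/LT** — all k-space, 20 frames/cycle (window W = 1/20): lumen
  segmentation and WSS from the near-wall velocity gradient,
  τ = μ·∂v_t/∂n;
* **LS/HT** — inner k-space only, 200 overlapping frames (W = 1/33,
  spacing 1/200): through-plane flow Q(t) at ~50 centerline-perpendicular
  planes, systolic upstroke times from a two-line (baseline × rising
  flank) intersection, and global PWV as the slope of the plane-distance
  vs upstroke-time regression, PWV = dx/dt.

`flow4d` implements this post-processing chain end to end in Python —
self-navigation, sliding-window binning, Kaiser–Bessel gridding NUFFT
with per-frame iterative density compensation, balanced 4-point velocity
decoding, seeded lumen segmentation with temporal label interpolation,
centerline/surface extraction, the multiple-points transit-time PWV
estimator and surface WSS with bulls-eye summaries — plus a fully
synthetic scanner: a pulsatile aortic-arch phantom whose pulse propagates
at a configurable true PWV, so every stage is testable without scanner
data.  Sampling bookkeeping (Nyquist projection count π·J²·(4/25),
undersampling factor, self-gating yield, temporal blurring) is computed
alongside.  See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate the desk-scale phantom (30 000 projections, true PWV 2.5 m/s,
six-minute-equivalent scan) and run the whole chain:

```bash
python scripts/acceptance.py --seed 0 --out results/acceptance.json
# equivalently: flow4d run --out runs/demo
```

which prints

```
PWV = 2.287 +/- 0.101 m/s (R^2 = 0.935, 38 planes)
mean WSS over the arch = 0.623 N/m^2
```

Reading this: the transit-time estimator recovered the configured
2.5 m/s within 9 % through the complete simulate → self-gate →
reconstruct → segment → decode → fit chain (the regression over 38
analysis planes spans ~4 ms of wavefront travel sampled at 0.5 ms frame
spacing); the WSS figure is the vertex-mean time-averaged shear over the
arch surface for the configured flow and a viscosity of 4 mPa·s (the
desk-scale voxel under-reads the parabolic wall gradient; the closed-form
Poiseuille check at fine voxels recovers 4μQ/(πR³) within 11 %).  The run
directory holds every intermediate: raw k-space (HDF5), gating tables
(CSV), cines and velocity maps (NIfTI), centerline and flow curves (CSV),
the wall surface (VTK), the dx/dt fit plot and `report.json` with yield,
undersampling, temporal blurring and the fit.

Library use mirrors the CLI:

```python
from flow4d import (PhantomConfig, SequenceParams, build_dynamics,
                    simulate_acquisition, gate, ReconProfile,
                    reconstruct_cine, decode_velocity)

cfg = PhantomConfig(pwv_true=2.5)
dyn = build_dynamics(cfg)
acq = simulate_acquisition(dyn, SequenceParams.desk_scale(), cfg)
table = gate(acq)                                   # beats, phases, yield
cine = reconstruct_cine(acq, table, ReconProfile.ls_ht_desk())
vel = decode_velocity(cine)                         # cm/s, 3 components
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
phantom from scratch at the given seed, executes the full pipeline
(simulate → gate → both reconstructions → segmentation → velocity →
PWV → WSS), prints the recovered PWV/WSS summary and writes the results
JSON to `--out` (the pipeline report and all intermediates are kept in a
sibling directory).  Runtime is roughly 8 minutes on one CPU.
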