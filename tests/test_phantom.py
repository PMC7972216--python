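"""Phantom geometry, waveform propagation, trajectory and raw simulation."""

import math

import numpy as np
import pytest
from scipy import stats

from flow4d.config import PhantomConfig, SequenceParams
from flow4d.errors import GeometryError
from flow4d import phantom as ph
from flow4d.nufft import nufft_forward
from oracles import ball_ft


def steady_cfg(q=0.1, **kw):
    return PhantomConfig(peak_flow=q, baseline_flow=q, noise_sd=0.0,
                         resp_motion_fraction=0.0, **kw)


# ----------------------------------------------------------------------
# geometry + waveform
# ----------------------------------------------------------------------
class TestGeometry:
    def test_centerline_arc_length(self):
        g = ph.ArchTube(1.0, 2.5, 2.5)
        assert g.arc_length == pytest.approx(5.0 + math.pi * 2.5)

    def test_project_roundtrip_on_centerline(self):
        g = ph.ArchTube(1.0, 2.5, 2.5)
        s = np.linspace(0.1, g.arc_length - 0.1, 41)
        pts = g.centerline(s)
        s2, r, _ = g.project(pts)
        assert np.allclose(s2, s, atol=1e-9)
        assert np.all(r < 1e-9)

    def test_tube_must_fit_in_fov(self):
        cfg = PhantomConfig(straight_length=15.0)
        with pytest.raises(GeometryError, match="y"):
            ph.build_dynamics(cfg, grid_spacing=0.4)
        cfg = PhantomConfig(lumen_radius=2.1)
        with pytest.raises(GeometryError, match="z"):
            ph.build_dynamics(cfg, grid_spacing=0.4)


class TestWaveform:
    def test_infinite_pwv_disables_delay(self):
        cfg = PhantomConfig(pwv_true=math.inf)
        w = ph.PulseWaveform(cfg)
        p = np.linspace(0, 0.99, 37)
        assert np.allclose(w.q(0.0, p), w.q(9.0, p))

    def test_delay_equals_dx_over_pwv(self):
        """Two positions 5 mm apart at 2.5 m/s: delay = 2.0 ms."""
        cfg = PhantomConfig(pwv_true=2.5, mean_rr=100.0)
        w = ph.PulseWaveform(cfg)
        d = (w.delay_phase(7.0) - w.delay_phase(2.0)) * cfg.mean_rr
        assert d == pytest.approx(2.0)

    def test_steady_poiseuille_vmax(self):
        """Q = 0.1 ml/s, R = 1 mm: v_max = 2Q/(pi R^2) = 6.37 cm/s, and the
        numerically integrated profile returns Q."""
        cfg = steady_cfg()
        g = ph.ArchTube(1.0, 2.5, 2.5)
        w = ph.PulseWaveform(cfg)
        v = ph._velocity_field(g, w, cfg, np.array([[-2.5, -1.0, 0.0]]),
                               0.37)
        assert np.linalg.norm(v) == pytest.approx(6.366, abs=0.01)
        h = 0.05
        xs = np.arange(-3.7, -1.3, h)
        zs = np.arange(-1.2, 1.2, h)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), np.full(X.size, -1.0), Z.ravel()])
        q = np.sum(ph._velocity_field(g, w, cfg, pts, 0.37)[:, 1]) \
            * h * h * 0.01
        assert q == pytest.approx(0.1, rel=0.01)

    def test_pure_delay_cross_correlation(self, dynamics, phantom_cfg):
        """Lag between inlet and outlet waveforms = arc length / PWV."""
        p = np.arange(2000) / 2000.0
        L = dynamics.geometry.arc_length
        qi = dynamics.flow(0.0, p)
        qo = dynamics.flow(L, p)
        lags = np.arange(2000)
        xc = [np.dot(qi, np.roll(qo, -l)) for l in lags]
        lag_cycle = lags[int(np.argmax(xc))] / 2000.0
        expect = L / (phantom_cfg.pwv_true * phantom_cfg.mean_rr)
        assert lag_cycle == pytest.approx(expect, abs=1.0 / 64)


# ----------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------
class TestTrajectory:
    def test_single_projection_in_slab_plane(self):
        d = ph.generate_trajectory(1)
        assert d.shape == (1, 3)
        assert abs(d[0, 2]) < 1e-12

    def test_unit_norm(self):
        d = ph.generate_trajectory(5000)
        assert np.abs(np.linalg.norm(d, axis=1) - 1).max() < 1e-12

    def test_azimuth_uniformity_chi_square(self):
        d = ph.generate_trajectory(20000)
        az = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
        counts, _ = np.histogram(az, bins=36, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_polar_density_follows_anisotropy_law(self):
        """Monte-Carlo binning of z-components against the anisotropic-FOV
        density p(c) ~ sqrt(c^2 + (4/25)^2 (1 - c^2))."""
        d = ph.generate_trajectory(50000)
        counts, edges = np.histogram(d[:, 2], bins=20, range=(-1, 1))
        c = 0.5 * (edges[1:] + edges[:-1])
        pdf = ph.polar_density(c)
        expected = pdf / pdf.sum() * counts.sum()
        assert np.abs(counts - expected).max() / expected.max() < 0.05

    def test_deterministic(self):
        assert np.array_equal(ph.generate_trajectory(777),
                              ph.generate_trajectory(777))


# ----------------------------------------------------------------------
# acquisition
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def tiny_seq():
    return SequenceParams(n_readout=32, n_projections=1500,
                          kr_max=48.0 / 50.0)


class TestSimulation:
    def test_static_phantom_encoders_identical(self, tiny_seq):
        """Zero velocity: the four encoders of one projection direction
        acquire identical spokes (noise and physiology disabled)."""
        cfg = steady_cfg(q=0.0)
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.3)
        acq = ph.simulate_acquisition(dyn, tiny_seq, cfg)
        k = acq.kspace.reshape(tiny_seq.n_projections, 4, -1)
        assert np.allclose(k[:, 0], k[:, 1], rtol=1e-6)
        assert np.allclose(k[:, 0], k[:, 3], rtol=1e-6)

    def test_sphere_spoke_matches_analytic_ft(self):
        """A noise-free spoke through a centred uniform ball follows the
        closed-form ball transform at low k (where voxelisation of the
        ball is faithful); the gridding itself is held to 1e-3 against the
        direct DFT oracle in test_nufft."""
        spacing = 0.1
        n = (64, 64, 40)
        axes = [(np.arange(m) - m // 2) * spacing for m in n]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        R = 1.2
        r = np.sqrt(X**2 + Y**2 + Z**2)
        ball = np.clip((R - r) / spacing + 0.5, 0, 1).astype(complex)
        k_r = np.linspace(0.0, 1.8, 40)
        direction = np.array([0.36, 0.48, 0.8])
        pts = 2 * np.pi * spacing * k_r[:, None] * direction[None, :]
        got = nufft_forward(ball, pts) * spacing**3
        ref = ball_ft(k_r, R)
        m = k_r < 0.5 / R
        assert np.abs(got[m] - ref[m]).max() / np.abs(ref[0]) < 0.01

    def test_periodic_navigator_autocorrelation(self, tiny_seq):
        """rr_sd = 0, RR = 100 ms: the navigator autocorrelation peaks at a
        100 ms lag."""
        cfg = PhantomConfig(rr_sd=0.0, noise_sd=0.0,
                            resp_motion_fraction=0.0)
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.3)
        acq = ph.simulate_acquisition(dyn, tiny_seq, cfg)
        nav = acq.nav - acq.nav.mean()
        n = len(nav)
        lags_ms = np.arange(1, n // 2) * tiny_seq.tr
        ac = np.correlate(nav, nav, mode="full")[n:n + n // 2 - 1]
        sel = (lags_ms > 50) & (lags_ms < 150)
        best = lags_ms[sel][np.argmax(ac[sel])]
        assert best == pytest.approx(100.0, abs=tiny_seq.tr)

    def test_aliasing_flag(self, tiny_seq):
        cfg = PhantomConfig(peak_flow=2.5)   # v_max ~ 159 cm/s > venc
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.3)
        with pytest.warns(UserWarning, match="aliasing"):
            acq = ph.simulate_acquisition(dyn, tiny_seq, cfg)
        assert acq.velocity_aliasing

    def test_hdf5_roundtrip_and_determinism(self, tiny_seq, tmp_path):
        """Identical config + seed produce byte-identical HDF5 files."""
        from flow4d import io

        cfg = PhantomConfig(seed=11)
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.3)
        a1 = ph.simulate_acquisition(dyn, tiny_seq, cfg)
        a2 = ph.simulate_acquisition(dyn, tiny_seq, cfg)
        io.save_raw(a1, tmp_path / "a.h5")
        io.save_raw(a2, tmp_path / "b.h5")
        b1 = (tmp_path / "a.h5").read_bytes()
        b2 = (tmp_path / "b.h5").read_bytes()
        assert b1 == b2
        back = io.load_raw(tmp_path / "a.h5")
        assert np.array_equal(back.kspace, a1.kspace)
        assert np.array_equal(back.traj, a1.traj)
        assert back.seq.venc == a1.seq.venc
        assert float(back.phantom["pwv_true"]) == cfg.pwv_true


class TestProtocol:
    def test_table1_scan_time_is_32_min(self):
        assert SequenceParams.table1().scan_time_min == pytest.approx(32.0)

    def test_flow_conservation_on_grid(self, dynamics, phantom_cfg):
        """Cross-sectional integral of the gridded axial velocity matches
        Q(s, p) to about the quadrature accuracy of the grid."""
        vol = dynamics.velocity_volume(10)
        # plane through the ascending limb at y = -1.25 (a grid row);
        # restrict to x < 0 so the descending limb is not counted
        iy = int(round((-1.25 - dynamics.origin[1])
                       / dynamics.grid_spacing))
        h = dynamics.grid_spacing
        nx_half = int(round(-dynamics.origin[0] / h))
        q = vol[1, :nx_half, iy, :].sum() * h * h * 0.01
        y = dynamics.origin[1] + iy * h
        s = y + phantom_cfg.straight_length
        q_true = dynamics.flow(s, dynamics.phases[10])
        assert q == pytest.approx(float(q_true), rel=0.01)
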