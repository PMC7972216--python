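"""Binning windows, k-space cropping, gridding recon, sampling metrics."""

import numpy as np
import pytest

from flow4d.config import PhantomConfig, SequenceParams
from flow4d.errors import ReconError
from flow4d import phantom as ph
from flow4d import recon, selfnav


class TestSelectProjections:
    def test_non_overlapping_partition(self):
        """W = spacing = 1/20: each projection lands in exactly one frame."""
        rng = np.random.default_rng(3)
        phase = rng.uniform(0, 1, 2000)
        frames = recon.select_projections(
            phase, None, recon.BinningScheme(20, 1 / 20))
        counts = np.zeros(2000, int)
        for f in frames:
            counts[f] += 1
        assert (counts == 1).all()
        sizes = [len(f) for f in frames]
        assert min(sizes) > 60 and max(sizes) < 140   # ~100 each

    def test_overlapping_membership_count(self):
        """W = 1/33, spacing = 1/200: every projection sits in 6-7 frames
        (brute-force membership count)."""
        rng = np.random.default_rng(4)
        phase = rng.uniform(0, 1, 3000)
        scheme = recon.BinningScheme(200, 1 / 33, 1 / 200)
        frames = recon.select_projections(phase, None, scheme)
        counts = np.zeros(3000, int)
        for f in frames:
            counts[f] += 1
        assert set(np.unique(counts)) <= {6, 7}
        # independent brute force for a sample of projections
        for i in range(0, 3000, 371):
            n = 0
            for c in scheme.frame_centers:
                d = (phase[i] - c + 0.5) % 1.0 - 0.5
                n += (-1 / 66 <= d < 1 / 66)
            assert n == counts[i]

    def test_circular_wrap_at_seam(self):
        """Phase 0.999 belongs to frame 0's window [-1/40, 1/40)."""
        phase = np.concatenate([[0.999], np.linspace(0.02, 0.97, 96)])
        frames = recon.select_projections(
            phase, None, recon.BinningScheme(20, 1 / 20))
        assert 0 in frames[0]
        assert all(0 not in f for f in frames[1:])

    def test_respects_accept_mask(self):
        phase = np.array([0.1, 0.1, 0.6])
        mask = np.array([True, False, True])
        frames = recon.select_projections(
            phase, mask, recon.BinningScheme(2, 0.5, 0.5))
        assert list(frames[0]) == [0]

    def test_empty_frame_raises(self):
        with pytest.raises(ReconError, match="frame"):
            recon.select_projections(np.array([0.5]), None,
                                     recon.BinningScheme(4, 1 / 8, 1 / 4))


class TestCropKspace:
    @pytest.fixture()
    def acq(self):
        seq = SequenceParams.table1()
        n = 40
        return ph.RadialAcquisition(
            kspace=np.ones((n, seq.n_readout), np.complex64),
            traj=ph.generate_trajectory(n), time_ms=np.arange(n) * 3.0,
            encoder=np.arange(n) % 4, nav=np.ones(n), seq=seq)

    def test_identity_at_spoke_max(self, acq):
        out = recon.crop_kspace(acq, acq.k_radii[-1])
        assert out.kspace.shape == acq.kspace.shape

    def test_table1_crop_retains_64_5_percent(self, acq):
        """kr < 85/FOV keeps the inner 64.5% of the 140 readout points."""
        out = recon.crop_kspace(acq, 85.0 / 25.0)
        assert abs(out.n_readout - 0.645 * 140) <= 1
        # supported matrix J = 2 kr_max FOV = 170 -> 147 um nominal voxel
        assert 25.0 / (2 * 85.0 / 25.0 * 25.0) * 1000 == pytest.approx(147.1,
                                                                       abs=0.1)

    def test_half_crop_keeps_half(self, acq):
        out = recon.crop_kspace(acq, acq.k_radii[-1] / 2.0)
        assert out.n_readout == acq.n_readout // 2

    def test_invalid_kr_max(self, acq):
        with pytest.raises(ValueError):
            recon.crop_kspace(acq, -1.0)


class TestReconstructFrame:
    def test_zero_samples_zero_volume(self):
        dirs = ph.generate_trajectory(100)
        k_r = np.linspace(0, 0.96, 16)
        vol = recon.reconstruct_frame(np.zeros((100, 16)), dirs, k_r, 24,
                                      (25, 25, 4))
        assert np.abs(vol).max() == 0

    def test_linearity(self):
        rng = np.random.default_rng(5)
        dirs = ph.generate_trajectory(120)
        k_r = np.linspace(0, 0.96, 12)
        s1 = rng.standard_normal((120, 12)) + 1j * rng.standard_normal(
            (120, 12))
        s2 = rng.standard_normal((120, 12)) + 1j * rng.standard_normal(
            (120, 12))
        a, b = 1.7, -0.4 + 0.2j
        v = recon.reconstruct_frame(a * s1 + b * s2, dirs, k_r, 16,
                                    (25, 25, 4))
        v1 = recon.reconstruct_frame(s1, dirs, k_r, 16, (25, 25, 4))
        v2 = recon.reconstruct_frame(s2, dirs, k_r, 16, (25, 25, 4))
        assert np.allclose(v, a * v1 + b * v2, rtol=1e-8, atol=1e-10)

    def test_mismatched_inputs_raise(self):
        dirs = ph.generate_trajectory(10)
        with pytest.raises(ReconError):
            recon.reconstruct_frame(np.ones((9, 8)), dirs,
                                    np.linspace(0, 1, 8), 16, (25, 25, 4))

    def test_gridding_matches_direct_dft(self):
        """Same spokes, gridding vs brute-force type-1 DFT: rel L2 < 1e-3
        (after identical density weighting)."""
        from oracles import ndft_adjoint

        rng = np.random.default_rng(6)
        dirs = ph.generate_trajectory(200)
        k_r = np.linspace(0, 0.9, 10)
        samples = rng.standard_normal((200, 10)) \
            + 1j * rng.standard_normal((200, 10))
        matrix, fov = 16, (25.0, 25.0, 4.0)
        vol = recon.reconstruct_frame(samples, dirs, k_r, matrix, fov,
                                      dcf="analytic")
        # oracle: same physical frequencies and weights, direct summation
        from flow4d.config import slab_matrix

        mz = slab_matrix(matrix, fov)
        voxel = np.array([fov[0] / matrix, fov[1] / matrix, fov[2] / mz])
        pts = (k_r[None, :, None] * dirs[:, None, :]).reshape(-1, 3)
        omega = 2 * np.pi * pts * voxel
        w = (recon.radial_weights(k_r)[None, :]
             / ph.polar_density(dirs[:, 2], fov)[:, None]).ravel()
        w /= w.sum()
        ref = ndft_adjoint(omega, samples.ravel() * w, (matrix, matrix, mz))
        err = np.linalg.norm(vol - ref) / np.linalg.norm(ref)
        assert err < 1e-3


class TestZeroFill:
    def test_doubles_grid_and_keeps_peak(self):
        vol = np.zeros((8, 8, 4), complex)
        vol[4, 4, 2] = 1.0
        out = recon.zero_fill(vol, 2)
        assert out.shape == (16, 16, 8)
        assert np.abs(out[8, 8, 4]) == pytest.approx(1.0, rel=1e-9)

    def test_identity_factor_one(self):
        vol = np.arange(8).reshape(2, 2, 2).astype(complex)
        assert recon.zero_fill(vol, 1) is vol


class TestMetrics:
    def test_nyquist_counts_match_protocol(self):
        """J = 170 -> ~1.4e4, J = 250 -> ~3.1e4 projections."""
        assert recon.nyquist_projections(170) == 14527
        assert recon.nyquist_projections(250) == 31416

    def test_uniform_window_phase_sd(self):
        """Uniform phases in a width-W window: sd = W/sqrt(12); with
        W = 1/33 and RR 100 ms the temporal blurring is 0.875 ms."""
        rng = np.random.default_rng(11)
        scheme = recon.BinningScheme(1, 1 / 33)
        phases = [rng.uniform(-1 / 66, 1 / 66, 200000) % 1.0]
        m = recon.compute_metrics(scheme, phases, 64, 100.0)
        assert m.temporal_blurring_ms == pytest.approx(
            (1 / 33) / np.sqrt(12) * 100.0, rel=0.02)
        assert m.temporal_blurring_ms == pytest.approx(0.875, abs=0.01)

    def test_us_arithmetic(self):
        """N_Nyq = 14527 over N_f = 3879 -> us = 3.75."""
        scheme = recon.BinningScheme(1, 1 / 33)
        phases = [np.full(10, 0.0)]
        m = recon.compute_metrics(scheme, phases, 170, 100.0,
                                  projections_per_frame=np.array([3879.0]))
        assert m.undersampling == pytest.approx(3.745, abs=0.005)

    def test_us_monotone_in_width_and_matrix(self):
        """us falls as the window widens (at fixed J) and as J falls (at
        fixed W)."""
        rng = np.random.default_rng(12)
        phase = rng.uniform(0, 1, 50000)

        def us(width, J):
            scheme = recon.BinningScheme(int(1 / width), width)
            frames = recon.select_projections(phase, None, scheme)
            m = recon.compute_metrics(scheme, [phase[f] for f in frames],
                                      J, 100.0)
            return m.undersampling

        assert us(1 / 33, 170) > us(1 / 20, 170) > us(1 / 10, 170)
        assert us(1 / 20, 250) > us(1 / 20, 170) > us(1 / 20, 96)

    def test_blurring_linear_in_rr(self):
        rng = np.random.default_rng(13)
        scheme = recon.BinningScheme(1, 1 / 20)
        phases = [rng.uniform(-1 / 40, 1 / 40, 5000) % 1.0]
        m1 = recon.compute_metrics(scheme, phases, 64, 100.0)
        m2 = recon.compute_metrics(scheme, phases, 64, 150.0)
        assert m2.temporal_blurring_ms == pytest.approx(
            1.5 * m1.temporal_blurring_ms, rel=1e-12)


class TestStaticContrast:
    def test_lumen_background_contrast_preserved(self):
        """Static (velocity-off) phantom at the HS/LT operating point keeps
        at least half the configured blood:tissue contrast."""
        cfg = PhantomConfig(peak_flow=0.0, baseline_flow=0.0, noise_sd=0.0,
                            resp_motion_fraction=0.0, rr_sd=4.0)
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.25)
        seq = SequenceParams(n_readout=40, n_projections=6000,
                             kr_max=64.0 / 50.0)
        acq = ph.simulate_acquisition(dyn, seq, cfg)
        rng = np.random.default_rng(cfg.seed)
        bt = ph._draw_beats(rng, cfg, seq.scan_time_ms)
        phase = ph.cardiac_phases(acq.time_ms, bt)
        gt = selfnav.GatingTable(
            beat_times=bt, rr_periods=np.diff(bt),
            mean_rr=float(np.diff(bt).mean()), phase=phase,
            accept_mask=np.ones(acq.n_spokes, bool), n_beats=len(bt) - 1,
            n_beats_expected=len(bt) - 1, yield_percent=100.0,
            scan_time_ms=seq.scan_time_ms)
        prof = recon.ReconProfile(name="hs", matrix=64,
                                  binning=recon.BinningScheme(4, 1 / 4))
        cine = recon.reconstruct_cine(acq, gt, prof)
        mag = cine.magnitude()[0]
        shape = mag.shape
        axes = [(np.arange(n) - n // 2) * v
                for n, v in zip(shape, cine.voxel)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        _, r, _ = dyn.geometry.project(pts)
        lum = (r < 0.7).reshape(shape)
        bg = (r > 1.8).reshape(shape) & (np.abs(Z) < 1.0)
        ratio = mag[lum].mean() / mag[bg].mean()
        assert ratio >= cfg.blood_tissue_signal_ratio / 2.0
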