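"""Segmentation, label interpolation, centerline and wall surface."""

import numpy as np
import pytest

from flow4d.config import PhantomConfig
from flow4d.errors import CenterlineError, SegmentationError
from flow4d import lumen
from flow4d import phantom as ph


def tube_dice(labels, geom, voxel, origin):
    shape = labels.shape
    axes = [origin[d] + np.arange(shape[d]) * voxel[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    truth = geom.contains(pts).reshape(shape)
    inter = np.logical_and(labels > 0, truth).sum()
    return 2.0 * inter / ((labels > 0).sum() + truth.sum())


@pytest.fixture(scope="module")
def gt_magnitude():
    """Anti-aliased phantom magnitude at R/4 voxels (no recon involved)."""
    cfg = PhantomConfig()
    dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.25)
    return cfg, dyn


class TestSegmentation:
    def test_dice_against_analytic_tube(self, gt_magnitude):
        """Blood:tissue 10, threshold 0.5: Dice >= 0.9 at R/4 voxels."""
        cfg, dyn = gt_magnitude
        labs = lumen.segment_lumen(
            dyn.magnitude[None], dyn.voxel, dyn.origin,
            np.array([[-2.5, 0.0, 0.0]]), 0.5)
        assert tube_dice(labs.labels[0], dyn.geometry, labs.voxel,
                         labs.origin) >= 0.9

    def test_volume_within_10_percent(self, gt_magnitude):
        """Segmented volume within 10% of the analytic tube volume at R/4
        voxels (cylindrical body plus the two hemispherical end caps of
        the closest-point lumen definition)."""
        cfg, dyn = gt_magnitude
        labs = lumen.segment_lumen(
            dyn.magnitude[None], dyn.voxel, dyn.origin,
            np.array([[-2.5, 0.0, 0.0]]), 0.5)
        R = cfg.lumen_radius
        true_vol = (np.pi * R**2 * dyn.geometry.arc_length
                    + 4.0 / 3.0 * np.pi * R**3)
        assert labs.volume_ml()[0] == pytest.approx(true_vol, rel=0.10)

    def test_background_seed_raises(self, gt_magnitude):
        cfg, dyn = gt_magnitude
        with pytest.raises(SegmentationError, match="seed"):
            lumen.segment_lumen(dyn.magnitude[None], dyn.voxel,
                                dyn.origin, np.array([[11.0, -11.0, 1.5]]),
                                0.5)

    def test_only_seeded_tube_labeled(self):
        """Two disjoint bright bars; the seeded one is segmented alone."""
        mag = np.full((40, 20, 10), 0.1, np.float32)
        mag[5:10, 5:15, 3:7] = 1.0
        mag[25:30, 5:15, 3:7] = 1.0
        voxel = np.full(3, 0.5)
        origin = -voxel * np.array([20, 10, 5])
        seed = origin + voxel * np.array([7, 10, 5])
        labs = lumen.segment_lumen(mag[None], voxel, origin, seed[None],
                                   0.5)
        assert labs.labels[0][7, 10, 5] == 1
        assert not labs.labels[0][25:30].any()


class TestInterpolateLabels:
    def _static(self):
        lab = np.zeros((2, 8, 8, 8), np.uint8)
        lab[:, 2:6, 2:6, 2:6] = 1
        return lumen.LabelCine(lab, np.full(3, 0.5),
                               -np.full(3, 2.0), np.array([0.0, 0.5]))

    def test_static_label_unchanged(self):
        labs = self._static()
        out = lumen.interpolate_labels(labs, 8)
        assert all(np.array_equal(out.labels[i], labs.labels[0])
                   for i in range(8))

    def test_midpoint_half_occupancy_is_labeled(self):
        """Empty -> full across one frame: 0.5 occupancy at the midpoint
        is labeled under the >= 0.5 rule."""
        lab = np.zeros((2, 4, 4, 4), np.uint8)
        lab[1, 1, 1, 1] = 1
        labs = lumen.LabelCine(lab, np.full(3, 1.0), -np.full(3, 2.0),
                               np.array([0.0, 0.5]))
        out = lumen.interpolate_labels(labs, 8)
        # target frame 2 sits at phase 0.25, halfway between the sources
        assert out.labels[2, 1, 1, 1] == 1

    def test_interpolated_volume_bounded_by_neighbours(self):
        rng = np.random.default_rng(2)
        lab = np.zeros((4, 10, 10, 6), np.uint8)
        for f, r in enumerate((2.0, 3.0, 2.5, 2.2)):
            X, Y, Z = np.meshgrid(*[np.arange(n) for n in (10, 10, 6)],
                                  indexing="ij")
            lab[f] = ((X - 5)**2 + (Y - 5)**2 + (Z - 3)**2) < r**2
        labs = lumen.LabelCine(lab, np.full(3, 1.0), -np.full(3, 5.0),
                               np.arange(4) / 4.0)
        out = lumen.interpolate_labels(labs, 16)
        vols = out.volume_ml()
        src = labs.volume_ml()
        lo, hi = src.min(), src.max()
        assert vols.min() >= lo - 2 and vols.max() <= hi + 2

    def test_spatial_regrid_keeps_geometry(self):
        labs = self._static()
        out = lumen.interpolate_labels(labs, 4, target_voxel=np.full(3, 0.2),
                                       target_shape=(20, 20, 20))
        # volume preserved by the 0.5-rule resampling to within a voxel shell
        assert out.volume_ml()[0] == pytest.approx(labs.volume_ml()[0],
                                                   rel=0.15)


def cylinder_labels(radius=1.0, length=10.0, voxel=0.25, axis=0):
    n = int(length / voxel) + 8
    m = int(4 * radius / voxel) + 8
    shape = [m, m, m]
    shape[axis] = n
    axes = [(np.arange(s) - s // 2) * voxel for s in shape]
    G = np.meshgrid(*axes, indexing="ij")
    perp = [G[d] for d in range(3) if d != axis]
    along = G[axis]
    lab = ((perp[0]**2 + perp[1]**2 < radius**2)
           & (np.abs(along) < length / 2)).astype(np.uint8)
    origin = np.array([a[0] for a in axes])
    return lumen.LabelCine(lab[None], np.full(3, voxel), origin,
                           np.array([0.0]))


class TestCenterline:
    def test_straight_cylinder_axis(self):
        labs = cylinder_labels()
        cl = lumen.extract_centerline(labs, 0)
        # interior points stay within half a voxel of the true axis
        mid = (cl.arc_length > 1.5) & (cl.arc_length
                                       < cl.total_length - 1.5)
        dev = np.linalg.norm(cl.points[mid][:, 1:], axis=1)
        assert dev.max() < 0.5 * 0.25 + 1e-6
        assert np.all(np.diff(cl.arc_length) > 0)

    def test_half_torus_arc_length(self):
        """U-tube with 5 mm bend radius: recovered length within 3% of the
        analytic arc (interior portion; the voxel ends round off)."""
        cfg = PhantomConfig(arch_curvature_radius=5.0, straight_length=2.0)
        dyn = ph.build_dynamics(cfg, n_phase_samples=50, grid_spacing=0.2)
        labs = ph.truth_labels(dyn, voxel=0.2)
        cl = lumen.extract_centerline(labs, 0)
        expect = 2 * 2.0 + np.pi * 5.0
        assert cl.total_length == pytest.approx(expect, rel=0.05)
        arch_only = np.pi * 5.0
        assert cl.total_length > arch_only

    def test_branching_raises(self):
        lab = np.zeros((1, 24, 24, 8), np.uint8)
        lab[0, 4:20, 11:14, 3:6] = 1      # trunk
        lab[0, 11:14, 4:20, 3:6] = 1      # crossing branch
        labs = lumen.LabelCine(lab, np.full(3, 0.5),
                               -np.full(3, 6.0), np.array([0.0]))
        with pytest.raises(CenterlineError, match="endpoint"):
            lumen.extract_centerline(labs, 0)

    def test_orientation_follows_start_hint(self):
        labs = cylinder_labels()
        cl = lumen.extract_centerline(
            labs, 0, start_hint=np.array([+6.0, 0.0, 0.0]))
        assert cl.points[0, 0] > cl.points[-1, 0]


@pytest.fixture(scope="module")
def cyl_surface():
    labs = cylinder_labels(radius=1.2, length=8.0, voxel=0.2)
    cl = lumen.extract_centerline(labs, 0)
    return labs, lumen.extract_surface(labs, cl), cl


class TestSurface:

    def test_vertex_radius(self, cyl_surface):
        labs, surf, cl = cyl_surface
        wall = np.abs(surf.vertices[:, 0]) < 3.0   # away from the caps
        r = np.linalg.norm(surf.vertices[wall][:, 1:], axis=1)
        assert np.abs(r.mean() - 1.2) < 0.5 * 0.2

    def test_normals_point_inward(self, cyl_surface):
        labs, surf, cl = cyl_surface
        eps = 0.4
        probe = surf.vertices + eps * surf.normals
        idx = ((probe - labs.origin) / labs.voxel).T
        from scipy import ndimage

        inside = ndimage.map_coordinates(labs.labels[0].astype(float),
                                         idx, order=1) > 0.5
        assert inside.mean() > 0.9

    def test_region_and_sector_partition(self, hs_labels, hs_centerline):
        """On the arch phantom every vertex carries exactly one region tag
        and one sector, and A/T/D are all populated."""
        surf = lumen.extract_surface(hs_labels, hs_centerline)
        assert set(np.unique(surf.region)) == {"A", "T", "D"}
        assert surf.sector.min() >= 0 and surf.sector.max() <= 7
        assert len(surf.region) == len(surf.vertices)
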