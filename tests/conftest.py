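"""Shared fixtures.

The expensive session fixtures build one desk-scale phantom dataset
(simulation, self-gating, both reconstructions, segmentation, velocity,
flow curves) that the acceptance tests and several module-level property
tests share.  Everything is generated at run time; nothing is read from
disk.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from flow4d.config import PhantomConfig, SequenceParams
from flow4d import phantom as ph
from flow4d import selfnav, recon, flowfield, lumen
from flow4d import pwv as pwv_mod


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def dynamics(phantom_cfg):
    return ph.build_dynamics(phantom_cfg)


@pytest.fixture(scope="session")
def desk_seq():
    return SequenceParams.desk_scale()


@pytest.fixture(scope="session")
def desk_acq(dynamics, desk_seq, phantom_cfg):
    """Desk-scale raw acquisition of the default pulsatile phantom."""
    return ph.simulate_acquisition(dynamics, desk_seq, phantom_cfg)


@pytest.fixture(scope="session")
def desk_gating(desk_acq):
    return selfnav.gate(desk_acq)


@pytest.fixture(scope="session")
def hs_cine(desk_acq, desk_gating):
    """High-spatial / low-temporal (20-frame) reconstruction."""
    return recon.reconstruct_cine(desk_acq, desk_gating,
                                  recon.ReconProfile.hs_lt_desk())


@pytest.fixture(scope="session")
def hs_labels(hs_cine):
    seeds = np.array([[-2.5, 0.0, 0.0], [0.0, 2.5, 0.0], [2.5, 0.0, 0.0]])
    return lumen.segment_lumen(hs_cine.magnitude(), hs_cine.voxel,
                               hs_cine.origin, seeds, 0.5,
                               hs_cine.frame_phase_centers)


@pytest.fixture(scope="session")
def hs_centerline(hs_labels):
    return lumen.extract_centerline(hs_labels, 0,
                                    start_hint=np.array([-2.5, -2.5, 0.0]))


@pytest.fixture(scope="session")
def ls_velocity(desk_acq, desk_gating, hs_labels):
    """LS/HT (200 overlapping frames) velocity cine, masked and filtered,
    plus the temporally interpolated labels on the same grid."""
    cine = recon.reconstruct_cine(desk_acq, desk_gating,
                                  recon.ReconProfile.ls_ht_desk())
    vc = flowfield.decode_velocity(cine)
    del cine
    labs = lumen.interpolate_labels(
        hs_labels, vc.n_frames, target_voxel=vc.voxel,
        target_shape=vc.shape, target_phase_centers=vc.frame_phase_centers)
    vc = flowfield.mask_velocity(vc, labs.labels)
    vc = flowfield.median_filter_velocity(vc, labs.labels)
    return vc, labs


@pytest.fixture(scope="session")
def ls_planes(hs_centerline):
    L = hs_centerline.total_length
    return pwv_mod.place_planes(hs_centerline, 50,
                                exclusions=[(0.0, 1.5), (L - 1.5, L)])


@pytest.fixture(scope="session")
def ls_curves(ls_velocity, ls_planes, desk_gating):
    vc, labs = ls_velocity
    return [pwv_mod.through_plane_flow(vc, p, labs, desk_gating.mean_rr)
            for p in ls_planes]


@pytest.fixture(scope="session")
def truth_curves(dynamics, phantom_cfg):
    """Flow curves from the noise-free analytic velocity field (recon
    bypassed): the oracle side of the recovery check."""
    vc = ph.truth_velocity_cine(dynamics, n_frames=200, voxel=0.25)
    labs = ph.truth_labels(dynamics, voxel=0.25)
    cl = ph.truth_centerline(dynamics)
    L = cl.total_length
    planes = pwv_mod.place_planes(cl, 50, exclusions=[(0.0, 1.5),
                                                      (L - 1.5, L)])
    curves = [pwv_mod.through_plane_flow(vc, p, labs,
                                         phantom_cfg.mean_rr)
              for p in planes]
    return curves
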