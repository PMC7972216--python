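"""Velocity decoding from the balanced 4-point encoder cines.

The four encoders impart signal phase ``phi_e = pi/(2 venc) * h_e . v``
with the tetrahedral scheme ``h`` (rows (-1,-1,-1), (+1,+1,-1), (+1,-1,+1),
(-1,+1,+1)).  Because the columns of ``h^T`` sum to zero, any phase offset
common to the four encoders cancels and the least-squares decode is simply
``v = venc/(2 pi) * h^T . phi``.  Velocities with |v| < venc (vector norm)
decode exactly; beyond that the phase wraps and components alias by
multiples of 2 venc (documented, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ReconError
from .phantom import H_SCHEME
from .recon import CineStack


@dataclass(frozen=True)
class VelocityEncoding:
    venc: float
    h_matrix: np.ndarray = field(default_factory=lambda: H_SCHEME.copy())

    @property
    def decode_matrix(self) -> np.ndarray:
        """(3, 4) matrix taking encoder phases to velocity in cm/s."""
        # pinv(h) = h^T / 4 for the tetrahedral scheme; keep the general form
        return self.venc * (2.0 / np.pi) * np.linalg.pinv(self.h_matrix)

    def encode_phases(self, v: np.ndarray) -> np.ndarray:
        """Encoder phases (rad) of velocity vectors (..., 3)."""
        return (np.pi / (2.0 * self.venc)) * np.einsum(
            "ec,...c->...e", self.h_matrix, np.asarray(v, float))

    def decode(self, phases: np.ndarray) -> np.ndarray:
        """Velocity (..., 3) from encoder phases (..., 4)."""
        return np.einsum("ce,...e->...c", self.decode_matrix,
                         np.asarray(phases, float))


@dataclass
class VelocityCine:
    """Decoded 3-component velocity (cm/s) per voxel per frame."""

    v: np.ndarray                    # (n_frames, 3, nx, ny, nz) float32
    voxel: np.ndarray                # mm
    origin: np.ndarray               # mm position of voxel (0,0,0)
    frame_phase_centers: np.ndarray
    venc: float
    magnitude: np.ndarray | None = None   # (n_frames, nx, ny, nz)
    mask_applied: bool = False

    @property
    def n_frames(self) -> int:
        return self.v.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.v.shape[2:]

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.v, axis=1)


def decode_velocity(cines: CineStack,
                    enc: VelocityEncoding | None = None) -> VelocityCine:
    """Per-voxel velocity from the phases of the four encoder cines."""
    if cines.images.shape[1] != 4:
        raise ReconError(
            f"expected 4 encoder cines, got {cines.images.shape[1]}")
    if enc is None:
        enc = VelocityEncoding(venc=cines.venc)
    phases = np.angle(cines.images)                      # (F, 4, ...)
    v = np.einsum("ce,fexyz->fcxyz", enc.decode_matrix,
                  phases).astype(np.float32)
    return VelocityCine(
        v=v, voxel=cines.voxel, origin=cines.origin,
        frame_phase_centers=cines.frame_phase_centers, venc=enc.venc,
        magnitude=cines.magnitude().astype(np.float32))


_FOOTPRINT_6 = ndimage.generate_binary_structure(3, 1)   # faces + centre
_FOOTPRINT_26 = ndimage.generate_binary_structure(3, 3)


def median_filter_velocity(vc: VelocityCine,
                           labels: np.ndarray | None = None,
                           connectivity: int = 6) -> VelocityCine:
    """Spatial median filter over the face-adjacent neighbourhood + centre.

    Frames are filtered independently; when ``labels`` is given the result
    replaces the field only inside the mask (the field outside is kept,
    typically zero after masking).
    """
    fp = _FOOTPRINT_6 if connectivity == 6 else _FOOTPRINT_26
    out = np.empty_like(vc.v)
    for f in range(vc.n_frames):
        lab = labels[f] if (labels is not None and labels.ndim == 4) \
            else labels
        for c in range(3):
            filt = ndimage.median_filter(vc.v[f, c], footprint=fp,
                                         mode="nearest")
            if lab is None:
                out[f, c] = filt
            else:
                out[f, c] = np.where(lab > 0, filt, vc.v[f, c])
    return VelocityCine(v=out, voxel=vc.voxel, origin=vc.origin,
                        frame_phase_centers=vc.frame_phase_centers,
                        venc=vc.venc, magnitude=vc.magnitude,
                        mask_applied=vc.mask_applied)


def mask_velocity(vc: VelocityCine, labels: np.ndarray) -> VelocityCine:
    """Zero the velocity field outside the lumen labels.

    ``labels`` is (nx, ny, nz) or per-frame (n_frames, nx, ny, nz).
    """
    labels = np.asarray(labels)
    if labels.ndim == 3:
        if labels.shape != vc.shape:
            raise ReconError(
                f"label grid {labels.shape} != velocity grid {vc.shape}")
        m = (labels > 0)[None, None]
    elif labels.ndim == 4:
        if labels.shape != (vc.n_frames,) + vc.shape:
            raise ReconError(
                f"label cine {labels.shape} does not match velocity cine "
                f"{(vc.n_frames,) + vc.shape}")
        m = (labels > 0)[:, None]
    else:
        raise ReconError("labels must be 3D or 4D")
    return VelocityCine(v=(vc.v * m).astype(np.float32), voxel=vc.voxel,
                        origin=vc.origin,
                        frame_phase_centers=vc.frame_phase_centers,
                        venc=vc.venc, magnitude=vc.magnitude,
                        mask_applied=True)
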