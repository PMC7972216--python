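"""File formats: raw HDF5 schema, NIfTI volumes, legacy VTK polydata, CSV.

Raw-data HDF5 schema (bit-exact contract)
-----------------------------------------
datasets ``/kspace`` (complex, n_spokes x n_readout), ``/traj`` (float,
n_spokes x 3 unit vectors), ``/time_ms``, ``/encoder`` (int 0-3), ``/nav``;
root attributes mirror SequenceParams and PhantomConfig (including
``pwv_true``).  Datasets are written with ``track_times=False`` so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import h5py
import numpy as np

from .config import PhantomConfig, SequenceParams
from .phantom import GroundTruthDynamics, RadialAcquisition

_SEQ_FIELDS = ("tr", "te", "flip", "n_readout", "n_projections",
               "n_encoders", "venc", "slab_thickness", "kr_max")


def save_raw(acq: RadialAcquisition, path) -> None:
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        for name, arr in (("kspace", acq.kspace), ("traj", acq.traj),
                          ("time_ms", acq.time_ms), ("encoder", acq.encoder),
                          ("nav", acq.nav)):
            f.create_dataset(name, data=arr, track_times=False)
        for k in _SEQ_FIELDS:
            f.attrs[k] = getattr(acq.seq, k)
        f.attrs["fov"] = list(acq.seq.fov)
        for k, v in acq.phantom.items():
            if isinstance(v, float) and math.isinf(v):
                v = np.finfo(np.float64).max
            f.attrs[f"phantom_{k}"] = v
        f.attrs["velocity_aliasing"] = bool(acq.velocity_aliasing)


def load_raw(path) -> RadialAcquisition:
    with h5py.File(path, "r") as f:
        seq_kw = {k: f.attrs[k] for k in _SEQ_FIELDS}
        seq_kw["fov"] = tuple(float(v) for v in f.attrs["fov"])
        for k in ("n_readout", "n_projections", "n_encoders"):
            seq_kw[k] = int(seq_kw[k])
        for k in ("tr", "te", "flip", "venc", "slab_thickness", "kr_max"):
            seq_kw[k] = float(seq_kw[k])
        seq = SequenceParams(**seq_kw)
        phantom = {k[len("phantom_"):]: f.attrs[k]
                   for k in f.attrs if k.startswith("phantom_")}
        return RadialAcquisition(
            kspace=f["kspace"][()], traj=f["traj"][()],
            time_ms=f["time_ms"][()], encoder=f["encoder"][()],
            nav=f["nav"][()], seq=seq, phantom=phantom,
            velocity_aliasing=bool(f.attrs.get("velocity_aliasing", False)))


# ----------------------------------------------------------------------
# NIfTI
# ----------------------------------------------------------------------
def save_nifti(volume: np.ndarray, voxel, path, description: str = "") -> None:
    """Write a 3D/4D/5D volume with a diagonal affine (mm voxel sizes)."""
    import nibabel as nib

    voxel = np.asarray(voxel, float)
    affine = np.diag(list(voxel[:3]) + [1.0])
    affine[:3, 3] = -voxel[:3] * (np.asarray(volume.shape[:3]) // 2)
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header["descrip"] = description.encode()[:79]
    zooms = list(voxel[:3]) + [1.0] * (volume.ndim - 3)
    img.header.set_zooms(zooms[:volume.ndim])
    img.to_filename(str(path))


def load_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    voxel = np.asarray(img.header.get_zooms()[:3], float)
    return np.asarray(img.dataobj), voxel


# ----------------------------------------------------------------------
# legacy ASCII VTK polydata (no external mesh library available)
# ----------------------------------------------------------------------
def write_vtk_polydata(path, vertices: np.ndarray, faces: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None,
                       ) -> None:
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    lines = ["# vtk DataFile Version 3.0", "flow4d surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(vertices)} float"]
    lines += [" ".join(f"{c:.6g}" for c in v) for v in vertices]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.6g}" for v in arr.astype(float)]
            else:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{c:.6g}" for c in v)
                          for v in arr.astype(float)]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# ground truth + tabular exports
# ----------------------------------------------------------------------
def export_ground_truth(dyn: GroundTruthDynamics, outdir) -> None:
    """NIfTI magnitude + one velocity volume per phase decile, CSV centerline."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_nifti(dyn.magnitude, dyn.voxel, outdir / "magnitude.nii.gz",
               "phantom magnitude")
    save_nifti(dyn.lumen_mask.astype(np.uint8), dyn.voxel,
               outdir / "lumen.nii.gz", "true lumen mask")
    pd.DataFrame(dyn.centerline_true,
                 columns=["x_mm", "y_mm", "z_mm", "s_mm"]).to_csv(
        outdir / "centerline_true.csv", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
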