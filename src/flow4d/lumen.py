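"""Lumen segmentation, temporal label interpolation, centerline, surface.

Segmentation is seeded threshold region-growing on the high-spatial-
resolution magnitude cine (the semi-automatic labelling step of the
original workflow; the contract is the label cine, not the tool).  Labels
are interpolated linearly along the (circular) temporal dimension and
re-gridded to the PWV reconstruction grid.  The centerline is the medial
path of the lumen, ordered from the ascending end; the wall surface is the
0.5-occupancy iso-surface with inward normals and bulls-eye region/sector
tags (ascending / top / descending x angular sectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import CenterlineError, SegmentationError

REGIONS = ("A", "T", "D")


@dataclass
class LabelCine:
    """Binary lumen labels per frame."""

    labels: np.ndarray           # (n_frames, nx, ny, nz) uint8
    voxel: np.ndarray            # mm
    origin: np.ndarray           # mm
    frame_phase_centers: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape[1:]

    def volume_ml(self) -> np.ndarray:
        """Lumen volume per frame in microlitres (mm^3)."""
        vv = float(np.prod(self.voxel))
        return self.labels.reshape(self.n_frames, -1).sum(axis=1) * vv


@dataclass
class Centerline:
    points: np.ndarray           # (n, 3) mm
    arc_length: np.ndarray       # (n,) mm, strictly increasing from 0
    tangents: np.ndarray         # (n, 3) unit

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def at(self, s):
        """Interpolate points and tangents at arbitrary arc positions."""
        s = np.atleast_1d(np.asarray(s, float))
        pts = np.column_stack([
            np.interp(s, self.arc_length, self.points[:, d])
            for d in range(3)])
        tg = np.column_stack([
            np.interp(s, self.arc_length, self.tangents[:, d])
            for d in range(3)])
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        return pts, tg


@dataclass
class WallSurface:
    vertices: np.ndarray         # (nV, 3) mm
    faces: np.ndarray            # (nF, 3) int
    normals: np.ndarray          # (nV, 3) unit, inward
    region: np.ndarray           # (nV,) str in {A, T, D}
    sector: np.ndarray           # (nV,) int
    vertex_arc: np.ndarray       # (nV,) mm along the centerline


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _segment_frame(mag: np.ndarray, seed_idx: np.ndarray,
                   threshold_fraction: float) -> np.ndarray:
    ref = []
    for s in seed_idx:
        sl = tuple(slice(max(c - 1, 0), c + 2) for c in s)
        ref.append(mag[sl].ravel())
    seed_level = np.percentile(np.concatenate(ref), 99)
    # a seed dropped into background has no blood contrast: its local
    # intensity sits at the global (background-dominated) median
    if seed_level < 2.0 * np.median(mag):
        raise SegmentationError(
            "seed intensity does not stand out from the background "
            "(seed outside any suprathreshold region?)")
    thr = threshold_fraction * seed_level
    binary = mag >= thr
    lab, n = ndimage.label(binary, structure=_STRUCT6)
    keep = set()
    for s in seed_idx:
        l = lab[tuple(s)]
        if l == 0:
            raise SegmentationError(
                f"seed at index {tuple(int(c) for c in s)} lies below the "
                f"threshold {thr:.3g}")
        keep.add(int(l))
    grown = np.isin(lab, sorted(keep))
    closed = ndimage.binary_closing(grown, structure=_STRUCT6, iterations=1)
    lab2, n2 = ndimage.label(closed, structure=_STRUCT6)
    if n2 > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab2), lab2,
                                   np.arange(1, n2 + 1))
        closed = lab2 == (1 + int(np.argmax(sizes)))
    return closed


def segment_lumen(magnitude: np.ndarray, voxel, origin,
                  seeds_mm: np.ndarray, threshold_fraction: float = 0.5,
                  frame_phase_centers: np.ndarray | None = None) -> LabelCine:
    """Seeded threshold region-growing, per frame.

    ``magnitude`` is (n_frames, nx, ny, nz); ``seeds_mm`` are physical
    points inside the vessel.  The threshold is ``threshold_fraction``
    times the 99th percentile of the intensities around the seeds.
    """
    magnitude = np.asarray(magnitude)
    if magnitude.ndim == 3:
        magnitude = magnitude[None]
    voxel = np.asarray(voxel, float)
    origin = np.asarray(origin, float)
    seeds = np.atleast_2d(np.asarray(seeds_mm, float))
    seed_idx = np.round((seeds - origin) / voxel).astype(int)
    shape = np.asarray(magnitude.shape[1:])
    if np.any(seed_idx < 0) or np.any(seed_idx >= shape):
        raise SegmentationError("seed point outside the image grid")
    frames = [
        _segment_frame(magnitude[f], seed_idx, threshold_fraction)
        for f in range(magnitude.shape[0])]
    if frame_phase_centers is None:
        frame_phase_centers = np.arange(len(frames)) / max(len(frames), 1)
    return LabelCine(labels=np.stack(frames).astype(np.uint8), voxel=voxel,
                     origin=origin,
                     frame_phase_centers=np.asarray(frame_phase_centers))


# ----------------------------------------------------------------------
# temporal interpolation + regridding
# ----------------------------------------------------------------------
def interpolate_labels(labels: LabelCine, target_frames: int,
                       target_voxel=None, target_shape=None,
                       target_phase_centers: np.ndarray | None = None,
                       ) -> LabelCine:
    """Linear circular interpolation in time, occupancy >= 0.5 rule.

    Optionally re-grids spatially (trilinear occupancy resampling with the
    same 0.5 rule) when ``target_voxel``/``target_shape`` are given.
    """
    if target_frames < labels.n_frames:
        raise ValueError("target_frames must be >= source frames")
    src = labels.labels.astype(np.float32)
    n_src = labels.n_frames
    src_c = np.asarray(labels.frame_phase_centers, float)
    if target_phase_centers is None:
        target_phase_centers = np.arange(target_frames) / target_frames
    occ_t = np.empty((target_frames,) + labels.shape, dtype=np.float32)
    for i, p in enumerate(target_phase_centers):
        # circular bracket around phase p
        rel = np.mod(p - src_c, 1.0)
        i0 = int(np.argmin(np.where(rel >= 0, rel, np.inf)))
        d0 = rel[i0]
        i1 = (i0 + 1) % n_src
        gap = np.mod(src_c[i1] - src_c[i0], 1.0)
        w = 0.0 if gap == 0 else d0 / gap
        occ_t[i] = (1 - w) * src[i0] + w * src[i1]
    if target_voxel is None:
        out = (occ_t >= 0.5).astype(np.uint8)
        return LabelCine(out, labels.voxel.copy(), labels.origin.copy(),
                         np.asarray(target_phase_centers))
    target_voxel = np.asarray(target_voxel, float)
    if target_shape is None:
        target_shape = tuple(
            int(round(n * labels.voxel[d] / target_voxel[d]))
            for d, n in enumerate(labels.shape))
    target_origin = -target_voxel * (np.asarray(target_shape) // 2)
    axes = [target_origin[d] + np.arange(target_shape[d]) * target_voxel[d]
            for d in range(3)]
    G = np.meshgrid(*axes, indexing="ij")
    coords = [(g - labels.origin[d]) / labels.voxel[d]
              for d, g in enumerate(G)]
    out = np.empty((target_frames,) + tuple(target_shape), dtype=np.uint8)
    for i in range(target_frames):
        res = ndimage.map_coordinates(occ_t[i], coords, order=1,
                                      mode="nearest")
        out[i] = res >= 0.5
    return LabelCine(out, target_voxel, target_origin,
                     np.asarray(target_phase_centers))


# ----------------------------------------------------------------------
# centerline
# ----------------------------------------------------------------------
def _skeleton_graph(skel: np.ndarray):
    vox = np.argwhere(skel)
    tree = cKDTree(vox)
    pairs = tree.query_pairs(r=np.sqrt(3.0) + 1e-6, output_type="ndarray")
    n = len(vox)
    adj = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    return vox, adj


def _bfs_far(adj, start):
    from collections import deque

    n = len(adj)
    dist = np.full(n, -1)
    prev = np.full(n, -1)
    dist[start] = 0
    dq = deque([start])
    while dq:
        u = dq.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                prev[v] = u
                dq.append(v)
    far = int(np.argmax(dist))
    return far, dist, prev


def _prune_endpoints(vox, adj, min_spur: int):
    """Count endpoints after removing spurs shorter than min_spur voxels."""
    deg = np.array([len(a) for a in adj])
    alive = np.ones(len(vox), bool)
    for _ in range(min_spur):
        ends = np.flatnonzero(alive & (deg <= 1))
        if len(ends) <= 2:
            break
        # drop all current endpoints except the two forming the diameter
        for e in ends:
            alive[e] = False
            for v in adj[e]:
                deg[v] -= 1
            deg[e] = 0
    return int(np.sum(alive & (deg == 1)))


def extract_centerline(labels: LabelCine, reference_frame: int = 0,
                       start_hint: np.ndarray | None = None,
                       smoothing: float | None = None,
                       spacing_factor: float = 1.0) -> Centerline:
    """Medial path of the lumen, ordered from the ascending end.

    The 3D skeleton of the reference-frame label is reduced to its longest
    geodesic (graph diameter); a smoothing spline removes voxel jitter and
    the result is resampled at about one voxel spacing.  A skeleton with
    more than two (non-spur) endpoints raises ``CenterlineError``.
    """
    lab = labels.labels[reference_frame] > 0
    if not lab.any():
        raise CenterlineError("empty label volume")
    skel = morphology.skeletonize(lab)
    if not skel.any():
        raise CenterlineError("skeletonization produced no voxels")
    vox, adj = _skeleton_graph(skel)
    n_end = _prune_endpoints(vox, adj, min_spur=5)
    if n_end > 2:
        raise CenterlineError(
            f"branching skeleton: {n_end} endpoints after spur pruning")
    a, _, _ = _bfs_far(adj, 0)
    b, dist, prev = _bfs_far(adj, a)
    path = [b]
    while prev[path[-1]] >= 0:
        path.append(int(prev[path[-1]]))
    pts = vox[path[::-1]].astype(float) * labels.voxel + labels.origin

    if start_hint is not None:
        if (np.linalg.norm(pts[-1] - start_hint)
                < np.linalg.norm(pts[0] - start_hint)):
            pts = pts[::-1]
    elif pts[-1, 0] < pts[0, 0]:
        pts = pts[::-1]

    # smoothing spline through the ordered voxel path
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise CenterlineError("degenerate centerline")
    if smoothing is None:
        smoothing = len(pts) * float(np.mean(labels.voxel)) ** 2
    tck, _ = interpolate.splprep(pts.T, u=chord / chord[-1], s=smoothing)
    n_out = max(int(chord[-1] / (spacing_factor * np.mean(labels.voxel))), 8)
    uu = np.linspace(0, 1, n_out)
    sm = np.column_stack(interpolate.splev(uu, tck))
    dsm = np.column_stack(interpolate.splev(uu, tck, der=1))
    tang = dsm / np.linalg.norm(dsm, axis=1, keepdims=True)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(sm, axis=0), axis=1))])
    return Centerline(points=sm, arc_length=arc, tangents=tang)


# ----------------------------------------------------------------------
# wall surface
# ----------------------------------------------------------------------
def extract_surface(labels: LabelCine, centerline: Centerline,
                    reference_frame: int = 0, n_sectors: int = 8,
                    region_breaks: tuple[float, float] = (1 / 3, 2 / 3),
                    ) -> WallSurface:
    """0.5-occupancy iso-surface with inward normals and bulls-eye tags."""
    lab = labels.labels[reference_frame].astype(np.float32)
    sm = ndimage.gaussian_filter(lab, sigma=0.6)
    verts, faces, norm, _ = measure.marching_cubes(
        sm, level=0.5, spacing=tuple(labels.voxel))
    verts = verts + labels.origin
    norm /= np.linalg.norm(norm, axis=1, keepdims=True)

    # orient normals inward: a small step along the normal must raise occupancy
    idx = ((verts + 0.75 * np.mean(labels.voxel) * norm - labels.origin)
           / labels.voxel).T
    occ_in = ndimage.map_coordinates(sm, idx, order=1, mode="nearest")
    idx2 = ((verts - 0.75 * np.mean(labels.voxel) * norm - labels.origin)
            / labels.voxel).T
    occ_out = ndimage.map_coordinates(sm, idx2, order=1, mode="nearest")
    if np.mean(occ_in > occ_out) < 0.5:
        norm = -norm

    tree = cKDTree(centerline.points)
    _, nearest = tree.query(verts)
    s_vert = centerline.arc_length[nearest]
    L = centerline.total_length
    region = np.full(len(verts), "T", dtype="<U1")
    region[s_vert < region_breaks[0] * L] = "A"
    region[s_vert >= region_breaks[1] * L] = "D"

    tang = centerline.tangents[nearest]
    zhat = np.array([0.0, 0.0, 1.0])
    b1 = zhat - tang * (tang @ zhat)[:, None]
    bad = np.linalg.norm(b1, axis=1) < 1e-6
    if bad.any():
        alt = np.array([1.0, 0.0, 0.0])
        b1[bad] = alt - tang[bad] * (tang[bad] @ alt)[:, None]
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    b2 = np.cross(tang, b1)
    d = verts - centerline.points[nearest]
    ang = np.arctan2(np.einsum("ij,ij->i", d, b2),
                     np.einsum("ij,ij->i", d, b1))
    sector = np.floor((ang + np.pi) / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    return WallSurface(vertices=verts, faces=faces, normals=norm,
                       region=region, sector=sector, vertex_arc=s_vert)
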