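"""Cell-level quantifications.

Seeded (semi-automatic) cell segmentation, spreading-area time series,
nucleus detection and adhesion-loss counting, migration tracking with
mean speed in µm/min, and filopodia count/length measurements.

Nucleus detection is a classical scale-space (Laplacian-of-Gaussian)
blob detector; track linking is greedy nearest-neighbor with gap
closing.  Both are deliberately simple, fully deterministic stand-ins
for the interactive tools commonly used for these measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import feature, filters, morphology, segmentation

__all__ = [
    "Track",
    "Filopodium",
    "segment_cell_from_seeds",
    "measure_spreading",
    "detect_nuclei",
    "adhesion_change",
    "link_tracks",
    "detect_filopodia",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Track:
    """A linked nucleus trajectory with derived motility statistics."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions_um: list[tuple[float, float]] = field(default_factory=list)

    @property
    def path_length_um(self) -> float:
        p = np.asarray(self.positions_um)
        if len(p) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))

    @property
    def net_displacement_um(self) -> float:
        p = np.asarray(self.positions_um)
        if len(p) < 2:
            return 0.0
        return float(np.hypot(*(p[-1] - p[0])))

    def duration_min(self, frame_interval: float) -> float:
        if len(self.frames) < 2:
            return 0.0
        return (self.frames[-1] - self.frames[0]) * frame_interval

    def mean_speed(self, frame_interval: float) -> float:
        d = self.duration_min(frame_interval)
        return self.path_length_um / d if d > 0 else float("nan")


@dataclass
class Filopodium:
    cell_id: int
    base: tuple[float, float]
    tip: tuple[float, float]
    length_um: float


def segment_cell_from_seeds(
    channel: np.ndarray,
    seeds: pd.DataFrame | np.ndarray,
    smooth_sigma: float = 2.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Marker-controlled region growing from user seeds.

    The foreground is a global threshold (Otsu unless given) on the
    smoothed intensity; each seed grows geodesically until the seeded
    labels partition the foreground.  ``seeds`` is an (n, 2) array of
    (row, col) or a frame with ``cell_id``, ``row``, ``col`` columns.
    """
    img = np.asarray(channel, dtype=float)
    if isinstance(seeds, pd.DataFrame):
        pts = seeds[["row", "col"]].to_numpy()
        ids = seeds["cell_id"].to_numpy() if "cell_id" in seeds else None
    else:
        pts = np.asarray(seeds, dtype=float)
        ids = None
    if pts.size == 0:
        raise ValueError("at least one seed is required")
    pts = np.atleast_2d(pts)
    if ids is None:
        ids = np.arange(1, len(pts) + 1)

    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    thr = filters.threshold_otsu(smoothed) if threshold is None else threshold
    fg = smoothed > thr

    markers = np.zeros(img.shape, dtype=np.int32)
    for (r, c), lab in zip(pts, ids):
        ir, ic = int(round(r)), int(round(c))
        if not (0 <= ir < img.shape[0] and 0 <= ic < img.shape[1]) or not fg[ir, ic]:
            raise ValueError(f"seed {lab} at ({r}, {c}) lies on background")
        markers[ir, ic] = int(lab)
    # constant elevation => breadth-first flooding = geodesic nearest-seed
    return segmentation.watershed(np.zeros_like(img), markers=markers,
                                  mask=fg, connectivity=2).astype(np.int32)


def measure_spreading(
    label_maps: list[np.ndarray],
    pixel_size: float,
) -> pd.DataFrame:
    """Per-timepoint mean cell area (µm²) and dispersion across cells.

    Timepoints without any segmented cell are recorded as missing, not
    as zero area.
    """
    if not label_maps:
        raise ValueError("need at least one timepoint")
    rows = []
    for t, lab in enumerate(label_maps):
        ids = np.unique(lab)
        ids = ids[ids > 0]
        if ids.size == 0:
            rows.append({"timepoint": t, "n_cells": 0,
                         "mean_area_um2": np.nan, "sd_area_um2": np.nan})
            continue
        areas = ndi.sum_labels(np.ones_like(lab), lab, index=ids) * pixel_size ** 2
        rows.append({"timepoint": t, "n_cells": int(ids.size),
                     "mean_area_um2": float(np.mean(areas)),
                     "sd_area_um2": float(np.std(areas, ddof=0))})
    return pd.DataFrame(rows)


def detect_nuclei(
    channel: np.ndarray,
    blob_scale_px: float = 6.0,
    threshold: float = 10.0,
) -> np.ndarray:
    """Scale-space blob detection of stained nuclei.

    A single-scale scale-normalized Laplacian-of-Gaussian response at
    sigma = scale/√2 is peak-picked with non-maximum suppression at the
    blob scale.  Returns an (n, 2) array of (row, col) centroids; an
    empty array is a valid result.  Two nuclei closer than the blob
    scale merge into one detection (documented limitation).
    """
    img = np.asarray(channel, dtype=float)
    sigma = blob_scale_px / np.sqrt(2.0)
    response = -(sigma ** 2) * ndi.gaussian_laplace(img, sigma)
    peaks = feature.peak_local_max(
        response, min_distance=max(1, int(round(blob_scale_px))),
        threshold_abs=threshold, exclude_border=False)
    # subpixel refinement: response-weighted centroid over the full
    # positive LoG lobe (radius ~2 sigma) around each peak
    h, w = img.shape
    r = max(2, int(np.ceil(2.0 * sigma)))
    out = np.empty((len(peaks), 2))
    for k, (pr, pc) in enumerate(peaks):
        sl = (slice(max(pr - r, 0), min(pr + r + 1, h)),
              slice(max(pc - r, 0), min(pc + r + 1, w)))
        win = np.clip(response[sl], 0, None)
        yy, xx = np.mgrid[sl]
        total = win.sum()
        if total > 0:
            out[k] = (yy * win).sum() / total, (xx * win).sum() / total
        else:
            out[k] = pr, pc
    return out


def adhesion_change(n_reference: int | float, n_condition: int | float) -> float:
    """Percent change in adherent-cell count relative to the reference."""
    if n_reference <= 0:
        raise ValueError("reference count must be > 0")
    return 100.0 * (n_condition - n_reference) / n_reference


def link_tracks(
    detections: list[np.ndarray],
    max_displacement_um: float = 30.0,
    max_frame_gap: int = 1,
    frame_interval: float = 20.0,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame detections.

    ``detections[t]`` is an (n_t, 2) array of (row, col) pixel positions
    in frame t.  Pairs closer than ``max_displacement_um`` are linked
    greedily by increasing distance; tracks unmatched for more than
    ``max_frame_gap`` frames are closed.  Speeds are total path length
    over total duration, in µm/min.
    """
    if frame_interval <= 0:
        raise ValueError("frame interval must be > 0")
    if len(detections) < 2:
        raise ValueError("need at least 2 frames")

    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 1
    for t, det in enumerate(detections):
        det = np.atleast_2d(np.asarray(det, dtype=float)) * pixel_size
        if det.size == 0:
            det = det.reshape(0, 2)
        unmatched = set(range(len(det)))
        if active and len(det):
            last = np.asarray([tr.positions_um[-1] for tr in active])
            dists = np.hypot(last[:, None, 0] - det[None, :, 0],
                             last[:, None, 1] - det[None, :, 1])
            pairs = sorted(
                ((dists[i, j], i, j)
                 for i in range(len(active)) for j in range(len(det))
                 if dists[i, j] <= max_displacement_um),
                key=lambda x: x[0])
            used_tracks: set[int] = set()
            for _, i, j in pairs:
                if i in used_tracks or j not in unmatched:
                    continue
                active[i].frames.append(t)
                active[i].positions_um.append(tuple(det[j]))
                used_tracks.add(i)
                unmatched.discard(j)
        for j in sorted(unmatched):
            tr = Track(track_id=next_id, frames=[t],
                       positions_um=[tuple(det[j])])
            next_id += 1
            tracks.append(tr)
            active.append(tr)
        active = [tr for tr in active if t - tr.frames[-1] <= max_frame_gap]
    return tracks


def _skeleton_geodesic(skel: np.ndarray, base_idx: int,
                       coords: np.ndarray) -> np.ndarray:
    """Geodesic distances (orthogonal=1, diagonal=√2) from one skeleton pixel."""
    n = len(coords)
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, w = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    w.append(np.sqrt(2.0) if dr and dc else 1.0)
    g = coo_matrix((w, (rows, cols)), shape=(n, n))
    return dijkstra(g.tocsr(), directed=False, indices=base_idx)


def detect_filopodia(
    cell_labels: np.ndarray,
    body_opening_radius_um: float = 2.0,
    min_length_um: float = 1.0,
    pixel_size: float = 0.2,
) -> tuple[list[Filopodium], pd.DataFrame]:
    """Detect thin protrusions and measure their geodesic lengths.

    The cell body is the morphological opening of the cell mask at the
    stated radius; every skeletonized component of (mask − body) that
    touches the body is one filopodium.  Length is the diagonal-corrected
    geodesic skeleton distance from the base (skeleton pixel nearest the
    body) to the farthest tip, in µm; filopodia shorter than
    ``min_length_um`` are discarded.
    """
    radius_px = int(round(body_opening_radius_um / pixel_size))
    filopodia: list[Filopodium] = []
    summary_rows = []
    for lab in np.unique(cell_labels):
        if lab == 0:
            continue
        mask = cell_labels == lab
        body = morphology.opening(mask, morphology.disk(radius_px))
        if not body.any():
            raise ValueError(
                f"cell {lab}: opening radius {body_opening_radius_um} µm "
                "larger than the cell")
        protrusions = mask & ~body
        body_rim = ndi.binary_dilation(body, structure=_STRUCT8)
        body_dt = ndi.distance_transform_edt(~body)
        comp_labels, n = ndi.label(protrusions, structure=_STRUCT8)
        cell_filo = []
        for k in range(1, n + 1):
            comp = comp_labels == k
            if not (comp & body_rim).any():
                continue  # detached speckle, not a protrusion
            skel = morphology.skeletonize(comp)
            coords = np.argwhere(skel)
            if len(coords) == 0:
                continue
            base_idx = int(np.argmin(body_dt[tuple(coords.T)]))
            dists = _skeleton_geodesic(skel, base_idx, coords)
            finite = np.isfinite(dists)
            tip_idx = int(np.argmax(np.where(finite, dists, -1)))
            length_um = float(dists[tip_idx]) * pixel_size
            if length_um < min_length_um:
                continue
            cell_filo.append(Filopodium(
                cell_id=int(lab),
                base=tuple(map(float, coords[base_idx])),
                tip=tuple(map(float, coords[tip_idx])),
                length_um=length_um))
        filopodia.extend(cell_filo)
        summary_rows.append({
            "cell_id": int(lab),
            "n_filopodia": len(cell_filo),
            "mean_length_um": (float(np.mean([f.length_um for f in cell_filo]))
                               if cell_filo else np.nan),
        })
    return filopodia, pd.DataFrame(summary_rows)
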