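"""Filtration-slit-density (FSD) measurement.

FSD is the total length of the slit diaphragm per glomerular capillary
area, in µm⁻¹ — the standard super-resolution readout of podocyte foot
process architecture.  The measurement operates on a 2D projection of
the slit channel: threshold the slit signal, thin it to a one-pixel
skeleton, measure its physical length with a diagonal-corrected step
metric, delineate the capillary area, and divide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import filters, morphology

__all__ = [
    "SlitNetwork",
    "segment_slits",
    "measure_curvilinear_length",
    "delineate_capillary",
    "filtration_slit_density",
    "measure_fsd",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SlitNetwork:
    """A segmented, skeletonized slit pattern with its FSD."""

    slit_mask: np.ndarray
    skeleton: np.ndarray
    skeleton_length_um: float
    capillary_mask: np.ndarray
    capillary_area_um2: float
    fsd: float  # µm⁻¹


def segment_slits(
    channel: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    smooth_sigma: float = 0.8,
) -> np.ndarray:
    """Binary mask of the slit-diaphragm signal.

    The channel is lightly Gaussian-smoothed (``smooth_sigma`` px, 0 to
    disable) before thresholding, suppressing shot-noise pixels that
    would otherwise survive the threshold and contaminate skeleton and
    envelope.  ``method='otsu'`` thresholds automatically;
    ``method='fixed'`` uses the given absolute threshold.  A constant
    image yields an empty mask with a warning; an already-binary input
    is returned unchanged.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D channel (project stacks first)")
    vals = np.unique(img)
    if len(vals) == 1:
        warnings.warn("constant image: empty slit mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    if len(vals) == 2 and set(vals) <= {0.0, 1.0}:
        return img > 0
    work = ndi.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    if method == "otsu":
        thr = filters.threshold_otsu(work)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    return work > thr


def measure_curvilinear_length(
    mask: np.ndarray,
    pixel_size: float,
) -> tuple[np.ndarray, float]:
    """Skeletonize a mask and measure its physical length in µm.

    Length sums, over every adjacent skeleton-pixel pair, 1 for an
    orthogonal and √2 for a diagonal step, scaled by the pixel size —
    plain pixel counting would underestimate diagonal curves by up to
    29 %.  An empty mask measures 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool), 0.0
    skel = morphology.skeletonize(mask)
    s = skel.astype(np.float64)
    # count each neighbor pair once via one-sided shifts
    ortho = (s[:, 1:] * s[:, :-1]).sum() + (s[1:, :] * s[:-1, :]).sum()
    diag = (s[1:, 1:] * s[:-1, :-1]).sum() + (s[1:, :-1] * s[:-1, 1:]).sum()
    length = (ortho + np.sqrt(2.0) * diag) * pixel_size
    return skel, float(length)


def delineate_capillary(
    slit_mask: np.ndarray | None = None,
    roi_polygon: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
    closing_radius_um: float = 1.0,
    pixel_size: float = 0.05,
) -> np.ndarray:
    """Capillary mask from an explicit ROI polygon or the slit envelope.

    With a polygon (n, 2 array of row/col vertices) the rasterized
    polygon is the mask.  Otherwise the slit mask is morphologically
    closed at ``closing_radius_um`` and hole-filled; the filled envelope
    is the capillary mask.
    """
    if roi_polygon is not None:
        poly = np.asarray(roi_polygon, dtype=float)
        if shape is None:
            if slit_mask is None:
                raise ValueError("need image shape (or a slit mask) for ROI rasterization")
            shape = slit_mask.shape
        return skdraw.polygon2mask(shape, poly)
    if slit_mask is None or not np.asarray(slit_mask).any():
        raise ValueError("empty slit mask and no ROI: cannot delineate capillary")
    radius_px = max(1, int(round(closing_radius_um / pixel_size)))
    mask = np.asarray(slit_mask, dtype=bool)
    # Euclidean closing via distance transforms (fast for large radii)
    dilated = ndi.distance_transform_edt(~mask) <= radius_px
    closed = ndi.distance_transform_edt(dilated) >= radius_px
    return ndi.binary_fill_holes(closed)


def filtration_slit_density(length_um: float, capillary_area_um2: float) -> float:
    """FSD = slit length / capillary area, in µm⁻¹."""
    if capillary_area_um2 <= 0:
        raise ValueError("capillary area must be > 0")
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return length_um / capillary_area_um2


def measure_fsd(
    channel: np.ndarray,
    pixel_size: float,
    roi_polygon: np.ndarray | None = None,
    method: str = "otsu",
    threshold: float | None = None,
    closing_radius_um: float = 1.0,
) -> SlitNetwork:
    """End-to-end FSD: segment → skeletonize/measure → area → divide."""
    slit_mask = segment_slits(channel, method=method, threshold=threshold)
    skel, length = measure_curvilinear_length(slit_mask, pixel_size)
    cap = delineate_capillary(slit_mask=slit_mask, roi_polygon=roi_polygon,
                              shape=channel.shape,
                              closing_radius_um=closing_radius_um,
                              pixel_size=pixel_size)
    area = float(cap.sum()) * pixel_size ** 2
    return SlitNetwork(
        slit_mask=slit_mask, skeleton=skel, skeleton_length_um=length,
        capillary_mask=cap, capillary_area_um2=area,
        fsd=filtration_slit_density(length, area),
    )
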