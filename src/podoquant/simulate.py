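"""Synthetic fluorescence scenes with exact ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — elliptical focal contacts with bright centers, meandering
slit-diaphragm curves of known total length, cells with thin protrusions,
drifting/diffusing nuclei, proteome tables with planted regulation — and
returns the scene together with a :class:`GroundTruth` record rich enough
to score any pipeline output without re-deriving anything from pixels.

All generators are deterministic given their seed.  Planted physical
quantities are stored in µm-based units, never pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

from .io import ImageScene, ResultTable, write_image

__all__ = [
    "GroundTruth",
    "FaSceneSpec",
    "SlitSceneSpec",
    "synth_fa_scene",
    "synth_slit_scene",
    "synth_filopodia_scene",
    "synth_nuclei_timelapse",
    "synth_proteome_table",
    "save_scene",
]


@dataclass
class GroundTruth:
    """Per-scene record of planted objects and scene-level scalars.

    ``objects`` holds one row per planted object (contact, curve,
    filopodium, track, protein); ``masks`` holds pixel-level truth
    (label maps, capillary masks); ``tables`` holds auxiliary frames such
    as full track trajectories; ``scalars`` holds scene-level quantities
    (total slit length, capillary area, planted counts).
    """

    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict = field(default_factory=dict)


def _apply_noise(img: np.ndarray, rng: np.random.Generator,
                 poisson_gain: float, gaussian_sd: float) -> np.ndarray:
    """Poisson (signal-dependent) then additive Gaussian noise, clipped at 0."""
    out = img.astype(float)
    if poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_gain) / poisson_gain
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# focal-contact scenes
# ---------------------------------------------------------------------------

@dataclass
class FaSceneSpec:
    """Parameters of a synthetic focal-contact scene.

    Defaults reproduce control-condition morphometry: mean single-contact
    area 1.32 µm² with a broad lognormal spread, bright-center contacts
    (center/periphery amplitude ratio > 1) on a diffuse cell-shaped
    background, imaged at SNR = peak amplitude / Gaussian noise sd.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1            # µm / px
    n_fa: int = 200
    fa_area_mean: float = 1.32         # µm²
    fa_area_cv: float = 0.35
    axis_ratio_range: tuple[float, float] = (1.5, 3.0)
    center_periphery_ratio: float = 3.0
    profile_power: float = 6.0         # generalized-Gaussian exponent
    peak_amplitude: float = 150.0
    background: float = 30.0
    touching_fraction: float = 0.0
    snr: float = 10.0                  # peak amplitude / Gaussian sd; inf => none
    poisson_gain: float = 1.0          # 0 disables Poisson component
    seed: int = 0
    max_place_tries: int = 200

    def __post_init__(self) -> None:
        if self.n_fa < 0:
            raise ValueError("n_fa must be >= 0")
        if self.fa_area_mean <= 0:
            raise ValueError("fa_area_mean must be > 0")
        if self.center_periphery_ratio <= 1:
            raise ValueError("center/periphery amplitude ratio must exceed 1 "
                             "for bright-center contacts")
        if not (0 <= self.touching_fraction <= 1):
            raise ValueError("touching_fraction must be in [0, 1]")


def _cell_background(shape: tuple[int, int], rng: np.random.Generator,
                     level: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth irregular cell-shaped blob; returns (background image, blob mask)."""
    h, w = shape
    cy, cx = h / 2, w / 2
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)
    r0 = 0.42 * min(h, w)
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        wobble += rng.uniform(-0.08, 0.08) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    mask = r <= r0 * (1 + wobble)
    bg = ndi.gaussian_filter(mask.astype(float), 8.0) * level
    return bg, mask


def _ellipse_fields(shape, center, a, b, phi):
    """Normalized elliptical radius over a bounding box; returns (slices, r)."""
    h, w = shape
    ext = int(np.ceil(1.8 * max(a, b))) + 2
    r0 = max(int(center[0]) - ext, 0)
    r1 = min(int(center[0]) + ext + 1, h)
    c0 = max(int(center[1]) - ext, 0)
    c1 = min(int(center[1]) + ext + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    rnorm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return (slice(r0, r1), slice(c0, c1)), rnorm


def synth_fa_scene(spec: FaSceneSpec) -> tuple[ImageScene, GroundTruth]:
    """Render elliptical focal contacts with center-bright profiles.

    The intensity profile of each contact is a generalized Gaussian on the
    ellipse's normalized radius, scaled so that the rim (r = 1) sits at
    ``peak / center_periphery_ratio`` above background.  A stated fraction
    of contacts is planted as touching pairs.  Noise is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img, cell_mask = _cell_background(spec.shape, rng, spec.background)
    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)
    placeable = ndi.binary_erosion(cell_mask, iterations=5)

    # lognormal areas with the requested mean and CV
    sigma2 = np.log(1 + spec.fa_area_cv ** 2)
    mu = np.log(spec.fa_area_mean) - sigma2 / 2

    rows = []
    ln_ratio = np.log(spec.center_periphery_ratio)
    n_touch_pairs = int(round(spec.touching_fraction * spec.n_fa / 2))

    def _sample_geometry():
        area_um2 = float(rng.lognormal(mu, np.sqrt(sigma2)))
        area_px = area_um2 / spec.pixel_size ** 2
        q = rng.uniform(*spec.axis_ratio_range)
        a = np.sqrt(area_px * q / np.pi)
        return area_um2, a, a / q, rng.uniform(0, np.pi)

    def _place(center, a, b, phi, area_um2, partner_of=None):
        sl, rnorm = _ellipse_fields(spec.shape, center, a, b, phi)
        inside = rnorm <= 1.0
        if partner_of is None and np.any(occupied[sl] & inside):
            return False
        idx = len(rows) + 1
        profile = spec.peak_amplitude * np.exp(-ln_ratio * rnorm ** spec.profile_power)
        img[sl][rnorm <= 1.6] += profile[rnorm <= 1.6]
        labels[sl][inside] = idx
        occupied[sl] |= ndi.binary_dilation(inside, iterations=3)
        rows.append({
            "object_id": idx, "row": center[0], "col": center[1],
            "area_um2": area_um2,
            "semi_major_um": a * spec.pixel_size, "semi_minor_um": b * spec.pixel_size,
            "orientation_rad": phi, "touching_partner": partner_of or 0,
        })
        return True

    placed = 0
    while placed < spec.n_fa:
        as_pair = (placed < 2 * n_touch_pairs) and (spec.n_fa - placed >= 2)
        area_um2, a, b, phi = _sample_geometry()
        for _ in range(spec.max_place_tries):
            center = (rng.uniform(0, h), rng.uniform(0, w))
            ir, ic = int(center[0]), int(center[1])
            if not (0 <= ir < h and 0 <= ic < w and placeable[ir, ic]):
                continue
            if _place(center, a, b, phi, area_um2):
                break
        else:
            raise RuntimeError(
                f"could not place contact {placed + 1}/{spec.n_fa} after "
                f"{spec.max_place_tries} tries; scene too crowded")
        placed += 1
        if as_pair:
            area2, a2, b2, phi2 = _sample_geometry()
            ang = rng.uniform(0, 2 * np.pi)
            d = 0.9 * (min(a, b) + min(a2, b2))
            c2 = (center[0] + d * np.sin(ang), center[1] + d * np.cos(ang))
            _place(c2, a2, b2, phi2, area2, partner_of=len(rows))
            placed += 1

    gaussian_sd = 0.0 if not np.isfinite(spec.snr) else spec.peak_amplitude / spec.snr
    noisy = _apply_noise(img, rng, spec.poisson_gain, gaussian_sd)
    scene = ImageScene(channels={"fa": noisy}, pixel_size=spec.pixel_size)
    truth = GroundTruth(
        objects=pd.DataFrame(rows),
        masks={"labels": labels, "cell": cell_mask},
        scalars={"n_fa": spec.n_fa, "fa_area_mean_um2": spec.fa_area_mean},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# slit-diaphragm scenes
# ---------------------------------------------------------------------------

@dataclass
class SlitSceneSpec:
    """Parameters of a synthetic filtration-slit scene.

    Meandering smoothed-random-walk curves are laid inside a circular
    capillary mask until the true polyline length per mask area matches
    ``target_fsd`` (µm⁻¹).  A minimum inter-curve spacing of twice the
    line width keeps skeletonization from merging neighboring curves at
    the default blur.
    """

    capillary_radius_um: float = 5.6419  # area ≈ 100 µm²
    pixel_size: float = 0.025            # µm / px (super-resolution scale)
    target_fsd: float = 4.57             # µm⁻¹
    line_width_px: int = 1
    blur_sd_px: float = 0.8
    amplitude: float = 200.0
    background: float = 20.0
    snr: float = 10.0
    poisson_gain: float = 1.0
    step_px: float = 1.5
    turn_sd: float = 0.12                # rad per step
    margin_px: int = 0
    min_spacing_px: int = 3              # exclusion radius between curves
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fsd < 0:
            raise ValueError("target FSD must be >= 0")
        if self.capillary_radius_um <= 0:
            raise ValueError("capillary radius must be > 0")

    @property
    def spacing_px(self) -> int:
        # at least 2x the line width, like real foot processes keep
        # neighboring slits a process-width apart
        return max(self.min_spacing_px, 2 * self.line_width_px)


def synth_slit_scene(spec: SlitSceneSpec) -> tuple[ImageScene, GroundTruth]:
    """Lay meandering curves of known total length inside a capillary mask.

    The true curve length L and mask area A satisfy |L/A − target| ≤ 2 %
    by construction (the walk stops within one step of L = target·A).
    Raises if the requested density cannot be packed at the minimum
    inter-curve spacing.
    """
    rng = np.random.default_rng(spec.seed)
    r_px = spec.capillary_radius_um / spec.pixel_size
    pad = int(np.ceil(r_px)) + 12
    h = w = 2 * pad
    cy = cx = pad

    yy, xx = np.mgrid[0:h, 0:w]
    cap_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
    area_um2 = float(cap_mask.sum()) * spec.pixel_size ** 2
    target_len_um = spec.target_fsd * area_um2

    # parallel lines at the exclusion spacing bound the achievable density;
    # a meandering packing reaches only a fraction of that bound
    spacing_um = spec.spacing_px * spec.pixel_size
    if spec.target_fsd > 0 and spec.target_fsd * spacing_um > 0.5:
        raise ValueError(
            f"target FSD {spec.target_fsd} µm⁻¹ geometrically unreachable at "
            f"inter-curve spacing {spacing_um:.3f} µm")

    walk_mask = (ndi.binary_erosion(cap_mask, iterations=spec.margin_px)
                 if spec.margin_px > 0 else cap_mask)
    occupied = np.zeros((h, w), dtype=bool)
    canvas = np.zeros((h, w), dtype=float)
    spacing = spec.spacing_px
    # a point is exempt from the self-proximity test while within this many
    # recent steps of the walker
    exempt = int(np.ceil(2.5 * spacing / spec.step_px)) + 1

    def _free(p) -> bool:
        ir, ic = int(round(p[0])), int(round(p[1]))
        if not (0 <= ir < h and 0 <= ic < w) or not walk_mask[ir, ic]:
            return False
        s = spacing
        win = occupied[max(ir - s, 0):ir + s + 1, max(ic - s, 0):ic + s + 1]
        return not win.any()

    total_um = 0.0
    curves = []
    failed_starts = 0
    n_placed = 0
    step_um = spec.step_px * spec.pixel_size
    free_pool: np.ndarray | None = None

    def _free_pool() -> np.ndarray:
        """Free start points, ordered so far-from-curve points come last.

        Sampling from the far tail gives space-filling curve placement,
        the way foot processes tile the capillary surface evenly.
        """
        blocked = ndi.maximum_filter(occupied.astype(np.uint8),
                                     size=2 * spacing + 1).astype(bool)
        pool = np.argwhere(walk_mask & ~blocked)
        if occupied.any() and len(pool) > 1:
            d = ndi.distance_transform_edt(~occupied)[tuple(pool.T)]
            pool = pool[np.argsort(d)]
        return pool

    while spec.target_fsd > 0 and total_um < target_len_um:
        if failed_starts > 2000:
            if total_um >= 0.98 * target_len_um:
                break  # within the guaranteed 2 % band
            raise RuntimeError(
                f"cannot pack FSD {spec.target_fsd} µm⁻¹: stuck after "
                f"{failed_starts} failed attempts "
                f"({total_um:.1f}/{target_len_um:.1f} µm placed)")
        if free_pool is None or len(free_pool) == 0 or failed_starts % 25 == 24:
            free_pool = _free_pool()
            if len(free_pool) == 0:
                if total_um >= 0.98 * target_len_um:
                    break
                raise RuntimeError(
                    f"cannot pack FSD {spec.target_fsd} µm⁻¹: no free space "
                    f"left ({total_um:.1f}/{target_len_um:.1f} µm placed)")
        lo = int(0.9 * (len(free_pool) - 1))
        start = tuple(free_pool[rng.integers(lo, len(free_pool))].astype(float))
        if not _free(start):
            failed_starts += 1
            continue
        heading = rng.uniform(0, 2 * np.pi)
        pts = [start]
        committed: list[tuple[float, float]] = []
        recent: list[tuple[float, float]] = []
        cur_len = 0.0
        # the rendered curve is the polyline through the *rounded* vertices;
        # truth length must describe that rendered geometry, not the float walk
        last_rv = (round(start[0]), round(start[1]))
        while total_um + cur_len < target_len_um:
            heading += rng.normal(0, spec.turn_sd)
            # slide along obstacles: try small heading deflections before
            # terminating the curve (lets curves run parallel to neighbors,
            # like interdigitating foot processes)
            for dh in (0.0, 0.3, -0.3, 0.6, -0.6, 0.9, -0.9):
                cand = (pts[-1][0] + spec.step_px * np.sin(heading + dh),
                        pts[-1][1] + spec.step_px * np.cos(heading + dh))
                if _free(cand):
                    heading += dh
                    break
            else:
                break
            pts.append(cand)
            rv = (round(cand[0]), round(cand[1]))
            if rv != last_rv:
                cur_len += np.hypot(rv[0] - last_rv[0],
                                    rv[1] - last_rv[1]) * spec.pixel_size
                last_rv = rv
            recent.append(cand)
            if len(recent) > exempt:
                old = recent.pop(0)
                occupied[int(round(old[0])), int(round(old[1]))] = True
                committed.append(old)
        # short curves are rejected, except when only a short remainder of
        # the length budget is left (otherwise the packer can never finish)
        min_pts = 4 if (target_len_um - total_um) >= 4 * step_um else 2
        if len(pts) < min_pts:  # too short to be a credible slit segment; undo
            for p in committed:
                occupied[int(round(p[0])), int(round(p[1]))] = False
            failed_starts += 1
            continue
        for p in recent + [start]:
            occupied[int(round(p[0])), int(round(p[1]))] = True
        failed_starts = 0
        n_placed += 1
        if n_placed % 8 == 0:
            free_pool = None  # refresh pool (and its ordering) periodically
        total_um += cur_len
        ipts = np.round(np.asarray(pts)).astype(int)
        for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
            rr, cc = skdraw.line(r0, c0, r1, c1)
            canvas[rr, cc] = 1.0
        curves.append({"curve_id": len(curves) + 1, "n_points": len(pts),
                       "length_um": cur_len})

    if spec.line_width_px > 1:
        canvas = morphology.dilation(
            canvas, morphology.disk(spec.line_width_px // 2))
    curve_mask = canvas > 0
    blurred = ndi.gaussian_filter(canvas, spec.blur_sd_px)
    if blurred.max() > 0:
        blurred = blurred / blurred.max()  # SNR refers to the rendered peak
    img = spec.background + spec.amplitude * blurred
    gaussian_sd = 0.0 if not np.isfinite(spec.snr) else spec.amplitude / spec.snr
    noisy = _apply_noise(img, rng, spec.poisson_gain, gaussian_sd)

    scene = ImageScene(channels={"slit": noisy}, pixel_size=spec.pixel_size)
    truth = GroundTruth(
        objects=pd.DataFrame(curves),
        masks={"curves": curve_mask, "capillary": cap_mask},
        scalars={"total_length_um": total_um, "capillary_area_um2": area_um2,
                 "fsd_true": total_um / area_um2 if area_um2 else 0.0,
                 "target_fsd": spec.target_fsd},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# filopodia scenes
# ---------------------------------------------------------------------------

def synth_filopodia_scene(
    n_filopodia: int,
    length_mean_um: float = 6.0,
    seed: int = 0,
    lengths_um: list[float] | None = None,
    length_cv: float = 0.25,
    cell_radius_um: float = 12.0,
    width_px: int = 3,
    pixel_size: float = 0.2,
    shape: tuple[int, int] = (300, 300),
    amplitude: float = 120.0,
    background: float = 10.0,
    snr: float = float("inf"),
) -> tuple[ImageScene, GroundTruth]:
    """Convex cell body plus thin protrusions of known geodesic length.

    Protrusions are straight rays of the requested lengths leaving the
    cell rim at angularly separated positions, ``width_px`` (≤ 3 px) wide,
    so the planted geodesic length equals the ray length exactly.
    """
    rng = np.random.default_rng(seed)
    if lengths_um is None:
        if n_filopodia > 0 and length_mean_um <= 0:
            raise ValueError("length_mean_um must be > 0")
        sigma2 = np.log(1 + length_cv ** 2)
        lengths_um = list(rng.lognormal(
            np.log(length_mean_um) - sigma2 / 2, np.sqrt(sigma2), n_filopodia))
    if len(lengths_um) != n_filopodia:
        raise ValueError("lengths_um must have n_filopodia entries")
    if any(l <= 0 for l in lengths_um):
        raise ValueError("filopodium lengths must be > 0")

    h, w = shape
    cy, cx = h / 2, w / 2
    r_px = cell_radius_um / pixel_size
    max_len = max(lengths_um, default=0.0) / pixel_size
    if r_px + max_len + width_px >= min(h, w) / 2:
        raise ValueError("protrusion extends beyond the image; enlarge shape")

    yy, xx = np.mgrid[0:h, 0:w]
    body = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
    mask = body.copy()

    # angularly separated emission points keep protrusions from merging
    angles = (np.arange(n_filopodia) / max(n_filopodia, 1)) * 2 * np.pi
    angles = angles + rng.uniform(0, 2 * np.pi) + rng.normal(
        0, 0.25 / max(n_filopodia, 1), size=n_filopodia)
    rows = []
    for i, (ang, L_um) in enumerate(zip(angles, lengths_um), start=1):
        L = L_um / pixel_size
        base = (cy + (r_px - 1) * np.sin(ang), cx + (r_px - 1) * np.cos(ang))
        tip = (base[0] + L * np.sin(ang), base[1] + L * np.cos(ang))
        rr, cc = skdraw.line(int(round(base[0])), int(round(base[1])),
                             int(round(tip[0])), int(round(tip[1])))
        stick = np.zeros(shape, dtype=bool)
        stick[rr, cc] = True
        if width_px > 1:
            stick = morphology.dilation(stick, morphology.disk(width_px // 2))
        mask |= stick
        rows.append({"object_id": i, "base_row": base[0], "base_col": base[1],
                     "tip_row": tip[0], "tip_col": tip[1],
                     "length_um": float(L_um)})

    img = background + amplitude * mask.astype(float)
    gaussian_sd = 0.0 if not np.isfinite(snr) else amplitude / snr
    noisy = _apply_noise(img, rng, poisson_gain=1.0 if np.isfinite(snr) else 0.0,
                         gaussian_sd=gaussian_sd)
    scene = ImageScene(channels={"actin": noisy}, pixel_size=pixel_size)
    obj = pd.DataFrame(rows)
    truth = GroundTruth(
        objects=obj,
        masks={"cell_labels": mask.astype(np.int32), "body": body},
        scalars={"n_filopodia": n_filopodia,
                 "mean_length_um": float(obj["length_um"].mean()) if len(obj) else 0.0},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# nuclei time-lapse
# ---------------------------------------------------------------------------

def synth_nuclei_timelapse(
    n_cells: int,
    drift_um: tuple[float, float] = (0.0, 0.0),
    step_sd_um: float = 0.0,
    n_frames: int = 10,
    frame_interval: float = 20.0,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (256, 256),
    spot_sigma_px: float = 3.0,
    amplitude: float = 100.0,
    background: float = 10.0,
    snr: float = float("inf"),
    min_separation_px: float = 18.0,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """Gaussian-spot nuclei moving by drift plus isotropic Gaussian steps.

    Per-frame displacement (µm) is ``drift_um + N(0, step_sd_um²·I)``.
    Trajectories are clipped to the field of view; true speeds are
    computed from the realized (post-clip) positions, so the ground truth
    always describes exactly what was rendered.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 4 * spot_sigma_px
    drift_px = np.asarray(drift_um, dtype=float) / pixel_size

    # leave headroom for the whole deterministic drift so pure-drift tracks
    # are never clipped at the field border
    total_drift = drift_px * (n_frames - 1)
    lo = margin + np.maximum(-total_drift, 0)
    hi = np.array([h, w], dtype=float) - margin - np.maximum(total_drift, 0)
    if np.any(hi <= lo):
        raise ValueError("field too small for the requested drift")

    starts: list[np.ndarray] = []
    tries = 0
    while len(starts) < n_cells:
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - s)) >= min_separation_px for s in starts):
            starts.append(cand)
        tries += 1
        if tries > 10000:
            raise RuntimeError("cannot place nuclei at requested separation")
    sd_px = step_sd_um / pixel_size
    pos = np.zeros((n_frames, n_cells, 2))
    if n_cells:
        pos[0] = np.asarray(starts)
        for t in range(1, n_frames):
            step = drift_px + rng.normal(0, sd_px, size=(n_cells, 2))
            pos[t] = np.clip(pos[t - 1] + step, margin,
                             [h - margin, w - margin])

    frames = np.zeros((n_frames,) + shape, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(n_frames):
        frame = np.full(shape, background, dtype=float)
        for k in range(n_cells):
            r0, c0 = pos[t, k]
            d2 = (yy - r0) ** 2 + (xx - c0) ** 2
            frame += amplitude * np.exp(-d2 / (2 * spot_sigma_px ** 2))
        gaussian_sd = 0.0 if not np.isfinite(snr) else amplitude / snr
        frames[t] = _apply_noise(frame, rng, poisson_gain=1.0 if np.isfinite(snr) else 0.0,
                                 gaussian_sd=gaussian_sd)

    traj_rows, summary_rows = [], []
    duration = (n_frames - 1) * frame_interval
    for k in range(n_cells):
        steps = np.diff(pos[:, k, :], axis=0) * pixel_size
        path_um = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
        summary_rows.append({"track_id": k + 1, "path_length_um": path_um,
                             "duration_min": duration,
                             "mean_speed_um_min": path_um / duration})
        for t in range(n_frames):
            traj_rows.append({"track_id": k + 1, "frame": t,
                              "row": pos[t, k, 0], "col": pos[t, k, 1],
                              "row_um": pos[t, k, 0] * pixel_size,
                              "col_um": pos[t, k, 1] * pixel_size})

    scene = ImageScene(channels={"nuclei": frames}, pixel_size=pixel_size,
                       frame_interval=frame_interval)
    truth = GroundTruth(
        objects=pd.DataFrame(summary_rows),
        tables={"trajectories": pd.DataFrame(traj_rows)},
        scalars={"n_cells": n_cells, "n_frames": n_frames,
                 "frame_interval_min": frame_interval},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# proteome tables
# ---------------------------------------------------------------------------

def synth_proteome_table(
    n_proteins: int = 1000,
    n_up: int = 71,
    n_down: int = 105,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[ResultTable, GroundTruth]:
    """Differential-abundance table with exactly planted regulation.

    Exactly ``n_up`` rows satisfy fold change ≥ ``fc_threshold`` together
    with p ≤ ``p_threshold``; exactly ``n_down`` satisfy fold change
    ≤ 1/``fc_threshold`` with p ≤ ``p_threshold``; every remaining row
    strictly fails at least one criterion.
    """
    if n_up + n_down > n_proteins:
        raise ValueError("n_up + n_down exceeds n_proteins")
    rng = np.random.default_rng(seed)
    lt = np.log2(fc_threshold)

    log2fc = np.empty(n_proteins)
    pvals = np.empty(n_proteins)
    direction = np.array(["ns"] * n_proteins, dtype=object)

    up = slice(0, n_up)
    down = slice(n_up, n_up + n_down)
    ns = slice(n_up + n_down, n_proteins)
    n_ns = n_proteins - n_up - n_down

    log2fc[up] = lt + np.abs(rng.normal(0.3, 0.5, n_up))
    pvals[up] = rng.uniform(1e-8, p_threshold, n_up)
    direction[up] = "up"
    log2fc[down] = -lt - np.abs(rng.normal(0.3, 0.5, n_down))
    pvals[down] = rng.uniform(1e-8, p_threshold, n_down)
    direction[down] = "down"

    # non-significant rows strictly fail at least one criterion
    small_fc = rng.random(n_ns) < 0.6
    log2fc[ns] = np.where(small_fc,
                          rng.uniform(-0.95 * lt, 0.95 * lt, n_ns),
                          rng.normal(0, 1.2, n_ns))
    pvals[ns] = np.where(small_fc,
                         rng.uniform(0, 1, n_ns),
                         rng.uniform(p_threshold * 1.02, 1, n_ns))

    order = rng.permutation(n_proteins)
    table = pd.DataFrame({
        "protein_id": [f"P{i:05d}" for i in range(n_proteins)],
        "fold_change": 2.0 ** log2fc[order],
        "p_value": pvals[order],
    })
    planted = pd.DataFrame({"protein_id": table["protein_id"],
                            "planted_direction": direction[order]})
    rt = ResultTable(data=table, provenance={
        "generator": "synth_proteome_table", "seed": seed,
        "n_proteins": n_proteins, "n_up": n_up, "n_down": n_down,
        "fc_threshold": fc_threshold, "p_threshold": p_threshold})
    truth = GroundTruth(objects=planted,
                        scalars={"n_up": n_up, "n_down": n_down})
    return rt, truth


# ---------------------------------------------------------------------------
# paired-directory emission
# ---------------------------------------------------------------------------

def save_scene(outdir: str | Path, name: str, scene: ImageScene,
               truth: GroundTruth) -> Path:
    """Write a scene and its ground truth as a paired TIFF/CSV/JSON layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(scene, outdir / f"{name}.tif")
    if len(truth.objects):
        truth.objects.to_csv(outdir / f"{name}_truth_objects.csv", index=False)
    for key, tab in truth.tables.items():
        tab.to_csv(outdir / f"{name}_truth_{key}.csv", index=False)
    if truth.scalars:
        with open(outdir / f"{name}_truth.json", "w") as fh:
            json.dump(truth.scalars, fh, indent=2, default=float)
    for key, m in truth.masks.items():
        np.savetxt(outdir / f"{name}_mask_{key}.txt", m.astype(np.int32), fmt="%d")
    return outdir
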