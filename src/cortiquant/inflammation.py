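"""Microglial (IBA1) activation metrics in perilesional ROIs.

Two complementary readouts, both computed in rectangular ROIs placed
500 μm from the lesion border:

1. **Threshold-sweep coverage** — the 16-bit ROI is linearly rescaled to
   8 bits with a display range shared across the compared image set, then
   the percentage of pixels at or above each threshold of the fixed ladder
   20..240 (step 10, 23 levels) is recorded.  Thresholds above 100 are
   flagged as excluded from statistics, since high cutoffs lose most of
   the genuine signal.  Coverage is non-increasing in the threshold by
   construction (superlevel sets shrink).

2. **Soma morphometry** — the ROI is binarized at a per-image threshold
   (Otsu by default, standing in for the manual choice of the original
   workflow), connected components of at least 30 px are retained,
   border-touching ones dropped, and each soma's perimeter and integrated
   density (sum of raw 16-bit intensities over its footprint) measured.
   Integrated densities are normalized to the control-group mean.

Lateral and central ROIs are kept separate and only pooled when a Welch
two-sample test finds no difference between them (p ≥ 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure

from .exceptions import RoiError
from .types import LayerROI, Particle, ParticleSet, SliceImage, ThresholdSweep

__all__ = [
    "SWEEP_THRESHOLDS",
    "to_8bit",
    "coverage_sweep",
    "soma_morphometry",
    "select_perilesional_rois",
    "pool_if_equivalent",
]

SWEEP_THRESHOLDS = np.arange(20, 241, 10)  # 23 levels
ANALYSIS_CEILING = 100


def to_8bit(img: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Linear 16→8-bit conversion with a common display range.

    Maps [vmin, vmax] to [0, 255] with round-half-up, clipping outside
    values; a shared (vmin, vmax) across a compared set keeps the sweep
    thresholds commensurable between images.
    """
    if vmax <= vmin:
        raise ValueError("vmax must exceed vmin")
    scaled = (np.asarray(img, float) - vmin) / (vmax - vmin) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def coverage_sweep(
    roi_img_8bit: np.ndarray,
    thresholds: np.ndarray = SWEEP_THRESHOLDS,
    analysis_ceiling: int = ANALYSIS_CEILING,
    roi_label: str = "",
) -> ThresholdSweep:
    """Percent of ROI pixels at or above each threshold of the ladder."""
    img = np.asarray(roi_img_8bit)
    n = img.size
    coverage = np.array([100.0 * np.count_nonzero(img >= t) / n
                         for t in thresholds])
    return ThresholdSweep(thresholds=thresholds, coverage_pct=coverage,
                          analysis_ceiling=analysis_ceiling,
                          roi_label=roi_label)


def soma_morphometry(
    roi_img: np.ndarray,
    threshold: float | None = None,
    min_size_px: int = 30,
    control_mean_density: float | None = None,
    pixel_size_um: float = 1.0,
    exclude_border: bool = True,
    roi_label: str = "",
) -> tuple[ParticleSet, dict[str, float]]:
    """Per-soma perimeter and integrated density in one ROI.

    ``threshold`` defaults to Otsu on the raw ROI.  ``integrated_density``
    sums raw intensities over the particle footprint; when
    ``control_mean_density`` is given the summary reports the mean density
    normalized to that control-group average.
    """
    img = np.asarray(roi_img, dtype=float)
    if threshold is None:
        if img.max() == img.min():
            warnings.warn("constant ROI; no particles")
            return ParticleSet([], min_size_px, roi_label), {
                "mean_perimeter_um": np.nan, "mean_integrated_density": np.nan,
                "mean_normalized_density": np.nan, "n_particles": 0}
        threshold = float(filters.threshold_otsu(img))
    binary = img >= threshold
    labels = measure.label(binary, connectivity=2)
    particles: list[Particle] = []
    h, w = img.shape
    for rp in measure.regionprops(labels, intensity_image=img):
        if rp.area < min_size_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        particles.append(Particle(
            label=rp.label, area_px=int(rp.area),
            perimeter_px=float(rp.perimeter),
            perimeter_um=float(rp.perimeter) * pixel_size_um,
            integrated_density=float(rp.image_intensity[rp.image].sum()),
            mean_intensity=float(rp.intensity_mean),
            centroid=tuple(rp.centroid),
            touches_border=touches,
            excluded=touches and exclude_border))
    pset = ParticleSet(particles=particles, min_size_px=min_size_px,
                       source_roi=roi_label)
    retained = pset.retained
    if not retained:
        warnings.warn("no particles retained after size/border filtering")
        summary = {"mean_perimeter_um": np.nan,
                   "mean_integrated_density": np.nan,
                   "mean_normalized_density": np.nan, "n_particles": 0}
        return pset, summary
    dens = np.array([p.integrated_density for p in retained])
    summary = {
        "mean_perimeter_um": float(np.mean([p.perimeter_um
                                            for p in retained])),
        "mean_integrated_density": float(dens.mean()),
        "mean_normalized_density": (float(dens.mean() / control_mean_density)
                                    if control_mean_density else np.nan),
        "n_particles": len(retained),
    }
    return pset, summary


def select_perilesional_rois(
    slice_image: SliceImage,
    lesion_mask: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    distance_um: float = 500.0,
    roi_size_um: tuple[float, float] = (100.0, 450.0),
    directions: dict[str, tuple[float, float]] = None,
) -> list[LayerROI]:
    """Two rectangular ROIs (lateral, central) whose near edges lie
    ``distance_um`` from the lesion boundary.

    ``roi_size_um`` is (depth along the outward axis, width along the
    border tangent).  ``directions`` maps ROI label to an outward unit
    direction (drow, dcol) from the lesion center; defaults place the
    lateral ROI toward the ipsilesional edge (+cols) and the central ROI
    below the lesion (+rows).  ROIs that would leave the tissue mask are
    shifted inward with a warning.
    """
    if not np.any(lesion_mask):
        raise RoiError("no lesion present; cannot place perilesional ROIs")
    if directions is None:
        directions = {"lateral": (0.0, 1.0), "central": (1.0, 0.0)}
    px = slice_image.pixel_size_um
    com = ndimage.center_of_mass(lesion_mask)
    depth_px = int(round(roi_size_um[0] / px))
    width_px = int(round(roi_size_um[1] / px))
    shape = slice_image.shape
    rois = []
    for label, (dr, dc) in directions.items():
        n = np.hypot(dr, dc)
        dr, dc = dr / n, dc / n
        # march from the lesion centroid to the boundary along direction
        r, c = com
        while (0 <= r < shape[0] and 0 <= c < shape[1]
               and lesion_mask[int(round(r)), int(round(c))]):
            r += dr
            c += dc
        start = (r + dr * distance_um / px, c + dc * distance_um / px)
        # the ROI long axis runs along the outward direction
        end = (start[0] + dr * depth_px, start[1] + dc * depth_px)
        shift_steps = 0
        while not _inside(end, shape) and shift_steps < 10_000:
            start = (start[0] - dr, start[1] - dc)
            end = (start[0] + dr * depth_px, start[1] + dc * depth_px)
            shift_steps += 1
        if shift_steps:
            warnings.warn(f"ROI {label!r} shifted {shift_steps} px inward "
                          "to stay inside the image")
        if tissue_mask is not None:
            rr = int(np.clip(round(start[0]), 0, shape[0] - 1))
            cc = int(np.clip(round(start[1]), 0, shape[1] - 1))
            if not tissue_mask[rr, cc]:
                warnings.warn(f"ROI {label!r} near edge falls outside the "
                              "tissue mask")
        rois.append(LayerROI(origin_px=start, distance_axis=(dr, dc),
                             depth_px=depth_px, width_px=width_px,
                             layer_label="perilesional", roi_label=label))
    return rois


def _inside(point: tuple[float, float], shape: tuple[int, int]) -> bool:
    return 0 <= point[0] < shape[0] and 0 <= point[1] < shape[1]


def extract_roi_image(image: np.ndarray, roi: LayerROI) -> np.ndarray:
    """Resample the (possibly rotated) rectangular ROI into a
    depth × width array, nearest-neighbour."""
    dr, dc = roi.distance_axis
    pr, pc = -dc, dr
    t = np.arange(roi.depth_px) + 0.5
    s = np.arange(roi.width_px) + 0.5 - roi.width_px / 2.0
    tt, ss = np.meshgrid(t, s, indexing="ij")
    rows = np.clip(np.floor(roi.origin_px[0] + tt * dr + ss * pr).astype(int),
                   0, image.shape[0] - 1)
    cols = np.clip(np.floor(roi.origin_px[1] + tt * dc + ss * pc).astype(int),
                   0, image.shape[1] - 1)
    return np.asarray(image)[rows, cols]


def pool_if_equivalent(
    lateral: np.ndarray, central: np.ndarray, alpha: float = 0.05,
) -> tuple[bool, float, np.ndarray | None]:
    """Pool lateral and central ROI measurements only when a Welch test
    finds no difference (p ≥ alpha).  Returns (pooled?, p, pooled array or
    None)."""
    lateral = np.asarray(lateral, float)
    central = np.asarray(central, float)
    if len(lateral) < 2 or len(central) < 2:
        return False, np.nan, None
    _, p = stats.ttest_ind(lateral, central, equal_var=False)
    if np.isnan(p):  # zero variance in both samples
        p = 1.0 if np.isclose(lateral.mean(), central.mean()) else 0.0
    pooled = np.concatenate([lateral, central]) if p >= alpha else None
    return p >= alpha, float(p), pooled
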