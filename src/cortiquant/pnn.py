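"""Perineuronal-net (WFA⁺) quantification with an intrinsic contralesional
control.

WFA-labeled nets appear as ring-shaped particles.  Counting uses a single
threshold shared between the ipsilesional ROI and its homotopic
contralesional mirror — calibrated on the contralesional staining, which
acts as each animal's internal control — followed by connected-component
labeling with a 200 px minimum size.  The thresholded mask is *not*
hole-filled, so an annular footprint counts once and the size filter
applies to the annulus area.  Per-cell intensity is measured on the raw
(pre-threshold) image over each particle footprint.

The headline statistic is the fold change of the WFA⁺ count in the
ipsilesional ROI relative to the contralesional ROI of the same slice,
optionally normalized so the control group sits at 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

from .types import LayerROI, PnnResult

__all__ = ["count_wfa_cells", "fold_change", "mirror_roi"]


def count_wfa_cells(
    roi_img: np.ndarray,
    threshold: float,
    min_size_px: int = 200,
    roi_label: str = "",
) -> PnnResult:
    """Count WFA⁺ particles at the shared threshold and measure each one's
    mean intensity on the raw image."""
    img = np.asarray(roi_img, dtype=float)
    binary = img >= threshold
    labels = measure.label(binary, connectivity=2)
    intensities = []
    count = 0
    for rp in measure.regionprops(labels, intensity_image=img):
        if rp.area < min_size_px:
            continue
        count += 1
        intensities.append(float(rp.intensity_mean))
    return PnnResult(roi_label=roi_label, wfa_count=count,
                     per_cell_intensity=np.asarray(intensities))


def fold_change(
    ipsi: PnnResult,
    contra: PnnResult,
    control_reference: float | None = None,
) -> float:
    """ipsi count / contra count, optionally divided by the control-group
    reference so the control cohort maps to ≈ 1.  Undefined (NaN, with a
    warning) when the contralesional count is zero."""
    if contra.wfa_count == 0:
        warnings.warn("contralesional WFA count is zero; fold change "
                      "undefined, slice excluded")
        return float("nan")
    fc = ipsi.wfa_count / contra.wfa_count
    if control_reference is not None:
        if control_reference <= 0:
            raise ValueError("control_reference must be positive")
        fc /= control_reference
    return fc


def mirror_roi(roi: LayerROI, midline_col: float) -> LayerROI:
    """Homotopic contralesional ROI: reflect an ipsilesional ROI across the
    estimated midline (vertical axis at ``midline_col``)."""
    r0, c0 = roi.origin_px
    dr, dc = roi.distance_axis
    return LayerROI(origin_px=(r0, 2 * midline_col - c0),
                    distance_axis=(dr, -dc),
                    depth_px=roi.depth_px, width_px=roi.width_px,
                    layer_label=roi.layer_label,
                    roi_label=(roi.roi_label + "_contra"
                               if roi.roi_label else "contra"))
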