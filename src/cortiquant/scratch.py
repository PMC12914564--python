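"""In vitro axonal-outgrowth quantification for the scratch assay.

Axons regrowing across a cell-free scratch are counted where they cross
lines parallel to the scratch border at fixed distances — proximal
(160 μm), medial (240 μm), and distal (320 μm).  The axon channel is
thresholded and skeletonized so the count is invariant to axon thickness;
each connected run of skeleton pixels on a distance line counts as one
crossing (a branch crossing the line twice therefore counts twice).

Raw counts are put through a three-step normalization: (1) crossings per
mm of line length; (2) per neuron counted in the field; (3) relative to
the control group's proximal value, taken as the outgrowth baseline (so
control-proximal ≡ 1).
"""

from __future__ import annotations

import numpy as np
from skimage import filters, morphology

from .exceptions import NormalizationError, RoiError
from .types import CrossingResult

__all__ = [
    "DEFAULT_DISTANCES_UM",
    "count_crossings",
    "count_neurons",
    "normalize_crossings",
]

DEFAULT_DISTANCES_UM = (160.0, 240.0, 320.0)


def _count_runs(line: np.ndarray) -> int:
    """Number of connected True runs in a 1-D boolean array."""
    line = np.asarray(line, dtype=bool).astype(np.int8)
    if line.size == 0:
        return 0
    starts = np.sum((np.diff(line) == 1)) + int(line[0])
    return int(starts)


def count_crossings(
    axon_img: np.ndarray,
    border_row_px: int,
    pixel_size_um: float,
    distances_um: tuple[float, ...] = DEFAULT_DISTANCES_UM,
    threshold: float | None = None,
) -> np.ndarray:
    """Crossing counts at each distance line below the scratch border.

    ``axon_img`` may be boolean (already segmented) or an intensity image,
    in which case it is thresholded (Otsu unless ``threshold`` given)
    before skeletonization.
    """
    img = np.asarray(axon_img)
    if 0 > border_row_px or border_row_px >= img.shape[0]:
        raise RoiError(f"border row {border_row_px} outside image")
    if img.dtype == bool:
        binary = img
    else:
        if threshold is None:
            threshold = (float(filters.threshold_otsu(img))
                         if img.max() > img.min() else np.inf)
        binary = img > threshold
    skeleton = morphology.skeletonize(binary)
    counts = []
    for d in distances_um:
        row = border_row_px + int(round(d / pixel_size_um))
        if row >= img.shape[0]:
            raise RoiError(f"distance line {d} μm falls outside the image")
        counts.append(_count_runs(skeleton[row]))
    return np.asarray(counts, dtype=int)


def count_neurons(
    soma_img: np.ndarray,
    band_rows: tuple[int, int] | None = None,
    min_size_px: int = 20,
    threshold: float | None = None,
) -> int:
    """Soma count in the cell band (simple blob detection on the soma
    channel): threshold, label, size filter."""
    from skimage import measure

    img = np.asarray(soma_img, dtype=float)
    if band_rows is not None:
        img = img[band_rows[0]: band_rows[1]]
    if threshold is None:
        if img.max() == img.min():
            return 0
        threshold = float(filters.threshold_otsu(img))
    labels = measure.label(img > threshold, connectivity=2)
    return sum(1 for rp in measure.regionprops(labels)
               if rp.area >= min_size_px)


def normalize_crossings(
    results: dict[str, CrossingResult],
    control_label: str = "Ctrl",
) -> dict[str, CrossingResult]:
    """Apply the three normalization stages in place and return the dict.

    axons_per_mm = raw / line length; per_neuron = axons_per_mm /
    n_neurons; normalized = per_neuron / control's per_neuron at the first
    (proximal) distance.
    """
    if control_label not in results:
        raise NormalizationError(f"control group {control_label!r} missing")
    for r in results.values():
        if r.line_length_mm <= 0:
            raise NormalizationError("line length must be positive")
        if r.n_neurons <= 0:
            raise NormalizationError(
                f"group {r.group!r} has no counted neurons")
        r.axons_per_mm = r.raw_counts / r.line_length_mm
        r.per_neuron = r.axons_per_mm / r.n_neurons
    baseline = results[control_label].per_neuron[0]
    if baseline <= 0:
        raise NormalizationError(
            "control-proximal baseline is zero; cannot normalize")
    for r in results.values():
        r.normalized = r.per_neuron / baseline
    return results
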