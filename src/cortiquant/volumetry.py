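"""Region volumetry from serial-section area profiles.

The volume of a region (lesion cavity, IBA1⁺ inflamed territory) is
estimated from its cross-sectional areas A(x) measured on AP-sorted
sections: a least-squares polynomial is fitted to the (x, A) samples and
integrated in closed form,

    V = ∫_a^b max(fit(x), 0) dx ,

with [a, b] the AP span of the data, extended outward to the fit's nearest
non-negative roots (clamped to a configurable margin) so a cavity that
tapers to zero just beyond the sampled sections is not truncated.  An
ellipsoidal cavity has an exactly quadratic area profile, hence the default
degree of 2; the fit R² is reported so misfit is visible.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .exceptions import ProfileError, RoiError
from .types import AreaProfile, SliceImage, SliceMask, VolumeResult

__all__ = [
    "lesion_area_per_slice",
    "fit_and_integrate",
    "iba1_area_per_slice",
    "calibrate_threshold",
]


def lesion_area_per_slice(
    slice_image: SliceImage,
    mask: SliceMask,
    min_hole_area_mm2: float = 0.01,
) -> float:
    """Area (mm²) of the lesion cavity: interior background components of
    the tissue mask, fully enclosed by the contour and at least
    ``min_hole_area_mm2`` large.  Returns 0 when no cavity is present."""
    if not mask.holes_excluded:
        raise ValueError("mask must have interior holes excluded")
    filled = ndimage.binary_fill_holes(mask.mask)
    cavity = filled & ~mask.mask
    labels, n = ndimage.label(cavity)
    if n == 0:
        return 0.0
    px_area = slice_image.pixel_area_mm2()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = sizes * px_area >= min_hole_area_mm2
    return float(sizes[keep].sum()) * px_area


def _r_squared(x: np.ndarray, y: np.ndarray, coeffs: np.ndarray) -> float:
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:  # constant profile: perfect iff residuals vanish
        return 1.0 if ss_res <= 1e-12 * max(1.0, float(np.sum(y ** 2))) \
            else -np.inf
    return 1.0 - ss_res / ss_tot


def _positive_part_integral(coeffs: np.ndarray, a: float, b: float) -> float:
    """∫_a^b max(p(x), 0) dx in closed form: split [a, b] at the real roots
    of p and integrate the antiderivative on subintervals where p ≥ 0."""
    roots = np.roots(coeffs) if len(coeffs) > 1 else np.array([])
    cuts = sorted({a, b} | {float(r.real) for r in roots
                            if abs(r.imag) < 1e-12 and a < r.real < b})
    antider = np.polyint(coeffs)
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (lo + hi)
        if np.polyval(coeffs, mid) >= 0:
            total += float(np.polyval(antider, hi) - np.polyval(antider, lo))
    return total


def fit_and_integrate(
    profile: AreaProfile,
    degree: int = 2,
    extend_margin_mm: float = 0.5,
    fit_support_only: bool = True,
) -> VolumeResult:
    """Fit A(x) with a degree-``degree`` polynomial and integrate it.

    With ``fit_support_only`` (default) the polynomial is fitted to the
    samples where a cavity was actually observed (area > 0): sections
    beyond the region's extent carry no information about its area
    function, only about where it ends — they are censored observations,
    not A(x) = 0 data points.  The fallback to all samples applies when
    fewer than ``degree + 1`` positive samples exist.

    The integration interval starts at the fitted-data span and is
    extended on each side to the fit's nearest root (where the fitted
    area crosses zero), never further than ``extend_margin_mm``; negative
    fitted areas inside the interval contribute nothing (areas cannot be
    negative).
    """
    x = np.asarray(profile.positions_mm, dtype=float)
    y = np.asarray(profile.areas_mm2, dtype=float)
    if len(x) < degree + 1:
        raise ProfileError(
            f"need >= {degree + 1} samples for a degree-{degree} fit, "
            f"got {len(x)}")
    if np.all(y == 0):
        warnings.warn("all-zero area profile; volume = 0")
        return VolumeResult(coefficients=np.zeros(degree + 1), degree=degree,
                            interval_mm=(float(x.min()), float(x.max())),
                            volume_mm3=0.0, fit_r2=1.0,
                            region_label=profile.region_label,
                            animal_id=profile.animal_id)
    if fit_support_only and np.count_nonzero(y > 0) >= degree + 1:
        support = y > 0
        x, y = x[support], y[support]
    coeffs = np.polyfit(x, y, degree)
    lo, hi = float(x.min()), float(x.max())
    a, b = lo, hi
    roots = np.roots(coeffs) if degree >= 1 else np.array([])
    real_roots = np.array([float(r.real) for r in roots
                           if abs(r.imag) < 1e-9])
    # extend only when the fitted area actually reaches zero close to the
    # sampled span; a fit that stays positive keeps the data interval
    below = real_roots[real_roots < lo]
    above = real_roots[real_roots > hi]
    if len(below) and below.max() >= lo - extend_margin_mm:
        a = float(below.max())
    if len(above) and above.min() <= hi + extend_margin_mm:
        b = float(above.min())
    volume = _positive_part_integral(coeffs, a, b)
    return VolumeResult(coefficients=coeffs, degree=degree,
                        interval_mm=(a, b), volume_mm3=max(volume, 0.0),
                        fit_r2=_r_squared(x, y, coeffs),
                        region_label=profile.region_label,
                        animal_id=profile.animal_id)


def iba1_area_per_slice(
    slice_image: SliceImage,
    threshold: float,
    blur_sigma: float = 5.0,
    min_size_px: int = 1000,
    iba1_channel: str = "iba1",
) -> float:
    """IBA1⁺ area (mm²): Gaussian blur (σ = 5 by default), threshold,
    keep connected components of at least ``min_size_px`` pixels."""
    img = slice_image.channel(iba1_channel).astype(float)
    blurred = ndimage.gaussian_filter(img, sigma=blur_sigma)
    binary = blurred >= threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = sizes >= min_size_px
    return float(sizes[keep].sum()) * slice_image.pixel_area_mm2()


def calibrate_threshold(
    slice_image: SliceImage,
    contralesional_roi: tuple[int, int, int, int],
    k: float = 3.0,
    blur_sigma: float = 5.0,
    channel: str = "iba1",
) -> float:
    """Threshold from the uninjured hemisphere: mean + k·sd of blurred
    intensities in ``contralesional_roi`` (r0, c0, height, width)."""
    r0, c0, h, w = contralesional_roi
    shape = slice_image.shape
    if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1] \
            or h <= 0 or w <= 0:
        raise RoiError(f"ROI {contralesional_roi} outside image {shape}")
    img = slice_image.channel(channel).astype(float)
    blurred = ndimage.gaussian_filter(img, sigma=blur_sigma)
    patch = blurred[r0:r0 + h, c0:c0 + w]
    return float(patch.mean() + k * patch.std())
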