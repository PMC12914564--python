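"""Core value types shared across the pipeline stages.

Conventions
-----------
* Images are 2-D ``numpy`` arrays on a 16-bit intensity scale (stored as
  ``uint16`` on disk, floats accepted in memory), row-major, origin at the
  top-left, 0-based indices.
* Physical coordinates: pixel size in μm/pixel; anteroposterior (AP)
  position of a coronal section in mm relative to bregma, anterior
  positive.
* Areas are reported in mm², volumes in mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import MissingChannelError, ProfileError

__all__ = [
    "SliceImage",
    "SliceMask",
    "RigidTransform",
    "AlignedSlice",
    "AlignedStack",
    "AreaProfile",
    "VolumeResult",
    "LayerROI",
    "PreservationProfile",
    "ThresholdSweep",
    "Particle",
    "ParticleSet",
    "PnnResult",
    "CrossingResult",
    "LdaResult",
]


@dataclass
class SliceImage:
    """One multi-channel coronal section.

    ``channels`` maps channel name (``"dapi"``, ``"gfp"``, ``"iba1"``,
    ``"wfa"``) to a 2-D intensity array.  All channels must share a shape.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    ap_position_mm: float
    animal_id: str = "animal0"
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return np.asarray(arr).shape  # type: ignore[return-value]

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name])
        except KeyError:
            raise MissingChannelError(
                f"slice {self.slice_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None

    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um * 1e-3) ** 2


@dataclass
class SliceMask:
    """Binary tissue mask for one slice (lesion cavity excluded)."""

    mask: np.ndarray
    pixel_size_um: float
    holes_excluded: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_um * 1e-3) ** 2


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, counter-clockwise, about the mask centroid)
    followed by a translation in pixels (rows, cols)."""

    rotation_deg: float
    translation_px: tuple[float, float]

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0))


@dataclass
class AlignedSlice:
    image: SliceImage
    mask: SliceMask
    transform: RigidTransform
    asymmetry_score: float
    flagged: bool = False


@dataclass
class AlignedStack:
    """Midline-aligned, AP-ordered stack of sections."""

    slices: list[AlignedSlice]
    midline_col: float  # common vertical axis (column index) after alignment

    def __post_init__(self) -> None:
        ap = [s.image.ap_position_mm for s in self.slices]
        diffs = np.diff(ap)
        if len(diffs) and not (np.all(diffs < 0) or np.all(diffs > 0)):
            raise ValueError("aligned stack must be strictly AP-ordered")


@dataclass
class AreaProfile:
    """Ordered (AP position, cross-sectional area) samples for one region."""

    positions_mm: np.ndarray
    areas_mm2: np.ndarray
    region_label: str = "lesion"
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.positions_mm.shape != self.areas_mm2.shape:
            raise ProfileError("positions and areas differ in length")
        d = np.diff(self.positions_mm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ProfileError("positions must be strictly monotone")
        if np.any(self.areas_mm2 < 0):
            raise ProfileError("areas must be non-negative")

    def __len__(self) -> int:
        return len(self.positions_mm)


@dataclass
class VolumeResult:
    """Polynomial fit of an area profile and its integral.

    ``coefficients`` are highest-degree-first (``numpy.polyval`` order).
    ``interval_mm`` is the integration interval [a, b] actually used.
    """

    coefficients: np.ndarray
    degree: int
    interval_mm: tuple[float, float]
    volume_mm3: float
    fit_r2: float
    region_label: str = "lesion"
    animal_id: str = "animal0"


@dataclass
class LayerROI:
    """Axis-oriented rectangular ROI with a distance axis pointing away
    from the lesion border.

    ``origin_px`` is the (row, col) of the ROI corner lying on the
    near-lesion edge; ``distance_axis`` is a unit vector (drow, dcol) along
    increasing distance from the lesion; ``depth_px``/``width_px`` are the
    extents along and across that axis.
    """

    origin_px: tuple[float, float]
    distance_axis: tuple[float, float]
    depth_px: int
    width_px: int
    layer_label: str = "II/III"
    roi_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.distance_axis, dtype=float)
        n = float(np.hypot(*v))
        if n == 0:
            raise ValueError("distance_axis must be non-zero")
        self.distance_axis = (v[0] / n, v[1] / n)


@dataclass
class PreservationProfile:
    """Binned, total-normalized tracer intensity versus distance from the
    lesion border, plus the close/far preservation ratio."""

    normalized_intensity: np.ndarray
    close_far_ratio: float
    layer_label: str
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        self.normalized_intensity = np.asarray(self.normalized_intensity, float)
        s = self.normalized_intensity.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ProfileError(f"normalized bins must sum to 1, got {s}")


@dataclass
class ThresholdSweep:
    """Area coverage at each member of the fixed threshold ladder
    20..240 step 10 (23 levels) on the 8-bit scale."""

    thresholds: np.ndarray
    coverage_pct: np.ndarray
    analysis_ceiling: int = 100
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=int)
        self.coverage_pct = np.asarray(self.coverage_pct, dtype=float)
        if len(self.thresholds) != len(self.coverage_pct):
            raise ValueError("thresholds and coverage differ in length")

    @property
    def analyzed(self) -> np.ndarray:
        """Boolean mask of thresholds retained for statistics (≤ ceiling)."""
        return self.thresholds <= self.analysis_ceiling


@dataclass
class Particle:
    label: int
    area_px: int
    perimeter_px: float
    perimeter_um: float
    integrated_density: float
    mean_intensity: float
    centroid: tuple[float, float]
    touches_border: bool = False
    excluded: bool = False


@dataclass
class ParticleSet:
    particles: list[Particle]
    min_size_px: int
    source_roi: str = ""

    @property
    def retained(self) -> list[Particle]:
        return [p for p in self.particles if not p.excluded]

    @property
    def count(self) -> int:
        return len(self.retained)


@dataclass
class PnnResult:
    """WFA⁺ particle counts and raw-image intensities for one ROI."""

    roi_label: str
    wfa_count: int
    per_cell_intensity: np.ndarray
    fold_change_vs_contra: float | None = None
    normalized_to_control: float | None = None

    def __post_init__(self) -> None:
        self.per_cell_intensity = np.asarray(self.per_cell_intensity, float)
        if self.wfa_count < 0:
            raise ValueError("count must be non-negative")


@dataclass
class CrossingResult:
    """Scratch-assay line-crossing counts for one group, with the three
    normalization stages: raw → axons/mm → per neuron → relative to the
    control group's proximal (160 μm) baseline."""

    group: str
    distances_um: np.ndarray
    raw_counts: np.ndarray
    line_length_mm: float
    n_neurons: int
    axons_per_mm: np.ndarray | None = None
    per_neuron: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=int)
        if np.any(self.raw_counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class LdaResult:
    """Fisher discriminant fit: weights, per-animal scores, Welch test on
    the scores, and leave-one-out accuracy."""

    weight_vector: np.ndarray
    intercept: float
    scores: "Sequence[float]"
    groups: "Sequence[str]"
    welch_t: float = float("nan")
    welch_p: float = float("nan")
    loo_accuracy: float = float("nan")
    feature_names: "Sequence[str]" = field(default_factory=list)
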