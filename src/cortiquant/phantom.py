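"""Synthetic section stacks, scratch-assay images, and feature tables with
known ground truth.

The phantom emulates the imaging data produced by a controlled cortical
damage (CCD) experiment read out on serial coronal sections:

* a tissue footprint (ellipse) whose DAPI counterstain is bright except in
  the lesion cavity;
* a lesion cavity carved as the cross-section of an ellipsoid, so its
  per-slice area follows the analytic profile
  ``π·b·c·(1 − (x−x0)²/a²)`` along the anteroposterior (AP) axis;
* a GFP axonal-tracer field whose intensity recovers exponentially with
  distance from the lesion border (axonal die-back near the injury);
* microglia-like somata (disks) whose planar density decays with distance
  from the lesion, emulating perilesional microgliosis;
* ring-shaped WFA⁺ perineuronal nets with independently controllable
  ipsilesional and contralesional densities;
* a scratch-assay culture image with axons regrowing across a cell-free
  band, for line-crossing counts at fixed distances.

Every generated object is recorded in a :class:`PhantomTruth` before noise
is added, so downstream measurements can be checked against exact counts
and analytic areas/volumes.  A fixed ``rng_seed`` makes every output
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import PhantomSpecError
from .types import SliceImage

__all__ = [
    "LesionShape",
    "AxonGradient",
    "MicrogliaField",
    "PnnField",
    "PhantomSpec",
    "PhantomTruth",
    "ScratchTruth",
    "generate_slice_stack",
    "generate_scratch_image",
    "generate_scratch_groups",
    "generate_feature_table",
]

CHANNELS = ("dapi", "gfp", "iba1", "wfa")
MAX_INTENSITY = 65535  # 16-bit scale


# --------------------------------------------------------------------------
# Specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionShape:
    """Ellipsoidal cavity: semi-axes in mm along (AP, mediolateral,
    dorsoventral); in-plane center offset from the slice center in mm."""

    semi_axes_mm: tuple[float, float, float] = (1.2, 0.5, 0.5)
    center_ap_mm: float = 0.75
    center_ml_mm: float = 0.7   # positive = ipsilesional (right) hemisphere
    center_dv_mm: float = -0.3  # negative = dorsal (toward top of image)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c

    def section_area_mm2(self, ap_mm: float) -> float:
        """Analytic cross-sectional area at AP position ``ap_mm``."""
        a, b, c = self.semi_axes_mm
        s2 = 1.0 - ((ap_mm - self.center_ap_mm) / a) ** 2
        return math.pi * b * c * max(s2, 0.0)


@dataclass(frozen=True)
class AxonGradient:
    """GFP tracer field: intensity ``baseline·(1 − exp(−d/decay))`` at
    distance d (μm) from the lesion border; uniform baseline when no lesion
    is present in the slice."""

    baseline: float = 20000.0
    decay_length_um: float = 100.0


@dataclass(frozen=True)
class MicrogliaField:
    """IBA1⁺ signal: discrete somata whose planar density decays from
    ``density_near_mm2`` at the lesion border to ``density_far_mm2`` with
    length ``decay_length_um``, on top of a diffuse neuropil component
    ``diffuse_intensity·exp(−d/diffuse_decay_um)`` that emulates the
    confluent perilesional staining real IBA1 sections show."""

    density_near_mm2: float = 250.0
    density_far_mm2: float = 40.0
    decay_length_um: float = 300.0
    soma_radius_um: float = 8.0
    soma_intensity_mean: float = 22000.0
    soma_intensity_sd: float = 3000.0
    diffuse_intensity: float = 6000.0
    diffuse_decay_um: float = 300.0


@dataclass(frozen=True)
class PnnField:
    """WFA⁺ perineuronal nets rendered as annuli.  Default densities encode
    the strong ipsilesional PNN loss seen after cortical injury
    (ipsi/contra density ratio 0.15)."""

    ring_outer_um: float = 22.0
    ring_inner_um: float = 13.0
    density_ipsi_mm2: float = 3.0
    density_contra_mm2: float = 20.0
    ring_intensity: float = 25000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic section stack.

    ``slice_positions_mm`` default to eight AP-ordered sections spanning
    +2.5 to −1.0 mm from bregma.  ``misalign_*`` plant a random rigid
    offset per slice (recorded in the truth) so midline alignment can be
    validated against known transforms.
    """

    rng_seed: int = 0
    pixel_size_um: float = 2.0
    slice_positions_mm: tuple[float, ...] = tuple(np.linspace(2.5, -1.0, 8))
    footprint_semiaxes_mm: tuple[float, float] = (2.0, 1.5)  # (ML, DV)
    lesion_shape: LesionShape | None = field(default_factory=LesionShape)
    axon_gradient: AxonGradient = field(default_factory=AxonGradient)
    microglia: MicrogliaField = field(default_factory=MicrogliaField)
    pnn: PnnField = field(default_factory=PnnField)
    dapi_intensity: float = 30000.0
    noise_sd: float = 800.0
    margin_mm: float = 0.3
    misalign_rotation_deg_sd: float = 0.0
    misalign_translation_px_sd: float = 0.0
    animal_id: str = "phantom0"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise PhantomSpecError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be non-negative")
        d = np.diff(self.slice_positions_mm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise PhantomSpecError("slice positions must be strictly monotone")
        for name in ("density_near_mm2", "density_far_mm2", "soma_radius_um"):
            if getattr(self.microglia, name) < 0:
                raise PhantomSpecError(f"microglia.{name} must be >= 0")
        if self.pnn.density_ipsi_mm2 < 0 or self.pnn.density_contra_mm2 < 0:
            raise PhantomSpecError("PNN densities must be >= 0")
        if self.pnn.ring_inner_um >= self.pnn.ring_outer_um:
            raise PhantomSpecError("ring_inner_um must be < ring_outer_um")
        if self.lesion_shape is not None:
            _, b, c = self.lesion_shape.semi_axes_mm
            A, B = self.footprint_semiaxes_mm
            if (abs(self.lesion_shape.center_ml_mm) + b >= A
                    or abs(self.lesion_shape.center_dv_mm) + c >= B):
                raise PhantomSpecError(
                    "lesion ellipsoid extends beyond the tissue footprint")

    @property
    def image_shape(self) -> tuple[int, int]:
        px_mm = 1000.0 / self.pixel_size_um
        A, B = self.footprint_semiaxes_mm
        w = int(round(2 * (A + self.margin_mm) * px_mm))
        h = int(round(2 * (B + self.margin_mm) * px_mm))
        return h, w


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Analytic / pre-noise ground truth for a generated stack."""

    lesion_volume_mm3: float
    per_slice_lesion_area_mm2: list[float]
    footprint_area_mm2: float
    microglia_xy_px: list[np.ndarray]      # (n, 2) row/col per slice
    pnn_xy_px: list[np.ndarray]            # (n, 2) row/col per slice
    pnn_side: list[np.ndarray]             # "ipsi"/"contra" per net per slice
    planted_transforms: list[tuple[float, tuple[float, float]]]
    midline_col: float
    lesion_center_px: list[tuple[float, float] | None]
    lesion_radii_px: list[tuple[float, float] | None]
    spec: PhantomSpec

    def microglia_count(self, slice_index: int,
                        roi: tuple[int, int, int, int] | None = None) -> int:
        """Planted somata in slice ``slice_index``; optionally restricted to
        an (r0, c0, height, width) rectangle in canonical coordinates."""
        xy = self.microglia_xy_px[slice_index]
        if roi is None:
            return len(xy)
        r0, c0, h, w = roi
        keep = ((xy[:, 0] >= r0) & (xy[:, 0] < r0 + h)
                & (xy[:, 1] >= c0) & (xy[:, 1] < c0 + w))
        return int(keep.sum())

    def pnn_counts(self, slice_index: int) -> tuple[int, int]:
        """(ipsi, contra) planted PNN counts for one slice."""
        side = self.pnn_side[slice_index]
        return int((side == "ipsi").sum()), int((side == "contra").sum())


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def _grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return rr.astype(float), cc.astype(float)


def _ellipse_mask(shape, center_rc, semi_px) -> np.ndarray:
    rr, cc = _grids(shape)
    return (((rr - center_rc[0]) / semi_px[0]) ** 2
            + ((cc - center_rc[1]) / semi_px[1]) ** 2) <= 1.0


def _draw_disk(img: np.ndarray, center_rc, radius_px: float,
               value: float) -> None:
    r0 = int(max(0, math.floor(center_rc[0] - radius_px - 1)))
    r1 = int(min(img.shape[0], math.ceil(center_rc[0] + radius_px + 2)))
    c0 = int(max(0, math.floor(center_rc[1] - radius_px - 1)))
    c1 = int(min(img.shape[1], math.ceil(center_rc[1] + radius_px + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = ((rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
              <= radius_px ** 2)
    sub = img[r0:r1, c0:c1]
    sub[inside] = np.maximum(sub[inside], value)


def _draw_annulus(img: np.ndarray, center_rc, outer_px: float,
                  inner_px: float, value: float) -> None:
    r0 = int(max(0, math.floor(center_rc[0] - outer_px - 1)))
    r1 = int(min(img.shape[0], math.ceil(center_rc[0] + outer_px + 2)))
    c0 = int(max(0, math.floor(center_rc[1] - outer_px - 1)))
    c1 = int(min(img.shape[1], math.ceil(center_rc[1] + outer_px + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
    ring = (d2 <= outer_px ** 2) & (d2 > inner_px ** 2)
    sub = img[r0:r1, c0:c1]
    sub[ring] = np.maximum(sub[ring], value)


def _sample_positions(rng: np.random.Generator, region: np.ndarray,
                      density_map: np.ndarray | float, pixel_size_um: float,
                      min_sep_px: float) -> np.ndarray:
    """Poisson-sample object centers inside ``region`` with a (possibly
    space-varying) density per mm², rejecting overlaps closer than
    ``min_sep_px`` so planted objects never merge."""
    px_area_mm2 = (pixel_size_um * 1e-3) ** 2
    area_mm2 = float(region.sum()) * px_area_mm2
    if area_mm2 == 0:
        return np.empty((0, 2))
    if np.isscalar(density_map):
        peak = float(density_map)
    else:
        peak = float(np.max(np.where(region, density_map, 0.0)))
    if peak <= 0:
        return np.empty((0, 2))
    n_target = rng.poisson(peak * area_mm2)
    idx = np.flatnonzero(region.ravel())
    if len(idx) == 0 or n_target == 0:
        return np.empty((0, 2))
    chosen = rng.choice(idx, size=n_target, replace=True)
    rows, cols = np.unravel_index(chosen, region.shape)
    accepted: list[tuple[float, float]] = []
    min_sep2 = min_sep_px ** 2
    for r, c in zip(rows.astype(float), cols.astype(float)):
        if not np.isscalar(density_map):
            p = density_map[int(r), int(c)] / peak
            if rng.random() > p:
                continue
        ok = all((r - ar) ** 2 + (c - ac) ** 2 >= min_sep2
                 for ar, ac in accepted)
        if ok:
            accepted.append((r, c))
    return np.asarray(accepted, dtype=float).reshape(-1, 2)


def _rigid_apply(img: np.ndarray, rotation_deg: float,
                 translation_px: tuple[float, float]) -> np.ndarray:
    out = img
    if rotation_deg != 0.0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=1,
                             mode="constant", cval=0.0)
    if any(t != 0 for t in translation_px):
        out = ndimage.shift(out, translation_px, order=1, mode="constant",
                            cval=0.0)
    return out


# --------------------------------------------------------------------------
# Stack generation
# --------------------------------------------------------------------------

def generate_slice_stack(
        spec: PhantomSpec) -> tuple[list[SliceImage], PhantomTruth]:
    """Render one :class:`SliceImage` per AP position plus the exact truth.

    Channels: ``dapi`` (counterstain, dark inside the cavity), ``gfp``
    (axonal tracer with the die-back gradient), ``iba1`` (microglial
    somata), ``wfa`` (PNN rings).  Identical spec (including seed) yields
    bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.image_shape
    px_mm = 1000.0 / spec.pixel_size_um
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    A, B = spec.footprint_semiaxes_mm
    footprint = _ellipse_mask(shape, center, (B * px_mm, A * px_mm))
    footprint_area = math.pi * A * B

    slices: list[SliceImage] = []
    truth = PhantomTruth(
        lesion_volume_mm3=(spec.lesion_shape.volume_mm3
                           if spec.lesion_shape else 0.0),
        per_slice_lesion_area_mm2=[],
        footprint_area_mm2=footprint_area,
        microglia_xy_px=[], pnn_xy_px=[], pnn_side=[],
        planted_transforms=[], midline_col=center[1],
        lesion_center_px=[], lesion_radii_px=[], spec=spec,
    )

    soma_r_px = spec.microglia.soma_radius_um / spec.pixel_size_um
    ring_out_px = spec.pnn.ring_outer_um / spec.pixel_size_um
    ring_in_px = spec.pnn.ring_inner_um / spec.pixel_size_um

    for i, ap in enumerate(spec.slice_positions_mm):
        lesion_mask = np.zeros(shape, dtype=bool)
        lesion_center = None
        lesion_radii = None
        if spec.lesion_shape is not None:
            ls = spec.lesion_shape
            a, b, c = ls.semi_axes_mm
            s2 = 1.0 - ((ap - ls.center_ap_mm) / a) ** 2
            if s2 > 0:
                s = math.sqrt(s2)
                lesion_center = (center[0] + ls.center_dv_mm * px_mm,
                                 center[1] + ls.center_ml_mm * px_mm)
                lesion_radii = (c * s * px_mm, b * s * px_mm)  # (row, col)
                lesion_mask = _ellipse_mask(shape, lesion_center,
                                            lesion_radii)
            truth.per_slice_lesion_area_mm2.append(ls.section_area_mm2(ap))
        else:
            truth.per_slice_lesion_area_mm2.append(0.0)
        truth.lesion_center_px.append(lesion_center)
        truth.lesion_radii_px.append(lesion_radii)

        tissue = footprint & ~lesion_mask

        # distance (μm) from the lesion border, used by gfp and iba1 fields
        if lesion_mask.any():
            dist_um = ndimage.distance_transform_edt(
                ~lesion_mask) * spec.pixel_size_um
        else:
            dist_um = np.full(shape, np.inf)

        dapi = np.where(tissue, spec.dapi_intensity, 0.0)

        ag = spec.axon_gradient
        with np.errstate(over="ignore"):
            recovery = 1.0 - np.exp(-np.minimum(dist_um / ag.decay_length_um,
                                                50.0))
        gfp = np.where(tissue, ag.baseline * recovery, 0.0)

        mg = spec.microglia
        if mg.density_near_mm2 > 0 or mg.density_far_mm2 > 0:
            dens = (mg.density_far_mm2
                    + (mg.density_near_mm2 - mg.density_far_mm2)
                    * np.exp(-np.minimum(dist_um / mg.decay_length_um, 50.0)))
            mg_xy = _sample_positions(rng, tissue, dens, spec.pixel_size_um,
                                      min_sep_px=2.0 * soma_r_px + 2.0)
        else:
            mg_xy = np.empty((0, 2))
        iba1 = np.where(
            tissue,
            mg.diffuse_intensity
            * np.exp(-np.minimum(dist_um / mg.diffuse_decay_um, 50.0)),
            0.0)
        for r, c in mg_xy:
            inten = rng.normal(mg.soma_intensity_mean, mg.soma_intensity_sd)
            _draw_disk(iba1, (r, c), soma_r_px, max(inten, 0.0))
        truth.microglia_xy_px.append(mg_xy)

        # PNNs: ipsi = lesion hemisphere (right of midline), contra = left
        cols = np.arange(shape[1])[None, :]
        ipsi_region = tissue & (cols > center[1])
        contra_region = tissue & (cols <= center[1])
        wfa = np.zeros(shape)
        xy_all, side_all = [], []
        for region, dens, side in ((ipsi_region, spec.pnn.density_ipsi_mm2,
                                    "ipsi"),
                                   (contra_region, spec.pnn.density_contra_mm2,
                                    "contra")):
            xy = _sample_positions(rng, region, dens, spec.pixel_size_um,
                                   min_sep_px=2.0 * ring_out_px + 2.0)
            for r, c in xy:
                _draw_annulus(wfa, (r, c), ring_out_px, ring_in_px,
                              spec.pnn.ring_intensity)
            xy_all.append(xy)
            side_all.append(np.full(len(xy), side, dtype=object))
        truth.pnn_xy_px.append(np.vstack(xy_all) if xy_all
                               else np.empty((0, 2)))
        truth.pnn_side.append(np.concatenate(side_all))

        rot = (rng.normal(0.0, spec.misalign_rotation_deg_sd)
               if spec.misalign_rotation_deg_sd > 0 else 0.0)
        trans = (tuple(rng.normal(0.0, spec.misalign_translation_px_sd,
                                  size=2))
                 if spec.misalign_translation_px_sd > 0 else (0.0, 0.0))
        truth.planted_transforms.append((rot, trans))

        channels = {}
        for name, arr in (("dapi", dapi), ("gfp", gfp), ("iba1", iba1),
                          ("wfa", wfa)):
            arr = _rigid_apply(arr, rot, trans)
            if spec.noise_sd > 0:
                arr = arr + rng.normal(0.0, spec.noise_sd, size=shape)
            channels[name] = np.clip(np.rint(arr), 0,
                                     MAX_INTENSITY).astype(np.uint16)
        slices.append(SliceImage(channels=channels,
                                 pixel_size_um=spec.pixel_size_um,
                                 ap_position_mm=float(ap),
                                 animal_id=spec.animal_id,
                                 slice_id=f"{spec.animal_id}_s{i:02d}"))
    return slices, truth


# --------------------------------------------------------------------------
# Scratch assay
# --------------------------------------------------------------------------

@dataclass
class ScratchTruth:
    """Exact crossing counts and geometry for one scratch-assay image."""

    crossings: dict[float, int]          # distance μm -> axon count
    n_neurons: int
    axon_depths_um: np.ndarray           # penetration beyond the border
    border_row_px: int
    line_length_mm: float
    pixel_size_um: float


def generate_scratch_image(
    n_axons: int,
    *,
    scratch_border_um: float = 300.0,
    line_distances_um: tuple[float, ...] = (160.0, 240.0, 320.0),
    axon_depth_um: tuple[float, float] | np.ndarray = (280.0, 120.0),
    field_um: tuple[float, float] = (1000.0, 1200.0),
    pixel_size_um: float = 2.0,
    axon_thickness_px: int = 2,
    jitter_px: float = 0.6,
    noise_sd: float = 400.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, ScratchTruth]:
    """Render a two-channel culture image (axon tracer, soma counterstain).

    Somata sit in a band above ``scratch_border_um``; each extends one axon
    downward across the cell-free scratch, penetrating a depth drawn from
    ``N(mean, sd)`` (pass ``axon_depth_um`` as an array for explicit
    depths).  An axon is planted to cross the line at distance ``d`` from
    the border iff its depth ≥ d; the truth stores those exact counts.
    """
    if any(d <= 0 for d in line_distances_um):
        raise PhantomSpecError("line distances must be positive")
    if n_axons < 0:
        raise PhantomSpecError("n_axons must be >= 0")
    rng = np.random.default_rng(rng_seed)
    h = int(round(field_um[0] / pixel_size_um))
    w = int(round(field_um[1] / pixel_size_um))
    border_row = int(round(scratch_border_um / pixel_size_um))
    if border_row >= h:
        raise PhantomSpecError("scratch border lies outside the field")

    if isinstance(axon_depth_um, tuple):
        mean, sd = axon_depth_um
        depths = np.maximum(rng.normal(mean, sd, size=n_axons), 10.0)
    else:
        depths = np.asarray(axon_depth_um, dtype=float)
        if len(depths) != n_axons:
            raise PhantomSpecError("explicit depths must match n_axons")

    axon = np.zeros((h, w))
    soma = np.zeros((h, w))
    soma_r_px = 8.0 / pixel_size_um
    # space somata so neighbouring axons stay separable after rendering
    margin = int(4 * axon_thickness_px) + 4
    xs = np.linspace(margin, w - margin, max(n_axons, 1))
    if n_axons > 1:
        xs = xs + rng.uniform(-2.0, 2.0, size=n_axons)
    # each axon jitters within its own lane so neighbours can never merge
    # and the planted crossing counts stay recoverable by construction
    half = max(axon_thickness_px // 2, 0)
    spacing = (xs[1] - xs[0]) if n_axons > 1 else w
    lane_half = max(spacing / 2.0 - half - 2.6, 1.0)
    for k in range(n_axons):
        x0 = float(np.clip(xs[k], margin, w - margin))
        y0 = rng.uniform(soma_r_px + 2, max(border_row - soma_r_px - 2,
                                            soma_r_px + 3))
        _draw_disk(soma, (y0, x0), soma_r_px, 25000.0)
        end_row = min(border_row + depths[k] / pixel_size_um, h - 1)
        # jittered, monotone-downward polyline
        x = x0
        lo = max(x0 - lane_half, half + 1)
        hi = min(x0 + lane_half, w - half - 2)
        for row in range(int(round(y0)), int(round(end_row)) + 1):
            x = float(np.clip(x + rng.normal(0.0, jitter_px), lo, hi))
            c = int(round(x))
            axon[row, max(c - half, 0): c + half + 1] = 20000.0

    crossings = {float(d): int(np.sum(depths >= d)) if n_axons else 0
                 for d in line_distances_um}
    img = np.stack([axon, soma])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)
    truth = ScratchTruth(crossings=crossings, n_neurons=n_axons,
                         axon_depths_um=depths, border_row_px=border_row,
                         line_length_mm=w * pixel_size_um * 1e-3,
                         pixel_size_um=pixel_size_um)
    return img, truth


def generate_scratch_groups(
    n_axons_per_group: dict[str, int], rng_seed: int = 0, **kwargs,
) -> dict[str, tuple[np.ndarray, ScratchTruth]]:
    """One scratch image per experimental group, with decorrelated seeds."""
    out = {}
    for k, (group, n) in enumerate(n_axons_per_group.items()):
        out[group] = generate_scratch_image(
            n, rng_seed=rng_seed + 1000 * (k + 1), **kwargs)
    return out


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

def generate_feature_table(
    n_per_group: int,
    group_means: dict[str, np.ndarray],
    group_sds: dict[str, np.ndarray],
    rng_seed: int = 0,
    feature_names: tuple[str, ...] = ("injury_volume_mm3", "iba1_volume_mm3",
                                      "iba1_integrated_density"),
) -> pd.DataFrame:
    """Two-group per-animal feature table with independent-normal features.

    Emulates the per-animal (injury volume, IBA1 volume, IBA1 integrated
    density) table fed to the discriminant analysis.
    """
    if n_per_group < 2:
        raise PhantomSpecError("need at least 2 animals per group")
    if set(group_means) != set(group_sds):
        raise PhantomSpecError("group_means and group_sds keys must match")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for group in group_means:
        mu = np.asarray(group_means[group], dtype=float)
        sd = np.asarray(group_sds[group], dtype=float)
        if mu.shape != sd.shape or len(mu) != len(feature_names):
            raise PhantomSpecError("means/sds must match feature_names")
        if np.any(sd <= 0):
            raise PhantomSpecError("feature sds must be positive")
        x = rng.normal(mu, sd, size=(n_per_group, len(mu)))
        for i in range(n_per_group):
            rows.append({"animal_id": f"{group}_{i:02d}", "group": group,
                         **dict(zip(feature_names, x[i]))})
    return pd.DataFrame(rows)
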