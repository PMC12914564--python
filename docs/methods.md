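# Methods

`cortiquant` quantifies focal cortical injury from serial coronal
fluorescence sections and from scratch-assay cultures, and validates every
stage against synthetic phantoms with analytic ground truth. This note
describes the models, the defaults and why they were chosen, the numerical
decisions, and what the phantom validation does and does not establish.

## Section workflow

### DAPI masking

The slice contour is segmented on the nuclear counterstain: Gaussian blur
(σ = 3 px), threshold, largest connected foreground component. Interior
background components at least 0.01 mm² large are treated as true tissue
holes (the lesion cavity) and stay excluded from the mask; smaller interior
gaps are regarded as staining artifacts and filled. The 0.01 mm² cutoff is
a package choice — it separates a genuine cavity (≥ 0.1 mm across) from
nuclear-free speckle at the default sampling. The threshold defaults to
Otsu's method on the blurred channel as a reproducible surrogate for an
operator-chosen threshold; an absolute override is available.

### AP ordering and midline alignment

Sections are ordered anterior→posterior by their anteroposterior (AP)
position in mm from bregma (anterior positive). Sorting is metadata-driven;
inferring order from area profiles alone is ambiguous (a profile is not
monotone through a lesion) and is deliberately not attempted — missing
metadata is an error.

The midline is estimated per slice as the axis of maximal left–right mask
symmetry: the mask (cavity filled first, so a unilateral lesion does not
bias the estimate) is rotated over ±15°, and the rotation maximizing the
intersection-over-union between the centroid-centered mask and its mirror
is selected, coarse (1° grid, 8× downsampled) to fine (0.2° grid, 2×
downsampled). The slice is then rotated and translated so the symmetry
axis coincides with the vertical axis through the image center. The
residual asymmetry (1 − best IoU) is exported per slice so distorted or
incomplete sections can be flagged for manual review; masks below a
minimum area (default 0.5 mm²) are flagged instead of aligned.

Because "rotate then translate" operators do not commute, a planted
misalignment is recovered exactly as a composite transform, not
coefficient-by-coefficient; validation therefore checks the estimated
rotation angle and the overlap of the re-aligned footprint with the
analytic one (phantom tests require ≤ 1° and IoU ≥ 0.97).

### Volumetry

Region volume is estimated from the per-slice cross-sectional areas A(x):
a least-squares polynomial is fitted to the (x, A) samples and integrated
in closed form,

    V = ∫ₐᵇ max(fit(x), 0) dx.

* **Degree.** Default 2: an ellipsoidal cavity has an exactly quadratic
  area profile, so the quadratic is the natural first model; the fit R²
  is reported so misfit is visible, and the degree is configurable.
* **Support-only fitting.** The polynomial is fitted to sections that
  actually show a cavity (A > 0) when at least degree + 1 such samples
  exist. Sections beyond the cavity's extent carry no information about
  the area function, only about where it ends; treating them as A(x) = 0
  data points drags a quadratic fit toward the clipped tails and biased
  the recovered sphere volume by roughly +27% in development phantoms.
* **Integration interval.** The span of the fitted samples, extended on
  each side to the fit's nearest real root when that root lies within
  0.5 mm of the span (so a cavity tapering to zero just beyond the
  sampled sections is captured); fits that stay positive keep the data
  span. Negative fitted areas contribute nothing; the closed-form
  antiderivative is evaluated piecewise between sign changes.

Lesion areas come from the enclosed-cavity components of the tissue mask
(automated analogue of manual tracing; a CSV import path accepts
externally traced areas). The IBA1⁺ (microglia/macrophage marker)
territory is measured by blurring the IBA1 channel (σ = 5 px),
thresholding at a level calibrated on the contralesional hemisphere
(mean + 3·SD of blurred intensities in an uninjured-side ROI), and
keeping connected components of ≥ 1000 px. Size filters are in pixels,
matching uncalibrated particle-analysis conventions; a μm² mode is
available through the pixel size.

### Axonal preservation (close/far ratio)

GFP tracer intensity is profiled in rectangular layer ROIs (cortical
layers II/III, IV, V) placed parallel to the lesion border, default depth
400 μm, 20 even bins along the distance axis. Bin means are normalized to
the ROI total, making the profile a distribution over distance and
cancelling inter-slice intensity gain. The preservation score is the
close/far ratio: mean of the near-half bins over mean of the far-half
bins (the 50% split falls exactly between bins because the bin count is
even). Raw pixel values are used — no background subtraction — and
halves are split by physical distance. Closed forms used for validation:
a uniform field gives 1, a linear ramp from zero at the border gives 1/3,
and an exponential recovery I(d) = I₀(1 − e^(−d/λ)) gives the ratio of
its two half-interval means (implemented as
`analytic_exponential_ratio`).

### Microglial activation metrics

Within two rectangular ROIs (lateral and central, default 100 μm deep ×
450 μm wide) whose near edges sit 500 μm from the lesion boundary:

* **Coverage sweep.** The 16-bit ROI is linearly rescaled to 8 bits with
  a display range common to the compared set (round-half-up), and the
  percentage of pixels **at or above** each threshold 20, 30, …, 240 is
  recorded (23 levels; ≥ is the inclusive-lower-bound convention of
  common image-analysis tools). Thresholds above 100 are flagged
  excluded from statistics, since high cutoffs lose most genuine signal.
  Coverage is non-increasing in the threshold by construction.
* **Soma morphometry.** Per-image threshold (Otsu default, standing in
  for operator verification of the soma-isolating level), connected
  components ≥ 30 px, border-touching particles dropped; per soma the
  perimeter (regionprops estimator, reported in px and μm) and the
  integrated density (sum of raw 16-bit intensities over the footprint)
  are measured, the latter normalized to the control-group mean.

Lateral and central ROIs are pooled only after a Welch two-sample test
finds no difference between them (p ≥ 0.05); the decision and p-value are
logged.

### Perineuronal nets (WFA)

WFA⁺ (Wisteria floribunda agglutinin) nets are ring-shaped. Counting uses
one threshold shared between the ipsilesional ROI and its homotopic
contralesional mirror — calibrated on the contralesional staining
(mean + 3·SD of raw intensities), the animal's intrinsic control —
followed by labeling with a 200 px minimum size. The mask is not
hole-filled, so an annulus counts once and the size filter applies to the
annulus area. Per-cell intensity is measured on the raw image. The
statistic is the ipsi/contra count fold change, optionally rescaled by a
control-group reference.

### Scratch assay

The axon channel is thresholded (strict >, so a degenerate two-valued
histogram cannot select the background) and skeletonized; crossings are
counted as connected skeleton runs on lines parallel to the scratch
border at 160, 240 and 320 μm (proximal/medial/distal). A branch crossing
a line twice counts twice — the counting unit is a skeleton run at the
line, and per-tree counting is possible when axon labels exist (the
phantom provides them). Normalization: (1) crossings per mm of line
length, (2) per counted neuron, (3) relative to the control group's
proximal value, the outgrowth baseline (control-proximal ≡ 1).

### Multivariate stage (Fisher LDA)

Per-animal features (injury volume mm³, IBA1⁺ volume mm³, IBA1 integrated
density a.u.) are z-scored — the raw features mix mm³ and arbitrary-unit
scales, and without standardization the largest-variance feature dominates
the scatter — then the Fisher direction w ∝ S_w⁻¹(μ₁ − μ₀) is computed
from the pooled within-group scatter (pseudo-inverse fallback when
singular). Scores are projections centered at the grand mean, signed so
the case group's mean is positive. Group separation is tested with a
two-tailed Welch t-test (Welch–Satterthwaite df) and classification
performance by leave-one-out cross-validation: per-fold refit, equal
class priors, midpoint threshold between projected class means. LOO
accuracy is invariant to z-scoring and to any invertible affine feature
transform; scores are not, which is why the raw-scale mode exists. With
only two animals per group every leave-one-out fold drops below two
training animals per class; such folds are skipped with a warning, and
when nothing remains the accuracy is reported as NaN rather than raising.

## The phantom

The generator renders what the pipeline consumes, with exact pre-noise
truth:

* tissue footprint: an ellipse (default semi-axes 2.0 × 1.5 mm) with
  bright DAPI (30 000 on the 16-bit scale);
* lesion: an ellipsoid (default semi-axes 1.2 × 0.5 × 0.5 mm along
  AP × ML × DV, centered AP +0.75 mm, 0.7 mm into the right hemisphere)
  carved out of all channels, so per-slice cavity area follows
  π·b·c·(1 − (x − x₀)²/a²) exactly. The 1.2 mm AP half-extent makes the
  default 8-section series (AP +2.5 … −1.0 mm, one section per 0.5 mm)
  intersect the cavity in enough sections for a quadratic fit, and is a
  realistic extent for a drill-induced cortical cavity;
* GFP: baseline 20 000 with exponential recovery away from the lesion
  border (decay 100 μm) — the axonal die-back the close/far ratio
  measures;
* IBA1: somata (disks, radius 8 μm, intensity 22 000 ± 3 000) sampled
  with density decaying from 250/mm² at the border to 40/mm²
  (decay 300 μm), on a diffuse neuropil component 6 000·e^(−d/300 μm).
  The diffuse term emulates the confluent perilesional staining of real
  IBA1 sections; without it no connected component would pass the
  1000 px region filter and the inflamed-territory volume would be zero
  by construction;
* WFA: annuli (outer/inner radius 22/13 μm — sized so the annulus area
  comfortably exceeds the 200 px filter at the default 2 μm/px sampling)
  at 3/mm² ipsilesionally and 20/mm² contralesionally, i.e. a planted
  density ratio of 0.15, matching the severe ipsilesional PNN loss seen
  after cortical injury;
* noise: additive Gaussian (SD 800), clipped at zero, after an optional
  planted rigid misalignment per slice (recorded in the truth);
* scratch images: somata in a band, one monotone-downward jittered axon
  each, penetration depths drawn N(280, 120) μm or given explicitly;
  truth stores the exact crossing count per line;
* feature tables: independent-normal two-group samples.

Objects are placed with a minimum separation (twice their radius) so
noise-free labeling recovers planted counts exactly. All sampling flows
from one `numpy` Generator seeded by the spec, making stacks
bit-reproducible.

**What the phantom does not emulate:** optics (PSF, z-extent), vignetting
and illumination gradients, tissue deformation and tears, autofluorescence,
ramified microglial processes, partial or fragmented PNNs, axon fasciculation
and crossing in vitro, and correlated (structured) noise. Passing phantom
tests therefore establishes that the measurement chain is correct —
geometry, counting, integration, statistics — not that segmentation
parameters transfer to any particular real dataset, where thresholds and
size filters must be re-validated.

## Problem sizes and numerical choices

Default images are 2 μm/px (a 4 mm slice ≈ 2000 px); the full 8-slice
pipeline runs in about 1–2 minutes on one CPU. Validation suites use
reduced footprints (≈ 1.2 × 1.0 mm) and 1–8 slices per phantom, 20 seeds
for stochastic recovery checks, and 200 permutations for the LDA null —
sizes at which the Monte-Carlo intervals are already far tighter than the
tolerances being checked. Other numerical decisions:

* 16-bit→8-bit conversion rounds half-up after linear mapping of the
  common display range.
* The zero-clipped noise floor biases background means upward by
  σ·φ(μ/σ) − μ·Φ(−μ/σ); the contralesional calibration absorbs this
  (both hemispheres share it), and the phantom-truth oracle for IBA1
  areas models it in closed form.
* Constant area profiles define R² = 1 when residuals vanish (the
  zero-variance case is otherwise undefined).
* Ties in the midline rotation search resolve to the first grid optimum;
  the grid is symmetric about 0° so an already-aligned slice returns the
  identity.
* Welch's test returns (0, 1) for two zero-variance samples with equal
  means and (±∞, 0) with distinct means.

## Known limitations

* The lesion border used for ROI placement is the cavity boundary; early
  post-injury tissue without a frank cavity would need a user-supplied
  border.
* Laminar boundaries are user-supplied (phantom encodes them by depth
  fraction); no automatic layer segmentation.
* No deformable or atlas registration; alignment is rigid per slice.
* Volume uncertainty is summarized only by the fit R²; no error
  propagation from segmentation to volume.
* Two-class LDA only, by design.
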