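# Methods

## Problem

Radiomic texture features are computed from the gray-level distribution of a
region of interest, so anything that changes the sampling of the underlying
tissue changes the features. In cardiac cine MRI the field of view (FOV) is
adjusted per patient while the acquisition matrix stays fixed, which makes
the in-plane pixel spacing — and therefore every texture feature — a function
of an essentially arbitrary acquisition choice. `radiomaps` implements and
tests one proposed remedy: instead of extracting a feature once from the ROI
of the original image (*conventional extraction*), the image is tiled into
voxels of fixed **physical** size, the feature is computed per tile, the tile
values are assembled into a *parametric feature map* at the original pixel
grid, and the ROI value is read off the map as a plain mean, like an ADC
measurement. Because the tile size is specified in millimetres, the local
statistics entering the map are computed over a (nearly) resolution-
independent support, which should — and in this pipeline does — reduce the
FOV dependence of most features.

## Synthetic cohort

No suitable public cine images exist for this design, so the package ships a
first-class phantom generator. A midventricular short-axis slice is modelled
as three compartments:

| parameter | default | meaning |
|---|---|---|
| `r_inner_mm` | 30 | blood-pool (cavity) radius |
| `r_outer_mm` | 46 | outer myocardial radius (16 mm wall) |
| `myo_mean_intensity` | 100 | myocardial mean signal (arbitrary units) |
| `myo_texture_sd` | 8 | SD of the myocardial texture field |
| `texture_corr_length_mm` | 4 | Gaussian correlation length of the texture |
| `blood_intensity` | 250 | blood-pool signal |
| `background_intensity` | 25 | background signal |
| `noise_sd` | 3 | additive Gaussian acquisition noise |
| `subject_jitter` | 5% radii, 2% intensities | uniform per-subject variation |

The myocardial texture is a unit-variance Gaussian random field (white noise
smoothed with a Gaussian kernel of the stated correlation length, tabulated
once per subject on a 0.5 mm grid), which is the simplest field with a
controllable spatial scale — the property that makes texture features
resolution-sensitive. Per-subject anatomy and intensity are deterministic
jittered variants of the template (uniform within the stated fractions), so
a (seed, subject) pair always reproduces the same tissue.

**Rendering and the partial-volume model.** A render at acquisition geometry
(FOV, matrix) samples the continuous scene at pixel centers with spacing
`fov/matrix`. Acquisition blur is modelled as an isotropic Gaussian with
sigma = 0.5 × mean pixel spacing: the texture field is smoothed with it, and
the circular tissue boundaries are mixed analytically with the matching
error-function edge profile (the exact intensity profile of a Gaussian-
blurred step). The analytic edge avoids rasterization artifacts that a
blurred hard mask would add at the 0.5 mm grid pitch. Blur scaling with
pixel spacing is the mechanism that makes conventional features
FOV-sensitive; a physical MR point-spread function is not attempted. Noise
is additive Gaussian; at these signal levels the Rician correction would be
negligible, so it is omitted. One frame per subject is produced (the
analysis concerns end-diastolic frames only; no cardiac cycle is simulated).

**Intensity placement.** Intensities are arbitrary units chosen so the
0–170 threshold logic works: myocardium + 3 SD stays below 170, blood sits
above, and the myocardium/blood edge midpoint (175) sits slightly above the
threshold so that the sub-threshold rim of the blood pool and the
supra-threshold rim of the myocardium each stay well below 1% of their
compartments at every study FOV. Pixels essentially centered on the
boundary genuinely carry mixed signal; they are the only pixels the
threshold misclassifies, which is why the separability property is asserted
on pixels pooled across the cohort rather than per image.

**Default acquisitions.** The three study geometries are 256×329, 279×359
and 302×390 mm at a fixed 224×157 matrix with 8 mm slice thickness. FOV
entries are paired with matrix axes so pixels come out near-isotropic
(329 mm / 224 px = 1.469 mm; 256 mm / 157 px = 1.631 mm); the pairing is an
explicit field of `AcquisitionSpec` and can be changed.

What the phantom does **not** emulate: SSFP banding and coil profiles,
k-space sampling/aliasing, papillary muscles and trabeculation, pathology,
cardiac and respiratory motion, through-plane effects. Passing tests on this
cohort therefore demonstrate the *mechanics and direction* of the
FOV/feature-map interaction, not clinical magnitudes.

## Segmentation

The clinical workflow (manual ROI around the LV, then an intensity window)
is reproduced as: a circular region around the known phantom center with
radius `r_outer + 1 mm`, intersected with the closed window [0, 170], then
the largest 8-connected component. Since segmentation reproducibility is not
the object of study, using the ground-truth center is deliberate; the window
is closed on both ends and edge pixels lost to partial volume are accepted
(Dice against the true annulus ≥ 0.90 on the default phantom).

## Feature catalog and conventions

93 features: 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM,
named `<class>_<FeatureName>` after the public reference catalog. Shape
features are excluded by design (ROI shape is not a function of FOV).
Conventions, all configurable via `ExtractionSettings`:

* **Discretization** — fixed bin width (default 25), anchored at the masked
  minimum: `level = floor((I − min)/width) + 1`, then levels re-indexed to
  consecutive occupied integers, `Ng` = occupied count. Anchoring at the
  minimum makes all texture classes invariant under global intensity shifts.
* **Angles** — GLCM and GLRLM use the four in-plane directions at distance 1;
  features are computed per angle and averaged over angles that produced a
  non-empty matrix (feature-level averaging, not matrix pooling).
* **Neighborhoods** — GLSZM zones, GLDM dependence and NGTDM neighborhoods
  are 8-connected (Chebyshev distance 1) by default; GLDM α = 0.
* **Logs** — all entropies are base 2 with 0·log 0 = 0.
* **Moments** — variance/skewness/kurtosis are population moments; kurtosis
  is non-excess (normal → 3). Total energy multiplies energy by the
  per-pixel volume (pixel area × slice thickness), the only place slice
  thickness enters.
* **Degenerate cases** — features whose formula is 0/0 carry an explicit
  validity flag instead of a silent fill and are excluded from downstream
  statistics. Flagged undefined: GLCM correlation of a one-level region,
  skewness/kurtosis at zero variance, robust MAD of regions whose closed
  10–90 percentile window is empty (2-pixel regions), all GLCM features when
  no in-mask pixel pair exists, all NGTDM features when no masked pixel has
  a masked neighbor. Finite limits are kept where they exist: NGTDM
  coarseness of a constant region is capped at 1e6, IMC1 is 0 when the
  marginal entropies vanish, MCC of a one-level co-occurrence matrix is 1.

### Implementation note

One batched, mask-aware engine computes all 93 features for a stack of
regions at once; conventional extraction is a stack of size one and the map
engine feeds all tiles of an image through the same kernels grouped by tile
shape. Sharing the code path makes the single-tile map identical to
conventional extraction bit for bit (an asserted invariant) and keeps the
full 36-image study in the tens of seconds. Correctness of the batched
kernels is established against naive exhaustive enumerations (dictionary
co-occurrence counting, line-walking run scanners, flood-fill zones,
per-pixel neighbor loops) on seeded random masked regions.

## Parametric maps

Tile extent in pixels is `round(tile_mm / spacing_mm)`, clamped to ≥ 1, per
axis; default tile 3×3×8 mm (z matching the slice thickness). Tiles are
anchored at the image origin and trailing partial tiles are kept, so tiles
partition the pixel grid. Each tile is discretized independently at its own
minimum (it is treated as an independent input image), computed over *all*
its pixels regardless of any ROI — the ROI enters only at readout, matching
the workflow of computing maps for the whole image and then copying ROIs
onto them. Values are broadcast to the tile's pixels so maps share the
source geometry exactly. The ROI readout is the unweighted mean over masked
pixels on valid tiles, with the invalid-pixel fraction reported; it is
computed over grouped equal values, which is the same mean but returns the
tile value exactly when the ROI covers a single tile. At the study
geometries every tile is 2×2 pixels (edge strips 2×1), so per-tile texture
matrices are tiny and many tiles of smooth tissue are single-level; their
undefined features are simply excluded from the readout.

## Reproducibility analysis

The coefficient of variation is the sample (n−1) standard deviation divided
by |mean|; the sample formula is used because the experimental design has
only three values (FOVs) per COV, where the population formula would
understate spread, and |mean| gives sign-crossing features (skewness,
cluster shade) a defined COV. A COV whose mean is numerically zero
(|mean| < 1e-12 × data scale) is flagged missing rather than reported as an
arbitrarily large number. Stability is COV ≤ 0.10, threshold inclusive.

* *Clinical design*: one COV per feature across all subjects.
* *Experimental design*: one COV per (subject, feature) across that
  subject's FOVs — 93 × n_subjects COVs per method — and a feature counts
  as reproducible only when it is stable for **every** subject.

Method comparison reports: stable-feature counts per method, the relative
increase as a percentage, features whose mean matched COV decreased under
map extraction, features crossing from unstable to stable, and the fraction
of all computed COVs under the cutoff per method. Per grouping,
stable + unstable + missing always partitions the catalog.

## Study sizes

The shipped analyses use the full study geometry: 12 subjects × 3 FOVs at
matrix 224×157 for the experimental design (36 images, 1116 COVs per
method) and 61 subjects at one FOV each — interpolated uniformly between
the smallest and largest experimental FOV pair, keeping a realistic aspect
ratio — for the clinical design. Both run in well under a minute on one
core thanks to the batched engine.

## Known limitations

* Feature definitions follow the public reference catalog's defaults; site-
  specific extraction settings (different bin widths, filters, resampling)
  are out of scope, as are shape features and 3D extraction.
* The spec-level re-indexing of discretized levels to consecutive integers
  differs from implementations that keep raw bin indices when the histogram
  has gaps; with min-anchored binning of smooth tissue the difference is
  rarely exercised.
* COV-based stability is the only reproducibility metric (no ICC or
  Bland–Altman); that is the metric under study.
* The directional finding (maps more stable than conventional extraction)
  is established on the synthetic cohort; magnitudes depend on the phantom's
  texture scale and jitter and are not claimed to transfer to clinical data.
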