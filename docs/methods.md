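# Methods

## The measurement model

`trichromequant` quantifies Masson's-trichrome-stained skin sections from
24-bit RGB brightfield photomicrographs. The chain of models, in pipeline
order:

**Beer–Lambert optical density.** A dye attenuates each camera channel
multiplicatively, so analysis happens in optical density,
`od_c = -log10((I_c + 1)/256)` for channel intensity `I_c ∈ [0, 255]`. The
`+1` offset keeps the transform finite at `I = 0`; the cost is that an 8-bit
channel can only represent densities up to `log10(256) ≈ 2.408`. ODs of
co-localised dyes add linearly: `od = a·v1 + b·v2`, with `v1, v2` the unit
absorbance directions (stain vectors) of the two working dyes. Note the
inverted colour logic: a blue–green dye absorbs mostly red light, so the
collagen vector is `(0.8001, 0.4070, 0.4407)` in (R, G, B) OD; the
muscle/cytoplasm red–pink vector is `(0.4311, 0.7154, 0.5498)`. These
printed defaults are re-normalised to exact unit length at load time (their
4-decimal components are unit only to ~1e-5).

**Stain-vector estimation.** A custom vector is the unit-normalised mean OD
triplet over a user ROI (dermal collagen for blue–green, panniculus
carnosus for red–pink). Mean OD rather than a principal component: for a
region dominated by one dye the two coincide, and the mean is robust for
the small, hand-picked ROIs this tool expects. Blank (white) ROIs are
rejected (`DegenerateROI`) rather than normalised from noise.

**Colour deconvolution.** The two stain vectors plus their unit cross
product (a residual axis, never rendered) form an invertible 3×3 matrix M
(vectors as rows); per pixel the concentrations solve `Mᵀ·conc = od`.
Negative coefficients from cross-talk are preserved in the concentration
image — clipping happens only when rendering the 8-bit channels — so the
solve is exactly linear and `recompose ∘ deconvolve` is the identity on any
RGB image up to rounding.

**8-bit stain channels.** Each concentration plane is rendered as
`255 - round(255·10^(-c))`, so larger values mean more stain, 0 means none,
and any `c ≥ 2.71` saturates at 255. This orientation reproduces the
expected behaviour of strongly stained regions reading a maximum gray value
of 255.

**Tissue mask.** From the blue–green channel: Gaussian blur (σ = 2.0 px,
reflective boundaries, re-quantised to uint8) to bleed stain across the
natural unstained cracks between collagen bundles; whole-image 256-bin
histogram with bin 0 removed ("ignore black" — gray 0 is the no-stain
background and would otherwise dominate); iterative-intermeans ("Default")
auto-threshold; foreground strictly above the threshold; one binary closing
with a 3×3 square element to consolidate the area.

**Iterative intermeans.** Starting from the midpoint of the occupied bin
range, iterate `t ← round((μ_≤t + μ_>t)/2)` (round half up) to a fixed
point. Candidates are clamped to `[first, last-1]` occupied bins so both
sides stay non-empty; a cycle — possible only on pathological histograms —
terminates at the current value. Fewer than two occupied bins raise
`DegenerateHistogram`. The map is monotone, so an integer fixed point
exists; tests verify the result against an exhaustive 256-candidate scan.

**Per-stain regions.** Each stain channel is auto-thresholded the same way
(by default on the whole-image histogram, then AND-ed with the tissue mask;
a `threshold_scope="mask"` variant computes the histogram inside the mask
instead). A channel that is entirely black — e.g. a slide with no red dye —
yields an empty region, reported as zero area with NaN intensity statistics
rather than an error, so batch runs survive single-stain images.

**Features.** Pixel counts convert to mm² through the calibration
`px_per_mm = 473` (areas divide by `473²`; `473² px = 1.000 mm²` exactly).
Per stain and image: mask area, thresholded area, thresholded-to-mask and
mask-to-image ratios (percent, full precision; rounding is a reporting
concern), and the gray-level distribution inside the AND region — mean,
median (even counts interpolate the two central values), SD, min, max,
skewness and excess kurtosis. SD uses the n−1 denominator while skewness
`m₃/m₂^1.5` and kurtosis `m₄/m₂² − 3` use population moments, mirroring the
conventions of common image-measurement software; both are NaN when
`m₂ = 0`.

**Statistics.** Each feature is compared between stains with a two-step
procedure: Shapiro–Wilk on both groups (normal iff p **strictly greater**
than 0.05; a constant group counts as non-normal), then a pooled-variance
independent t-test if both pass, else a two-sided Mann–Whitney U. The
Mann–Whitney p is exact — full enumeration over all group labelings, with
midranks so ties are handled — when the combined n ≤ 12, and the tie- and
continuity-corrected normal approximation otherwise; two samples with no
spread at all (every comparison tied) report p = 1 directly. Groups are
summarised as mean ± SD when normal, median [IQR] otherwise (quartiles by
linear interpolation). Cross-stain relationships use OLS on image-paired
values with R² and the slope's p-value. No multiple-testing correction is
applied across the feature table; the report footer says so. Welch's t is
available behind `equal_var=False`.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| stain vectors | printed trichrome pair | unit OD | dataset-wide custom vectors; per-image estimation via `estimate_stain_vector` |
| blur σ | 2.0 | px | the protocol's stated mask-blur width |
| closing element / iterations | 3×3 square, 1 | – | the common default of the original tool; unstated in the protocol |
| threshold_scope | image | – | whole-image histogram then AND, matching the protocol's ordering |
| px_per_mm | 473 | px/mm | the stated calibration (1 mm = 473 px). The source's other pixel-size statements (0.20 µm/px; 2.60 mm height) are mutually inconsistent and are not used |
| α | 0.05 | – | conventional; also the normality-gate level |

## The synthetic-scene generator

`generate_scene` emulates a full-thickness rodent-skin section, top to
bottom: bright background, a thin red epidermis (keratin), a dermis band
(45 % of height by default, giving a mask-to-image ratio near 40 %) of
blue–green collagen bundles, a red–pink muscle band, and background. One
integer seed drives a single RNG with a documented draw order (bundle
texture, cytoplasm texture, crack paths, follicle geometry, sensor noise),
so scenes are bit-reproducible.

Bundles are the top `collagen_fill` quantile of a Gaussian-smoothed
white-noise field (σ = 6 px) over the dermis, selected by exact top-k
partition so the true collagen fraction of the dermis equals
`collagen_fill` to within one pixel — the ground truth the recovery tests
compare against. Bundle concentration ramps with the texture field from 1.0
up to `peak_blue_conc` (default 3.0, which saturates the 8-bit channel at
255 inside the densest bundles). Thin random-walk polylines of zero
concentration carve the inter-bundle "cracks"; elliptical unstained voids
stand in for follicles and are excluded from the dermis ground truth.
Cytoplasm is a speckle of red (top `dermis_red_fill` quantile of an
*independent* texture field over the dermis, so measured blue and red areas
are uncorrelated by construction). Sensor noise is additive Gaussian in RGB
space after composition, as a camera would add it.

**Why the inter-bundle dermis is lightly stained.** Non-bundle dermis
carries a low blue concentration (0.28, gray ≈ 121) representing
ground-substance staining. This value sits in the narrow window the
intermeans threshold's fixed-point structure dictates: the blurred-channel
histogram is trimodal (background ≈ 0–6, ground ≈ 121, bundles ≈ 230–255),
and the mask threshold must fall below the ground mode (so the mask covers
the whole dermis) while the unblurred per-stain threshold falls above it
(so only bundles count as collagen). Below ≈ 0.25 the mask threshold can
overtake the ground mode at high fills; at ≈ 0.30 and above the stain
threshold collapses to the lower fixed point and swallows the ground mode.
With 0.28, measured thresholded-to-mask ratios track the true fill within
2.2 percentage points across fills 0.3–0.7 and ten seeds (the test bound is
six points). When `collagen_fill = 0` the dermis is left unstained
entirely — no collagen, no ground-substance stain.

**What the generator does not emulate — and what passing tests therefore do
not show.** No nuclei or hematoxylin component, no fibre orientation or
bundle anisotropy, no illumination gradients, stain-batch variation or
focus blur, and a background that is perfectly white. Bundle gray levels
are deliberately driven into saturation, so synthetic intensity
distributions are narrow and left-skewed near 255 — unlike real trichrome
sections, whose intensity histograms are broad and platykurtic. Recovery
and calibration results on these scenes validate the pipeline's arithmetic
and segmentation logic, not its behaviour under real-world staining
variability.

## Numerical choices and degenerate inputs

- OD uses `(I+1)/256`; the inverse clamps to `[0, 255]` and treats negative
  round-trip residue as zero absorbance.
- Unmixing keeps negative concentrations; rendering clamps at 0 and 255.
- Round half up (`floor(x+0.5)`) for the threshold update; thresholding is
  strict (`value > t`).
- Closing: dilation treats outside-image as background, erosion as
  foreground, making the closing extensive up to the border.
- Empty ROI, blank ROI, collinear vectors, sub-two-bin histograms, empty
  regions, constant samples, zero-variance regressors and sub-minimum
  sample sizes all raise typed exceptions rather than returning NaN
  silently; the batch CLI logs and skips per-image failures and fails only
  if every image does.
- The 8-bit dynamic range bounds what deconvolution can recover: per-channel
  OD caps at `log10(256) ≈ 2.408` and the gray-level quantisation step near
  saturation is ≈ 0.15 OD (between gray 0 and 1). Concentration recovery
  from rendered images is therefore accurate (≤ 0.02) only while all
  composite OD channels stay ≲ 1.1; mixtures of two dyes near concentration
  3 are unrepresentable and cannot be unmixed from 8-bit pixels at all.
  Area-based measurements are unaffected — saturated pixels are still
  correctly *classified* as heavily stained.

## Problem sizes used by the test suite

Identity and oracle checks run on constructed arrays; end-to-end checks use
full-geometry scenes (1832×1321) for the saturation and runtime tests, and
480×360 scenes for the 30-scene fill-recovery grid and 320×240 for the
30-scene independence check — ratios and thresholds are resolution-invariant
here because every histogram mass scales proportionally with pixel count.
The null-calibration check runs 2000 simulated two-group comparisons at
n = 20 per group.

## Known limitations

- Images are treated as independent replicates; no per-animal clustering or
  mixed models (a faithful reproduction of the protocol being emulated, and
  a real limitation when several sections come from one animal).
- The "Default" threshold is plain iterative intermeans; the original GUI's
  variant additionally trims extreme end bins, which is out of scope here,
  so thresholds may differ by a few gray levels on histograms with heavy
  end-bin mass.
- Whether the emulated protocol computed per-stain thresholds on the whole
  image or inside the mask is ambiguous; both are implemented,
  whole-image-then-AND is the default.
- No whole-slide pyramidal formats, no three-dye bases, no texture or
  orientation features.
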