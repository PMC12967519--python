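# trichromequant

Quantitative histomorphometry for Masson's-trichrome-stained skin sections.

Trichrome staining marks collagen blue–green (aniline blue) and
muscle/cytoplasm/keratin red–pink (Biebrich scarlet–acid fuchsin).
Pathologists usually read such slides qualitatively; this package turns a
batch of 24-bit RGB photomicrographs into reproducible numbers — how much
of the dermis is collagen, how intensely it stains, and how the two dyes'
intensity distributions differ — for anyone studying dermal remodelling,
fibrosis or wound healing in histological sections.

## What it computes

1. **Colour deconvolution.** Pixels move to optical density,
   `od_c = −log10((I_c+1)/256)`, where dye contributions add linearly
   (Beer–Lambert): `od = a·v₁ + b·v₂` with unit stain vectors
   `v₁ = (0.8001, 0.4070, 0.4407)` (blue–green) and
   `v₂ = (0.4311, 0.7154, 0.5498)` (red–pink) by default — or vectors
   estimated from your own ROIs (`estimate_stain_vector`, the mean-OD
   direction of a reference region). A per-pixel 3×3 solve recovers the
   concentrations `(a, b)`, rendered as 8-bit channels where larger = more
   stain.
2. **Segmentation.** A fibrous-tissue mask from the collagen channel:
   Gaussian blur (σ = 2 px) → iterative-intermeans ("Default")
   auto-threshold with gray 0 ignored → 3×3 binary closing. Each stain
   channel is auto-thresholded the same way and AND-ed with the mask.
3. **Features.** Per image × stain: calibrated areas (473 px = 1 mm, so
   473² px = 1 mm²), thresholded-to-mask and mask-to-image ratios, and the
   region's gray-level statistics (mean, median, SD, min, max, skewness,
   excess kurtosis).
4. **Statistics.** Per feature: Shapiro–Wilk normality gate on both stain
   groups (normal iff p > 0.05), then a pooled-variance t-test if both are
   normal, else a two-sided Mann–Whitney U (exact by enumeration for
   combined n ≤ 12); summaries as mean ± SD or median [IQR]; OLS regression
   with R² for image-paired cross-stain relationships.

A synthetic-scene generator (`generate_scene`) produces trichrome-like skin
images — dermis band of collagen bundles with unstained cracks and
follicle voids, red muscle band, sensor noise — with exact ground truth, so
the whole pipeline is testable without any slide data.

## Worked example

Generate a fixture suite and measure the nine realistic scenes in it:

```sh
trichrome-quant simulate --out-dir fixtures --suite
trichrome-quant run 'fixtures/scene_fill*_seed?.png' --out-dir results
trichrome-quant compare results/features.csv --out-dir results
```

`run` logs every data-dependent choice to stderr, e.g.:

```
INFO scene_fill030_seed1: mask threshold=81, blue_green threshold=158, red_pink threshold=127, mask area=0.3192 mm^2
```

and writes `features.csv` (one row per image × stain) and `paired.csv`.
`compare` prints the cohort table (also saved as `comparison.csv` and
`report.md`); for the nine suite scenes (192×256 px, collagen fills 0.3,
0.5, 0.7):

```
| feature | blue_green | red_pink | test | statistic | p_value | significant |
|---|---|---|---|---|---|---|
| Thresholded area (mm²) | 0.167 ± 0.0577 | 0.0406 ± 0.000962 | t_test | 6.543 | 6.771e-06 | True |
| Thresholded to mask area ratio (%) | 51.3 [30.8–71.1] | 12.5 ± 0.221 | mann_whitney | 81 | 0.0004123 | True |
| Mean intensity | 243 ± 1.36 | 239 ± 1.72 | t_test | 4.665 | 0.0002585 | True |
| Maximum intensity | 255 [255–255] | 255 [255–255] | mann_whitney | 40.5 | 1 | False |
```

Reading it: the collagen (blue–green) area is far larger than the red–pink
area, as designed into the scenes — the blue ratio spread 30.8–71.1 % spans
the three programmed fills while the red speckle stays near 12.5 % — and
both channels saturate at 255 inside strongly stained regions, so their
maxima never differ. Columns report each group as mean ± SD when its
Shapiro–Wilk p exceeds 0.05 and median [IQR] otherwise, and the `test`
column records which comparison the normality gate selected.

The same numbers are available as a library:

```python
import trichromequant as tq

rgb, truth = tq.generate_scene(tq.SceneParams(collagen_fill=0.6, seed=1))
blue, red, paired = tq.extract_features(rgb, image_id="demo")
print(blue.thresholded_to_mask_pct)            # 61.1 — vs. 60.0 true fill
print(blue.intensity.max)                      # 255.0
print(truth.true_collagen_fraction_of_dermis)  # 0.5999998
```

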