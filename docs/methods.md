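# Methods

## The assay being emulated

A rectangular silica TLC plate carries three functional regions along
the migration axis y (origin at the plate bottom): the sample loading
line (`origin_y`, default 10 mm), an Ag(I)-impregnated retention zone
reaching up to `ag_zone_top_y` (default 23.3 mm, the lower third of the
70 mm default plate), and the mobile-phase boundary line (`front_y`,
default 60 mm).  Cannabinoids with a 1,5-diene (CBD, CBDA, CBG) bind
Ag(I) strongly and stop inside the retention zone; cannabinoids with at
most one olefinic bond (THC, THCA, CBN) migrate into the detection zone
to analyte-specific retention factors.  A reference lane holds an
olivetol spot that is loaded but never eluted.  Fast Blue BB spraying
turns each phenolic spot into an azo dye whose HSB saturation increases
with the amount loaded: orange for THC/THCA, purple for CBN.

## The synthetic plate model

`render_plate` draws the plate directly in HSB space and converts to an
8-bit RGB raster at write time (`pixel_size` 0.2 mm/px by default).

* **Spots.**  Each spot is an isotropic 2-D Gaussian chroma footprint
  (σ = `sigma_mm`, default 1.1 mm, truncated at 4σ so noiseless
  backgrounds are exactly flat) centred at
  `y = origin_y + Rf·(front_y − origin_y)` in its lane.  Peak
  saturation is `min(sat_slope · amount · gain, sat_max)`.
* **Blending.**  Co-located spots (the THC/CBN pair) mix by
  chroma-weighted circular hue averaging; saturations add and are
  capped at `sat_max` (0.85).  This makes the combined spot's hue slide
  continuously from orange (25°) toward purple (285°) as the CBN
  fraction grows — the physical basis of the classifier.
* **Background.**  Near-white silica: saturation 0, brightness 0.96,
  optionally darkened by `ag_tint` (8%) below the Ag-zone boundary and
  tilted by `illum_gradient` (0 by default; the assay assumes a light
  box).

### Noise model

Four variance components, all seeded by one integer:

| parameter | default | meaning |
|---|---|---|
| `noise_sd` | 0.015 | per-pixel Gaussian noise on saturation |
| `plate_cv` | 0.05 | one multiplicative development gain per plate, shared by every spot including the reference — removed exactly by olivetol normalization |
| `dev_cv`, `dev_corr_mm` | 0.05, 35 mm | a smooth development field (Gaussian process, squared-exponential covariance, sampled at spot centres): spray and development unevenness varies over centimetres, so adjacent lanes develop almost identically while the reference spot, sitting far away at the loading line, partially decorrelates |
| `spot_cv` | 0.03 | independent per-spot jitter (loading volume, local development) |

The decomposition matters more than the totals.  Olivetol
normalization removes `plate_cv` entirely and the correlated part of
the field; what survives — field decorrelation over the
reference-to-spot distance plus `spot_cv` — sets replicate precision.
Because the field is smooth, two sample lanes sitting side by side on
one plate agree with each other far better than either agrees across
plates, which is why a CBD-spiked and a CBD-free sample screened on the
same plate produce nearly identical calibration-scale responses.  The
defaults were set so that, under the standard screening workup,
replicate relative SDs land in the mid single digits to ~10% — the
precision class of phone-camera colorimetry — while calibration curves
retain r² ≈ 0.96–0.99.

The spike-recovery experiment adds one more term, `matrix_cv` (0.06):
plant co-extractives modulate the chromogenic yield of sample spots.
It is drawn once per extraction/plate, applies to the sample lanes but
not to the matrix-free olivetol reference, and is absent from
pure-standard calibration plates.

### What the generator does not model

Rf values, hues and response slopes are *inputs* (preset table), not
predictions: there is no model of Ag(I)–olefin complexation, solvent
flow, spot tailing, or FBBB kinetics.  Perspective distortion, specular
reflections, white-balance drift and camera vignetting are likewise out
of scope (the assay uses a rectified light-box photograph).  Passing
tests therefore demonstrate that the *analysis chain* is correct and
robust to realistic radiometric noise — not that real plates will show
these exact Rf values or LODs.

## Analysis chain

* **Color.**  Standard hexcone HSB (B = max/255, S = (max−min)/max).
  Region statistics average S and B per pixel (not from mean RGB), with
  a circular mean for hue excluding achromatic pixels, which have no
  defined hue and are reported as 0°.
* **Detection.**  Background saturation per pixel column is the column
  median; pixels above background + `sat_threshold` (0.03 ≈ 2× pixel
  noise SD) are grouped by 8-connectivity and components under
  `min_area_px` (20 px) are dropped.  Centroids are intensity-weighted.
  Lane assignment is nearest-lane-centre with ties toward the lower
  index; zone is `ag_retention` at or below `ag_zone_top_y`,
  `detection` above (an exhaustive, disjoint partition of y), and
  `reference` for the reference lane regardless of y.
* **Quantification signal.**  Mean background-subtracted saturation in
  a fixed 2.4 mm-radius disc around the centroid.  For a fixed spot
  shape this aperture mean is proportional to peak saturation, so the
  analyte/reference ratio equals the peak ratio and the fitted
  normalized slope recovers `sat_slope / S_olivetol` exactly on
  noiseless renders (the unit tests assert this).  A thresholded-region
  mean would not be amount-linear, because the region itself grows with
  amount.
* **Widths and resolution.**  Spot width is 4σ from a Gaussian fit of
  the vertical saturation profile (weighted-SD fallback);
  Rs = 2|Δy|/(w₁+w₂).  On the default presets the closest
  THC-analogue/CBD-analogue pair gives Rs ≈ 4.8 on the Ag(I) plate and
  ≈ 0.56 on unmodified silica — an ~8-fold separation gain.
* **Calibration.**  Amounts 0.2/0.5/0.8/1.0/2.0 µg, three replicate
  plates, every replicate an individual OLS point; the line is not
  forced through the origin.  A flat response yields slope 0 and an
  invalid curve.  LOD = 3·SD(blank)/slope in ng; the blank SD comes
  from ≥10 clean 3 mm background patches of the analyzed plate.
  Below-LOD predictions are reported as "<LOD", never as zero;
  out-of-range predictions keep their point estimate but carry a flag.
* **Classifier.**  raw = (R̄−B̄)/(R̄+B̄) over the spot region, normalized
  between per-run pure-THC and pure-CBN references, then mapped to a
  CBN fraction by piecewise-linear interpolation fitted on a noiseless
  11-point mixture series at 1 µg total.  Duplicate indices (the flat
  orange limb, where hues within the red sector give identical R−B
  contrast) are merged by averaging.  The CBN curve is selected
  strictly above fraction 0.6; the boundary itself uses the THC curve.
* **Potency.**  The 0.877 coefficient is computed from IUPAC standard
  atomic weights as MW(C21H30O2)/MW(C22H30O4) and rounded to three
  decimals at import.  A potency-weighted variant discounting CBN to
  10% exists but is not the default, keeping the screening statistic
  deliberately conservative.

## Study-scale choices

The spike-recovery experiment uses 8 spike volumes
(0–0.6 mL of a stock at 1000/300/50 µg/mL THCA/THC/CBN) × 3 replicates
× 2 sets; the paired sets share each plate (sample lanes side by side
plus the reference lane).  The stock was chosen so the top level loads
2.0 µg THCA (the upper end of the linear range), true total THC
potential spans 0–0.74% of dry weight, and the stock's CBN/(THC+CBN)
of 0.14 keeps it in the THC-curve regime.  These sizes run the full
experiment, including calibration, in about a minute on one CPU.

## Known limitations

* The R−B index is not amount-invariant: saturation scales (R−B)
  directly, so the index drifts for spots far from the 1 µg total at
  which the mixture lookup is calibrated.  The binary curve decision is
  robust in practice, but the *fraction estimate* is coarse off-scale,
  and borderline samples (fraction ≈ 0.6) at unusual loads may flip.
* 8-bit quantization leaves a small positive floor on faint-spot
  signals (≈0.001 saturation), visible as a slightly positive
  calibration intercept and a noiseless end-to-end linearity of
  r² ≈ 0.9986 rather than 1.
* One olivetol spot per plate is a single point estimate of the
  development gain; its own jitter enters every normalized signal on
  that plate.  Replicate plates are the only averaging over this term,
  exactly as in the physical assay.
* THC and CBN cannot be deconvolved from the combined spot; only their
  sum is reported, quantified with whichever single-analyte curve the
  classifier selects — an underestimate of up to ~30% of the CBN share
  when the wrong-side curve would have applied.
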