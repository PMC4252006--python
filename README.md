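# ihc-catscore

Quantification of DAB immunohistochemistry (IHC) from brightfield images:
colour deconvolution, Gaussian-mixture conversion of continuous stain
intensity to categorical pathology scores, nuclear positivity counting,
decalcification time-course statistics, and scanner histogram comparison —
all exercisable end to end on synthetic H-DAB images with known ground truth.

## Who this is for

Digital-pathology and image-analysis researchers who measure biomarker
expression (ER, PR, Ki-67, p53, HER2, …) in DAB-stained tissue and need to

* turn continuous per-pixel DAB darkness into the ordinal 0 / 1+ / 2+ / 3+
  grades pathologists use,
* count percent-positive nuclei against a background cutoff,
* quantify pre-analytical artifacts (e.g. decalcification of bone-containing
  specimens) across time points with the appropriate test battery, or
* compare image capture between two slide scanners.

## The model

Brightfield stains absorb light, so stains add linearly in optical density
(OD = −log₁₀(I/I₀)); an RGB pixel is unmixed into hematoxylin, DAB and a
residual channel by inverting the 3×3 matrix of unit stain OD vectors
(Ruifrok–Johnston colour deconvolution). Analysis runs on the DAB channel's
**white pixel intensity** w ∈ [0, 255] — 255 means no stain, low values mean
dark staining.

Positive pixels (w ≤ t₀, with t₀ from Otsu's method or a fixed cutoff such
as 230) are modeled as a three-component Gaussian mixture

  p(w) = Σₛ πₛ N(w; μₛ, σₛ),  s ∈ {strong, moderate, weak},

fitted by expectation-maximization with a k-means initialization. The two
intersections of adjacent weighted component densities give the category
thresholds t₁ (strong/moderate) and t₂ (moderate/weak). A nucleus is
positive iff its mean DAB white intensity is ≤ t₀; a region's continuous
score is

  score = 1·f_weak + 2·f_moderate + 3·f_strong ∈ [0, 3],

where fₛ are the category fractions of its (by default positive) cells.
For decalcification studies, measurements at 0/1/6/24 h are normalized to
time zero per case and compared by one-way ANOVA (confirmed by Welch's ANOVA
on ranks) with Tukey HSD pairs, or Kruskal–Wallis with pairwise Wilcoxon
rank-sum tests at the Bonferroni level 0.05/6 ≈ 0.0083 for non-normal
markers.

## Worked example

Simulate a 1024² field with 500 nuclei (65% DAB-negative, positives drawn
from a mixture with means 40/130/205), calibrate thresholds on it, and score
it:

```bash
ihc-catscore simulate image --config spec.yaml --seed 7 --out sim
ihc-catscore calibrate sim/image.tif --t0 230 --out thresholds.json
ihc-catscore score sim/image.tif --thresholds thresholds.json --out measurements.csv
```

The calibration recovers the generating mixture (fitted means 36.9 / 129.3 /
202.7 against true 40 / 130 / 205) and emits `t1 = 74.0`, `t2 = 178.6`
(analytic intersections of the generating mixture: 74.7 and 178.9).
`measurements.csv` then reads:

```
region  n_cells  n_negative  n_weak  n_moderate  n_strong  frac_weak  frac_moderate  frac_strong  pct_positive  mean_intensity   score
     1      500         327      40          89        44     0.2312         0.5145       0.2543          34.6        122.0851  2.0231
```

34.6% of nuclei measured positive against the 35.0% ground truth, and the
fraction-weighted score 2.02 summarizes the mostly-moderate staining.

A decalcification time course with a programmed 15% drop at 1 h plateauing
at 20%:

```bash
ihc-catscore simulate timecourse --seed 7 --out tc.csv
ihc-catscore decal-stats tc.csv --marker ER --out stats.json
```

reports normalized group means 100 / 85.4 / 79.4 / 79.9 %, ANOVA
F = 212.2 (p = 3.4e-21), Tukey 0 h vs 1 h p < 0.0001 (significant) and
6 h vs 24 h p = 0.96 (not significant) — the drop-then-plateau pattern.

## Layout

| module | contents |
|---|---|
| `ihc_catscore.stains` | OD transform, colour deconvolution, white-intensity mapping |
| `ihc_catscore.categorization` | Otsu t₀, 1-D k-means, EM mixture fit, intersection thresholds, categorization |
| `ihc_catscore.quantify` | nucleus segmentation, positivity, region measurement, score, %CV, baseline normalization |
| `ihc_catscore.decal_stats` | ANOVA, Welch-on-ranks, Tukey HSD, Kruskal–Wallis, Wilcoxon/Bonferroni |
| `ihc_catscore.scanner` | channel histograms, zone areas, intensity correspondence |
| `ihc_catscore.synthetic` | ground-truthed image / sample / time-course generators |
| `ihc_catscore.io`, `.config`, `.cli` | formats, run configuration, `ihc-catscore` CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
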