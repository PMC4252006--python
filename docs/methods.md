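# Methods

## Stain separation

The forward model is Beer–Lambert: a pixel's optical density
OD_c = −log₁₀((I_c + ε)/I₀) (c ∈ {R, G, B}, I₀ = 255, ε = 1/255 guarding
log 0) is a non-negative linear combination of unit stain OD vectors.  The
default vectors are the published hematoxylin (0.650, 0.704, 0.286) and DAB
(0.268, 0.570, 0.776) triplets; the residual column is completed as
rᵢ = √(1 − hᵢ² − dᵢ²) and normalized, which keeps every entry non-negative
(the raw cross-product completion does not).  Deconvolution is an exact 3×3
linear solve per pixel; negative concentrations from noise are preserved for
diagnostics and clipped only when mapping to white intensity
w = round(clip(255·10^(−max(c,0)), 0, 255)), the exact single-stain inverse
of the OD transform, so the 0–255 semantics of the input image carry over to
each stain channel.  Vendor deconvolution implementations are proprietary;
equivalence is claimed only to the published optical-density method, and the
vectors are a configuration item because instruments differ.

## Background threshold t₀

`global_threshold` maximizes between-class variance over all 255 candidate
cuts (Otsu), with the low class defined as w ≤ t.  Ties are broken toward
the smallest threshold.  The argmax is decided in exact rational arithmetic
(a float pre-pass narrows to near-tie candidates, then exact comparison), so
the result is reproducible bin-for-bin even on histograms with exact variance
ties — quantized 8-bit data produce such ties routinely.  A fixed cutoff
(conventionally 230 on the white-intensity axis) can be supplied instead; a
single-occupancy histogram returns its only bin with a degenerate-data
warning.

## Mixture model and category thresholds

Positive-pixel white intensities are modeled as a k = 3 Gaussian mixture —
one component per staining category.  EM runs on the value histogram
(`np.unique` with counts), mathematically identical to per-observation EM
for quantized data and much faster on megapixel fields.  Defaults:
tol = 1e-6 on the absolute log-likelihood change, max_iter = 500,
initialization from deterministic quantile-seeded 1-D k-means (so the
default run needs no seed; passing one enables randomized initialization).
σ is floored at 0.5 grey levels and component weights at 1e-4; a collapsing
component is re-initialized once and then reported as an error, since such
data genuinely support fewer components.  The log-likelihood is
non-decreasing at every iteration and asserted as such in tests.

Thresholds t₁ and t₂ are the intersections of adjacent *weight-scaled*
component densities πₛN(x; μₛ, σₛ) = πₛ₊₁N(x; μₛ₊₁, σₛ₊₁) — a quadratic in
x — taking the root strictly between the two means.  Weight scaling is the
default because the plotted quantity being intersected is the mixture's
component probability density; an unweighted variant is provided.  Under
extreme weight imbalance both quadratic roots can leave the (μₛ, μₛ₊₁)
interval; the code then falls back to the responsibility-equality point by
bisection, which always crosses between the means.  Fits whose thresholds
violate 0 < t₁ < t₂ < t₀ are rejected with a diagnostic rather than
repaired.  Both raw pixel intensities and per-cell mean intensities are
accepted as input; the two give similar thresholds when staining is
per-cell homogeneous.

Category intervals use the "≤ goes to the stronger side" convention —
strong: w ≤ t₁; moderate: t₁ < w ≤ t₂; weak: t₂ < w ≤ t₀; negative: w > t₀
— matching interval scoring schemes quoted as 0–85 / 86–180 / 181–230.

## Quantification

Nuclei are segmented on the hematoxylin white image (Otsu, 8-connected
components, min_area = 20 px default).  A nucleus is positive iff its mean
DAB white intensity is ≤ t₀.  The category of a positive nucleus is that of
its mean positive-pixel intensity — the minimal aggregation that works for
both nuclear and membrane stains, since no membrane segmentation (or
membrane-completeness scoring) is attempted.  Region fractions default to
the positive-cell denominator; the all-cells denominator is an option.  The
region score Σ fₛ·rank(s) is reported as a continuous 0–3 value; mapping to
discrete grades requires user-supplied cut-points because no canonical bin
edges exist.  Region mean intensity offers positive-pixels (default) and
all-pixels modes, as both definitions are in circulation; the mode is
recorded in the output.

%CV is 100·SD/mean with the sample SD (ddof = 1) across the fields of one
slide.  Baseline normalization divides each time point's field mean by the
case's time-zero field mean, so time zero is exactly 100%.

## Decalcification statistics

One-way ANOVA, Tukey HSD, Kruskal–Wallis and the Wilcoxon rank-sum test
delegate to scipy.stats; Welch's ANOVA (applied to mid-ranks of the pooled
sample) is implemented from the standard formula because scipy lacks it, and
is cross-checked against an independent implementation in the tests.  Tests
are two-sided.  The rank-sum tests use the exact null distribution for
combined n ≤ 20 without ties and the tie- and continuity-corrected normal
approximation otherwise.  Kruskal–Wallis additionally offers an exact
permutation p-value for tiny samples (total n ≤ 10) where the chi-square
approximation is poor.  The Bonferroni level for pairwise comparisons of
k = 4 time points is 0.05/6 ≈ 0.0083.  With baseline-normalized data the
time-zero group is constant, so Welch-on-ranks is flagged degenerate there
(its weights are inverse variances); the primary pairwise inference in that
setting is Tukey's.  Case/field hierarchy is not modeled (no mixed
effects); groups are treated as independent samples of slide-level values.

## Synthetic data

`generate_ihc_image` renders non-overlapping elliptical nuclei (axes uniform
in 6–12 px, random orientation, ≥ 2 px separation enforced via an inflated
occupancy footprint; rejection sampling gives up after 100 attempts per
nucleus and reports how many were placed).  Defaults emulate a calibration
field of view: 2,048² px, 2,000 cells, 65% DAB-negative (i.e. 35% positive,
a typical baseline for a proliferation marker), positive intensities drawn
from the mixture π = (0.3, 0.4, 0.3), μ = (40, 130, 205), σ = (15, 25, 12)
clipped to [0, 230], hematoxylin white 120 ± 8 (a visibly stained
counterstain), background 255.  The negative count is deterministic
(round(fraction·n)) so the realized positive fraction equals the requested
one exactly.  Composition uses the same Beer–Lambert forward model and stain
vectors as the analysis, so deconvolution inverts the generator; quantization
to uint8 uses dithered rounding (floor(x + u), u ~ U[0,1)), which is
unbiased, so per-cell mean intensities are recovered within ±1 grey level
even at zero noise — deterministic rounding would leave a systematic offset
of up to ~1.3 grey levels because all pixels of a cell share one value.
Optional pixel noise is i.i.d. Gaussian added in RGB before quantization.
Everything is bit-reproducible given the seed.

What the generator does **not** emulate: tissue texture, membrane staining
patterns, nucleus shape irregularity, spatial correlation of staining
(categories are assigned i.i.d. per cell), chromatic scanner aberrations.
Passing tests therefore demonstrate correctness of the measurement chain on
its own forward model, not robustness to real-tissue morphology.

`generate_timecourse` draws case baselines N(150, 20) and multiplies by
per-time effects with multiplicative Gaussian field noise, matching the %CV
framing of between-field heterogeneity.  Defaults are the study design the
package targets: 9 cases × 5 fields at 0/1/6/24 h, effects
(1, 0.85, 0.80, 0.80) — a 15% drop at 1 h plateauing at 20% — and 5% field
CV, inside the 0.2–11% heterogeneity band reported for such data.

## Problem sizes and numerical choices

The test suite runs the mixture-recovery checks at n = 10⁴ samples, the
Otsu-vs-exhaustive check at 1,000 random histograms, the pattern-detection
check at 100 seeded time-course replicates, and the end-to-end image check
on one default 2,000-cell field — sizes at which every estimate under test
is stable.  EM monotonicity is asserted to −1e-8 (floating-point slack);
deconvolution round trips to 1e-9; intersection closed forms to 1e-9 and
grid searches (step 0.001) to 0.01.

## Known limitations

* No stain-vector estimation from the image; wrong vectors silently bias
  the DAB channel.
* No colour normalization between scanners; the comparison module measures
  differences, it does not correct them.
* Region polygons are rasterized by pixel-center containment (even-odd
  rule); sub-pixel region boundaries are not supported.
* The continuous score's mapping to clinical grade bins is user-supplied.
* Whole-slide formats (.svs and relatives) are out of scope; inputs are
  8-bit RGB PNG/TIFF tiles.
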