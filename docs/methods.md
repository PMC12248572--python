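# Methods

## Estimator

The multifractal estimator follows the classical moment (Legendre) route
on a fixed box grid.

**Box measure.** Boxes of side ε are anchored at the top-left pixel;
partial boxes at the right/bottom edges are kept with their true content.
For a binary mask the measure of a box is its white-pixel count divided by
the total white-pixel count; the grayscale path (used for cascade mass
maps) divides the summed intensity by the total intensity.  Empty boxes
are omitted, so negative-order moments are always finite; an image with no
foreground raises `EmptyMeasureError` rather than producing NaNs.

**Scale schedule.** Default: dyadic, from the largest power of two not
exceeding half the shorter image side down to `min_box = 4` pixels (six
scales at 256², five at 243²).  At least four scales are required for the
regressions.  Constructions with a different natural base can pass an
explicit schedule — the Sierpinski carpet analysed with powers of three is
an exactly uniform measure at every scale, which the test suite uses as a
machine-precision oracle.  Halving the number of scales moves the carpet
D_0 by under 0.03, so the default schedule is not a tuned quantity.

**Moment grid.** q runs from −5 to +5 in steps of 0.25 (always containing
0, 1, 2 exactly, enforced by integer construction of the grid).  The grid
is symmetric because the spectrum's left branch (q > 0, concentrated
boxes) and right branch (q < 0, sparse boxes) are both needed for the
width and shift descriptors.

**Fits.** For q ≠ 1, D_q is the OLS slope of log Σ p^q versus log ε
divided by (q − 1); at q = 1 the entropy sums Σ p log p replace the log
moments and the slope itself is D_1.  The per-q coefficient of
determination is kept as a diagnostic.  τ(q) = (q−1) D_q is differentiated
by central finite differences (one-sided at the grid ends) to obtain α(q),
and f = qα − τ.

**Landmarks.** f(α) attains its maximum at q = 0, where f = −τ(0) = D_0
identically; the implementation reads f(α)_max and (in the default
`argmax_f` mode) α_center at q = 0.  This makes the f(α)_max = D_0
identity exact on every input — matching the fact that the two columns are
identical in published feature tables — instead of fluctuating with
estimation noise when the empirical τ is not perfectly concave.  A
`midpoint` mode for α_center ((α_min + α_max)/2, which makes the symmetric
shift identically zero) is exposed because published per-image tables are
ambiguous between the two conventions; the default follows the stated
definition (α at the spectrum peak).

**Numerical behaviour.** For measures with exact scale invariance (filled
square, aligned carpet, multiplicative cascades) the fitted D_q is
monotone non-increasing in q to machine precision.  On noisy masks the OLS
slopes can wiggle by ~1e−4 at |q| ≥ 4.5; this is genuine estimation
variance, not a numerical defect, and is surfaced as the
`monotone_violation` diagnostic on the results object (an α inversion
above 0.02 additionally triggers a warning).  Note that D_q for q < 0 may
legitimately exceed the embedding dimension 2 on concentrated measures;
the D_q ≤ 2 bound applies to the non-negative branch only.

## Preprocessing

The conditioning chain is blur → CLAHE → threshold, in that order, and is
fully deterministic.

* **Gaussian blur**, σ = 2 px: sampled Gaussian kernel truncated at 4σ and
  renormalized to unit sum (constants are reproduced exactly; the mean is
  conserved away from borders), reflect padding.
* **CLAHE**: tile size 127, 256 histogram bins, contrast cap expressed as
  a max mapping slope of 3.  The implementation clips the tile histogram
  at `slope/nbins` of the tile pixel count, which is how a slope cap
  translates into the histogram-clip convention of the underlying
  scikit-image routine.  Reflect padding again avoids dark-frame
  artifacts that would otherwise distort box counts along the borders.
* **Threshold**: Otsu's criterion on the enhanced image by default
  (parameter-free and reproducible), foreground strictly above the
  threshold; a fixed threshold can be forced.  A constant image yields an
  all-background mask with a warning rather than an error.
* **Batch processing** walks a directory in sorted filename order,
  accepts `.png/.tif/.jpg`, writes `<stem>_processed.png`, counts skipped
  non-image files, and logs unreadable files instead of aborting.  Images
  are not resized.

## Synthetic ground truth

The package ships its own oracles because the downstream statistics are
only trustworthy if the estimator can be checked against known answers.

* **Filled square** — D_q = 2 for all q; exact on the dyadic schedule.
* **Sierpinski carpet** — foreground count exactly 8^level; similarity
  dimension log 8/log 3 ≈ 1.8928.  On the dyadic schedule the estimate is
  ≈ 1.883 (box grid incommensurate with the ternary construction); on the
  ternary schedule it is exact.
* **2D binomial cascade** — each 2×2 subdivision multiplies by the outer
  product of independent row and column (p, 1−p) splits with seeded random
  orientation, i.e. the product measure of two 1D dyadic cascades.  Hence
  τ_2D = 2·τ_1D and D_q = 2·log2(p^q + (1−p)^q)/(1−q) (twice the binary
  entropy of p at q = 1); α(q) and the finite-grid width α(−5) − α(5)
  follow in closed form.  Mass is conserved to 1e−9 at every level.  On
  aligned dyadic boxes the partition sums scale exactly, so the estimator
  reproduces the closed form to machine precision — this is the package's
  strongest end-to-end oracle.  The median-threshold binarization
  (`binarize_mass_map`) keeps the foreground fraction at one half at any
  level, giving a scale-free binary view for the white-pixel path.
* **Random quadrant dust** — keep k of 4 children per halving step;
  D_0 = log2 k, with exactly k^level surviving cells.

### Retinal phantoms

The phantom generator emulates what the real pipeline sees in OCT
B-scans, not their photometric physics.  A phantom is a stack of
alternating bright/dark horizontal bands (jittered edges and intensities,
8-bit) over a dark background, with additive Gaussian speckle
(σ = 8 gray levels).  Two mechanisms inject class-dependent multifractal
structure, both scaled by `cascade_heterogeneity` (DR default 0.65,
Normal default 0.05):

* **bright-layer texture disruption** — the bright bands are multiplied by
  a smoothed multiplicative-cascade field (weight p = 0.5 + 0.3·het,
  amplitude 0.8·het), carving intensity dips that survive thresholding and
  depress D_I, D_C and α_min for DR;
* **debris specks** — ⌊60·het^1.5⌋ small bright foci (radius 2–3 px)
  placed in the dark regions at positions drawn from a coarse cascade
  measure (clustered, as hyper-reflective foci are).  After blur, CLAHE
  and Otsu these isolated specks dominate the sparse (negative-q) tail of
  the box measure and are the main driver of the wider DR spectrum.

DR phantoms additionally receive six lesion-like dark elliptical blobs.
Two design findings are deliberately baked in: layer boundaries are flat
and horizontal because smooth oblique boundaries contribute a curve-like
(1-D) measure whose thin slivers against the box grid saturate α_max for
both classes; and dark-band intensities stay well below the Otsu cut
because bands near the threshold turn into CLAHE-amplified salt that
likewise swamps the sparse tail.

What the phantoms do **not** reproduce: real speckle statistics, curved
retinal geometry, vascular shadows, device-dependent intensity scales, or
the absolute descriptor values of clinical datasets (phantom D_B ≈ 1.79
versus ≈ 1.999 for real OCT masks, because the phantom background is
empty where real scans carry noise floor everywhere).  Passing tests
therefore demonstrate that the pipeline measures designed heterogeneity
correctly and that the descriptors carry class information through the
full chain — not that any particular clinical accuracy is attainable.

### Statistical feature tables

`sample_feature_table` draws the nine descriptors from class-conditional
independent Gaussians whose equal-weight merge reproduces published global
summary moments per column (means such as Δα = 1.0941) exactly in
expectation; class mean offsets are qualitative (wider spectra, higher
α_max/α_center, more negative shift for DR) since per-class moments were
never published numerically.  `f_alpha_max` duplicates the `Db` column row
by row.  The deterministic identities between descriptors (width =
α_max − α_min, shift = center − midpoint) are *not* imposed on sampled
rows: the published global moments are mutually inconsistent with those
identities (the mean center equals the mean midpoint while the mean shift
is −0.23), so a sampler cannot satisfy both; these tables are meant for
classifier benchmarking, where only the marginal structure matters.

## Evaluation protocol

Stratified 5-fold cross-validation (shuffled, seeded; with k = 5 each test
fold is 20% of the data and per-fold class counts are within one of exact
proportion).  Features are z-scored with training-fold statistics only;
constant features pass through unscaled with a warning.  The positive
class is DR.  Metrics follow the standard confusion-count definitions;
zero-denominator cases are reported as NaN with a warning, never coerced
to 0.  Aggregation reports fold means, a Student-t 95% CI of the accuracy
(k−1 degrees of freedom — the standard choice for CV folds), and a
one-sided one-sample t-test of the fold accuracies against the 0.50 chance
level; with zero fold variance the CI collapses to a point and the
p-value is 0 or 1 by the sign of the mean difference.

Classifier presets are fixed (not re-tuned): logistic regression
(liblinear, L2, C = 1), random forest (100 trees, depth 10), decision tree
(depth 5, entropy), SVM (poly degree 3, C = 1, probability output),
gradient boosting (100 × depth 3, lr 0.1), XGBoost (100 × depth 4,
lr 0.1, logloss), LightGBM (100 × depth 5, lr 0.1), and an MLP with hidden
layers (128, 64), ReLU activations, sigmoid output, Adam, at most 1000
iterations and random state 42 (the package-wide default seed).  The two
boosted-tree presets are backed by the xgboost and lightgbm libraries; the
other six by scikit-learn.  Non-convergence at the iteration cap is logged,
not fatal.

## Problem sizes and determinism

Default study sizes keep a full synthetic experiment light: 100 phantoms
per class at 256², six dyadic scales and a 41-point q grid — feature
extraction for the 200-image study takes seconds, and the eight-model
benchmark under a minute on one CPU.  Every stochastic step (phantom
geometry, cascade orientations, speck placement, fold shuffling, model
initialization) flows from explicit integer seeds; library calls that omit
a seed fall back to the documented default 42.  Identical inputs and
configuration reproduce byte-identical artifacts.

## Known limitations

* The moment/Legendre route needs an (approximately) concave empirical
  τ; direct Chhabra–Jensen estimation, wavelet leaders and MFDFA are out
  of scope, as are 3D volumes and sliding-window local spectra.
* Finite-size effects bias the carpet's dyadic-box estimate low by ≈ 0.01;
  closed-form comparisons in the tests use tolerances (0.05 on dimensions,
  0.1 on widths) that cover this, not hide it.
* Binary box counting discards intensity gradation; the mass-map path is
  provided but the white-pixel convention is the default throughout.
* Phantom realism is deliberately limited (see above); conclusions about
  clinical OCT data require clinical images.
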