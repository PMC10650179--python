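# Methods

`afmtex` classifies cervical epithelial cells as precancerous
(HPV-immortalized) versus cancerous (carcinoma-derived) from atomic-force
microscopy adhesion maps: per-pixel rasters of the pull-off force between
the AFM probe and the cell surface, recorded in subresonance tapping.
One 10 × 10 µm² map at 512 × 512 pixels represents one cell. This note
records the model, the numerical choices, and what the synthetic data do
and do not establish.

## Units and conventions

The texture parameters mix force and length dimensions, so their values
depend on the unit system. The package fixes **adhesion in nN and lateral
coordinates in nm** at load time and applies it everywhere; rescaling the
input demonstrably changes Sdr, Sdq and Spk (covered by a test).

Grids are stored row = y, column = x, origin top-left. Pixel spacing uses
the sample-point convention `dx = scan_width / (n_cols − 1)`; a 512-pixel,
10 µm scan has dx ≈ 19.57 nm. Spacing is what the slope and frequency
formulas index, so the convention is stated once and never varied.

## Quadrant protocol and quality control

Each map is split into four equal quadrants (256 × 256 for a full scan),
each parameter is computed per quadrant, and the per-cell value is the
mean over retained quadrants. The QC rule compares the mean and the median
of the four per-quadrant values: relative difference
`|mean − median| / |median|` (the median being the robust baseline the
rule defends), flagged for review above 50 %. A localized artifact — a
piece of dirt on the cell or on the probe — inflates one quadrant and
trips the rule; Spk is the most sensitive parameter in practice. The
automated stand-in for manual inspection (`qc_auto_exclude`) drops the
single most deviant quadrant, re-checks, and repeats at most twice; it is
off by default, so the default behaviour is flag-and-keep. The rule is
applied per parameter: any failing parameter flags the cell.

## The six surface parameters

* **Sdr (surface area ratio, %)** — excess of the true interfacial area
  over the projected flat area. Each pixel cell contributes a
  quadrilateral facet area `A_kl = ¼ [√(δy²+Δzy0²)+√(δy²+Δzy1²)] ·
  [√(δx²+Δzx0²)+√(δx²+Δzx1²)]`, with Δzy the value differences along y on
  the cell's two x-edges and Δzx the differences along x on its two
  y-edges (the y-segments live under δy radicands and the x-segments
  under δx; the two coincide for square scans). A uniformly tilted plane
  of unit slope gives the closed form (√2 − 1)·100 %, which the tests
  assert, and a naive double-loop implementation serves as the oracle on
  small grids.
* **Sdq (RMS gradient)** — root mean square of backward-difference slope
  magnitudes. The sum runs over the (M−1)(N−1) interior sample points
  where both backward differences exist, normalized by that count; a
  plane z = x gives exactly 1, z = x + y gives √2.
* **Spk (reduced summit height, nN)** — from the bearing-area
  (Abbott–Firestone) curve: height versus the fraction of the surface at
  or above that height. The curve is evaluated at 0.1 % bearing-ratio
  steps; among all 40 %-wide sliding windows a least-squares line is
  fitted (running-sum formulation) and the window with the smallest
  absolute slope kept, earliest window on ties. That core line is
  extrapolated to 0 % and 100 %; the horizontal line through its 0 %
  height is intersected with the curve, and the peak material between
  curve and line is replaced by a right triangle of equal area (trapezoid
  integration, closed-form solution) based at the intersection abscissa.
  Spk is the triangle height. Degenerate single-level surfaces return 0
  with a warning. An independent direct-geometry oracle (brute-force
  window search, fine-grid integration) agrees to 1e-6 nN on staircase
  surfaces.
* **Sfd, Sfd_top, Sfd_bottom (spectral fractal dimensions)** — from the
  2-D DFT with 1/(NxNy) normalization (Parseval: Σ|F|² = grid variance),
  amplitudes |F| averaged in annular bins one fundamental frequency wide
  (bin centre = mean Q of contributing modes, zero frequency excluded),
  then a least-squares line of log A versus log Q: `A(Q) ~ Q^b`, fractal
  dimension `2 − b`. Sfd_top is fitted over features larger than 300 nm
  (Q < 1/300 nm⁻¹), Sfd_bottom over smaller features (Q ≥ 1/300 nm⁻¹ up
  to Nyquist), and the full-band Sfd from the second radial bin to 80 %
  of Nyquist — the first bin and the corner-contaminated top of the band
  carry the largest estimation bias. Bands are half-open `[q_min, q_max)`.
  The grid mean is subtracted before transforming (removes only the
  zero-frequency spike); Hann windowing and power-spectrum (|F|²)
  averaging exist as flags, both off by default, the default following
  the amplitude-spectrum reading of `A(Q)`. Note the exponent and hence
  the fd value differ by convention between amplitude and power
  averaging; all defaults here are amplitude-based.

A practical resolvability constraint: for a 10 µm scan the 1/300 nm⁻¹
crossover lies inside a *quadrant's* frequency band only for parent grids
of at least 128 px. Constant maps have an identically zero spectrum; their
fractal fits are reported as failures (NaN) and such cells are excluded
before classification.

## Synthetic cohorts

The generator targets exactly the statistical structure the estimators
consume, nothing more: inverse-FFT spectral synthesis shapes Gaussian
white noise with a two-segment power-law amplitude profile, continuous at
the crossover (no spectral step), then rescales to a target RMS, offsets
to a mean adhesion and clips at 0 nN (adhesion force is nonnegative).
Defaults are one full-scale map: 512 px, 10 µm, crossover 1/300 nm⁻¹.
Because the method reports no absolute adhesion scale for these cells,
the amplitude defaults (mean 1 nN, RMS 0.3 nN) are plausible placeholders
and configurable; the texture parameters that drive classification are
scale-covariant, so the choice shifts but does not reorder the classes.

Cohorts default to 108 precancerous + 64 cancerous cells, the class
imbalance of a realistic screening cohort. Class templates differ in
their spectral exponents — precancerous (b_low, b_high) = (−0.5, −0.9),
cancerous (−0.8, −1.2), i.e. cancerous surfaces carry relatively more
large-scale roughness and a higher fractal dimension, consistent with
reported fractality increases along the progression to cancer. Per-cell
Gaussian jitter (SD 0.1, applied to both exponents and the RMS) makes the
classes overlap without destroying separability; the jittered RMS is
floored at 10 % of nominal so no cell degenerates to a flat map. One
cohort seed deterministically spawns independent per-cell seed sequences,
so cohorts are bit-reproducible while cells stay independent. Optional
Gaussian bumps (σ = radius/2) emulate dirt artifacts for QC testing.

What the generator does **not** emulate: AFM tip–sample mechanics, scan
artifacts other than isolated bumps (line noise, drift, bow), spatial
nonstationarity across a cell, correlations between cells from the same
patient line, and any biochemical ground truth. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it
assumes and is internally calibrated — not that real cervical cells are
classifiable at any particular accuracy.

## Classification and validation

The six-feature table is split into stratified train/test subsets
(default 70/30; per-class floor on the training side, so 172 cells yield
119 train / 53 test), a random forest is fitted on the training subset
and scored on the held-out cells, and the split is redrawn K = 500 times;
means and standard deviations of AUC, accuracy, sensitivity and
specificity are reported. Forest hyperparameters are standard defaults —
100 trees, square-root feature sampling, leaf size 1 — all exposed in
configuration. Stratification is used because the 64/108 imbalance would
otherwise occasionally produce near-single-class test sets across 500
draws. The positive class is "cancerous"; scores are the forest's
predicted probability of cancer.

ROC curves sweep all score thresholds; tied scores move the operating
point diagonally in one step, which makes the trapezoid-rule area equal
to the tie-aware pair-concordance (Mann–Whitney) statistic exactly — the
tests verify the identity to 1e-12 against a brute-force pairwise oracle.
Confusion-matrix entries are reported as class-normalized rates
(TP + FN = 1, TN + FP = 1) at the 0.5 probability threshold; accuracy
uses raw counts.

**Shuffle null.** The overtraining control trains on the true training
labels and randomizes only the test-set labels, K = 500 times. The
default randomization draws each test label independently and uniformly
from the two classes, under which AUC and accuracy have expectation
exactly 50 % for any classifier (null sensitivity and specificity
instead converge to the classifier's positive-prediction rate p̂ and
1 − p̂, which is near 50 % only for a classifier with balanced
predictions); a
permutation variant (preserving the class multiset, and hence leaving
expected null accuracy at p² + (1−p)² ≈ 53.5 % for a 108/64 cohort whose
classifier tracks the prior) is available as `null_method="permute"`.
Significance of the actual-versus-null separation is assessed by one-way
ANOVA on the two AUC samples; for two groups F is the square of the
pooled-variance t statistic, which the tests check.

**A calibration subtlety.** For a single finite cohort with *no* class
signal, the mean test AUC over repeated splits does not centre on 0.5: it
centres on that cohort's own chance empirical association (training and
test subsets of a fixed pool are negatively dependent, and the cohort's
sampling noise is itself a weak "signal"). Measured on 172-cell noise
cohorts the cohort-level mean ranges roughly 0.44–0.54. Chance-level
calibration is therefore a property of the cohort *ensemble*: the
no-signal test averages splits over ten independently generated cohorts,
whose grand mean is 0.5. The shuffled-label null does not suffer from
this effect, because randomizing labels severs the association entirely
— which is precisely why it is the appropriate significance control.

## Problem sizes used in the shipped tests

The test suite runs the validation protocol at full cohort scale
(172 cells, K = 500) but generates test cohorts at 256 px (separated
cohort) and 128 px (no-signal ensemble, half-scale 54 + 32 cells), the
smallest grids on which all six parameters are resolvable; spectral
recovery checks use full 512 px grids. The acceptance script
(`scripts/acceptance.py`) runs everything at full scale: 512 px maps,
172 cells, K = 500.

## Known limitations

* Spk depends mildly on the 0.1 % bearing-curve discretization and the
  first-window tie-break; both are fixed and documented rather than
  estimated.
* The full-band limits for plain Sfd (second bin to 80 % of Nyquist) are
  a convention; alternatives shift Sfd by a few hundredths.
* Radial binning assumes isotropic sampling; non-square maps are
  rejected rather than resampled.
* The classifier wrapper delegates to a standard random-forest
  implementation; exact per-tree behaviour (and hence per-split scores)
  is tied to that implementation's versioned RNG semantics, though all
  summary statistics are seed-reproducible within a version.
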