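# Methods

## Scope and model

floodqc implements the NEMA NU 1-2018 intrinsic-uniformity computation for
gamma-camera flood-field images and the statistical layer used to compare
uniformity readings across QC software. A flood image is a 2-D count matrix
with square pixel spacing; the package is agnostic to how it was acquired and
reads single-frame DICOM or a plain CSV dialect. All computations are
deterministic functions of the image and an `AnalyzerConfig`.

## Pixel-size gate and rebinning

The gate checks the mean of the (row, col) spacing against the closed window
`nominal_mm · (1 ± tol_fraction)`, defaults 6.4 mm and 0.30 (4.48–8.32 mm).
Spacing must be square within 1% or a geometry error is raised. For a pixel
finer than the window the suggested rebin factor is the smallest integer
k ≥ 2 with k·pixel inside the window; sum-rebinning merges k × k blocks,
multiplies the spacing by k, drops trailing rows/columns that do not fill a
block, and records the dropped count total. Counts over full blocks are
conserved exactly. A pixel coarser than the window only warns: enlarging
counts cannot be undone by rebinning, so reduction is not executed.

## Field-of-view masks

The UFOV starts as the strictly positive pixels within their bounding box
(zero pixels inside the box are excluded from the start — they carry no
signal and would poison max/min statistics). Then, iteratively:

1. the CFOV is the sub-rectangle spanning `cfov_fraction` (default 0.75) of
   the UFOV bounding box's height and width, rounded to the nearest integer
   (ties up), centered with any odd excluded margin pushed to the
   bottom/right, and intersected with the UFOV mask;
2. UFOV edge pixels (4-connectivity boundary, including the matrix border)
   with counts below `edge_threshold_fraction` (default 0.75) of the CFOV
   mean are removed.

The mask shrinks monotonically, so the iteration reaches a fixed point; a
single pass would leave threshold-dependent stragglers. The defaults are the
conventional 75%/75% parameters of the standard protocol and are exposed as
configuration because console implementations are not observable. Degenerate
inputs fail loudly: an all-zero image raises an empty-FOV error and a UFOV
bounding box under 5 × 5 pixels raises a too-small error (the five-pixel
differential window would be undefined).

## Smoothing and uniformity statistics

Smoothing is a masked weighted mean with the nine-point kernel
[[1,2,1],[2,4,2],[1,2,1]] (sum 16): each in-mask pixel becomes
Σ w·c over its in-mask 3 × 3 neighbourhood divided by the sum of the weights
actually used. Renormalization — rather than zero padding — is essential at
mask edges: padding would fabricate cold edge pixels and inflate uniformity.
The kernel is validated (3 × 3, non-negative, flip-symmetric, center
maximal) and configurable.

Integral uniformity is `100·(max − min)/(max + min)` over in-mask pixels of
the smoothed image. Differential uniformity scans every run of exactly
`window` (default 5) contiguous in-mask pixels along rows (x) or columns (y)
and reports the worst windowed contrast plus the number of windows
evaluated; windows touching an out-of-mask pixel are skipped, never
shortened, because the statistic is defined for fixed-length windows. Both
require strictly positive in-mask values (guaranteed by the mask
construction; violation raises a data error rather than silently producing
a contrast > 100%). These definitions force two orderings used as
invariants: DU ≤ IU on the same mask, and IU_CFOV ≤ IU_UFOV because the
CFOV extrema are a subset of the UFOV extrema over one common smoothed
image.

`analyze_flood` chains gate → optional rebin → masks → smoothing → the six
statistics, and stores every parameter, the applied rebin factor, and the
mask sizes in the result's provenance. Reports print percentages at 2
decimals; full precision is kept internally.

## Agreement statistics

Percentage deviation between two software readings of the same images
defaults to point differences `d_i = b_i − a_i` (both readings are already
percentages); a relative mode `100·(b−a)/a` is available. The default was
chosen because observed between-software gaps in uniformity comparisons are
naturally expressed in percentage points; neither convention is asserted as
the only valid one.

The Mann–Whitney U test uses midranks, U for the reference group
(`U = R_a − n_a(n_a+1)/2`), the tie-corrected variance
`σ² = (n_a n_b/12)·((N+1) − Σ(t³−t)/(N(N−1)))`, and `z = (U − n_a n_b/2)/σ`
with a two-sided normal p. No continuity correction is applied by default:
for two groups of 10 with complete separation the uncorrected z is −3.7796
(−3.780 at three decimals) while the corrected value is −3.742; the
uncorrected convention is the one matching reported practice for this
comparison design. An all-tied pool raises a degenerate-variance error. The
normal approximation is anticonservative below roughly n = 8 per group;
exact permutation is out of scope and covered only as a test oracle.

Bland–Altman limits: classic mode is `mean(d) ± k·sd(d)` (k = 1.96). The
regression mode fits OLS of d on the pair means m for the bias line D(m),
then OLS of |residuals| on m for a spread line R(m), and sets the limits to
`D(m) ± k·√(π/2)·R(m)` — the √(π/2) factor converts the mean absolute
deviation of a normal variable to its SD. The half-width line is floored at
zero when evaluating limits. Regression mode requires n ≥ 4 and non-constant
pair means (a collinear design raises an error and the study layer falls
back to classic mode). Note an intrinsic property of this construction: if
the comparison method differs by a component proportional to the *reference*
reading (`b = a + β₀ + β₁·a + ε`), the slope recovered against the pair mean
is attenuated to `β₁/(1 + β₁/2)` and the intercept to `β₀/(1 + β₁/2)`,
because the pair mean itself contains half the difference. The tests assert
this closed form.

## Synthetic acquisitions

The generator models an acquisition as independent per-pixel Poisson counts
whose mean is uniform over the active area (full rectangle by default, or a
centered circle), modulated multiplicatively by parametric defects and
scaled so the expected total equals `total_kilocounts · 1000`:

- **gradient**: `1 + a·(2t − 1)`, t the normalized coordinate along the
  orientation over the active area — spans exactly [1−a, 1+a], so a
  noiseless gradient flood has analytic UFOV IU = 100a%. The CFOV sees only
  the central `cfov_fraction` of a monotone gradient's span, so its analytic
  IU is correspondingly smaller (the tests check it against a brute-force
  scan of the closed-form field).
- **blob**: `1 + a·exp(−r²/2σ²)` — a hot or weak PMT region.
- **ring**: `1 + a` on an annulus — the canonical ring artifact.

Defects multiply because nonuniformity physically scales with local
sensitivity; each factor is bounded away from zero by the amplitude
constraint |a| < 1 (a defensive check still rejects a non-positive expected
field). Noiseless mode returns the real-valued expected field itself —
integer rounding is deferred to DICOM export so analytic oracle values
survive exactly; CSV keeps reals.

Defaults mirror routine practice: 128 × 128 matrix, 6.4 mm pixels, 20,000
kilocounts. At that geometry a flat flood has ≈1,221 expected counts per
pixel, so the separate count-density recommendation of ≥10,000 counts in the
center pixel (which presumes coarser binning) cannot hold simultaneously
with the total-count stop; the total is treated as binding and the achieved
expected center-pixel count is recorded in the image metadata. Defect
amplitude examples in tests use a = 0.01–0.06, bracketing the <5% tolerance
band typical of clinical acceptance. Most tests run a desk-scale profile
(64 × 64, 2,000 kilocounts, ≈488 counts/pixel) chosen to keep the whole
suite interactive; statistical assertions are sized for the larger noise at
that scale.

What the generator does *not* emulate: PMT-level physics (energy windows,
scatter, spatial linearity maps), detector dead pixels, and — importantly —
the proprietary flat-field/uniformity corrections scanner consoles apply
before their integrated analysis. Passing tests therefore validate the
computation chain and its statistics, not equivalence with any vendor's
corrected output.

`generate_paired_readings` emulates two software readings of the same images
directly at the statistics layer: `b = a + bias + proportional·a + ε`,
ε ~ Normal(0, noise_sd), with reference values defaulting to uniform draws
on [2, 6] % (the range of a passing uniformity test). All generators are
pure functions of (spec, seed) via `numpy.random.default_rng`.

## Study orchestration

`run_study` analyzes every image under a reference configuration and each
named variant, tabulates point-mode percentage deviations (variant −
reference), runs the Mann–Whitney comparison per metric × FOV, fits
regression-based limits of agreement (classic fallback for n < 4 or
collinear means), and applies a tolerance verdict (default: any of the six
values ≥ 5% fails, the scanner-level acceptance limit). Exports are plain
CSV/JSON with fixed float formatting, so a rerun on the same inputs is
byte-identical.

## Known limitations

- UFOV geometry is rectangular-bounding-box based; circular detectors are
  supported through the mask-false mechanism but true detector-shape UFOVs
  (vendor-specified usable areas) are not modelled.
- Only single-frame DICOM is read; multi-frame, energy-window metadata and
  private vendor tags are ignored.
- The Mann–Whitney p is asymptotic; at the typical n = 10 per group it is
  adequate for the complete-separation regime but approximate near the null.
- Agreement statistics assume one reading pair per image (no
  repeated-measures variance decomposition).
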