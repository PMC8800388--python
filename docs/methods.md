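# Methods

## Standardized grayscale

Color frames are reduced to 8-bit gray with the ITU-R BT.601 luma
weights (0.299, 0.587, 0.114), rounded half-to-even so the conversion is
bit-reproducible. Regions of interest are user-declared, 0-based,
half-open pixel rectangles; one ROI per fragment is reused across the
whole series. The standardization G₀ = (G꜀ − G_W)/(G_B − G_W) is exact
under any affine pixel transform that affects coral and strip alike and
does not clip; with 8-bit quantization the residual error is below one
gray level, which is the tolerance used throughout the tests. If more
than 1% of reference-patch pixels sit at 0 or 255 a saturation warning
is attached to the measurement, because clipped references break the
affine cancellation. G₀ outside [0, 1] is legal (coral darker than the
black patch can occur with dark tissue) and is flagged, never clamped.
JPEG gamma is deliberately not inverted: the per-fragment RG%
normalization absorbs most of the residual nonlinearity, and inverting
an unknown camera curve would add a free parameter the protocol cannot
constrain.

## Trajectories and RG%

Times are days since the first photograph of the first heating day,
with the 6 AM / 6 PM sessions at +0.0 / +0.5 d; acclimation points carry
negative times so bleaching times are always measured from heating
onset. Completion is a run of 6 consecutive points (5 successive
differences) with no decrease in G₀ beyond a tolerance (default 0;
exposed because strictly-zero tolerance never terminates on noisy
plateaus). Baselines are the means of the first 5 and last 5 points; by
default the last 5 points of the record are used even if imaging
continued past detected completion, and the completion index can be
passed to truncate instead. Series may be irregular — no imputation is
performed, the curve fit consumes raw (t, RG%) pairs. If the two
baselines agree within 1e-6 the fragment never changed and is rejected
as degenerate rather than normalized into noise.

## Curve fit

The bleaching model is f(t) = y₀ + a·exp(−0.5·|(t − x₀)/b|ᶜ): floor y₀
(RG% when fully bleached, ~0), amplitude a (~100), peak time x₀, width
b in days, shape c. c ≈ 2–5 produces the observed long plateau followed
by a rapid fall. Fitting is bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobian) with a fixed
deterministic multi-start ladder: c ∈ {1, 2, 4} × b ∈ {¼, ½, 1}·span,
with y₀, a, x₀ initialized from the data (min, range, argmax). The
|u|ᶜ cusp at the peak defeats single-start gradient methods for small
c, hence the ladder; the candidate with the smallest SSE wins, so the
fit is deterministic given the data. Bounds: y₀ ∈ [−50, 150],
a ∈ [0, 300], x₀ within one span of the data, b ∈ (1e-3, 10·span],
c ∈ [0.1, 10]. R² is the conventional 1 − SSres/SStot about the
observed mean. The Jacobian entries at u = 0 are set to their one-sided
limit (0), which is also the correct subgradient choice.

A note on identifiability: with a flat top (c ≳ 3), x₀ is only weakly
determined by data that start inside the plateau — individual noisy
fits can place x₀ anywhere under the flat region while b compensates.
The post-peak threshold crossings (the quantity of interest) remain
well determined, and the x₀/b estimators are centred: across 20 noisy
replicates (RG% noise SD 3) the median recovered x₀ and b are within
10% of truth even though individual x₀ draws scatter by ±3 days.

## BTI

BTI at cutoff X is the earliest t at or after the fitted peak where
f(t) = 100 − X, located by bisection to 1e-6 day on the fitted curve
(the regression is the smoother; raw points are not interpolated).
"Decreased by X%" is read as X percentage points below the normalized
100% start, not relative to the fitted peak: RG% is already
per-fragment normalized, and the initial-rise statistic uses the same
100% reference, so drops do too. Starting the search at the peak means
fragments with a transient rise report the falling-limb crossing, the
biologically meaningful one; such records carry a `crossing-after-peak`
flag. Thresholds below the fitted floor, or not crossed inside the
observed span, report not-reached (NaN) rather than an extrapolated
time. The 5% cutoff defines the bleaching-start day; the initial rise
is max(0, y₀ + a − 100) when the peak lies in the observed span.

## Comparison statistics

One-way ANOVA (`scipy.stats.f_oneway`) with Tukey HSD pairwise
p-values (`scipy.stats.tukey_hsd`; cross-checked against statsmodels in
the test suite) feeds an insert-and-absorb compact letter display:
species share a letter iff their Tukey p ≥ α (default 0.05). The
degenerate zero-within-variance case reports p = 0 for unequal means.
Pearson correlation pairs the two fragments cut from each colony — one
per heating regime — and pools all species into a single n = 25
correlation, matching the paired-fragment design. CV% uses the sample
SD (n − 1), the convention for 5-replicate summaries.

## Synthetic studies

The generator emulates the five-species, two-regime, five-colony tank
assay sampled twice daily. Species profiles are modified-Gaussian
parameter means calibrated so the noiseless fast-regime bleaching-start
days (5% criterion) sit at 3.2, 5.5, 6.4, 6.8 and 8.4 days and the
slow-regime ones at 7.9–22.5 days, with the *Millepora*-like profile
carrying an initial rise (~10% fast, ~40% slow; its fast-regime shape
uses c = 2 so the species order also holds at the 30%/50% cutoffs).
Between-colony variability enters through a standard-normal colony
susceptibility factor that is *shared across regimes* and scales the
width b lognormally (keeping b positive and right-skewed); the
remaining parameters get small independent per-fragment jitter.
Measurement noise is additive Gaussian on RG% with SD 3, the simplest
model consistent with fit R² in the 0.93–0.998 band. Every stream is
keyed on (seed, regime, species, colony), so regenerating with the same
seed is bit-exact and adding species or colonies does not perturb
existing fragments.

What the generator does not emulate: spatially textured coral tissue
(rendered frames use dithered uniform patches), temperature-dependent
noise, fragment mortality or missing photographs, and camera gamma.
Passing tests therefore demonstrate the pipeline's numerical
correctness and its robustness to exposure drift, not robustness to
segmentation error or lighting gradients inside a frame.

With the published between-colony spreads driving the shared factor,
the pooled cross-regime Pearson r of the synthetic default study lands
around 0.55–0.7 — lower than the 0.75–0.90 reported for the real data.
The printed slow-regime spreads are large relative to the
between-species separation, so a pooled linear r of 0.9 is not
recoverable from the printed summary statistics alone; the synthetic
value is reported as computed and not tuned.

Rendered frames place three 21×21 patches (coral, black ≈ 30, white
≈ 225) on a mid-gray background. Patches carry a zero-mean ±10 integer
texture plus a dithered fractional level, so the patch mean encodes the
requested G₀ to ~1/880 gray level and per-pixel rounding under affine
jitter averages out instead of biasing the mean. Jitter defaults
(α ∈ [0.95, 1.03], β ∈ [−10, 10]) are chosen so no pixel clips;
generation fails rather than clip.

The ranking benchmark uses a separate well-separated profile set
(adjacent true BTI₃₀ gaps ≥ 2.6 d fast / ≥ 3.25 d slow, same layout and
noise) over 100 seeded replicates; study durations are 28 d (fast) and
35 d (slow), long enough for the slowest benchmark species to complete
its decay. The temperature programs are generated for realism and
plotting only — the bleaching curves are parameterized in time, as is
the index itself.

## Command line

`coralbti simulate / extract / analyze` wrap the library; `analyze`
writes the fit, BTI, rise, letter-group, correlation and CV tables in
one pass (separate `bti`/`compare` commands would re-run the same
path). All analysis commands are deterministic; randomness exists only
in `simulate --seed`. Exit codes: 0 ok, 1 usage error, 2 data error.

## Known limitations

- ROIs are user-declared; no segmentation or strip detection.
- The grayscale weights of the original Photoshop workflow are
  undocumented; any fixed luma convention satisfies the protocol, but
  bit-level agreement with measurements made in other software is not
  claimable.
- Whether the published fits imposed parameter bounds is unknown;
  refits of the same raw data may differ in late decimals of the
  parameters while matching R² closely.
- Fragments whose curve never reaches a threshold inside the observed
  window yield not-reached rather than an extrapolated BTI; very
  heat-tolerant species need longer records.
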