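# Methods

## The measurement

Hair tubes are short baited tubes lined with double-sided adhesive
tape; small mammals passing through leave dorsal guard hair on the
tape. The tapes are mounted on a red background and scanned (8-bit
RGB, nominally 600 dpi). `hairtube` turns such a scan into a
quantitative activity index, the *hair density* of a region of
interest (ROI):

    density (%) = 100 · n_hair / (n_hair + n_tape)

The denominator is the set of *effective* pixels — everything in the
ROI that is tape or hair. Background pixels are excluded because the
hair lies on the tape: enlarging an ROI into the background must not
dilute the density. A red background is assumed because it maximizes
the RGB separation from both the pale tape and the (dark, desaturated)
hair.

## Pixel classification

Classification works alternately in two spaces.

**Colour space.** Each class is an inclusive per-channel RGB box.
Boxes come either from calibration patches — per channel,
`low = max(0, min − tolerance)`, `high = min(255, max + tolerance)` —
or from the package defaults:

| class      | low           | high          |
|------------|---------------|---------------|
| background | (150, 0, 0)   | (255, 90, 90) |
| tape       | (180, 150, 110) | (255, 235, 210) |

with `tolerance = 10`. A pixel inside the background box is
background; else, inside the tape box, tape; everything else is hair
(the residual class — hair colour varies across species and is never
calibrated directly). Where the two boxes overlap, background wins:
a background-over-tape mistake is visible on screen and correctable
with an override, whereas hair silently absorbed into a class is not.

**Pixel space.** Two cleanup passes absorb scanner noise, brightness
variance and surface roughness: (1) morphological closing of the
background class with a 3×3 square element, which fills pinholes
(dust grains, noise tails) in the background; (2) 8-connected hair
components smaller than 3 px are reassigned to tape. Closing is
applied to the background class only — closing the tape class would
erase genuine 1-px-wide hairs — and the speck threshold of 3 px is
far below the footprint of any real hair at 600 dpi (a 5 mm hair is
≳ 120 px long) while covering isolated dust. Both parameters are
configurable per run. Manual overrides (rectangles forced to
background or tape) are applied after refinement, and later overrides
win on overlap, mirroring how an operator corrects the machine's
output. All rectangles are 0-based half-open `[x0,x1)×[y0,y1)` with
x rightward and y downward.

## Reproducibility protocol

The *calculated* density of an ROI is the mean over 10 repetitions in
which the ROI is re-drawn with each of its four edges offset by an
independent uniform integer in [−3, +3] px, a reproducible surrogate
for the variability of manual region selection. The replicate spread
gives the sample SD (n−1 denominator) and SE = SD/√n. Replicates
whose jittered ROI contains no effective pixels are excluded with a
warning rather than zero-filled. Since the classified mask does not
depend on the ROI, the implementation classifies once and re-counts
per replicate; this is arithmetically identical to re-running the
pipeline per replicate.

The *real* density is computed from a pixel-exact truth mask with the
same ratio. With synthetic sheets the truth mask is exact by
construction; a manually marked ground truth on real scans carries a
small overestimation bias from rectangular marking that the synthetic
truth does not have. Agreement is summarized by the mean absolute
error in percentage points and by R² of the OLS fit of calculated on
real.

## Synthetic sheets

`generate_sheet` paints, in order: the background colour; tape
rectangles; hair strands; dust; a horizontal brightness ramp; i.i.d.
Gaussian colour noise. Defaults (chosen once, documented here as the
package's own study conditions):

* sheet 900×560 px with one 700×400 px tape rectangle — a
  single-tape-section crop rather than a full A4 page at 600 dpi,
  which carries no extra information, only more pixels;
* nominal colours: background (200, 30, 30), tape (230, 205, 170),
  hair (40, 30, 25); the spec validator requires every colour pair to
  be separated by more than 2·(noise SD + 10) in at least one channel;
* noise SD 4, gradient amplitude ±8 — large enough to scatter
  individual pixels out of their calibration box (exercising the
  pixel-space cleanup), small enough that nominal colours stay
  separable;
* 25 dust specks of 1–2 px painted in a brownish-grey; their *truth*
  label remains the underlying class, since manual ground-truthing
  assigns dirt to background or tape, never to hair;
* strands are bounded-turning random walks (step 3 px, turn ≤ 0.35
  rad, 30–120 steps ≈ 4–15 mm at 600 dpi) of width 1–3 px drawn with
  probabilities (0.3, 0.5, 0.2), stamped as a densified polyline so a
  strand is always a connected curve; strands are clipped to the tape
  rectangle and may cross (overlap pixels counted once in the truth).

Strands are added one at a time until the realized truth density
first reaches the target, so overshoot is bounded by one strand, and
the realized (not requested) density is the reference everywhere.

What this emulates — and what it does not: colour statistics,
brightness drift, dust, curved overlapping hairs of realistic width.
Not emulated: tape curling and glare, ragged tape edges, compression
artefacts, species-specific hair morphology. Pipeline accuracy on
these sheets therefore measures the colour-classification and
refinement logic, not robustness to every physical artefact of real
scans.

## Synthetic field survey

`generate_survey` reproduces the validation design: 3 habitats × 10
transect replicates × 10 tubes × 2 tape sides × 4 repetitions = 2400
tape records, aggregating to 40 datapoints per habitat. Per
(habitat, replicate, repetition) unit a latent activity `a` is
log-normal (meanlog 0.9 grassland/wheat, 1.4 hedge; sdlog 0.7);
expected tape density follows the saturating curve
`25 · a / (a + 5)` %, with per-side Gaussian noise (SD 1 pp) clipped
to [0, 100]. Each tube is *visited* with probability
`1 − exp(−0.25 · a)`; unvisited tubes stay hairless, which reproduces
the roughly-half share of hairless tapes seen in field surveys.
Camera events are Poisson with rate `6 · a` per 3-day window, with
uniform timestamps and taxa drawn from the observed field mix
(Apodemus 0.849, vole 0.134, rat 0.015, shrew 0.002). The Poisson
count is drawn by inverse CDF on a per-unit common uniform, so
raising a unit's activity with everything else fixed provably never
lowers its densities or its count (`camera_noise=False` replaces the
draw with the rounded expectation for fully deterministic limits).
The synthetic coupling between tapes and cameras is cleaner than any
field pairing, so synthetic correlations run higher than field ones;
positive-correlation tests here validate the statistical chain, not
field performance.

## Validation statistics

* **Tube/transect aggregation** — the two sides of a tube are
  averaged (a single readable side stands alone; a tube with none is
  excluded with a warning), then the tubes of a transect repetition
  are averaged unweighted. The two-stage mean differs from the flat
  mean exactly when sides are missing.
* **Camera deduplication** — events are scanned in time order; an
  event is counted iff at least the quiet window (default 600 s) has
  passed since the preceding small-mammal event *of any taxon*; the
  first event counts; taxon filtering (default Apodemus + voles; rats
  and shrews excluded) applies to the counted events. Whether
  uncounted events restart the window is genuinely ambiguous in the
  field protocol; the default says yes (`reset_on="all"`), and
  `reset_on="counted"` implements the alternative. A gap exactly
  equal to the window counts as quiet, which makes window = 0
  degenerate to the raw count.
* **Johnson normalization** — the Slifker–Shapiro four-percentile
  method: for each z on a grid (0.25–1.25, step 0.01) the sample
  quantiles at normal probabilities ±z, ±3z yield the spread ratio
  mn/p², which selects SB (< 1), SU (> 1) or SL (≈ 1) and gives
  closed-form parameter estimates; every candidate whose domain
  contains the sample is scored by the Shapiro–Wilk W of the
  transformed sample, the best W wins, and the identity is the
  fallback. Accepted fits are strictly increasing on the sample
  range (checked by property test), so the transform cannot change
  any rank statistic.
* **Spearman correlation** — Pearson correlation of mid-ranks, with
  a two-sided p from the t-approximation on n−2 df (standard at
  n = 40); an exact permutation p (|ρ|-tail convention) is available
  for n ≤ 10. Because accepted Johnson fits are monotone, ρ with and
  without the transform is identical — the package implements both
  steps to match the published chain, and the test suite asserts the
  invariance explicitly.

## Numerical and degenerate-input choices

* Density of an ROI with no effective pixels is flagged undefined
  (NaN), never reported as 0.
* Replicate SD is exactly 0 when all replicates are equal (explicit
  short-circuit; no floating residue).
* R² of the real-vs-calculated fit requires ≥ 3 pairs and non-zero
  variance in both coordinates; otherwise it is flagged unavailable.
* Jittered ROIs are clipped to the image; a degenerate draw is
  re-drawn (bounded retries) and jitter 0 returns the ROI unchanged.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; sheet, jitter and survey streams are
  independent sub-streams, so any output is bit-reproducible from
  its logged seed.

## Known limitations

* Hair is a residual class: any object that matches neither
  calibration box (insects, plant fragments larger than the speck
  threshold) counts as hair unless overridden.
* The geometric jitter models region-selection variability only, not
  inter-operator differences in override judgement.
* Rectangular ROIs only; non-rectangular tape outlines must be
  handled with overrides.
* The Johnson fit optimizes W over a fixed z grid; it is a
  normalization device, not a maximum-likelihood distribution fit.
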