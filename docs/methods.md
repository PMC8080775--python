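# Methods

This note documents the models and procedures implemented in `combmap`,
their assumptions, the parameters that matter, and the numerical
conventions, including the choices made where the design was genuinely
open.

## Data model

A recording is a 3-D array `data[row, col, frame]` of fluorescence
intensities (arbitrary units) with a frame interval in milliseconds and an
optional boolean validity mask.  Intensities are promoted to float64 on
read regardless of source bit depth so all downstream numerics behave
uniformly.  The frame interval is always supplied by the user; timing
metadata embedded in TIFF files is ignored — the acquisition time base is
treated as user knowledge, not file metadata.  Folders of single-frame
images are ordered by lexicographic filename sort (zero-padded frame
numbers recommended), never by file timestamps.

Spatial binning averages `f×f` blocks and truncates incomplete trailing
blocks rather than padding them, avoiding partially-averaged edge pixels
with biased noise statistics.  The mask is *carried*, not applied to the
intensities: raw data are preserved and masking is purely an analysis
concern.  Masked-out pixels appear as IEEE NaN in every derived map; the
CSV writers emit NaN as an empty cell.

The *maximum-contrast image* used for drawing masks is defined here as the
per-pixel temporal range (max − min of the trace) rescaled to span [0, 1]
over analyzed pixels.  This is a reasoned definition of an informally named
quantity; if all pixels have equal contrast the rescaling is degenerate and
the image is all zeros.

## Signal polarity

With calcium dyes the activation deflection is upward ("peaks" polarity);
with voltage dyes, higher membrane potential means lower intensity, so the
activation is a downward deflection ("troughs").  Troughs-polarity traces
are rectified internally as `2·median − trace`, so every feature definition
is written once for upward deflections and amplitudes are always reported
positive.  The median is a robust centre: for physiological duty cycles
most samples lie near the diastolic baseline, so rectification
approximately mirrors the trace about its baseline.

## The comb algorithm

Given tooth offsets `t_0 = 0 < t_1 < … < t_{K−1}` (uniform for fixed-rate
pacing; arbitrary for custom protocols such as S1-S2), the comb is placed
at every offset that keeps all teeth inside the trace
(`o = 0 … N − span − 1`) and the mean signal under the teeth is scored.
The extremal offset wins; ties are broken deterministically by the smallest
offset.  Each tooth is then refined to the local extremum within
`±round(refinement_width_ms / frame_interval_ms)` frames, clipped at the
trace boundaries, with ties broken by the earliest index.  If a refinement
would break the strict ordering of tooth positions, the offending tooth
keeps its unrefined position — downstream segmentation requires ordered
diastoles.

The default `refinement_width_ms` is 10 ms: small relative to typical
cycle lengths (85–300 ms in the recordings this pipeline targets), large
enough to absorb frame-quantization and mild rate jitter.  For S1-S2
measurements in tissue, where regional conduction-velocity restitution
spreads activation times, a larger radius is appropriate.

A uniform comb for period `p` in an `N`-frame recording carries
`floor(N/p)` teeth, covering as many beats as fit while preserving a full
sliding range.  Upstroke times (used by "augmented" object selection) are
found by running the comb on the first-difference of the whole smoothed
trace — far more robust to noise than locating the steepest slope within a
single beat.

The comb requires the activation pattern to be known; it is not an
unknown-rate event detector.  For spontaneously active preparations a
heuristic helper (`estimate_custom_comb`) thresholds the low-noise spatial
average trace at mid-range and builds a custom comb from the intervals
between per-excursion maxima; it is explicitly documented as heuristic.

## Per-trace processing and features

Traces are optionally smoothed with a Savitzky-Golay filter (default
window 11 frames, order 4), chosen because it suppresses noise while
preserving sharp genuine deflections such as AP upstrokes; polynomials up
to the filter order pass through unchanged.  Baseline drift is removed by
subtracting a least-squares polynomial of configurable degree (default 4,
negative disables) fitted to the whole trace, with the original mean
re-added so `mean(out) = mean(in)` exactly — the preserved offset lets
photobleaching be monitored across consecutive recordings.

Diastoles split the trace into segments inclusive of both endpoints.  Per
segment:

- **baseline** — the first sample, or the mean of first and last samples
  (`baseline_mode="firstlast"`); default "first".
- **amplitude** — segment maximum minus baseline (after rectification).
- **duration** — measured by thresholding at
  `baseline + (1 − recovery_level)·amplitude`; `recovery_level` is a
  fraction in (0, 1), so 0.8 means APD80/CaTD80.  Maximal runs strictly
  above the threshold become objects, with crossing times linearly
  interpolated between the bracketing samples (runs touching a segment
  boundary use the boundary time).  Noise or motion can split one beat
  into several objects; the selection modes are "first" (earliest),
  "largest" (longest duration) and "augmented" (closest to the
  comb-detected upstroke; distance zero if the upstroke lies inside the
  object).  Default "largest".
- **recovery time** — the selected object's end crossing (the instant the
  recovery level is reached).
- **activation time** — the first interpolated up-crossing of
  `baseline + 0.5·amplitude` within the selected object's extent.
  Restricting the search to the object prevents noise crossings elsewhere
  in the segment from defining activation.  When the object already starts
  above half-max (recovery levels below 0.5) the object start is used.

A beat with no sample above the duration threshold, or no reachable
half-max inside the object, yields a *missing* record rather than an
extrapolated one.

## Recording clock and multi-wave analysis

The clock is built from the spatially averaged trace (masked pixels
excluded): comb-detected peak activations (maxima for calcium, minima for
voltage), at least three of which are required; boundaries are consecutive
midpoints.  The clock is not a per-beat segmentation — it is a global set
of bins that assigns every pixel's features to the same wave pass even
though each pixel's diastoles differ.

Activation and recovery times are converted to global milliseconds and the
greatest clock boundary not exceeding each event is subtracted from it.
Each beat is binned by its *half-time*, defined here as the temporal
midpoint between the segment's bounding diastoles (an informally named
quantity; the alternative — the half-maximum activation time — changes bin
assignment only for activations nearly coincident with a clock boundary).
Beats whose half-time falls before the first or at/after the last boundary
are discarded as potentially incomplete.  If two activations of one pixel
land in the same bin (erratic segmentation), the later overwrites the
earlier and a warning is logged.  Per-beat maps are dense `rows × cols ×
bins` arrays with NaN for missing entries; beat-averaged maps, per-beat
spatial means and grand means are derived from them ignoring NaN.

Single-wave analysis treats each whole trace as one segment with no comb
and no clock; times are global milliseconds from frame 0, so no rate
assumption is made.  Hybrid analysis splits a regular recording at the
first clock boundary and then every basic cycle length (the user-supplied
period, not re-estimated), frame-averages the complete substacks
(discarding an incomplete tail, requiring at least two) and runs
single-wave analysis on the average.  Averaging reduces residual noise by
`1/√N` and suppresses occasional per-beat artefacts, but it destroys
beat-to-beat information: features that alternate are averaged toward
their mean, so alternans must be analyzed in multi-wave mode.

The temporal-SD map — the per-pixel standard deviation (ddof 1) of a
feature over wave passes — flags sites of irregular activation: where a
periodic comb is forced onto nonperiodic activity the segmentation
degrades and the SD rises, while regularly activated sites stay near zero.

## Conduction velocity

Point-to-point CV is the Euclidean pixel distance (scaled by the pixel
pitch in mm) divided by the absolute activation-time difference; pairs
differing by less than 1 µs are reported missing with a warning.  Note the
point-to-point estimate is only unbiased along the propagation axis;
oblique pairs overestimate speed.

Local CV follows Bayly's construction: a second-order bivariate polynomial
`T(x,y) = ax² + by² + cxy + dx + ey + f` is least-squares fitted to the
activation times in a square, unweighted `(2w+1)²` window around each pixel
(coordinates in mm), and the velocity is the fitted gradient divided by its
squared magnitude, `v = g/(g·g)`, speed `1/|g|`.  A window must contain at
least six valid activation times (the number of polynomial coefficients)
and the gradient magnitude at least `1e-9` ms/mm; otherwise the pixel is
invalid.  On a planar wave the activation surface is linear and the
recovery is exact to machine precision.  On curved fronts the quadratic is
an approximation: accuracy improves with smaller windows (the default
radius of 3 px suits noisy experimental maps; radius 1 recovers a circular
target wave within 5% outside a 3-pixel core around the source, where the
activation surface is not differentiable).

## Alternans

Even wave passes (bin indices 0, 2, 4, …) and odd passes are averaged per
pixel, and alternans is quantified as `max(e,o)/min(e,o)`
(large-to-small), `|e−o|/(e+o)` (sMAPE) or `1 − min(e,o)/max(e,o)`.  The
three are algebraically linked (`1−ratio = 1 − 1/LTS`,
`sMAPE = (LTS−1)/(LTS+1)`) and all are invariant to which parity is called
"even", so dropping the first beat changes nothing.  The formulas assume a
positive feature (amplitude, duration); pixels with a non-positive mean or
with fewer than one even and one odd measured beat are missing, with a
warning.  For an amplitude alternating as `A(1±a)` the metrics are exactly
`a`, `(1+a)/(1−a)` and `2a/(1+a)`.

## Synthetic fixtures

The generator module synthesizes recordings with exact ground truth so
every stage is testable without experimental data.  Templates are a
piecewise-linear "tent" AP (rise `R`, fall `F` frames; closed forms:
duration at level `L` is `L(R+F)`, half-max activation `R/2`, recovery
`R + LF`) and a skewed calcium transient (linear rise, exponential decay
with three time constants over the fall, peak exactly at `R`).  Trains
paste templates at cumulative stimulus times, with per-beat alternans
scaling `1 + a(−1)^k`, polynomial drift over normalized time, and seeded
i.i.d. Gaussian noise per pixel-frame.  Planar waves propagate row-wise
with integer-rounded per-row delays (so stack and ground truth agree
exactly); `speed = ∞` gives a uniform flash train.  The discordant
alternans stack flips alternans phase across a nodal row, with the
magnitude tapering linearly to zero over a configurable width (default
1 row) so alternans is full-strength away from the line and absent on it.

Default study conditions used across the tests: tent rise 10 ms, fall
30 ms, amplitude 1; pacing cycle length 100–150 ms; 6–20 beats; noise SD
up to 0.5× amplitude for robustness studies; fields of 4×4 to 16×16
pixels.  These sizes keep every test and the acceptance script within
seconds while leaving the statistics meaningful (e.g. 50-seed medians for
the noise study, 1000 traces for mean-conservation).

What the fixtures do *not* emulate: ionic-model AP shapes, rate-dependent
restitution, motion artefacts, spatially correlated noise, curved or
re-entrant wavefronts.  Passing tests therefore demonstrate the
correctness of the algorithms on geometrically ideal signals, not
robustness to every experimental pathology; the noise-robustness and
drift tests cover the dominant real-world perturbations the pipeline is
designed for.

## Numerical conventions and edge cases

- All interpolations are linear; on piecewise-linear signals crossings and
  durations are exact to ≤1e-9 relative error.
- Ties are always broken deterministically (smallest offset, earliest
  index, earliest object), so repeated runs are bit-identical.
- Degenerate inputs have defined outcomes rather than errors wherever an
  analysis can continue: empty object lists and flat traces yield missing
  records; per-pixel failures never abort a map; all-missing maps raise
  only in functions whose output would be meaningless (plotting).
- The duration of a beat is non-increasing as the recovery level
  decreases (APD50 ≤ APD80), by construction of the threshold.

## Known limitations

- The comb requires prior knowledge of the activation pattern; the
  auto-comb helper is a convenience, not a detector for arrhythmic data.
- Only the temporal-SD map addresses irregular activation; arrhythmia
  tracking is out of scope.
- The hybrid mode assumes stationarity of the beat shape over the
  recording.
- Calcium decay time-constant fitting and spatial/temporal filters beyond
  Savitzky-Golay and polynomial drift removal are intentionally not
  provided; users may pre-filter stacks with any external tool.
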