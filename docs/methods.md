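# Methods

## Scope and model

`astroroa` decomposes a single-channel fluorescence movie into regions
of activity (ROAs) and analyzes each ROA's ΔF/F₀ trace independently.
The model underlying every stage is deliberately minimal: astrocyte
calcium activity is treated as a set of spatially fixed micro-domains
that emit transients independently, with no propagation, merging or
event model imposed. All spatial reasoning is 8-connected (diagonal
contact counts), matching the connectivity convention of common
particle-analysis tools, and all labeling is in raster order of each
component's first pixel so region numbering is deterministic.

## Active pixel detection

Per pixel, the temporal baseline is the median of its time series and
the noise SD is `1.4826 × median(|F − median|)` (MAD). The robust
estimator is the default because sparse transients would inflate a
plain SD and depress sensitivity; a plain-SD variant is available
(`sd_method="std"`). Each frame is smoothed with a reflective-boundary
Gaussian (σ = 0.5 px by default) before thresholding at
`baseline + intensity_scaling × SD` (default 2.5); baseline and SD are
always computed on the *unsmoothed* series so the threshold scale is
not altered by the filter. Supra-threshold pixels are grouped into
8-connected per-frame patches; patches under `min_size` pixels
(default 10) are discarded, and the survivors are filtered by physical
area (defaults: `min_size` converted to µm² up to 40 µm²). The `min_size`
filter is in pixels and the area filter in µm² because they play
different roles (detection support vs. domain-scale proof-reading); both
are applied, in that order. With `border_exclude = b > 0` the outer `b`
pixels never activate and the exported activity stack is cropped to the
interior canvas; `restore_canvas` re-centers such a cropped canvas on
the full one, putting any odd leftover margin on the trailing side.

Patches are strictly per-frame 2-D objects. No spatio-temporal linking
is attempted: the ROA map only needs to know *where* activity ever
occurred.

## ROA map

The ROA map is the union of all surviving patch footprints over time
(optionally restricted to a frame range, useful when long recordings
drift), with interior holes filled by background-complement filling and
components labeled 8-connected. ROAs of every size are kept — size
selection belongs to the patch area filter. Because the map is a union
over time, a pixel that ever joined a patch stays in the ROA; footprints
are therefore generous at domain edges, and two domains whose patches
ever touch (even diagonally, even in different frames) merge into one
ROA. Loosening the patch area cutoff can only grow or merge ROAs.

## Traces

Each region's trace is the arithmetic mean of the raw movie over the
region's full footprint in every frame, exactly the multi-measure
semantics of the interactive workflow this pipeline automates — even
though instantaneous activity rarely fills the footprint. Trace
extraction is linear in the movie, which the tests exploit.

## Iterative baseline (F₀)

Per trace, iterate:

1. F₀ ← mean of the currently signal-free samples inside the baseline
   window (defaults to the whole trace); SD ← sample SD (ddof = 1) of
   the same samples. The first iteration uses every sample.
2. Find maximal runs exceeding `F₀ + k·SD` (`k` = `signal_threshold`,
   default 3; 2–3 is the sensible range). Extend each run outward to the
   nearest samples at or below F₀ and mark the strictly interior samples
   as signal. Only interior samples are marked — the crossing samples
   sit at or below F₀ and stay in the baseline pool — which guarantees
   the F₀ sequence is non-increasing.
3. Stop when the relative change in F₀ is below 10⁻⁶ or after
   `iterations` passes (default 5).

After the loop, ΔF/F₀ = (F − F₀)/F₀, the detection threshold in ΔF/F₀
units is τ = k·SD/F₀, and signals are delimited on the ΔF/F₀ trace
(below). Degenerate zero-variance traces get F₀ = mean, an SD floored at
10⁻¹²·F₀ (so thresholds stay positive), no signals, and a warning. A
non-positive converged F₀ is an error: ΔF/F₀ is undefined there and
upstream data should be inspected.

**Convergence behavior.** Both F₀ and SD are re-estimated from the
shrinking signal-free pool each pass. On sparse traces the procedure
reaches its fixed point in ~3–5 iterations. On dense traces (event rates
of a few per minute with multi-second decays, so that much of the trace
is signal) each pass lowers the threshold enough to expose the next
stratum of events, and exact convergence at the 10⁻⁶ tolerance can take
on the order of 10–15 iterations; the interim F₀ after 5 iterations is
already close, but not converged to tolerance. We examined freezing the
SD (or the whole threshold) at its first-pass value, which converges in
≤ 6–7 passes but leaves F₀ inflated by a large margin on dense traces
(the high mixture SD prevents most signal from ever being removed), and
robust (MAD) SD variants, which do not converge faster. Accurate F₀ was
judged more important than a small iteration count; users analyzing
dense recordings should raise `iterations` above the default. The
benchmark battery reported by `scripts/acceptance.py` measures exactly
this: the maximum first iteration at which the relative F₀ change drops
below 10⁻⁶ across 200 synthetic traces spanning rates 0.5–4 min⁻¹ and
SNR 2–10.

## Signal detection

A signal is the maximal excursion bounded by the nearest
at-or-below-baseline samples flanking one or more threshold crossings:
start = last F₀ crossing before the first threshold crossing, end =
first F₀ crossing after the last one, peak = argmax of ΔF/F₀ within the
bounds (earliest frame on ties). Two threshold excursions separated by
a dip that never reaches baseline share their crossings and merge into
one signal; kinetics then reference the global peak. Bounds are at
sample resolution (frame indices); no sub-sample interpolation is used
for bounds. Excursions missing a bound (they run into a recording edge)
are *truncated*: excluded by default, carried along with partial
features when `include_incomplete` is set — the pragmatic rescue for
sustained drug responses that never return to baseline.

## Features

Per complete signal: amplitude = ΔF/F₀ at the peak; AUC = composite
Simpson over the bounded samples with spacing 1/frame_rate (an odd
interval count is closed with a trapezoid on the final interval — this
exact rule, rather than a library's odd-interval correction, so the
quadrature is stated and testable); rise time = time between the 10 %
and 90 % amplitude crossings nearest the peak on the rise limb, linearly
interpolated between samples (at ~1 Hz sampling, whole-frame crossings
would quantize kinetics to seconds); decay time analogously 90 %→10 %;
half-width between the 50 % crossings flanking the peak; duration =
end − start; inter-event interval = start time minus the previous
signal's end time within the same ROA (absent for the first signal);
signal-to-noise = amplitude divided by the *peak* (not SD) of the
trace's signal-free ΔF/F₀ samples, with truncated excursions also
masked out of the noise pool. Exponential fits are deliberately absent:
at ~1 Hz they are under-determined for these kinetics. Epoch assignment
is by peak frame; a peak exactly at the drug frame belongs to the drug
epoch. Truncated signals, when included, report only amplitude, peak
time/frame, and rise time (the latter only when the initiation bound
exists).

## ROA and cell summaries

Every ROA contributes one row per epoch (baseline/drug when a drug frame
is set, a single unnamed epoch otherwise, covering the full recording),
with signal count, frequency per minute (count over epoch duration), and
unweighted means of the per-signal features. ROA types: stable (signals
in both epochs), on (drug only), off (baseline only), inactive
(neither); the census of types is the `ROA_summary` table. Cell
assignment maps each ROA to the cell mask region with maximal pixel
overlap; no overlap → cell 0 (unassigned), ties → the smaller cell ID
with a warning. Per-cell summaries average a cell's ROA means
unweighted and sum signal counts; cell 0 appears as its own row and
never contributes to a real cell.

## Synthetic data

Transients use a difference-of-exponentials kernel normalized to unit
peak, rise τ = 2 s and decay τ = 8 s by default (typical of ~1 Hz
astrocyte recordings). The kernel is hard-zeroed eight decay constants
past its peak (discarding < 5 × 10⁻⁴ of the peak) so that noise-free
traces return *exactly* to baseline — without this, the infinite tail
never re-crosses F₀ and every noise-free event would be classified as
truncated. Trace model:
`F = F₀·(1 + Σ events) + F₀·noise_sd·N(0,1) + drift·(t − mean t)`,
with Poisson event times, uniform amplitudes, an optional drug epoch
rescaling rate and amplitude, and an optional fraction of event-free
traces. Movie model: Gaussian-profile blobs (disk footprint of radius
`roi_radius`, brightness σ = radius/2) placed ≥ `2·radius + 3` px apart
by rejection sampling on a dim background; the calcium dynamic is
*multiplicative on each pixel's resting level* inside the footprint, so
the mean trace over any sub-footprint recovers the planted ΔF/F₀
amplitude exactly. Defaults (background 20, blob peak 200, noise SD 15)
emulate a membrane-tethered indicator — dim non-indicator background and
per-pixel peak z-scores of roughly 5–15 for unit-amplitude events.

The `generate_trace_battery` helper draws one event rate (0.5–4 min⁻¹)
and one target SNR (2–10) per trace and converts SNR to amplitude via
the expected peak of ~600 Gaussian noise samples (≈ 3.2 σ), matching the
pipeline's peak-over-peak SNR definition.

What the generator does *not* emulate: photon (shot) statistics,
motion, focal drift, bleaching nonlinearity, overlapping or
propagating domains, and within-domain ΔF/F₀ gradients. Passing
recovery tests on this generator therefore demonstrates the pipeline's
measurement fidelity under its own assumptions, not robustness to every
artifact of real recordings.

## Numerical choices and edge cases

- Convergence tolerance 10⁻⁶ relative on F₀; iteration cap
  user-controlled (default 5).
- SD floor 10⁻¹²·F₀ on zero-variance traces.
- Crossing samples use `≤` comparisons (a sample exactly at baseline is
  a crossing); threshold comparisons are strict (`>`).
- Ties at the signal peak go to the earliest frame (`argmax`).
- Butterworth smoothing (optional, order 4, cutoff 0.4 Hz) is zero-phase
  (`sosfiltfilt`), DC gain exactly 1; a cutoff at or above Nyquist
  degrades to a warned pass-through.
- Drift correction fits an OLS slope on *all* samples (large signals
  bias the fit — surfaced as a caveat; inspect the slope distribution
  before trusting it) and subtracts `correction_factor` (default 0.5) of
  the mean-centered trend, preserving the trace mean.
- ImageJ CSV slice columns (1-based) are detected as an exact
  `1..n` integer sequence and converted to 0-based internal frames;
  outputs use `%.17g` floats and round-trip parsing so CSVs reproduce
  arrays bit-for-bit.
- Masks are nominally {0, 255}; other nonzero values are accepted as
  foreground with a logged warning.

## Problem sizes used in the test battery

Unit and property tests run on 16–128 px canvases, 20–600 frame traces,
and up to 1000-trace oracle comparisons; the end-to-end recovery
benchmark uses a 128 × 128 × 300 movie with 20 planted domains. The
whole suite completes in well under a minute on one core.

## Known limitations

- Whole-footprint means dilute ΔF/F₀ when a ROA footprint overshoots
  its emitting domain (union-over-time maps are generous at edges).
- No sliding-window or nonlinear baseline: recordings with strong
  non-linear drift need external correction first.
- Merged signals (no baseline re-crossing between events) under-count
  frequency at high event rates relative to transient duration.
- ROA numbering follows mask raster order, which is deterministic here
  but is only guaranteed to match interactive ROI-manager numbering in
  count, not order.
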