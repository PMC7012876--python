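# Methods

This note documents the models, conventions and numerical choices behind
`hemosys`, the parameters that matter, and what the synthetic scenes do and
do not establish about real data.

## Data model and conventions

A *trial* holds one `FrameStack` per physiological variable — Hb_sat
(oxygen saturation, %), BV and BF (arbitrary units) — on a shared field of
view and time base. Arrays are row-major with the origin at the top-left
pixel, 0-based. Nominal acquisition: one frame per variable every 30 s for
60 min (30 min for stimulus sessions) at 5 μm/pixel over a 5×7 mm² field,
giving a 20×28 grid of 50×50 px sub-regions; the bundled synthetic presets
use 200×200 px (4×4 sub-regions) so that full pipelines run in seconds.
When no timing sidecar exists, times are synthesized at the configured
cadence (default 0.5 min) starting at zero. Resampling onto a common step
averages all frames per `[t, t+step)` bin and keeps the bin left edge as
the timestamp, so resampling at the native cadence is the identity.

## Pre-processing

* **Temporal filter** — sliding boxcar, kernel 5 min, step 1 min. Only
  fully covered windows are emitted (no padding): a 60-min series on a
  1-min base yields exactly 56 samples, which fixes the 56-point FFT
  downstream. Output timestamps are the mean of the member sample times.
  The filter commutes with affine maps and with block averaging (both are
  linear means); tests verify both to 1e-10.
* **Spatial filter** — non-overlapping 50×50 px tiles (trailing partial
  tiles discarded). A tile mean excludes non-finite pixels; a tile with
  fewer than half its pixels finite in any frame is missing downstream.
  Tiling (not sliding) is used because sub-regions are indexed as a grid
  `S[row, col]` and treated as independent observational units.
* **Fractional change** — ΔBV/BV is the forward difference
  `(v[t+1] − v[t]) / v[t]`, chosen for causality; steps with nonpositive
  denominators are flagged missing rather than raised, since a zero signal
  level is a data property, not a caller error.
* **Windowed reduction** — −ΔX = mean(early) − mean(late), positive when
  the variable declined; default windows are the first and last five
  filtered samples.

## Propagation

Hypoxia is `Hb_sat < threshold` (default 30%, strict). Per filtered
minute, the 4-connected sub-threshold component containing the origin O
(or the nearest component within a 10 px capture radius) is selected; its
contour is the set of component pixels with a background 4-neighbour
(outer boundary at pixel resolution — no sub-pixel interpolation). The
radial distance along a ray O→anchor is found by sampling the component
mask at quarter-pixel steps and taking the farthest inside sample, so a
fingering front reports its leading edge. Speed is the forward difference
of radial distance over time; retreats give negative speeds (not
clipped). Zone labels use the cell's center pixel: CHRONIC inside the
first contour, ACUTE inside the last but not the first, NORMOXIC outside
the last. Center-pixel classification is deterministic but means cells
straddling the final front can mix planted and unaffected pixels through
block averaging; recovery tests therefore distinguish straddling cells
from cells wholly outside the front.

## Clustering

Run on ΔBV/BV per sub-region, per time window (default: the filtered run
split at its midpoint, mirroring 0–30 / 30–60 min). Stages:

1. **Master correlation matrix** — pairwise Pearson r over all
   non-missing, non-constant cells (row-major order), symmetrized, unit
   diagonal. Equivalent to stacking the seed-correlation maps of every
   cell.
2. **SVD initialization** — K = smallest rank whose cumulative squared
   singular values reach 80% of the total (capped at 10). Each cell joins
   the component with the largest |loading| among the first K, split by
   loading sign (up to 2K groups) so anticorrelated dynamics never share
   a preliminary cluster.
3. **Refinement** — iterate: centroids = member-mean series; reassign each
   cell to the best-correlating centroid if r strictly exceeds the 0.7
   threshold, else UNASSIGNED; dissolve niches below ⌈5% of cells⌉
   members; merge niche pairs whose centroids correlate above 0.7
   (union-find, lowest id survives). Stop when labels are stable or after
   100 iterations. Ties in reassignment break to the lowest niche id, so
   the procedure is deterministic. An all-UNASSIGNED outcome returns an
   empty labeling with a warning — pure-noise fields should and do
   dissolve.

Final labelings are relabelled by descending size and satisfy both
printed rules (membership r > 0.7, size ≥ 5%) by construction of the last
stable pass; acceptance tests re-verify them from the final centroids.

## Coupling

Per cell, Pearson r between BF and BV over each of two windows.
Classification: TIGHT iff r > 0.7 in both windows, POOR iff in neither,
INTERMITTENT otherwise; a cell exactly at the threshold does not exceed
it. Constant series in any window make the cell MISSING. The threshold is
a single configurable value shared by both windows. Since Pearson r is
invariant to positive affine maps, so is the classification; swapping the
windows permutes nothing and negates Δr = r₂ − r₁.

## Perturbation

The paradigm (default BASELINE 10 min, STIMULUS 10, BASELINE 10) becomes
a 0/1 boxcar sampled at the acquisition cadence and passed through the
identical temporal-filter code path as the data — not a reimplementation —
so reference and data align sample for sample (26 filtered points for the
30-min session). Responsive cells satisfy r > 0.7 strictly (one-sided:
anticorrelated cells are not responsive). Δ = stimulus mean − baseline
mean, positive for a stimulus-driven increase; filtered samples whose
averaging window overlaps a state transition are excluded from both means
(the filtered boxcar is not at steady state there; inclusion is available
via `exclude_transitions=False`). Δ is shift-invariant by construction.

## Fourier

Series are normalized by their temporal mean, `y = x/mean(x) − 1`, so
0 dB means fluctuation power equal to the squared mean; this realizes
"power relative to the mean level" and makes the dB reference explicit
(recorded in output metadata). One-sided power: `P_k = 2|Y_k|²/N²` for
`0 < k < N/2`, with the Nyquist bin not doubled and `P_0 ≡ 0`; then
`Σ P_k = var(y)` exactly (Parseval, tested to 1e-9). For a pure relative
modulation of depth c, `P = c²/2` at the modulation bin (−16.99 dB for
c = 0.2). No taper is applied by default. Bands map period ranges onto
bins `T_k = NΔt/k`: LF 10–56 min (bins 1–5 at N = 56), HF 2–10 min (bins
6–28); a bin exactly on a shared edge belongs to the lower-frequency
band. Band power is the linear bin sum reported in dB; values at or below
the −60 dB floor are omitted, and the H_f/L_f ratio is computed on linear
powers, omitted when either band is below floor. Periods ≤ 1 min need no
special casing: the filtered base's Nyquist period is 2 min. Note that
the 5-min boxcar attenuates in-band signal (≈ −0.46 dB at a 28-min
period, ≈ −15 dB at 4 min); band maps report the power of the *filtered*
series, without compensation.

## Synthetic scenes

Scenes emulate the acquisition geometry (5 μm/px, 30 s cadence, 60- or
30-min runs) at a 200×200 px preset and record every planted parameter in
a JSON manifest. Noise is independent Gaussian per pixel per frame;
scenes whose contracts are stated at sub-region level additionally plant
independent Gaussian noise per sub-region per frame, because 50×50
averaging attenuates pixel noise ~50-fold and sub-region-level contracts
(niche noise at 25% of signal SD, coupling noise at 20%, responder SNR 3)
would otherwise be vacuous.

* **WAVEFRONT** — disc of sub-threshold Hb_sat growing at constant speed
  (default 15 μm/min from radius 5 px), pixel noise 10% of the 40%
  saturation contrast; BF/BV decline by 40% inside the final disc with
  flat plateaus in the first and last 10 min so windowed reductions see
  the planted drops exactly.
* **NICHES** — contiguous cell bands with cosine BV modulations
  (amplitude 10%, periods 28/14/28⁄3 min — integer cycles per half-run
  window, hence mutually near-orthogonal) merging into a shared 14-min
  profile at 30 min.
* **COUPLING** — thirds of cells with BF tracking BV (TIGHT), BF on a
  frequency-disjoint multisine (POOR; orthogonal by construction, so the
  planted truth does not depend on null-distribution luck), or switching
  at the midpoint (INTERMITTENT).
* **PERTURBATION** — boxcar responses (ΔHb_sat 12, ΔBF 30, ΔBV 10) in an
  evenly interleaved half of cells at SNR 3 (Δ over raw sub-region noise
  SD); optional per-cell Δ jitter decorrelates responses across
  variables.
* **SPECTRAL** — alternate cells carry 28-min or 4-min relative
  sinusoids at depth 0.2.

What passing these scenes shows: the estimators recover planted structure
at realistic noise levels, the printed thresholds are implemented
exactly, and the pipeline is deterministic under a fixed seed. What they
do not show: robustness to motion, spatially correlated noise,
non-Gaussian speckle statistics, drifting baselines or registration
error — real acquisitions have all of these, and the generator
deliberately models none of them (extension hooks exist for correlated
noise).

## Problem sizes and determinism

Default verification sizes: 200×200 px × 120 frames (60 min at 0.5-min
cadence), ten seeds for wavefront and coupling recovery, fifty for
responder statistics; these were chosen so the whole suite completes in
well under a minute per module on a single core. All randomness flows
through `numpy.random.default_rng` seeded from the scene spec or the
acceptance script's `--seed`; identical configuration and seed reproduce
bit-identical stacks, label maps and CSV outputs (verified by checksum).

## Known limitations

* Contours are pixel-resolution; reported speeds quantize at one pixel
  per step (5 μm/min at the default geometry), which bounds accuracy for
  slow fronts.
* The refinement loop is guaranteed to terminate only via the iteration
  cap; on all tested inputs it stabilizes in far fewer passes, but
  pathological near-threshold cycling is conceivable.
* `GridSeries` serialization is CSV-based (cell_row, cell_col, time,
  value); very large grids would warrant the HDF5 container for which
  h5py is an optional future dependency.
* The dB reference is the squared temporal mean of each cell's series; an
  alternative reference (DC bin of the unnormalized transform) differs
  slightly for strongly modulated series and is intentionally not used.
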