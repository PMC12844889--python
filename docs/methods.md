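# Methods

This note records the models, parameter choices and numerical decisions
behind `spncoact`, in the spirit of a methods section: what each stage
assumes, which knobs matter, and what the synthetic data does and does not
emulate.

## Signal chain

Extracted fluorescence traces (cells × frames, ~20 frames/s, with per-frame
timestamps) and behavior-camera tracking (~30 frames/s, pixel coordinates)
are merged onto a common 5 Hz grid of half-open 200 ms bins anchored at the
later of the two stream starts.  Each miniscope frame belongs to exactly one
bin; bins without a tracking sample inherit the nearest-neighbor position,
and bins whose nearest sample is more than 500 ms away are marked invalid
and excluded from every statistic (real tracking streams drop frames; the
cutoff keeps interpolation honest).  Streams overlapping by less than half
of the shorter stream are rejected rather than analyzed.  A 1 ns guard is
added before the floor in bin assignment so timestamps lying exactly on a
bin edge (as happens when 5 Hz data is re-aligned) open their own bin.

Each trace is divided by its whole-session 99th-percentile value
(linear-interpolation quantile), z-scored over the whole session, and
max-downsampled onto the grid.  The p99-then-z-score order makes the result
invariant to the arbitrary gain of extracted traces; max (not mean)
downsampling preserves transient peaks.  Z-scoring is oriented so positive
values are fluorescence above the session mean — events are positive
excursions.  Whole-session moments (not a sliding window) are used: the
traces are assumed stationary at the session scale, which holds for the
generator and is the standard treatment for hour-scale open-field sessions.
No ΔF/F, detrending or neuropil correction is performed; those belong to
the upstream extraction.

## Event detection

An event is a maximal run of 5 Hz bins with z ≥ 2.5 lasting ≥ 1 s (5 bins).
The event time is the midpoint between the time of the run's maximum and
the preceding local minimum of the z-trace, found by walking left from the
run start while the trace keeps decreasing; at the trace start the first
sample serves as the minimum.  Amplitude is the run maximum (z units);
duration is time above threshold.  Runs separated by even a single
sub-threshold bin are kept separate — the simplest faithful rule; its main
consequence is that transients closer than the transient width merge, which
bounds the temporal resolution of rate estimates (see *Generator*).

## Behavior

Velocity is `cm_per_px · ‖Δposition‖ / Δt` at tracking rate, cleaned with a
1 s centered median filter (shrinking windows at the edges, so no phantom
movement appears at session boundaries), then averaged within grid bins.
Rest is v ≤ 0.5 cm/s; movement is strictly above — the boundary value
classifies as rest, applied uniformly.  Movement bouts are maximal runs of
movement bins.  Onset detection operates at tracking rate: velocity is
zeroed wherever the centroid fails to move 1 cm within the following 1 s
(suppressing grooming/dithering in place), smoothed with a ~167 ms moving
average (5 frames at 30 fps), and an onset is the first frame of every run
with v > 0.5 cm/s lasting ≥ 2 s whose preceding 4 s are entirely at or
below threshold.  Onset rules run at tracking rate while epoch statistics
run at 5 Hz, mirroring the two measurement purposes (precise event
alignment vs. time budgets).

## Pairwise co-activity

The binary event raster (bins within detected events) is dilated 1 s
forward in time; this forgives small timing offsets between cells.  The
Jaccard index — co-active frames over frames where either cell is active —
is computed per pair, optionally restricted to rest or movement frames.
Pairs with an empty union are undefined and excluded.  Pairs are grouped
into half-open distance bins (50 µm default, 250 µm available) and each
bin's mean is divided by the mean of a shuffle null: each cell's
*unsmoothed* raster independently circularly rotated by a uniform offset,
then passed through the identical smoothing and scoring (1000 shuffles).
Circular rotation preserves event counts and run lengths, which is exactly
what the null must retain to control for activity level; full permutation
of bins would destroy event durations.  Normalization is bin-level (ratio
of bin means) rather than per-pair, because per-pair shuffle means can be
zero for sparse cells.  An all-frames denominator variant (co-active frames
over all scored frames) is exposed but not the default.

One caveat worth stating: when the analysis is restricted to one behavioral
state, the rotation null draws activity from the whole session, so a cell
that is systematically more active in the other state biases the
state-restricted normalized value away from 1 even for independent cells.
The rest-vs-move comparisons in the tests therefore isolate the shared-drive
mechanism with velocity-independent rates; on real data the same caveat
applies and the comparison is interpreted directionally.

## Spatial coordination index

Per frame, the distances between all co-active pairs (on the same
forward-smoothed substrate as co-activity, so "active" means one thing) are
compared with a shuffled null by a pair of one-sided two-sample KS tests;
the index is −log₁₀ of the smaller p-value, signed positive when the
clustered (left-shifted) side wins — so "more clustered" is larger, the only
orientation under which the index can meaningfully *peak* at movement
onset.  Frames with fewer than two active cells score exactly 0.

Two null schemes are provided.  The default permutes *cell identities*:
1000 random same-size subsets of cells are drawn, their pair distances
pooled into the null sample, and the p-value is the Monte Carlo permutation
tail of the one-sided KS statistic across the draws, computed as
(1 + #exceedances)/1000 (the standard conservative estimator).  The reason
this is the default is calibration: the C(a,2) pair distances of a active
cells carry only 2a coordinates' worth of randomness, so treating them as
an i.i.d. sample (as a plain two-sample KS p-value does) dramatically
overstates significance — in simulation, |SCI| > 2 occurred on ~9% of
uniformly random frames instead of the nominal ≤ 2%.  Cell-identity
permutation is exchangeable with the random-subset null by construction and
calibrates correctly (measured 1.9% at the |SCI| > 2 threshold).  The
second scheme (`distance_pool`) resamples frame-sized distance *sets* from
the pooled pair-distance list and applies the asymptotic one-sided
two-sample KS formula `exp(−2·n_eff·d²)`; it reproduces the
shuffled-distance description the index originates from and is fine for
comparative use, but its absolute p-values are anti-conservative for the
reason above.  Null samples are drawn once per distinct active-cell count
and reused across frames (the draws depend on nothing else); an option to
cycle several independent null realizations exists for tail-rate studies.
An exact enumeration over all cell subsets is provided for small
populations and is what the Monte Carlo p-values converge to.

Onset-aligned SCI averages the series at each offset across onsets and
divides by the mean over the 4 s pre-onset window — the rest period the
onset definition already guarantees; the reported peak is the maximum of
the normalized curve within 2.5 s post-onset.  The baseline window is a
package decision (the normalization denominator is otherwise
under-determined); it is exposed as a parameter.

## Group statistics

Single per-animal values are compared with two-sided Mann–Whitney U
(unpaired) or Wilcoxon signed-rank (paired) tests.  Correlated
within-animal measurements (per-distance-bin co-activity, per-velocity-bin
rates) are compared with a linear mixed-effects model — condition as fixed
effect, animal as grouping factor, per-(animal, stratum) means as
responses, equal weight per stratum — delegated to statsmodels MixedLM; the
module owns only the design construction and the reporting shape (β, SE, z,
p, 95% CI).  Singular fits raise rather than silently fall back.  α = 0.05,
two-sided, no multiplicity correction beyond that.

## Synthetic sessions (the generator)

The generator produces the statistical structure the analysis assumes, with
ground truth for every stage:

- **Geometry.** Centroids uniform in the field of view (600×600 µm
  default); ensemble centers uniform in the field inset by the ensemble
  radius, so a synthetic ensemble fits inside the field; a cell joins the
  nearest center within `ensemble_radius` (100 µm default).
- **Locomotion.** Alternating rest/move epochs with exponential lengths
  (defaults 6 s rest / 7 s bouts, the scale of open-field vehicle
  behavior); per-bout speed from a gamma distribution around
  `mean_move_speed` (4 cm/s), floored at 1 cm/s so bouts stay above the
  0.5 cm/s threshold; half-normal velocity jitter (0.1 cm/s scale) at rest.
  The centroid follows a heading random walk reflected at the walls of a
  60 cm arena, emitted at 30 frames/s in pixels (0.1 cm/px) so the full
  calibration and alignment path is exercised.
- **Events.** Per-cell rate `base_rate + rate_velocity_slope · v(t)`
  (defaults 0.01 events/s and 0.0075 (events/s)/(cm/s): ~0.6 events/min at
  rest rising to ~2.4/min at 4 cm/s, the scale reported for SPNs in
  miniscope studies).  Each ensemble additionally emits shared events as a
  state-modulated process (0.08 events/s at rest vs 0.02 during movement by
  default, producing the rest-dominant co-activity direction); each member
  fires with `p_coactivate` at exactly the shared time.  A 1.2 s minimum
  separation is enforced per cell: threshold detection cannot split
  transients closer than the transient width, so closer ground-truth events
  would be unrecoverable by construction.  The enforced separation makes
  the realized rate `1/(1.2 + 1/rate)` — the renewal thinning the tests
  account for.
- **Fluorescence.** A Ca²⁺ "event" stands in for a burst of action
  potentials, so each event renders as a compound transient: seven
  difference-of-exponentials kernels (rise 0.05 s, decay 0.4 s —
  GCaMP6f-like) spread evenly over a 1.0–1.4 s plateau, peak-normalized to
  a lognormal amplitude (σ = 0.25), plus white Gaussian noise (SD 0.08,
  peak SNR ≈ 12).  A single-kernel transient with a 0.4 s decay cannot stay
  above 2.5 trace-SDs for a full second once the trace SD includes the
  events themselves; the burst shape is both the physiological reading and
  the regime in which the stated detection rule operates.

What the generator does *not* emulate: photobleaching and slow drifts,
motion artifacts, neuropil contamination and segmentation cross-talk,
overlapping-cell demixing errors, non-Poisson firing statistics, graded
(distance-dependent) ensemble membership, and any onset-specific drive.
Passing tests therefore certify the statistical machinery — alignment,
normalization, detection, nulls, calibration — under clean conditions; they
do not certify robustness to extraction artifacts in real recordings.

## Problem sizes and determinism

Every stochastic component takes a seed (NumPy `default_rng`); a fixed
`SimConfig` reproduces a session bit-identically, and CSV round trips are
exact (`%.17g` writing, round-trip float parsing).  The test suite runs
sessions of 20–60 cells and 5–60 minutes with 200–1000 shuffles; the
end-to-end property tests use 20-minute sessions with 1000 shuffles for the
co-activity nulls and 15 000 frames for SCI calibration — sizes chosen so
each bin or tail estimate has standard error comfortably inside the asserted
tolerance.  Corner-distance bins hold few pairs in any square field, so the
flatness check pools pairs across eight session realizations and the
monotonicity check compares adjacent bins against 3× a leave-one-cell-out
jackknife SE (pairs sharing a cell are correlated, so naive per-pair SEs
understate bin noise).
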