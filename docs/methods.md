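# Methods

This note documents the models and procedures implemented in `ripplemap`,
the assumptions behind them, the defaults that matter, and the choices we
made where the design was genuinely open. Units: times in seconds on the LFP
clock (imaging frame k at `t0 + k / fs_img`), intervals half-open
`[t_start, t_end)`, positions in micrometers, delays in milliseconds.

## Ripple detection

The LFP is band-passed 120–250 Hz with a 4th-order Butterworth applied
forward and backward (zero phase; the effective roll-off is that of an
8th-order filter), and the ripple envelope is the magnitude of the analytic
signal. A channel event starts as a crossing of mean + 4.5 SD of that
channel's envelope and is extended to the surrounding crossings of the
channel mean. Candidates closer than 10 ms are merged (iterated to a fixed
point — merging can create new sub-threshold gaps) *before* the 20 ms
minimum-duration filter, because merging is specified ahead of discarding.
Envelope mean and SD are computed over the full recording per channel; an
optional sample mask can restrict them (e.g. to immobility), but no
re-referencing of the LFP is applied — data are analyzed as recorded.

Array-level events are the transitive closure of channel events under
"overlaps or gap < 10 ms"; their span is earliest member start to latest
member end. Manual artifact curation has no equivalent here; the optional
amplitude-rejection flag is off by default.

## Delay mapping

Each array event is padded by 50 ms on both sides and every channel envelope
is cross-correlated with the 16-channel mean envelope (lags limited to
±20 ms, sub-sample peak by parabolic interpolation). Positive delay = later
than the mean. Channels whose peak correlation is below 0.5 are invalid;
events with fewer than 13 valid channels are discarded, the rest are
completed by barycentric linear interpolation over the grid, with a
least-squares plane fit for points outside the convex hull of the valid
channels (grid corners) — the plane fit is exact for plane-wave delay maps,
which is what the interpolation is asked to restore.

Two numerical details matter:

* **Baseline handling.** Envelopes are non-negative bumps riding on a noise
  floor. Subtracting the window *mean* before correlating leaves both series
  with non-zero plateaus, and the product of those plateaus contributes a
  term proportional to the overlap length — a triangle peaked at lag 0 that
  systematically compresses recovered delays toward zero (we measured a
  ~0.63 regression slope against planted delays). We therefore subtract the
  window *median* (the baseline floor), which zeroes the plateaus without
  touching the bump.
* **Template sharpening.** The unaligned mean envelope of a traveling event
  is temporally blurred. `channel_delays` re-aligns the channels by their
  current delay estimates and recomputes the mean for a few iterations
  (default 3); with the baseline fix this brings the slope to ~0.99 and the
  per-channel error to ~0.7 ms at the generator's default amplitude.

## Envelope shape screen

Events whose envelope is not a single dominant peak make the delay estimate
unreliable. Each event's peak-power-channel envelope is resampled to 64
points, scaled to unit maximum, and compared by dynamic time warping
(absolute-difference cost, distance normalized by path-length bound) to a
unit Gaussian template with σ = length/6. Events farther than
mean + 3.5 SD of the population of distances are discarded; with fewer than
10 events the population statistics are meaningless and the screen is
skipped. The screen uses the peak channel by default (a flag averages the
distance over all channels).

## Features, clustering, group rules

Features are the 16 completed delays (centered per event on the valid-channel
mean) and the 16 per-channel mean squared ripple-band powers normalized by
the per-event maximum. Delay and power blocks are each rescaled to unit
pooled SD (idempotent, and equivalent to "equal SDs" weighting). K-means
runs for k = 2…10, best of 10 restarts by inertia (restart seeds
seed+0…seed+9, ties to the lowest), and k* is the maximum-curvature point
(discrete second difference) of the inertia curve. Cluster templates in raw
space (mean delays ms, mean normalized powers) feed the group rules, all
strict inequalities: traveling ⇔ delay span > 5 ms; active channel ⇔
normalized power > 0.6; global ⇔ more than 10 active channels. Span
(max − min) is used because delays are relative quantities — adding a
constant to all delays cannot change the label.

## Synchronous calcium events

ΔF/F is deconvolved by inverting a first-order exponential kernel
(`a[t] = max(0, f[t] − φ f[t−1])`, φ = exp(−1/(fs·τ)), τ = 0.4 s default);
this is deliberately simple, documented, and swappable — precomputed
activity can be passed straight in. Firing frames are activity >
mean + 3 SD per cell; the coactivity count at frame t is the number of
cells with ≥ 1 firing frame in the 5-frame window centered on t (edges
truncated). The SCE threshold is the 95th percentile of counts pooled over
20 circular shuffles of every cell's row; runs of supra-threshold frames
collapse to one SCE at the peak-count frame. Co-occurrence uses ±200 ms;
significance redraws the SWR times uniformly 1000 times (inside immobility
epochs when a state mask exists — unrestricted redraw against
immobility-locked SCEs would inflate significance) with the +1-corrected
p-value.

## Cell assemblies

A cell is active at a ripple when its mean ΔF/F in ±150 ms around the onset
exceeds 0.30 (applied to ΔF/F as provided, no rescaling). The Jaccard matrix
of active-event sets (both-silent pairs get 0; diagonal 1) is pruned by a
per-pair null: 200 surrogates in which each cell's active set is replaced by
a uniform random subset of the same size; the pair's threshold is the 95th
percentile of its null similarities (percentile configurable — the exact
level is not pinned down by the procedure we reimplement).

Two choices here are deliberately stricter than a literal reading:

* **Pruning keeps only J strictly above the threshold.** The null similarity
  of a pair is a discrete quantity (small integer overlaps); a large
  probability mass can sit exactly at the 95th percentile, and keeping ties
  would let two to three times the nominal 5% of chance pairs through. A
  pair sitting exactly at its chance percentile carries no evidence of
  association. (Corollary: a pair of cells active at *every* event has a
  null degenerate at 1 and is pruned — such a pair is indistinguishable from
  its own shuffle null.)
* **The size null is the per-surrogate maximum community size.** Louvain
  communities are found on the pruned graph (weighted by default, seeded;
  isolated cells are singletons) and the identical pruning + detection runs
  on every surrogate. The minimum assembly size is the 99th percentile of
  the *largest* community per surrogate. Pooling all surrogate community
  sizes instead would give each real community a ~1% tail chance, and with
  ~10 communities per partition roughly one structureless session in ten
  would yield a spurious assembly; the max statistic makes the filter
  family-wise, so a structureless session passes ~99% of the time.

Hard-partition community detection assigns *every* cell somewhere, so
surviving assemblies typically contain their planted membership plus weakly
attached cells; the size filter, not the partition, is what controls false
assemblies.

Firing ratio of assembly A in cluster c = mean over c's events of the
fraction of A's members active. The null permutes event→cluster labels
10,000 times (one shared permutation set across assemblies). We report
upper-tail, lower-tail and two-sided (+1-corrected) p-values with the
2.5/97.5 null percentiles, and BH-adjust the two-sided p across all
assembly × cluster tests; clusters with < 5 events are flagged low-power.
Recruited-cell counts per event are compared across clusters or groups by
rank-sum with BH correction.

## Decoding

Features: per-event, per-cell mean ΔF/F over frames in the half-open
±150 ms window. Classes are balanced by subsampling without replacement to
the smallest class. The classifier is a linear one-vs-rest SVM (squared
hinge, C = 1 fixed — no tuning, to keep the procedure simple and honest);
recursive feature elimination removes the 50 features with the smallest
aggregate squared weight per round and keeps the subset with the best
cross-validated accuracy. By default RFE runs *inside* each training fold of
the stratified 10-fold CV (leak-free); a flag reproduces the simpler
whole-set variant. The chance reference is a label-permutation null — the
same folds refit on permuted labels (50 permutations by default) — giving a
distribution around 1/k rather than a point value; the permutations use the
plain classifier without RFE, since feature selection cannot raise the
expectation of a null accuracy, only its cost.

Controls: "holding" draws a fraction f of cells uniformly from the union of
all assemblies; "in-order" concatenates whole assemblies in random order and
truncates to the same count. Both run `reps` times with matched seeds and
are compared per fraction by Wilcoxon signed-rank with BH correction; the
mean pairwise distance of the drawn cells is recorded when centroids are
available. The assembly-label shuffle control permutes membership across all
cells and recomputes in-order decoding per permutation.

## Spike–ripple analyses

Phase convention: phase is the angle of the analytic signal of the
ripple-band LFP, so 0 sits at the signal maximum (cosine phase) and the
rising zero-crossing at −π/2. Phases at spike times come from linear
interpolation of the unwrapped phase. The PLV is the magnitude of the mean
unit phasor; per channel it uses only spikes inside that channel's ripple
intervals (flag to use all spikes), with an n < 20 low-count flag, a
closed-form Rayleigh test (Zar's approximation, cross-checked against an
independent implementation in the tests), and a resampling null for
uniform-phase reference. Spike–calcium matching counts spikes inside each
nearby cell's (≤ 100 µm) transient intervals against a null of 10,000
circular time shifts (shifts preserve inter-spike structure, which a uniform
redraw would destroy), one-sided p, BH across cells.

PSTHs are spike counts binned relative to event onsets, averaged over
events, in Hz with SEM over events; the integral over the window equals the
mean spike count per window by construction.

## Traveling theta

Per-channel theta lags come from the circular mean of the instantaneous
phase differences between each channel and the grid-mean phase (4–8 Hz
band), divided by the measured instantaneous frequency; the plane fit
`delay(x, y) = ax + by + c` gives speed `1e-3/|(a, b)|` m/s and propagation
direction `(a, b)/|(a, b)|`. A flat delay map returns the stationary
sentinel (infinite speed); collinear layouts are rejected. The estimation
method for wave speed is not pinned down by the procedure we reimplement;
the plane fit is our choice and is exact for an ideal plane wave.

## Synthetic data: what it emulates, and what it does not

The generator plants: pink (1/f) background noise; alternating
immobility/running epochs (30 s); ripples only in immobility as
Gaussian-windowed 150 Hz carriers with per-event σ ∈ [15, 25] ms, peak
amplitude 8× the broadband noise SD (±10% per event), drawn from the four
archetypes with equal weight; a traveling theta plane wave (6 Hz, 0.15 m/s
default) only in running; disjoint cell assemblies (default four, 30–140
cells) each preferring one archetype, members responding with probability
0.8 (others 0.05) via unit-peak double-exponential GCaMP kernels (rise
50 ms, decay 400 ms, amplitude 1.5 ΔF/F) on Gaussian noise (σ = 0.05) plus
sparse spontaneous transients; and Poisson multi-unit spikes whose in-ripple
rate is gain-multiplied and whose extra spikes sit at von Mises(µ, κ = 4)
phases of the *recorded* home-channel carrier.

Two structural choices keep the archetypes coherent within a session: the
seed channel of local events and the travel axis are drawn once per session
(± 5° per-event jitter on the axis). This models a session-stable generator
site and a fixed anatomical propagation axis — ripples that travel do so
along a consistent hippocampal axis — and it is what makes the four
archetypes four clusters rather than a continuum of seed sites. "Local"
footprints are Gaussians (σ = 300 µm) with a 0.3 amplitude floor so that
every channel carries a correlated (if weak) copy of the event; "global"
profiles are flat with ±5% jitter.

What the generator does **not** emulate: sharp-wave (stratum radiatum)
components, ripple-frequency drift within events, photon-shot or motion
artifacts in imaging, neuropil contamination, overlapping assemblies
(memberships are disjoint unless requested), cross-hemisphere structure, or
any dependence of ripple amplitude on behavior. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it assumes,
at realistic SNR — not that it is robust to every artifact of real
recordings.

A separate probe (`simulate_plv_probe`) plants identical ripple bursts on
all channels with per-event carrier phase offsets whose dispersion grows
with grid distance from a home channel, so that the expected PLV decreases
linearly with distance rank; note the effective sample size of a channel's
PLV is the number of events, not spikes, because offsets are shared within
an event.

## Problem sizes, tolerances, degenerate inputs

The validation suite measures: detection on a 10-minute 16-channel session
at 1250 Hz (~60 events); delay and classification accuracy on a 20-minute
session with ~200 events (~50 per archetype); SCE calibration on 500 × 18,000
Bernoulli rasters; co-occurrence calibration over 200 independent sessions
of 40 + 40 events; assembly recovery on 180 cells × 200 events with planted
40/60/80 blocks at 14% mean participation, with 100–200 surrogates; decoding
on ~200 events × 400 cells with 50-permutation nulls and 40-repetition
holding/in-order comparisons at the 25% fraction; phase locking on 400-burst
probes (~3000 spikes). `scripts/acceptance.py` re-runs the same measurements
from a single seed in about two minutes.

Numerical conventions: sampling at 1250 Hz is the default (20 kHz
supported); envelope delays are quantized by the sample grid before
parabolic refinement; K-means ties break to the lowest restart seed; the
permutation p-values use the +1 correction (no p = 0 from finite nulls);
zero-variance envelope or activity rows yield warnings and empty results
rather than errors; writers refuse non-finite ΔF/F; CSV floats are printed
with 17 significant digits so round-trips are bitwise.

## Known limitations

* Delay recovery is SNR-limited: at the default 8× amplitude the per-channel
  error is ~0.55 ms (sd); much weaker events will blur the
  traveling/stationary boundary at 5 ms.
* The elbow rule needs a genuine inertia kink; feature clouds without
  cluster structure yield an arbitrary small k (a warning covers the
  all-identical degenerate case).
* Hard-partition assemblies absorb weakly attached cells; membership lists
  should be read as "community containing the assembly", and the firing
  ratio dilutes accordingly.
* The deconvolution is a first-order inverse, adequate for event timing at
  30 Hz but not for spike-count inference.
* With fewer than ~10 ripples per archetype, balanced decoding and the
  10-fold CV are not meaningful; the code raises rather than silently
  reducing folds.
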