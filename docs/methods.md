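# Methods

This note documents the models and numerical conventions behind
`betapop`: what each analysis stage computes, what the synthetic-data
generator does and does not emulate, and the design choices made where
the underlying procedure left room.

## Spectral estimation and the beta cursor

Band power is estimated with the multitaper method using five Slepian
tapers. Only the taper *count* is conventionally reported for this kind
of online estimator, so the time–bandwidth product is set to NW = 3 via
the standard relation K = 2·NW − 1; tapers are normalized to unit
energy so the one-sided density integrates to signal variance
(Parseval, verified in tests).

The normalized beta estimate βest is the ratio of the channel-averaged
25–40 Hz band sum to the channel-averaged 1–100 Hz band sum. Band sums
include every frequency-grid bin whose center lies in the closed
interval. The grid follows the window length: the online cursor's
200 ms windows give a 5 Hz grid (beta bins {25, 30, 35, 40}); analyses
with ≥ 1 s windows use a ≤ 1 Hz grid, where a flat spectrum yields
βest = 16/100 = 0.16 exactly. Note a physical consequence of five
tapers on 200 ms: the spectral bandwidth is ±15 Hz, so even a pure
30 Hz tone leaves some power outside 25–40 Hz and βest saturates near
~0.76 at that window length; on a 1 s window it reaches ~1. Cursor
windows are trailing (causal), mirroring the real-time task; offline
spectrograms use centered windows.

The cursor pipeline applies a per-subject linear transform
(gain, offset) to βest and a two-timestep (200 ms) boxcar; the first
update passes through unsmoothed. A two-axis task variant adds
normalized 1–10 Hz power on the x-axis, computed identically.

Detrended spectrograms fit power = m·frequency + b over **all** trials
and timepoints and subtract the fit before trial-averaging, flattening
the 1/f trend; z-scored PSDs standardize each frequency across trials
(vectors M, S) before within-condition averaging, with zero-variance
frequencies dropped and reported.

## Burst labeling

The on-beta label is defined on one neurofeedback channel: 25–40 Hz
5th-order Butterworth bandpass, applied forward–backward (zero phase —
the labeling is offline, and burst timing must not be skewed by filter
delay), Hilbert envelope, threshold at the 60th percentile of the
day-level envelope distribution aggregated over rewarded trials, and
erasure of supra-threshold runs shorter than 125 ms (3–4 beta cycles).
Bins longer than 1 ms take the strict-majority label; exact ties
resolve to off-beta (the conservative choice). The zero-phase pass
doubles the effective filter order; its transient needs ~300 ms to
settle below 5%, which the tests respect with edge margins.

Interval recovery against generator ground truth counts an interval as
recovered when detections (dilated by a ±20 ms edge tolerance) cover at
least half of it, symmetrically for precision.

## Movement onset and speed labels

Velocity is projected on the unit center→target vector; from the peak
(i, M) a backward scan finds the first sample strictly below 0.2·M.
Boundary conventions, each pinned deterministically: the scan uses
strict inequality; the retention range [0.0, 0.7] s is closed; a bin
with mean speed exactly 3.5 cm/s is *slow*. "Onset acceleration" has no
standard formula in this setting; it is implemented as the
projected-speed time derivative at the MOT sample and flagged as a
convention. When hardware velocity is unavailable, velocity is derived
by central differences after a 50 ms moving-average smooth so
differentiation noise cannot create spurious peaks.

## Trend statistics

Cuzick's test uses midranks and the exact linear-rank-statistic
variance Var[T] = [Σ_j n_j (l_j − l̄)²]·[Σ_i (r_i − r̄)²]/(N − 1),
which reduces to the textbook (N+1)/12·(N Σ l²n − (Σ ln)²) without ties
and equals the permutation variance under ties — verified against full
enumeration for every grouping with N ≤ 8. Z is referred to the
standard normal; the tests reproduce the classical sanity check
(10,000 label shuffles vs N(0,1) by Kolmogorov–Smirnov) and nominal
type-I error.

Quartile re-labeling assigns label ⌈rank·k/n⌉ with max-ranks, so
boundary values fall in the lower quartile and group sizes differ by at
most one up to ties. Residualized trends regress the metric on
time-to-target and re-test the residuals. Nested model comparison uses
the standard F with (q, n − p − 1) degrees of freedom, where q is the
number of added coefficients.

## Chance-level simulation

Each simulation permutes the session's realized target sequence
(preserving target frequencies — "shuffled", not resampled) and walks
the displayed cursor trace. The cursor is piecewise-constant between
100 ms updates; a hold completes in continuous time 450 ms after its
start if the displayed position stays in band, and a success consumes
hold + mean-reach + reward + ITI before the next target. This
continuous-time accounting makes an always-in-band cursor acquire
exactly ⌊session/cycle⌋ targets, which pins the arithmetic. A target
unmet within the 60 s timeout repeats, so elapsed trace time is simply
consumed. The observed rewards/min is z-scored by the mean and SD of
the simulated distribution; a zero-spread distribution yields NaN
(reported, never fabricated).

## Unit coupling and the decile mapping

For each task, rewarded trials are sliced (−1.5, +1.0) s around the go
cue, spike counts binned at 1 ms (2500 samples/trial) and concatenated;
the beta envelope is computed the same way as for labeling. Timepoints
are sorted by envelope (spike rows co-sorted), both reduced to decile
means — log10 amplitude on one side, rate in Hz (counts × 1000) on the
other — and a least-squares line through the 10 pairs gives the slope
in Hz per log10-amplitude. Non-positive amplitudes are floored at the
smallest positive envelope value before the log, with a warning. No
rate smoothing is applied beyond decile averaging. Stability uses
interleaved even/odd timepoint halves, or two 75% subsets (overlapping
by construction) where one task has limited data; cross-task shifts are
assessed with paired t-tests over units.

## Population decoder

Spike counts at 25 ms over the (−1.5, +1.0) s window give 100 bins per
trial; z-scoring uses each unit's CO-task mean and SD (zero-variance
units are excluded and reported); chunks concatenate the current and
two previous bins (3 × n_units features, 98 chunks/trial). A chunk is
PreMO iff its last bin ends before the trial's MOT; beta and speed
labels are 2-of-3 majorities. The classifier is a standard logistic
regression (monotone increasing in β₀ + β₁·X toward PostMO) with a mild
L2 penalty (C = 100) for numerical stability with 3·n_units features;
training uses the first two-thirds of CO trials *in trial order* to
avoid leakage through chunk history. The movement-onset threshold
maximizes percent-correct on the held-out CO third over a 0.005 grid,
ties resolving toward 0.5; the signed distance is measured in
probability space, p(PostMO) − threshold. "Chosen" units are those
whose single-unit classifier separates held-out PreMO from PostMO
(one-sided Mann–Whitney) and scores on-beta slow chunks below off-beta
slow chunks, in both tasks; group contrasts use Kruskal–Wallis. Beta
rhythmicity has no standard definition here and is left to the caller
as a per-unit metric input.

## Synthetic data generator

The generator's job is to produce sessions in which each analysis has a
known right answer.

**LFP.** 1/f^α background (α = 1 by default) by spectral shaping of
white noise, RMS 10 (arbitrary units), independent per channel. Bursts
are non-overlapping intervals from a Poisson count process, durations
uniform in 0.2–0.5 s, carrier drawn uniformly per burst, under a
plateau envelope with 50 ms raised-cosine onset/offset ramps, added to
all channels. Carriers default to 27–37 Hz: the detection bandpass has
|H|² = 0.5 at the 25/40 Hz band edges, so edge carriers are
half-attenuated and structurally under-detected; keeping carriers
inside the filter skirts makes burst recovery measure the labeling
logic rather than filter roll-off (the range is configurable).
`burst_amplitude_gain` is expressed in units of the *mean background
beta envelope* (Rayleigh mean = √(π/2) × band RMS): gain 3 means the
burst's peak envelope is three times the typical background envelope.
Burst rates per condition default to 0.25/0.40/0.55/0.70 bursts/s for
beta targets 1–4 (CO 0.4), giving on-beta occupancy ordered by target.
The burst-recovery benchmark uses 1.6 bursts/s (~45% occupancy), the
regime in which the day-level 60th-percentile threshold sits above the
background envelope range; at low occupancy that same percentile falls
*inside* the background distribution, where the band's ~60–70 ms
envelope correlation time makes >125 ms background runs intrinsic
(~0.1–0.5/s) and caps precision near 0.87 regardless of burst strength.

**Kinematics.** True MOT per trial from a normal with condition-level
means (defaults 0.25/0.28/0.31/0.34 s for targets 1–4, SD 0.08 s),
truncated to (0, 0.7). The projected speed is a Gaussian bell (width
0.12 s, peak 15 cm/s) positioned so its 20%-of-peak crossing falls
exactly at the true MOT; since the bell rises monotonically to its
peak, speed before the MOT stays below 20% of peak by construction, and
the backward-scan estimator recovers the true MOT to within ~1 sample
on noiseless profiles. MOT–beta coupling is implemented through
condition means, not per-trial closed-loop feedback: the claim under
test is condition-level ordering.

**Spikes.** Per-unit inhomogeneous Poisson,
rate(t) = max(0, baseline + slope·log10(envelope(t)) + step·1[t ≥ MOT]),
sampled by thinning against the rate maximum. Defaults: baseline 20 Hz,
slopes ~ N(−6, 2.5²) Hz per log10-amplitude (beta suppresses firing),
steps ~ N(+10, 3²) Hz. Negative clamped rates are a simulation artifact
of the linear model; a unit clamped on more than half its samples is
reported. Spikes are driven by the *realized* Hilbert envelope of
channel 0, so the mapping estimator sees exactly the covariate that
generated the rates.

**What it does not emulate.** No biophysical beta generation, no
spike-waveform or sorting noise, no EMG or movement artifacts, no
per-trial closed-loop neurofeedback, no cross-day nonstationarity.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated statistical model, not robustness to
every pathology of real recordings.

## Problem sizes and determinism

Recovery analyses use sizes at which their statistical claims have
power on a single CPU: slope recovery 30 units × 300 trials; the
behavioral trend 250 trials/target over 100 generator seeds (the
kinematics→MOT→trend path, which is the part of the pipeline that
consumes kinematics); the decoder contrast 6 synthetic days × (30 CO +
32 NR trials) × 12 units, with a zero-coupling control. All randomness
flows from `numpy.random.Generator` seeds; a single pipeline seed fans
out to per-stage children via `SeedSequence.spawn`, so stages are
independently reproducible and fixed-seed runs are byte-identical.

## Known limitations

- The decile mapping assumes rate linear in log10 amplitude; curvature
  would bias the slope (as in the underlying procedure).
- The chance simulation models only in-band holds — hand-exit errors
  during the neurofeedback epoch are out of scope.
- The session container keeps one day per `Session`; cross-day
  analyses are composed by the caller (lists of day results).
- With 5 tapers on 200 ms windows, βest of narrowband signals
  saturates below 1 (taper bandwidth), which is a property of the
  estimator, not a bug.
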