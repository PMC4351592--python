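# Methods

## Task model

A trial begins when the animal presses the center ready lever, which
simultaneously lights one of five cues (LL, L, C, R, RR); the left and
right response levers extend 2 s after cue onset, and the first response
press defines the reported choice. For directional-choice analysis the
two left cues collapse to "left" and the two right cues to "right";
center-cue trials are excluded. Trial classes are cue-side × press-side:
`L-L` and `R-R` (correct), `L-R` and `R-L` (errors). Sessions enter
analysis only with at least 20 trials in each correct class, the same
inclusion rule applied to the recorded data this pipeline targets.

Analysis windows are a fixed half-open catalog relative to their anchor:
BC [−500, 0) ms before cue onset (the pre-cue baseline is taken as the
500 ms immediately preceding the cue), CO [300, 1800), CO1 [500, 1000),
CO2 [1000, 1500), CO3 [1500, 2000) after cue onset, and LP [−100, 400)
around the first response press. Half-open intervals everywhere: a spike
on a boundary belongs to the later bin, so nothing is double-counted.

## Firing-rate statistics

Single-trial rates use a 100 ms boxcar sliding at 20 ms (50 estimates/s).
Window centers sit on the step grid starting at the interval start, so
edge windows extend up to half a boxcar beyond the interval; this keeps
the estimate count exact (50 per second) and makes the step = width case
a clean partition. A window's mean rate is the average of the sliding-bin
rates inside it, matching the sliding-estimate convention rather than a
single long count (equal in expectation, not per-trial).

Per-unit and ensemble statistics follow the definitions in the README.
Standard deviations (across trials, and inside Z-scores) use the sample
(n−1) form because session counts are small. Z-scoring is per subject
over sessions before any pooling. Per-bin class comparisons use the
two-sided rank-sum test (p < 0.01 flags); the pooled time-resolved
difference treats each unit-session record as one independent sample and
tests each bin against zero with a one-sample t-test (p < 0.001).

## Decoding protocol

Spike-count vectors concatenate per-unit bin counts unit-major in
ascending unit-id order, fixed across sessions. Defaults: CO window,
500 ms bins (3 per unit). Non-divisor bin sizes are rejected unless
truncation of the trailing remainder is explicitly enabled.

Each session's performance estimate aggregates `n_repeats = 100`
independent classifiers. Per repeat: draw a constant number of trials
per class (default: the smaller class count, for balance and maximal
use of data) without replacement; hold out ceil(20%) per class as raw
single-trial test samples (the ceiling guarantees at least one); build
the training set by repeatedly averaging `n_average = 5` distinct
same-class vectors, producing as many averaged samples per class as the
raw training set had trials (keeps set sizes comparable); fit; classify
test samples by the sign rule df ≥ 0 → left choice. Repeat accuracy is
pooled correct/total over both classes; session accuracy is the
unweighted mean over repeats. The class-distance metric is the
difference of class-mean decision-function values over test samples
pooled across repeats. The SVM uses a linear kernel with C = 1.0
(exposed in the config); LDA is available as a cross-check classifier
and shows the same qualitative behavior on generator data.

The shuffle control permutes the averaged training samples' labels
before fitting, leaving test labels untouched — the standard way to
destroy the label–feature association while preserving everything else.
Reproducibility: repeat r of a protocol seeded s draws from RNG stream
[s, r]; the shuffle permutation uses [s, r, 1]; ensemble-subset draws
use [s, 977, size]. The 100 repeats draw independently of one another
(each with replacement across, without replacement within).

The 1-D control (`mean_rate_decoding`) reduces each trial to the
ensemble mean rate over the window — the lowest-resolution
representation of the same data — and runs the identical protocol, so
spatiotemporal and rate-only readouts are compared like for like.

## Trend statistics

Slopes come from ordinary least squares against normalized session
number (first → 0, last → 1), with the confidence interval from the
slope's standard error and the t distribution (df = n − 2); the sign
call is positive/negative only when the whole interval clears zero.
Stage summaries split sessions into three contiguous stages of equal
length, extra sessions going to the last stage(s) (deterministic
remainder rule); stage pairs are compared by one-way ANOVA, which for
two groups is the two-sample t-test (F = t²). Slope comparison between
two measures on a common axis is the ANCOVA interaction term of
y ~ x + group + x:group. The across-subject behavior regression pools
subjects unweighted. The behavior summary compares first and last
sessions by rank-sum over per-trial success indicators, tests the early
latency drop by ANOVA over sessions 1–4, and regresses mean latency on
raw session index from session 4 onward (slope in s/session).

## Synthetic generator

The generator emulates the statistical structure of the target
recordings, not their biophysics. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_units` | 4 | ensembles of 3–6 units, 4.4 on average |
| `n_sessions` | 21 | learning spans ~18–30 daily sessions |
| `trials_per_class` | 56 | ~56–58 correct trials per class per session |
| `baseline_rate` | 10 Hz | typical motor-cortical single-unit rate; not constrained by the target data |
| `tuning_amplitude_schedule` d(k) | 3 Hz constant | cue-on class differences of ~2–3 Hz; no quantitative growth model exists for d(k), so learning scenarios pass an explicit schedule |
| `modulation_onset` | 400 ms | class difference emerges ~400 ms after cue onset |
| behavior curve | 0.308 → 0.760 | accuracy from ~31% (session 1) to ~76% (session 18); saturating exponential (smooth, monotone, two parameters) pinned to both endpoints |
| latency curve | 0.44 → 0.32 s | linear drop over the first three sessions, constant from session 4 |

Spikes are inhomogeneous Poisson with piecewise-constant rate in 100 ms
panels over [−1000, 3000) ms around each cue: a Poisson count per panel,
spikes placed uniformly within it — exact and fast at this scale.
Timestamps round to integer ms so sessions round-trip exactly through
the CSV interchange. Error trials (first press opposite the cue) are
appended until the session's accuracy matches the behavior curve; their
spike trains express either the chosen side's tuning (`error_tuning =
"choice"`, the default, consistent with motor-cortical patterns
following the choice) or the cued side's (`"cue"`), which is what the
correct-vs-error decoding control discriminates between. One master seed
drives everything; session k uses the subseed stream [seed, k], so any
session regenerates in isolation.

`rate_offset` mode adds a constant class difference over
[onset, 2000) ms, scaled so the CO-window mean difference equals d(k)
per unit; all units share a left preference, giving a positive pooled
difference. With `mean_conservation` (default) the offsets are
symmetric (±δ/2), so the class-averaged rate is the baseline for every
unit and session — analytically exact, not a sampling property; with it
off, the whole difference is added on top of the baseline and the mean
drifts with d(k).

`pattern_rotation` mode realizes rate-free pattern separation: the class
difference is +δ on [400, 900) and −δ on [1300, 1800) ms (sign
alternating across units). Per unit, the panel-wise difference sums to
zero, and over the CO window's three 500 ms bins the binned differences
(+400, +100, −500)·δ ms also cancel exactly — so the 1-D ensemble mean
difference and the per-unit window difference D^i are zero in
expectation, while individual 500 ms bins carry signal proportional to
δ. Raising d(k) across sessions therefore grows spatiotemporal
discriminability with flat M(k), D(k), and 1-D decodability.

What the generator does **not** emulate: non-Poisson spiking statistics
(refractoriness, bursting, rate drift within sessions), correlated noise
across units, movement kinematics (only a scalar latency per trial),
center-cue and multi-press trials, and any quantitative model of how
discriminability actually grows with learning — d(k) schedules are
scenario inputs, not estimates. Passing tests therefore demonstrate that
the pipeline's statistics behave correctly on data with the designed
structure, not that real recordings have that structure.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are desk-scale
choices of this package: chance-level and null checks use 4-unit
sessions with 50 trials per class and 100-repeat protocols over 20
seeds; the learning-dissociation scenario uses 21 sessions with
d(k) = linspace(0, 4) Hz and 50-repeat protocols; oracle equivalence
uses 1000 randomized small instances; CI calibration uses 1000 noise
simulations. Under the no-signal null, a single session's 100-repeat
mean accuracy has an SD of ~0.05 (repeats share one finite trial pool),
so chance-level bands are asserted on seed-averaged means.

Degenerate inputs fail loudly rather than silently: zero-spread
Z-scores, constant regressors, single-session normalization, too-few
trials for averaging (the error names the class), negative rates from
an over-large d(k), and LP windows on trials without a press all raise
with descriptive messages.

## Known limitations

- The resampled protocol's repeats are not independent (they share one
  trial pool), so per-session accuracy estimates carry correlated
  uncertainty; trend statistics treat sessions, not repeats, as samples.
- Pooled regressions and per-bin tests treat unit-session records as
  independent, inheriting the target analysis's convention; no
  mixed-effects alternative is implemented.
- The interchange format stores integer-ms timestamps, adequate for
  100 ms-scale binning but not for submillisecond analyses.
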