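# Methods

This note documents the models, the tunable parameters and their
defaults, the numerical choices, what the synthetic generator does and
does not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Event model and plumbing

A sensor event is `(timestamp, sensor_id, kind, value, room)` with kind
∈ {pir, door_contact, power, concussion, key_switch}. Binary kinds carry
0/1, power carries watts ≥ 0. Timestamps are naive local wall-clock
times: the system monitors a single home, and all features are defined
on local clock hours, so no timezone arithmetic is performed. Days are
cut at local midnight — the activity maps are hour-of-day indexed, so
days must align with clock hours.

Validation drops events with unknown sensors, kind mismatches or
out-of-domain values (counted per reason); more than 50% rejects is
treated as corrupted input and refused. Exact duplicates are dropped and
PIR retriggers within a debounce gap (default 2 s, configurable)
collapse to one detection, preventing count inflation in maps and
transition graphs. Validation is idempotent.

## Component 1 — assessment-score prediction from IMU windows

Windows are 1 s blocks of 3-axis samples from four modalities. Each
modality is reduced to its magnitude series √(x²+y²+z²), then to
mean/std/peak and a dominant-frequency proxy (mean-crossing rate). The
prediction step is a contract (`ScorePredictor`): any model mapping
feature sequences to per-window TUG categories and SPPB points can be
plugged in. Learned predictors for this task exist but their
architectures and weights are out of scope here; the bundled
`AmplitudeThresholdPredictor` is a transparent heuristic calibrated to
the simulator's gait encoding: a sinusoidal gait oscillation of
amplitude A on top of gravity gives magnitude std ≈ A/√2, and the
decision thresholds are the midpoints of the simulator's amplitude
ladder (TUG categories 1..4 ↔ low-range-accel amplitudes 0.80, 0.55,
0.35, 0.15 g; SPPB p ↔ wide-range amplitude 0.10 + 0.05·p g). Passing
the recovery tests therefore shows the aggregation/linking machinery is
sound, not that real gait can be scored this way.

Per-window scores are aggregated per period by majority vote; ties break
toward the more impaired score (higher TUG category, lower SPPB) so the
system errs on sensitivity. When a period has no windows, the assessment
record substitutes. Change detection compares ICF qualifiers of
consecutive monthly periods; if the two items disagree on direction, the
component reports deterioration, again erring toward sensitivity.

The TUG band edges (10, 20, 40 s → categories 1|2|3|4) are exposed in
the link-table configuration: the qualifier mapping for category 2 is
fixed by the published worked case, but band edges themselves are a
design choice consistent with all published case values. Qualifier 1 is
unused by the default TUG map.

## Component 2 — meal preparation and body weight

Interval algebra (all configurable): a power reading above the standby
threshold (5 W) opens an active interval; the interval ends `close_gap`
(60 s) after the last above-threshold reading, or at the first
below-threshold reading if sooner. Kitchen PIR/door events are
zero-length activity marks that extend a session when they fall within
`merge_gap` (10 min) of one, but add no time on their own. Intervals and
marks merging transitively within `merge_gap` form preparation sessions;
daily minutes are the summed spans of sessions containing at least one
power interval.

Change detection compares a period's mean daily minutes against a
reference period; the flag is |Δ|/ref ≥ δ with δ = 0.15. The pipeline
uses a 3-month lookback reference (periods `(max(0, T+1−3), T+1)`): the
component's target capability is a 5% weight change within 3 months, and
a gradual 3-month decline never exceeds a month-over-month threshold.
With the generator's coupling (0.2 kg per daily preparation minute, 70 kg
body weight, 70 min/day baseline), a 5% weight change implies a 25%
preparation change and a 1 kg change implies 7%, bracketing δ with wide
margins. Both periods need ≥ 7 days of data, else the component reports
unavailable; unavailable outputs are excluded from fusion rather than
read as "no change". Direction is never claimed — the rank coupling is
sign-ambiguous.

## Component 3 — concept drift and activity trend

**Probability maps.** Per-map normalization is the default (all
sensor×hour cells of a day sum to 1), making the map a joint
distribution over sensor and hour and the total-variation distance well
defined; per-sensor normalization is available as a config switch.

**Day classification.** The statistic is TV distance between the day map
and the baseline map (mean of the 7 most recent normal days). The null
is built by double resampling from the pooled day+baseline distribution:
each iteration draws both a synthetic day (at the day's event count) and
a synthetic baseline (at the window's total count), so the baseline's
own sampling noise is inside the null — resampling the day alone is
anticonservative. Counts are deflated by the window's Pearson
overdispersion (mean χ²/df of window days against the window mean, with
a k/(k−1) small-sample correction, floored at 1): daily event streams
cluster (movement bouts, appliance reading blocks), so per-cell counts
spread wider than a multinomial, and an uncorrected null rejects far too
often. With B = 1000 seeded resamples the decision is: same-distribution
probability < α (default 0.05) ⇒ abnormal. An event-free day is abnormal
outright. Tests verify the false-abnormal rate on stationary days
matches α within a binomial 95% CI under a fixed baseline; the adaptive
update (below) biases the window toward central days and can shift the
effective rate by a few points in either direction, which is acceptable
for an alarm system whose threshold is meant to be tuned online.

A note on the decision convention: a *small* probability of coming from
the same distribution means *abnormal*. Descriptions of such detectors
sometimes state the inverse wording; this implementation follows the
statistically meaningful direction.

**Baseline update.** Normal days enter the rolling 7-day window (oldest
evicted); abnormal days never touch it, so the reference adapts to slow
behaviour change but holds through anomalies.

**Transition graph.** Consecutive PIR events in different rooms within
`max_gap` (300 s) increment the directed edge between the rooms;
same-room pairs and longer gaps (returns after an absence) count
nothing. Daily activity = total edge weight; the baseline activity is
the mean over the first 7 days, and daily percent differences
(day−baseline)/baseline are tracked with x = days since T0. The trend is
an OLS line; the slope source priority is: personal fit when ≥ 30 daily
differences exist, else the configured group's reference slope (control
−8.5829×10⁻⁴/day, intervention −4.9948×10⁻⁵/day — the control group
declines an order of magnitude faster, which makes the score more
sensitive for residents not following an exercise programme), else 0.

**Score and output.** f_env = |s| + c/p, flag = 1 iff f_env > 0.3.
Attribution: e115 when abnormal days contributed (c > 0), e245 when the
slope contributed (|s| > 0). Note the magnitudes: a realistic |s| is
~10⁻³–10⁻⁴, so crossing the 0.3 threshold is in practice driven by
abnormal days, with the slope as a sensitizer near the boundary (e.g.
c = 9, p = 30 gives exactly 0.30; any non-zero slope tips it).

## Fusion

Alarm = OR over present component flags. "Absent ≠ 0": a component that
is unavailable (not installed, resident does not cook, insufficient
data) is excluded, so it can neither suppress nor cause an alarm; fusing
an all-absent period is an error. Every alarm lists ≥ 1 ICF-item
attribution and no attribution exists without an alarm. Reports
serialize to JSON; the CLI renders a per-month timeline table.

## Synthetic household generator

What it emulates: hour-of-day-structured event rates per sensor
(inhomogeneous Poisson), room-to-room movement with stable transition
statistics (a Markov chain over rooms whose moves emit PIR events),
kitchen meal sessions producing appliance power intervals and the daily
preparation time, a monthly body-weight series coupled to preparation
time, a monthly mobility level driving TUG/SPPB and IMU gait intensity,
and a monthly assessment cadence of 31 days (matching a ~31-day average
visit interval). Defaults: ~150 moves/day concentrated in waking hours,
two meal sessions/day of 35 ± 5 min anchored mid-hour (08:10, 18:10
± 3 min), kettle 8 min at 1800 W sampled every 15 s, stove at 1500 W
every 60 s.

The weight coupling is deterministic by default (weight = 70 kg +
0.2 kg/min × (previous month's mean daily preparation − 70 min)): the
component's premise is a near-perfect rank coupling (|ρ| ≥ 0.99), which
any realistic measurement noise would destroy at monthly sample sizes; a
`noise_sd_kg` dial exists for sensitivity studies. Consequently the
Spearman recovery tests validate the coupling contract, not robustness
to scale error.

Meal sessions are anchored mid-hour deliberately: if session starts
straddle an hour boundary, a large block of power readings swaps between
adjacent hour bins from day to day — a structural variation that the
drift detector's within-day null cannot absorb, and real appliance
routines are not synchronized to clock hours in that adversarial way.

Drifts: `activity_decline` scales movement and ambient-sensor rates by
(1 + s·days) planting a percent-difference slope s; `routine_shift`
rotates event hours by an offset on affected days (ground-truth abnormal
days); `appliance_disuse` silences one sensor from onset;
`weight_loss` shrinks meal durations linearly over `span_days` to the
preparation deficit implied by the target weight fraction;
`mobility_decline` shifts TUG seconds and SPPB from an onset day.
`inject_drift` applies the first three to any existing event stream
(activity decline as p-thinning); the last two act on the generator's
meal/assessment synthesis, as they are not stream transformations.

Preset scenarios pin the study conditions: `drift-free` (all
invariants quiet), `control-decline` (the control-group reference slope
planted as gradual decline, plus a 12-day routine shift in the final
month — a gradual slope alone is ~10⁻³/day and can never cross the 0.3
threshold, and the adaptive baseline tracks gradual drift, so the
abnormal-day term must come from an abrupt component; c = 12, p = 31
puts c/p ≈ 0.39), `routine-shift` (+6 h from day 155),
`appliance-disuse` (kettle, day 155), `malnutrition` (5% weight loss
over 60 days from day 93), `fluctuation` (0.8 kg wobble, same schedule),
and `mobility-decline` (TUG +13 s across the 20 s band, SPPB −3, month
5). Same seed ⇒ byte-identical output.

What it does not emulate: physically realistic gait (the IMU encoding is
an amplitude ladder, see component 1), visitors beyond the key-switch
event kind, seasonal/weekday structure, sensor dropout or clock drift,
and measurement error on the scale. Passing tests on this generator
shows the pipeline recovers planted dynamics under its stated model
class, not clinical validity on real homes.

## Problem sizes and numerical choices

Default simulations run 310 days (10 monthly periods) at ~330 events/day
(~100k events), 40 IMU windows/month at 100 Hz; the permutation test
uses B = 1000 resamples per day. These sizes keep a full-pipeline run in
the tens of seconds on one core while leaving the planted effects many
standard errors above their thresholds. Calibration and recovery suites
use 200 stationary days, 50 trend seeds (n = 300 days, σ = 0.05) and 20
seeds per weight scenario. All randomness (generator, permutation test)
descends from explicit integer seeds; reruns are bit-reproducible.

Degenerate inputs: zero baseline activity makes percent differences
undefined and is reported, not silently zeroed; constant sequences make
Spearman ρ undefined (NaN); a trend fit needs ≥ 2 distinct x; f_env
requires p > 0 and 0 ≤ c ≤ p.

## Known limitations

* The ICF link table's TUG row is configurable because published
  sources underdetermine the band edges; qualifier 1 is unreachable via
  TUG by default.
* Component 2's δ is calibrated against the generator's coupling
  constants, not against nutritional ground truth.
* The adaptive baseline's selection effect mildly distorts the
  false-abnormal rate relative to α (see component 3).
* Component 1's bundled predictor is a simulator-calibrated heuristic;
  real deployments must plug in a trained model behind `ScorePredictor`.
* e115/e245 outputs are change flags only; a facilitator/barrier score
  cannot be concluded from a probability map.
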