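# Methods

This note records the model behind each stage of the pipeline, the
parameters that matter, the choices made where the method left room, and
the known limitations — in particular the statistical character of the
threshold-crossing rules, which the test suite measures rather than
assumes.

## Stimulus model and conventions

All spike times are trial-relative with light onset at *t* = 0; the
pre-stimulus baseline occupies negative times. The standard protocol is a
full-field 1-s light step from darkness, 20 s interstimulus interval, 20
repeats, at an irradiance of 4.21 × 10¹⁵ photons·cm⁻²·s⁻¹; the
sensitivity protocol repeats this at six increasing irradiances, lowest
first. PSTH bins are half-open `[left, right)`, so a spike exactly at
onset belongs to the first ON bin; this gives a consistent tiling with no
double counting. The default analysis range is [−10 s, +8 s], covering
the baseline window and the ON/OFF/Sustained windows of a 1-s flash.

## Baseline statistics

Baseline mean is the average rate over the 10 s preceding onset across
trials. The SD that scales the detection thresholds is taken **across
the one hundred 100-ms bins of the trial-averaged PSTH** within that
window (population SD, ddof = 0). Rationale: the thresholds are applied
to the trial-averaged PSTH, so the noise scale must describe that same
object. For a stationary Poisson unit at rate *b* with *n* trials and bin
width Δ this SD is ≈ √(bΔ/n)/Δ (1.58 spikes/s at 5 Hz, 20 trials,
100 ms), which matters for the false-positive analysis below.

A silent or perfectly regular baseline has SD = 0 and would make the
thresholds degenerate; they are then widened to mean ± ε with
ε = max(0.5 spikes/s, one spike per trial per window), so floating-point
noise is never scored as a response. Such units are flagged
(`degenerate_baseline`) in the output.

## Classification

Windows for a flash of duration *D*: ON (0, *D*], OFF (*D*, 2*D*],
Sustained (2*D*, 8*D*] — the sustained span is six stimulus durations,
configurable via `sustained_multiplier`. Within a window:

* increase: rate > baseline + 3 SD for ≥ 100 ms contiguously;
* decrease: rate < baseline − 1 SD for ≥ 300 ms contiguously;

both thresholds and durations are `RunConfig` fields. Contiguity (rather
than cumulative time above threshold) is the default and is configurable
(`contiguous_runs`). If one window contains both a qualifying increase
run and a qualifying decrease run, the earlier-starting run decides the
window's state — a deterministic, time-causal tie-break.

The (ON, OFF, Sustained) triple maps through an explicit 27-entry lookup
table onto 10 classes. The prose definitions pin 19 entries (e.g.
increase/none/none → ON; increase/decrease/any → ON suppressed by dark;
decrease/decrease/any → suppressed ON-OFF; none³ → non-light-responsive;
increase with a sustained increase → slow sustained). The remaining
triples follow a fixed precedence — ON-window state > OFF-window state >
Sustained-window state — with two deliberate extensions: a
sustained-only increase (none, none, increase) is scored slow sustained,
since a slowly rising intrinsic response may first cross threshold after
the OFF window; and a sustained-only decrease maps to suppressed OFF,
the nearest suppressive class in time. The table is data
(`classification.LOOKUP_TABLE`), not logic, and is checked for totality.

## False-positive character of the crossing rules

The increase rule is a per-bin *z* ≈ 3 test repeated over every bin of
the three analysis windows (80 bins for a 1-s flash) with no multiplicity
control. For an ideal stationary Poisson unit at 5 Hz with 20 trials,
each trial-averaged bin is Poisson(10)/2, and
P(bin > mean + 3 SD) = P(X ≥ 20 | λ = 10) ≈ 0.0035 — more than the
Gaussian 0.0013 because of Poisson skew. Over 80 bins the family-wise
rate is ≈ 1 − (1 − 0.0035)⁸⁰ ≈ 24%. The decrease rule (three contiguous
bins below mean − 1 SD, per-bin p ≈ 0.13) contributes another ≈ 10%.
Roughly a third of ideal Poisson units are therefore scored as something
other than non-light-responsive, and about one strong responsive unit in
ten picks up a spurious extra window state (most often a false Sustained
increase that relabels ON as slow sustained). The acceptance suite
measures exactly this: ~52–59% specificity on 5 Hz Poisson units and
~90% archetype recovery at high signal-to-noise, and the per-unit
blockade-reversibility pattern inherits the same inflation.

This is a property of the rules at these settings, not of the
implementation. It is far less visible on real MEA data, where baselines
are not ideal Poisson and where flagged units were traditionally
re-checked by eye; that manual verification step is deliberately outside
this package, which is fully automatic. Raising the threshold or the
required duration would control the rate but would change the published
constants, so the defaults stand and the behavior is documented and
measured instead.

## Latency and amplitude

Amplitude: maximum rate in the component window minus the rate of the
100-ms bin containing the stimulus edge (onset for ON, offset for OFF).
The literal edge-referenced definition is the default; a baseline-mean
reference is available (`amplitude_reference="baseline"`). Values are
clipped at zero and depend only on rates relative to the edge bin, so an
additive offset to the whole PSTH cancels.

Latency: argmax-bin center within the component window of the 10-ms
PSTH smoothed with a normalized Gaussian kernel (σ = 20 ms, truncated at
±3σ, edges replicated), minus the edge time; ties break to the earliest
bin, and a flat window returns a missing value. The kernel is symmetric,
so it preserves the argmax of a unimodal peak; σ = 20 ms suppresses
single-bin noise while resolving latencies in the 150–400 ms range
typical of these responses. Bin centers make the report unbiased for
symmetric peaks.

Two statistical caveats, both verified by simulation in the acceptance
suite. First, the 100-ms binning trims a transient's peak, so estimated
amplitudes are compared against the same functional applied to the
noiseless generating profile, not against the profile's instantaneous
peak. Second, single-unit latency at modest signal-to-noise is
information-limited: with ~20 repeats a unit whose response peak is only
a few times the smoothed-bin noise will occasionally lock onto a noise
peak elsewhere in the 1-s window, so latency claims hold for the median
across units (and, at high signal, per unit), not for every unit.

Suppressed classes and non-light-responsive units receive no component
metrics; ON-OFF units contribute one row per component, and pooling
across units is left to the reporting layer.

## Sensitivity curves

Each irradiance block keeps its own 10-s pre-stimulus baseline (absorbing
slow drift over the ~40-minute series). Δrate at a level is the mean rate
over the first 400 ms of the step minus that block's baseline mean. A
unit enters the analysis only if its top-irradiance 400-ms rate exceeds
baseline + 3 SD; the five lower levels are then used regardless of
significance. No irradiance-response function is fitted.

## Behavior

The arena is 45 × 39 cm, divided along its width into equal light and
dark compartments joined by a 7-cm aperture centered on the divider.
Compartment assignment uses the tracked centroid with a 2-cm hysteresis
band: a crossing registers only when the centroid penetrates 2 cm past
the divider, which approximates the three-paws criterion (not computable
from centroid tracks) and suppresses chatter from divider-grazing paths.
Time in dark is time-weighted by midpoint intervals (robust to irregular
frame rates) and, with its light-side complement, partitions the trial
exactly. First-crossing latency is reported in minutes and is censored at
the 10-minute trial length when the animal never crosses; sessions that
start in the dark compartment violate the protocol and raise. Occupancy
heatmaps use a 1 × 1 cm grid (unstated in the original protocol; chosen
at the tracking system's typical resolution), conserve each session's
total dwell time, and are rendered with a 20 s ceiling while the raw
grids keep their values.

## Synthetic data

Rate profiles are a stationary baseline plus class-shaped modulations:

* fast transients — linear rise over 100 ms to a peak excursion at the
  component latency (defaults 0.32 s after onset, 0.35 s after offset),
  then exponential decay with τ = 150 ms, returning to baseline within
  the light step;
* plateaus spanning the step (ON-suppressed-by-dark);
* rectangular suppressions removing a fraction (default all) of the
  baseline for 600 ms — suppressive archetypes default to a 20 Hz
  baseline because a decrease is only detectable against sustained
  firing, while excitatory and silent archetypes use 5 Hz;
* a melanopsin-style envelope for the slow-sustained class — saturating
  rise (τ = 1 s) during the step, slow decay (τ = 10 s) after offset —
  which also survives simulated synaptic blockade, unlike every
  cone-driven archetype (`blockade_sensitive`).

Default peak excursions of 15 spikes/s sit in the range reported for
cone-driven RGC responses at photopic irradiance while clearing the
detection threshold comfortably at a 5 Hz baseline. Spikes are drawn per
trial from a 1-ms discretization of the profile, which is exactly an
inhomogeneous Poisson process with the discretized intensity: window
counts are Poisson-dispersed (tested), and every generator is
deterministic given its seed. Sensitivity series replace the archetype
waveform with a rate step over the full pulse whose height is the
level's gain, so the generating Δrate over the first 400 ms equals the
gain exactly. Arena tracks are biased random walks pursuing goal points
resampled every 5 s (dark-side goals with the configured preference, 8
cm/s nominal speed) with the divider acting as a wall outside the
aperture; the realized dark-side occupancy is recorded as ground truth.

What the generator does **not** emulate: refractoriness and other
non-Poisson spike statistics, inter-unit correlations, oscillatory
baseline rhythms of degenerated retina, electrode geometry, slow rate
drift within a block, and tracking noise or body-pose detail. Passing
recovery tests therefore demonstrates the pipeline's correctness under
its own statistical assumptions, not classifier performance on real
recordings — real baselines are less well-behaved than Poisson in some
respects (drift, oscillation) and better behaved in others
(refractory-driven underdispersion).

## Problem sizes

The test and reproduction runs use 50 units per class (1,000-unit scale
overall) for recovery, 100 units for specificity and metric recovery,
200 trials for trial-averaged sensitivity checks, and 8–10 simulated
animals per behavioral group; these sizes give standard errors small
relative to every tolerance tested while keeping a full run in the
single-digit minutes on one core.
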