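# Methods

## Task model

A session consists of stop trials.  In each trial the subject taps along
with an isochronous metronome (900 ms interval); taps are *anticipatory* —
drawn at metronome time plus a Gaussian offset with negative mean (default
−30 ms, SD 40 ms) — because synchronization, not reaction, is the task.
After 5–9 taps (uniform) a stop cue is played at a fixed delay (default
707 ms) after the **last registered tap**, not after the sound: timing the
cue from the tap prevents the strategy of delaying taps to gain stopping
time.  The stop outcome is Bernoulli (default p(success) = 0.55, the rate
the delay is titrated to produce).  Stopping performance is graded by
*movement extent*: the post-cue downward goniometer excursion as a
percentage of the preceding upward movement (0% = full stop, ~100% =
failed stop).  Successful stops split into full (< 10% extent) and
intermediate; failed means the pressure sensor was touched.

The time left to stop is an emergent quantity: the inhibited tap would
have occurred one metronome interval after the last tap, i.e. about
900 − 707 − 30 ≈ 160 ms after the cue.  The pipeline measures this
*stopping window* per dataset as the mean latency of failed taps after
the cue rather than hard-coding it.

## Synthetic signals

Channels: C3, C4, Cz, Fz, Pz, Oz (EEG), STN_contra/STN_ipsi (bipolar
LFP), EOG, FDI EMG, pressure, goniometer.  Neural channels carry 1/f
background noise (spectrally shaped white noise, exponent 1.0, unit SD —
all amplitudes below are in background-SD units, flattened below 0.5 Hz so
variance stays bounded).  Injected effects:

* **Stop-locked STN gamma burst** — a 70 Hz sinusoid under a Gaussian
  envelope (FWHM 90 ms; the envelope makes peak latency well defined for
  recovery tests) on STN_contra after each cue.  Outcome-coupled: peak
  amplitude 0.6 (success) vs 0.25 (fail), envelope peak at 106 ms
  (success) vs 179 ms (fail) after the cue; trial SDs 0.12 / 25 ms,
  between-subject SDs 0.08 / 12 ms.  Amplitudes were fixed once so that
  the group-level success-vs-fail difference lands in the "very large"
  range (standardized effect ≈ 1–2 for the 60–90 Hz stopping-window
  contrast at nine subjects), and so that the stop-related increase is
  stronger and spectrally sharper than the movement-related one — the
  qualitative structure the analysis is designed to detect.
* **Movement-locked effects** at every executed tap (regular taps, the
  escaped tap of failed stops, and partial flexion of intermediates,
  scaled by extent): a broad 55–95 Hz noise burst (amplitude 0.2, FWHM
  300 ms) on the contralateral motor channel and STN_contra, and a
  multiplicative dip (depth 0.6, FWHM 250 ms) in the ongoing 20 Hz beta
  oscillation (amplitude 0.35) on the same channels.
* **Slow cue response** — a 4 Hz Gaussian-windowed wave on Cz 150 ms
  after every cue, independent of outcome (salience, not inhibition).
* **Artifacts** — Poisson blinks (10/min) as 250 ms Hann deflections on
  EOG, leaked into EEG with fixed per-channel coefficients (Fz 0.15 …
  Oz 0.01).
* **Effectors** — goniometer flexion bumps (raised cosine, 450 ms, depth
  scaled by extent) plus sensor noise; 120 ms half-sine pressure pulses
  only when the finger actually lands (regular taps, failed stops); EMG
  bursts iff extent exceeds the 10% full-stop threshold.
* **Optional STN–M1 gamma carrier** (`gamma_coupling_amp`, default 0) —
  shared 65–75 Hz band noise on STN_contra and the contralateral motor
  channel that collapses for 300 ms after each cue, providing ground
  truth for the ISPC-decrease analysis.  It is off by default because the
  carrier is itself stop-locked band power and would be conflated with
  the burst effects in the power contrasts; the connectivity driver and
  tests enable it explicitly.

Determinism: per-subject seeds are spawned from the cohort seed
(`SeedSequence`); identical configuration gives bit-identical output.

What the generator does **not** emulate: volume conduction and realistic
cross-channel covariance, non-stationary background spectra, tremor,
line noise, electrode drift, and any amplitude–extent coupling beyond the
outcome classes.  Passing recovery tests therefore demonstrates that the
analysis measures what it claims under the assumed effect structure — not
that the effects exist in patients.

## Preprocessing

DC removal is a first-order IIR high-pass with RC = 2 s, applied forward
only (it models the acquisition hardware's AC coupling; zero-phase
behavior is deliberately not claimed, and the first/last 4 s are flagged
as edge regions that epochs must avoid).  EEG is re-referenced to linked
earlobes when A1/A2 exist, otherwise to the common average of the scalp
channels only.  Eye artifacts are removed per EEG channel by subtracting
the 40 Hz low-passed EOG (Butterworth order 6, forward–backward) scaled
by the closed-form least-squares projection coefficient — the same
optimum an iterative optimizer would find, but exactly reproducible; one
scale per channel over the whole recording.  Signals are then
downsampled to min(1000 Hz, input rate) by polyphase resampling.
Recordings without EEG pass through the EEG-specific steps untouched.

## Spectral analysis

Two-resolution filterbank: 3 Hz-wide bands stepped 1 Hz over 3–40 Hz and
10 Hz-wide bands stepped 2 Hz over 50–120 Hz.  Each band is isolated with
a zero-phase order-6 Butterworth **band-pass** (forward–backward).  A
single band-pass design was chosen over separate high-/low-pass stages:
at these band widths cascaded order-6 high+low stages attenuate the band
center itself by up to ~6 dB two-pass, whereas the band-pass is maximally
flat there, giving the clean calibration "tone of amplitude A → envelope²
= A²" that the tests rely on.  Per-frequency normalization cancels any
flat gain anyway; the choice matters only for absolute power.

Power is the squared magnitude of the analytic (Hilbert) signal (a plain
envelope flag exists as a sensitivity probe), smoothed with a centered
100 ms moving average (edge-renormalized so constants are preserved) and
downsampled to 200 Hz.  High-band filtering runs at the full rate before
that downsampling — 120 Hz content cannot exist at 200 Hz.

Epochs are aligned to the stop cue, to tap onsets, or to the *virtual
stop*: second-to-last pre-cue tap + stop delay, i.e. where the cue would
have fallen one tap earlier — a movement-matched reference trace.
Percent change is computed per subject and frequency against the mean
power over all regular taps, excluding each trial's first tap and the tap
directly followed by the cue.

Bipolar selection: per candidate contact pair, the median across taps of
the smoothed 60–90 Hz power time course in a window spanning twice the
tapping interval around each tap; the selection index is (max − min)/mean
of that median course, and the argmax pair is analysed.  Peak latency is
the argmax of the 60–90 Hz band time course inside a configurable window
(default 0–320 ms, wide enough for both configured burst latencies); ties
break to the earliest sample.  The 100 ms smoothing window is centered;
a causal window would shift apparent latencies by up to +50 ms.

## Connectivity

ISPC (mean-resultant length of phase differences) is computed per trial
over sliding windows — 200 ms for bands ≥ 50 Hz, 250 ms for 6–40 Hz
(more cycles per window at low frequencies; bands below 6 Hz are dropped
because 250 ms holds barely one cycle) — stepped 10 ms and timestamped at
the window center, then averaged over trials and normalized per frequency
by **subtracting** the mean over the −350:0 ms pre-cue baseline.
Subtraction (rather than a ratio, which is available behind a flag) keeps
the no-change null at zero for the against-zero cluster test.  Windowed
sums use cumulative phasor sums, so the sliding evaluation is O(1) per
window.

## Statistics

Per-pixel paired t over subjects; z is the signed probit of the two-sided
t p-value (reconciling t-score maps with summed z-scores), capped at
|z| = 8.21 for zero-variance pixels.  Clusters are 4-connected
suprathreshold regions (two-sided pre-cluster p < 0.05), positive and
negative separately; the cluster statistic is the summed z ("mass").  The
null permutes each subject's difference sign (pairing preserved, order of
subtraction flipped), 2000 permutations by default in the full analysis
(500–1000 in the scaled runs), recording the single largest |mass| per
permutation — max-statistic family-wise control, with both signs tested
against the same absolute-mass null.  A cluster is significant when its
|mass| exceeds the 95th percentile of the null; the reported
p = (1 + #{null ≥ |mass|}) / (n_perm + 1) ≥ 1/(n_perm+1).  Numerical
shortcuts in the permutation loop: the sum of squares is sign-flip
invariant, so each permuted t-map is a pure function of the flipped mean;
sub-threshold z values are irrelevant to masses and are set to zero, with
the supra-threshold t→z conversion done through a dense monotone
interpolation table (|z| error < 1e-6); all permutation maps are labeled
in one pass by stacking them along a non-connected axis.  A brute-force
per-pixel re-implementation serves as the oracle in the tests.

Correlations between movement extent and signal/behavioral covariates are
Spearman with percentile-bootstrap 95% CIs over paired resamples;
group-level inference Fisher-z transforms each subject's rho and applies
a one-sample t-test.  Families of tests are corrected with
Benjamini–Hochberg FDR (statsmodels step-up).  Pairwise comparisons use a
paired t-test unless a Lilliefors test rejects normality of the
differences (statsmodels table-based implementation — deterministic,
standard), in which case a Wilcoxon signed-rank test (exact for n ≤ 15)
is used; the branch taken is always reported.  The max-correlation search
scans every pixel in 60–90 Hz × the stopping window and returns the
extremum by |rho| with its location and bootstrap CI.

## Problem sizes

The default `SimConfig` carries the study conditions (9 subjects, 2048 Hz,
100 planned stop trials).  The test suite and the acceptance script run
scaled cohorts — 9 subjects × 24 stop trials synthesized at 400 Hz
(Nyquist 200 Hz comfortably above the 125 Hz top band edge) — which the
package treats as its standard desk-scale experiment; at these sizes the
headline contrast retains a standardized effect size well above 1 and
every recovery experiment is reliable.  The latency-recovery experiment
additionally isolates the stop-locked burst (movement gamma off,
amplitudes 0.8/0.5, trial latency jitter 15 ms, between-subject latency
SD zero): it is a measurement-chain calibration against the *configured*
106/179 ms values, so between-subject truth scatter is noise for that
comparison rather than signal, the bursts are kept strong and temporally
sharp so the peak is well defined, and the movement gamma of the escaped
tap — which overlaps the failed-stop burst in time by design — is
disabled.  The type-I-error calibration uses 500 null datasets
(9 × 40 × 50 grids) at 500 permutations; bootstrap coverage uses 2000
datasets of 60 pairs.

## Known limitations

* The generator's effect amplitudes are stylized; only their qualitative
  ordering (stop burst > movement gamma; success > fail; full >
  intermediate > failed) is anchored.
* Baseline normalization assumes stationary background power across a
  session; drifts would bias percent change.
* The ISPC time grid mixes 200/250 ms windows on one 10 ms-step axis, so
  low-band timestamps are quantized to the nearest grid center (≤ 5 ms).
* Cluster inference is two-sided by default; a one-sided flag exists but
  directionality of any given contrast is the caller's decision.
* `select_bipolar` assumes the candidate set already consists of valid
  bipolar derivations; it does not construct montages from raw contacts.
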