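# Methods

`whiskthal` analyzes single-neuron thalamic recordings from head-fixed mice
that receive two kinds of single-whisker deflections: passive 30-ms air
puffs and active touches of a pole that the animal reaches by whisking.
The package quantifies how first-order (VPM) and higher-order (POm) relay
neurons respond to each deflection kind, how the whisking state and
whisk-cycle phase modulate firing, whether kinematic differences between
puffs and touches explain response differences, and how cortical silencing
changes all of the above.  A synthetic-session generator provides a
ground-truth test bed for every stage.

## Whisking decomposition

The whisker angle (degrees, protraction positive) is first normalized by
subtracting the median angle over stationary samples (a two-pass scheme:
a first decomposition provides the stationary mask).  The normalized angle
is band-pass filtered in the whisking band, 3–30 Hz, with a zero-phase
5th-order Butterworth filter (`sosfiltfilt`, reflect padding of 3x the
effective filter order), and the analytic signal of the filtered trace
gives the instantaneous phase, with 0 = fully protracted and ±π = fully
retracted.  Whisk-cycle extrema sit at the phase transitions through 0
(protraction peak) and ±π (retraction trough).  Whisking **amplitude** is
the absolute difference of consecutive extrema (peak-to-trough, degrees)
and **setpoint** their mean; both are assigned piecewise-constant per half
cycle, sampled forward.  Extrema values are read from the band-passed
signal (robust to setpoint drift; the low-frequency residual is added back
into the setpoint); reading them from the raw angle is config-switchable.
Samples in maximal runs with amplitude > 3° lasting more than 200 ms are
**whisking**, everything else **quiescence**.  Band-pass ringing smears a
sharp bout edge by roughly one half cycle, so segment boundaries carry a
~0.1 s uncertainty; state labels away from bout edges agree with the
generator's ground truth on ≥95% of samples.

Phase at spike times (20 kHz events against 625 Hz video) is obtained by
linear interpolation on the unwrapped phase, rewrapped to (−π, π]; queries
whose enclosing video sample is quiescent are undefined (NaN).

## Events

Air-puff command times precede the actual whisker deflection by a
pneumatic line delay.  The delay is estimated once per session from the
command-aligned mean angle trace: the first sustained retraction
(3 consecutive samples below 3 s.d. of the pre-command baseline, backed
off to the deflection foot) gives a scalar delay added to all commands;
estimates outside 0–50 ms fall back to a configured default (19 ms).

Touches are read from the touch-area brightness trace: the threshold is
the midpoint between the two modes of the brightness distribution
(1-D two-means); maximal below-threshold runs are touch intervals.  An
effectively unimodal distribution yields no touches, with a warning.

Puffs and touches merge into one time-sorted deflection sequence.  The
inter-deflection interval is computed on this joint sequence (a per-kind
option exists); the first event's interval is measured from the recording
start, so first events land in the longest-interval group — they are
unadapted by construction.  The pre-event state (Q/W) is the mean
whisking amplitude in the 500 ms before onset against the 3° cutoff.  A
puff counts as laser-on only when the laser covers at least 5 ms before to
35 ms after onset.  Touch bouts are touch groups separated by ≥ 500 ms;
the first touch of each bout has within-bout index 1.  Manually curated
exclusion intervals (grooming, stuck whisker) drop intersecting events.

## Response quantification

PSTHs use 1-ms half-open bins (display window −25 to +75 ms), converted to
rate by dividing counts by bin width and trial count, and normalized for
display by the mean rate in the 25 ms before onset (log2 scale; a zero
baseline flags the neuron as not normalizable).  Responsiveness is a
Wilcoxon signed-rank test over per-trial spike counts in paired 50-ms
windows, one-sided for puffs (inclusion requires a rate *increase*, tying
the neuron to the stimulated whisker) and two-sided for touches.  Zero
differences are dropped (Wilcoxon's treatment); an exact distribution is
used at small n, a continuity-corrected normal approximation otherwise.
The modulation index MI = (post − pre)/(post + pre) is 0 at 0/0.
First-spike latency is the latency of the first spike within 75 ms of
onset; trials without such a spike are excluded rather than censored.
Population PSTHs convert each neuron to spike probability (divide by total
spikes), average, and smooth with a Gaussian "over a 10 ms window",
interpreted as s.d. = 2.5 ms truncated at ±2 s.d. (config-switchable to
s.d. = 10 ms); the smoothed trace is renormalized so total probability is
conserved exactly despite edge padding.

## State, amplitude and phase analyses

Q/W firing rates use steady-state time only: ±25 ms around state
transitions, ±500 ms around every deflection onset, and (for laser-off
assignment) laser transitions are excluded; the residual time is
stratified by state × laser and rates are spikes/duration per stratum
(strata under 1 s are flagged absent).  Significance uses a 10,000-fold
spike-time shuffle null built from circular time shifts of the whole
train — shifts preserve the ISI structure and rate autocorrelation, the
conservative reading of "spike-time shuffling" (ISI permutation is a
config option).  A stratum is significant when its observed rate falls
outside the 2.5–97.5 percentile interval of the shuffled rates.

Amplitude tuning bins whisking time in 5° amplitude bins and correlates
bin center with bin rate (Pearson r; two-sided p from the t distribution
with n−2 d.f.).  Note that with a state-dependent baseline the low-
amplitude bins mix in bout-edge time, so this correlation is a property of
the recording, not a pure within-whisking slope.

Phase tuning divides whisking time into 16 phase bins, normalizes spike
counts by per-bin occupancy, and fits f = ⟨Rate⟩ + Amp·cos(φ − φ_pref) by
linear least squares on (1, cos φ, sin φ); negative amplitudes are
resolved by a π shift.  The tuning signal-to-noise ratio is
SNR = (2·Amp/⟨Rate⟩)·√(⟨Rate⟩·T) with T = 0.111 s, one mean whisk cycle
(optionally estimated from data).  Significance is a Kuiper test of the
spike phases against the *occupancy* distribution — the null CDF is
piecewise-linear over the phase bins with slopes proportional to occupancy
— so phase locking is tested beyond what occupancy alone predicts.  The
Kuiper p-value uses the standard asymptotic series with the
(√n + 0.155 + 0.24/√n) effective-n correction.  The pipeline excludes
±500 ms around deflections from phase tuning: deflection-evoked spikes
occur at systematic phases (touches happen at pole crossing) and would
otherwise bias the fitted preferred phase.

## Kinematic matching

Each deflection gets window statistics on the 625 Hz series (central
differences for velocity and acceleration, no extra smoothing by default):
mean |angular acceleration| over ±25 and ±50 ms, mean normalized curvature
over 0–25 and 0–50 ms, curvature change over ±50 ms, signed and absolute
velocity over ±50 ms, and pre-onset (−50–0 ms) setpoint, amplitude, angle
and circular-mean phase, plus the inter-deflection interval.  Curvature is
normalized by subtracting the per-session median curvature during
quiescence (removes intrinsic whisker shape).  The pooled puff+touch
distribution of a feature is split into tertiles by rank (stable ties;
circular features are ranked after anchoring at −π), and per-neuron MIs
are computed per kind × tertile cell (cells under 5 events exclude that
neuron).  Population statistics use one-sided signed-rank tests within
condition and two-sided signed-rank tests between tertiles or kinds.
First-vs-later touches compare within-bout index 1 against >1, with the
baseline window always before the bout's *first* touch (both classes share
the bout baseline); neurons need ≥10 touches per class.

## Classification

Per-neuron puff and/or touch PSTHs, each normalized to its maximum rate,
are the features of an L2 logistic regression with internal 5-fold
stratified cross-validation over 50 log-spaced regularization strengths in
[1e−3, 1e2], trained on a stratified shuffled 75/25 split.  Significance
of the test accuracy is an empirical permutation test (default 256
permutations) that permutes the labels jointly over train and test and
re-runs the entire split/fit/test pipeline per permutation — the
conservative reading of permuting the PSTH-to-cell correspondence;
p = (1 + #{permuted ≥ observed})/(n_perm + 1), with floor 1/257.

## Synthetic sessions

The generator emulates the recorded paradigm, not raw biophysics:

* **Behavior.** Whisking bouts (exponential gaps at 0.3 bouts/s of
  quiescence, 1–3 s duration, raised-cosine ramps of 150 ms) gate a 9 Hz
  sinusoid (111-ms whisk cycle) with per-bout peak-to-trough amplitude
  20° ± 40%, an elevated setpoint (5° at full envelope), and 0.3° s.d.
  sub-threshold noise.  Stimulation alternates 60-s blocks of puffs, pole
  presence, and free whisking, as the recordings alternated 2–5 min
  periods.
* **Deflections.** Puff inter-command intervals are drawn from five
  candidates (50, 150, 350, 650, 1,250 ms); the deflection follows the
  command by a 19-ms line delay and adds a fast retraction transient
  (alpha kernel, 8°).  Touches are the maximal intervals where the
  noiseless protraction exceeds the pole angle (10°, reachable only by
  large-amplitude whisks) during pole blocks; touches bend the whisker
  (curvature ∝ over-protraction) and darken a synthetic touch-area
  brightness trace by a fixed step.
* **Spikes.** Baseline is an inhomogeneous Poisson process on the video
  grid: 6 Hz in quiescence, ×2 during whisking, optionally + amp_slope ·
  amplitude, times (1 − cortical_dependence) during laser-on.  A phase
  drive depth·base·cos(φ − φ_pref) is added during whisking and is *not*
  laser-gated (phase information arrives from the brainstem), so cortical
  silencing lowers ⟨Rate⟩ but not Amp and phase-SNR rises — matching the
  observed increase in phase locking under cortical silencing.  Each
  deflection releases a volley: K ~ Poisson(ν·resource·laser gain) spikes
  at a shared latency drawn from a Gamma distribution with mean
  `latency_ms` and s.d. `jitter_ms` (right-skewed, as empirical latency
  distributions are; a Gaussian at 15 ± 10 ms would put heavy mass near
  zero and bias first-spike estimates low), plus 1 ms intra-volley jitter.
  ν is `deflection_rate_hz` × 50 ms.  The relay resource depletes by
  fraction u per deflection and recovers exponentially with τ, shared
  between puffs and touches (one depressing relay).  Laser-on scales the
  volley by (1 − deflection_cortical_dependence), a separate parameter
  from the baseline dependence: scaling baseline and volley by the same
  factor would leave the scale-invariant MI unchanged, whereas the
  higher-order relay's deflection responses are nearly abolished
  (default 0.95) while its baseline only halves (0.6).
* **Profiles.** `NeuronParams.vpm_like()`: 42 Hz response over the 50-ms
  window, 15 ± 10 ms latency, weak depression (u = 0.3, τ = 0.3 s), no
  cortical dependence.  `NeuronParams.pom_like()`: 21 Hz, 27 ± 15 ms,
  strong depression (u = 0.8, τ = 1.5 s), strong cortical dependence.

What the generator does **not** emulate: multi-whisker fields, whisker
mechanics and real contact forces, spike waveforms, non-Poisson firing
(bursting), slow drifts in excitability, or grooming artifacts.  Passing
tests therefore demonstrate that the *estimators* recover known structure
under the stated statistical assumptions, not that real recordings meet
those assumptions.

## Validation experiments (problem sizes)

`whiskthal.calibration` fixes the experiment designs used by the tests and
by `scripts/acceptance.py`:

* Type-I error of the responsiveness test: 1,000 null runs of 100 trials
  at 6 Hz.  Shuffle-test calibration: 1,000 homogeneous-Poisson runs
  against one 60-s trace at 1,000 shuffles.  Kuiper calibration: 1,000
  runs of 100 phases drawn from a skewed occupancy.
* Parameter recovery: 300-s default sessions (≈230 puffs, ≈100 touches
  per session).  Latency is measured on unadapted puffs (joint interval
  ≥ 0.65 s); the preferred phase on a 300-s free-whisking session
  (several hundred whisk cycles); the quiescent-puff MI on a single
  1,250-ms-interval stream, compared against the closed-form resource
  fixed point r* = (1 − e^{−Δ/τ}) / (1 − (1 − u)e^{−Δ/τ}).
* Interval sensitivity: per seed, a 600-s quiescent puff stream with
  candidate intervals ≥ 150 ms — so one event's 50-ms response window
  cannot leak into the next event's baseline window; in full sessions
  short intervals co-vary with whisking state and with that leakage,
  which is why the mechanism contrast is run on the controlled stream —
  plus a 600-s default session for the touch-bout contrast; 20 seeds per
  depression level.
* Classification: 20 + 20 synthetic neurons from 120-s sessions (puff and
  touch blocks), 256 permutations.

## Known limitations

* Amplitude and setpoint are piecewise-constant per half cycle; analyses
  needing sub-cycle amplitude resolution should interpolate.
* The two-means brightness threshold assumes a bimodal trace; gradual
  occlusions need the manual-curation input.
* The circular-shift shuffle null assumes stationarity of the overall
  rate; with strong within-session drift its CI is too narrow.
* MI over 50-ms windows is contaminated when deflections follow each
  other within ~latency + 50 ms; interval analyses on real data inherit
  this, as discussed above.
* The classifier reports a single stratified split by default (plus a
  multi-seed mean in the validation experiment); with ~40 neurons the
  test set is small and accuracy is quantized in steps of 1/10.
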