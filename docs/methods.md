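# Methods

## Protocol constants

The TOVA session is modelled as two 324-trial halves: H1 with 72 targets and
252 nontargets, H2 reversed. The trial period (stimulus onset to next onset)
is fixed at 2000 ms with a 100-ms stimulus, which makes each half
324 × 2 s = 648 s = 10.8 min; the scheduler uses exact counts, so the
realized target probability in H1 is 72/324 ≈ 22.2 %. Responses within
150 ms of stimulus onset are anticipatory: they are classed `invalid`,
excluded from the four Go/NoGo trial classes, and their epochs are dropped.
The sampling rate is 512 Hz throughout.

## The synthetic EEG generator

`simulate.synthesize_eeg` renders a schedule into continuous EEG as a sum of
independent components, each with a documented ground truth so downstream
estimators can be validated by parameter recovery:

* **1/f background** — white noise spectrally shaped to f^(−β/2) in
  amplitude (β = 1 by default), scaled to an 8-µV SD per channel.
* **Alpha with phase reset** — a 10-Hz oscillation whose phase performs a
  Brownian walk with diffusion D = 8 rad²/s. Over one 2-s trial the phase
  variance (≈16 rad²) makes phases effectively uniform across trials, so
  prestimulus ITC sits at the Rayleigh chance level √π/(2√n). At
  `reset_latency_s` after each onset the phase is pulled a fraction
  `phase_reset_strength` ∈ [0, 1] of the (wrapped) way toward a fixed
  target phase: 0 leaves ITC at chance, 1 aligns all trials exactly, and
  the poststimulus ITC peak is monotone in the strength between these
  limits (verified by Monte-Carlo in the tests).
* **Evoked transients** — Gaussian-windowed half-sine deflections added
  identically on every trial: an N2-like negative wave (200 ms, ±50 ms,
  4 µV) and a P3-like positive wave (380 ms, ±80 ms, 6 µV), matching the
  windows used by the amplitude tests (150–250 and 330–430 ms).
* **Theta modulations** — ongoing 8-Hz and 4-Hz oscillations (independent
  diffusing phases, no reset) whose amplitude envelopes are raised during
  the 600 ms before onset (8 Hz) and `theta4_post_duration_s` = 400 ms
  after onset (4 Hz), with 50-ms raised-cosine ramps. An amplitude factor
  *a* corresponds to a recoverable ERSP of 20·log₁₀(a) dB. The alpha
  amplitude can likewise be scaled poststimulus (`alpha_post_factor`) to
  emulate alpha desynchronization or to place a 10-Hz power probe.
* **Blinks** — Hann-shaped 300-ms, 150-µV deflections on VEOG with a 25 %
  frontal spread, at Poisson times (default 3/min), each recorded as a
  `blink` annotation. Mastoid (M1/M2) and EOG channels carry no cortical
  signal.

All 16 ROI electrodes receive the same cortical signal with unit gain plus
independent noise. This is deliberate: it keeps ground-truth recovery exact
and is sufficient for every analysis in scope; the generator makes no
attempt at volume conduction, realistic topographies, or a 128-channel
montage (the channel list is configurable). Other features of real EEG the
generator does not emulate: non-stationary artifact families (muscle,
electrode drift), heavy-tailed noise, inter-electrode phase gradients, and
any coupling between behavior and neural components. Passing recovery tests
therefore demonstrates correctness of the estimators, not performance on
real recordings.

Group presets (`GROUP_PRESETS`, `BEHAVIOR_PRESETS`) encode only the
*direction* of the contrasts the pipeline targets — the "control" preset has
stronger/earlier phase reset, larger evoked components, a larger 4-Hz
poststimulus synchronization, and better task performance than the "adhd"
preset — with magnitudes chosen once as plausible, not fitted to any data.

### Parameter-recovery conditions

The ±1-dB ERSP recovery tests inject the modulation over the full
poststimulus second and read the estimate where the wavelet support lies
wholly inside the modulated (respectively baseline) interval — at 4 Hz the
3-cycle wavelet spans 750 ms, so estimates are averaged over time centers
0.38–0.62 s with the divisive baseline from −0.62 to −0.38 s. They also
disable components that overlap the probed band: the diffusing phase gives
every oscillation a Lorentzian linewidth of roughly D/2π ≈ 1.3 Hz, so for
example the 5-µV alpha line leaks enough power into a 4-Hz probe to bias a
1-µV injection by several dB. Shorter modulations (the 400-ms default) are
recovered with the expected wavelet smearing and are not used as recovery
targets.

## Preprocessing conventions

* Epoch time axis is the half-open [−1.0, +1.0) s — exactly 1024 samples,
  with the t = 0 sample counted as poststimulus.
* Filtering is a windowed-sinc (Hamming) linear-phase FIR band-pass applied
  by centered convolution, hence zero-phase; the transition width is 1 Hz
  (≈1691 taps at 512 Hz).
* Blink rejection drops any epoch whose guard window (−400 ms to +600 ms
  around onset) overlaps a blink annotation. Blink *detection* is expected
  to come from upstream annotations; the bundled VEOG threshold detector is
  a convenience, not a validated method.
* Amplitude rejection discards an epoch when |x| exceeds ±80 µV on
  *strictly more than* half of the EEG channels (EOG leads are excluded
  because blinks legitimately exceed the threshold there). It operates on
  epochs; a continuous recording can be screened by epoching a dummy event
  grid.
* Baseline correction subtracts the per-trial, per-channel mean over
  (−1.0, 0.0) s; phase-focused analyses use (−1.0, −0.9) s so the baseline
  does not absorb prestimulus oscillatory structure.
* Balancing draws exactly 36 epochs for infrequent cells (responses in H1,
  inhibitions in H2) and 72 for frequent cells, uniformly without
  replacement per participant; a cell below quota contributes nothing and
  is reported as excluded. Across-draw stability of a spectral statistic
  can be estimated with `sampling_stability` (11 draws by default). Note
  that for a mean-type statistic the across-draw variance is
  (σ²/q)(N−q)/(N−1) for q drawn of N available — zero when N = q and
  *increasing* toward σ²/q with more available epochs — so a small variance
  indicates a tight available pool relative to quota, not abundance.
* Early/late splits order trials by onset; an odd count gives the extra
  trial to "early".

## ERP images

Trials are sorted by the covariate (RT, or alpha phase at −80 ms) and
smoothed across trials with a moving Gaussian following the trial-count
rule: SD = n/30 trials, window width = n/5. The truncated-Gaussian band
matrix is balanced to doubly stochastic form by Sinkhorn iteration
(tolerance 1e−12), which secures two exact invariants at once: identical
input trials pass through unchanged (row sums 1), and the column means of
the image equal the grand ERP whatever the sorting (column sums 1). Phase
sorting probes 9 frequencies across 8–12 Hz with 3-cycle wavelets, takes
the per-trial power maximum at −80 ms, discards the 5 % of trials with
lowest power, and sorts ascending from −π with ties broken by trial index.

The windowed amplitude tests reduce each trial to its mean ROI amplitude in
fixed windows (150–250 / 330–430 ms target-locked; −170…−70 / 0–100 ms
response-locked) and compare the two groups' trial-level distributions with
a two-sample KS test, BH-FDR corrected across windows at α = 0.05. Trials
are pooled within group by default; averaging to one value per participant
first is available via the caller reducing its own inputs.

## Spectral conventions

* Frequency grid: 54 log-spaced frequencies, 4–30 Hz (a linear option
  exists). Cycles interpolate linearly in frequency from 3 at 4 Hz to
  3 × (30/4) × 0.5 = 11.25 at 30 Hz; wavelet support is
  round(cycles·fs/f) samples.
* Wavelets are complex exponentials under a Gaussian taper whose FWHM
  equals the support, truncated at the support and normalized to unit L2
  energy, so power is comparable across frequencies.
* TFRs are evaluated at 200 time centers spanning the region where the
  largest wavelet fits without padding (±0.62 s of a ±1-s epoch at the
  default grid).
* dB convention: 10·log₁₀(P / P_base(f)) with a per-frequency divisive
  baseline, by default the mean power over all prestimulus time centers.
  The evoked/induced estimates accept the total-power baseline so all three
  are expressed on one reference. The three estimates satisfy
  total = evoked exactly (and induced = 0) only in the phase-locked
  noise-free limit; in general total ≈ induced + evoked holds only
  approximately and the residual is reported data, not an assumed identity.
* ITC at a single frequency uses the grid's cycle rule at that frequency,
  is computed per channel and then channel-averaged, and lies in [0, 1] by
  construction.
* Welch PSD: Hann windows of 512 samples (1 s) with 384-sample overlap,
  averaged periodograms in 1-Hz bins over 4–16 Hz. Shorter segments (the
  500-ms prestimulus alpha analysis) clip the window to the segment and
  zero-pad the FFT back to 1-Hz bin spacing.

## Permutation inference

The group contrast statistic is the difference of 10·log₁₀ mean linear
power per (frequency, time) tile, with trials as the exchangeable unit and
the identical code path used for observed and permuted statistics. Masks
are two-sided and computed from exact order statistics of the null with the
(n_perm + 1) convention — k-th order-statistic thresholds give a realized
level of exactly α for α = 0.05 at 200 permutations. Both default levels
(0.05/200, 0.0005/2000) are derived from one null built at the largest
requested permutation count, which nests the strict mask inside the loose
one by construction. At α = 0.0005 with 2000 permutations the two-sided
tail cannot be resolved below 2/(n_perm+1) ≈ 0.001; the implementation
clamps to the extreme order statistic and warns. Tiles are deliberately
not corrected across the grid. ITC significance uses per-trial circular
time shifts of the phase series as surrogates (pointwise 1−α null
quantile); a participant-level permutation and phase-scramble surrogate are
possible extensions, not defaults.

## Behavioral scoring

d′ defaults to z(H) − z(FA) with the log-linear correction
H = (hits+0.5)/(targets+1); a "ratio" mode (hit rate / false-alarm rate) is
exposed for comparability with ratio-style summaries but is not on the d′
scale. Standard scores are 100 + 15·z against a user-supplied norm table
keyed by measure, age range, and gender, signed so that lower scores always
mean worse performance; the 100/15 scale and the classification cutoffs
(normal ≥ 85 > borderline ≥ 70 > not-within-normal) are package surrogates
for proprietary scoring rules and are configurable.

## Serialization

Recordings and epoch sets travel as HDF5 (with timestamp tracking disabled
so artifacts are byte-reproducible) plus TSV sidecars for events,
annotations, and trial metadata; spectral outputs additionally export to
long-format TSV. EDF/BDF input is read through mne when installed. EDF/BDF
*export* is not provided: no writer is available among the package's
dependencies, and the HDF5+TSV container is the native interchange format.

## Problem sizes in tests

The test and acceptance workloads are scaled to what the statistics need,
not to the full study: recovery experiments use 100-trial schedules,
decomposition limits 1000 constructed trials, calibration loops 300–1000
simulations on reduced grids, and the end-to-end determinism check runs the
demo configuration (two groups × two participants, 48-trial halves,
reduced frequency grid). The full-protocol path (324-trial halves, 54 × 200
grid) is exercised once per run by the acceptance script's balanced-session
computation.

## Known limitations

* The generator's single-gain, noise-independent channel model cannot probe
  spatial methods (interpolation, ICA, topography) — all out of scope here.
* The 200 time centers span the largest-wavelet valid region (±0.62 s),
  which brackets but does not exactly reproduce conventional toolbox
  padding choices; endpoints are data-driven, not protocol constants.
* Statistical batteries beyond the permutation/KS/FDR core (MANOVA, mixed
  ANOVA, Bayesian or robust mixed models) are intentionally absent: the
  pipeline exports tidy tables for external statistics software.
* iAPF-recalibrated frequency bands are deliberately not implemented; all
  bands are fixed a priori.
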