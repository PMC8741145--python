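# tovaosc

Event-related EEG analysis for the **TOVA** continuous-performance test — a
Go/NoGo paradigm with an infrequent-target half (H1: 72 targets, 252
nontargets) and a frequent-target half (H2: reversed), 100-ms stimuli on a
2000-ms trial period. The package is written for cognitive-neurophysiology
groups who want the full event-related oscillation workflow as tested,
reusable code rather than one-off analysis scripts:

* **simulate** — synthetic TOVA sessions with known ground truth: trial
  schedules, a probabilistic response model (hits, commissions, lognormal
  RTs, anticipatory presses), and multichannel EEG built from 1/f noise,
  an ongoing ~10-Hz alpha rhythm with stimulus-locked phase reset, N2/P3-like
  evoked transients, and theta-band (8/4 Hz) power modulations;
* **preprocess** — mastoid re-referencing, 2–45 Hz zero-phase FIR filtering,
  epoching to [−1, +1) s, blink-guard and ±80 µV amplitude rejection,
  baseline correction, and participant-wise balancing to 36/72 epoch quotas
  (108 epochs per half);
* **erp** — ERP images (RT- and alpha-phase-sorted, with trial-count-scaled
  Gaussian smoothing), median-split and response-locked ERPs, and windowed
  Kolmogorov–Smirnov amplitude tests with Benjamini–Hochberg FDR;
* **spectral** — Morlet time-frequency analysis on a 54-point log grid
  (4–30 Hz, cycles scaling linearly from 3 to 11.25), per-electrode TFRs
  averaged within frontal/parietal ROIs, the total (ERSP) / evoked / induced
  power decomposition, 10-Hz intertrial coherence (ITC), and Welch PSD
  (512-sample Hann windows, 384 overlap, 1-Hz bins);
* **stats** — label-shuffling permutation contrasts of log mean spectral
  power at two significance levels (α = 0.05 / 200 permutations and
  α = 0.0005 / 2000), circular-shift ITC significance, FDR, and KS helpers;
* **behavior** — TOVA scoring (mean RT, RT variability, commissions,
  omissions, d′) and norm-referenced standard scores on the 100/15 scale;
* **cli** — `tova-osc`, a thin command-line front end with an end-to-end
  `run-all` that writes deterministic TSV/JSON artifacts and a manifest.

## The quantities at the core

For trials *k* = 1…*n* with ROI signal *x_k(t)*, complex Morlet coefficients
*W_k(f, t)* (unit-energy wavelets, cycles(f) = 3 → 11.25 across 4–30 Hz):

- **Total power (ERSP)**  P_tot(f,t) = ⟨|W_k(f,t)|²⟩_k, reported as
  10·log₁₀(P/P_base(f)) dB against the mean prestimulus power per frequency.
- **Evoked power**  the same transform applied to the across-trial average
  (the ERP), per electrode, then electrode-averaged.
- **Induced power**  per-trial power after subtracting the grand ERP from
  each epoch in the time domain.
- **ITC**  ITC(f,t) = |⟨ W_k/|W_k| ⟩_k| ∈ [0, 1]: 0 = random phase,
  1 = perfect phase locking across trials.
- **d′**  z(hit rate) − z(false-alarm rate) with the log-linear correction
  for extreme rates.

ROI power is always computed **per electrode and then averaged** — averaging
channels first cancels activity that is out of phase between electrodes and
underestimates power (the package ships a property test demonstrating this).

## Worked example

One synthetic "control" participant, infrequent-target half:

```python
import tovaosc as tv
from tovaosc import behavior as beh, preprocess as pre, simulate as sim, spectral as spec

schedule = sim.make_schedule("H1", 72, 252, seed=7)
record = sim.simulate_behavior(schedule, sim.BEHAVIOR_PRESETS["control"], seed=8)
scores = beh.raw_scores(record)

rec = sim.synthesize_eeg(schedule, record, sim.GROUP_PRESETS["control"].with_(seed=9))
rec = pre.filter_band(pre.rereference(rec), 2.0, 45.0)
epochs = pre.epoch(rec)
epochs, _ = pre.reject_invalid_trials(epochs)
epochs, _ = pre.reject_blink_epochs(epochs, rec.annotations)
epochs, _ = pre.reject_amplitude(epochs)
balanced, report = pre.balance_epochs(pre.baseline_correct(epochs), seed=10)

grid = spec.build_freq_grid()
responses = balanced.where(condition="correct_response")
tfr = spec.ersp(spec.roi_tfr(responses, tv.PARIETAL_ROI, grid))
series = spec.itc(responses, tv.PARIETAL_ROI, freq_hz=10.0)
```

which prints (seeds as above):

```
H1: 324 trials over 10.8 min
hits=71 commissions=9 omissions=1 meanRT=392 ms RTV=77 ms d'=3.82
epochs: 324 raw -> 297 clean (27 blink, 0 amplitude) -> 108 balanced
parietal 4-Hz ERSP, 0-400 ms: +0.51 dB
10-Hz parietal ITC peak (0-300 ms): 0.50 (prestim mean 0.11)
```

Reading: the schedule reproduces the 10.8-min condition; the participant
passes both balancing quotas and contributes 36 response + 72 inhibition
epochs; the 4-Hz poststimulus synchronization injected by the generator
shows up as a positive ERSP; and the stimulus-locked alpha phase reset
raises the 10-Hz ITC well above its prestimulus chance level.

A full two-group study runs from the shell:

```bash
tova-osc run-all --seed 3 --out study_out       # scaled-down demo study
tova-osc fixtures --size small --out fixtures   # test recordings + checksums
```

`run-all` writes behavioral scores, balance/rejection tables, group ERSPs,
the permutation contrast, ITC series, and a `manifest.json` that reconciles
epoch counts across every rejection stage. Identical seeds give
byte-identical artifacts.

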