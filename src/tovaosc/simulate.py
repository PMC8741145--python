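"""Synthetic TOVA sessions: trial schedules, behavior, and multichannel EEG.

The Test of Variables of Attention (TOVA) is a Go/NoGo continuous-performance
test with two halves: H1 presents the target infrequently (72 targets, 252
nontargets), H2 reverses the ratio (252 targets, 72 nontargets).  Stimuli
last 100 ms and recur every 2000 ms (onset-to-onset), so each half lasts
10.8 min.  Responses within 150 ms of stimulus onset are anticipatory and
invalid.

The EEG generator produces a controllable superposition of

* 1/f ("pink") background noise, synthesized by spectral shaping,
* an ongoing ~10-Hz alpha oscillation whose phase diffuses between trials
  and is pulled toward a fixed phase shortly after each stimulus
  (a von-Mises-style phase reset with tunable strength in [0, 1]),
* stimulus-locked N2/P3-like transients (Gaussian-windowed half-sine
  deflections), and
* theta-band amplitude modulations: an 8-Hz prestimulus and a 4-Hz
  poststimulus event-related synchronization with known dB magnitude,

so every downstream estimator (ERP, ERSP, ITC, behavioral scores) has a
ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Protocol constants
SOA_S = 2.0               # stimulus onset asynchrony, onset-to-onset
STIM_DURATION_S = 0.1
FS_HZ = 512.0
ANTICIPATORY_CUTOFF_S = 0.150
H1_TARGETS, H1_NONTARGETS = 72, 252
H2_TARGETS, H2_NONTARGETS = 252, 72

#: 10-5 labels of the two analysis ROIs (frontal, parietal) and EOG leads.
FRONTAL_CHANNELS = ("F4", "F4h", "Fz", "F3h", "F3", "AFF4h", "AFz", "AFF3h")
PARIETAL_CHANNELS = ("P3", "P1", "CPPz", "P2", "P4", "PO3", "POz", "PO4")
MASTOID_CHANNELS = ("M1", "M2")
EOG_CHANNELS = ("VEOG", "HEOG")
DEFAULT_CHANNELS = FRONTAL_CHANNELS + PARIETAL_CHANNELS + MASTOID_CHANNELS + EOG_CHANNELS
#: channels that carry no cortical signal in the generator
NON_SIGNAL_CHANNELS = MASTOID_CHANNELS + EOG_CHANNELS


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered stimulus events for one TOVA half.

    ``trials`` has columns ``onset_s`` (seconds from schedule start),
    ``stim`` ('target'|'nontarget') and ``half`` ('H1'|'H2').  Onsets are
    strictly increasing with constant spacing ``soa_s``.
    """

    trials: pd.DataFrame
    soa_s: float = SOA_S
    stim_duration_s: float = STIM_DURATION_S

    def __post_init__(self) -> None:
        if self.stim_duration_s >= self.soa_s:
            raise ValueError("stimulus duration must be shorter than the SOA")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        """Total schedule duration: one full SOA per trial."""
        return self.n_trials * self.soa_s

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)


def make_schedule(
    half: str,
    n_target: int,
    n_nontarget: int,
    soa_s: float = SOA_S,
    seed: int | None = None,
    stim_duration_s: float = STIM_DURATION_S,
) -> TrialSchedule:
    """Randomized TOVA trial schedule with exact per-type counts.

    Target/nontarget order is a uniform shuffle without replacement.
    ``make_schedule('H1', 72, 252, 2.0)`` gives 324 trials over 648 s
    (10.8 min).
    """
    if half not in ("H1", "H2"):
        raise ValueError(f"half must be 'H1' or 'H2', got {half!r}")
    if n_target < 0 or n_nontarget < 0:
        raise ValueError("trial counts must be non-negative")
    if soa_s <= 0:
        raise ValueError("soa_s must be positive")
    rng = np.random.default_rng(seed)
    stims = np.array(["target"] * n_target + ["nontarget"] * n_nontarget)
    rng.shuffle(stims)
    n = len(stims)
    trials = pd.DataFrame(
        {
            "onset_s": np.arange(n, dtype=float) * soa_s,
            "stim": stims,
            "half": half,
        }
    )
    return TrialSchedule(trials=trials, soa_s=soa_s, stim_duration_s=stim_duration_s)


def standard_session(seed: int | None = None) -> tuple[TrialSchedule, TrialSchedule]:
    """The two halves of a standard TOVA session (infrequent then frequent)."""
    s1 = make_schedule("H1", H1_TARGETS, H1_NONTARGETS, seed=None if seed is None else seed)
    s2 = make_schedule("H2", H2_TARGETS, H2_NONTARGETS, seed=None if seed is None else seed + 1)
    return s1, s2


@dataclass(frozen=True)
class BehaviorModel:
    """Response model for one participant.

    RTs for non-anticipatory responses are lognormal:
    ``rt = exp(N(log(rt_median_s), rt_sigma))``, truncated below the SOA.
    Anticipatory responses (probability ``p_anticipatory`` among responses
    to targets) get RT drawn uniformly in [0, 150 ms).
    """

    p_hit: float = 0.95
    p_commission: float = 0.10
    rt_median_s: float = 0.40
    rt_sigma: float = 0.22
    p_anticipatory: float = 0.01

    def __post_init__(self) -> None:
        for name in ("p_hit", "p_commission", "p_anticipatory"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.rt_median_s <= 0:
            raise ValueError("rt_median_s must be positive")


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-trial responses aligned to a schedule.

    ``trials`` columns: ``stim``, ``half``, ``onset_s``, ``responded``
    (bool), ``rt_s`` (NaN when not responded).
    """

    trials: pd.DataFrame
    soa_s: float = SOA_S

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False, na_rep="NA")


def simulate_behavior(
    schedule: TrialSchedule,
    model: BehaviorModel = BehaviorModel(),
    seed: int | None = None,
) -> BehavioralRecord:
    """Draw responses and RTs for every trial of a schedule."""
    rng = np.random.default_rng(seed)
    t = schedule.trials
    n = len(t)
    is_target = (t["stim"] == "target").to_numpy()
    p_resp = np.where(is_target, model.p_hit, model.p_commission)
    responded = rng.random(n) < p_resp
    rt = np.full(n, np.nan)
    n_resp = int(responded.sum())
    draws = np.exp(rng.normal(math.log(model.rt_median_s), model.rt_sigma, n_resp))
    # RT cannot exceed the trial period
    draws = np.minimum(draws, schedule.soa_s - 1.0 / FS_HZ)
    anticipatory = rng.random(n_resp) < model.p_anticipatory
    draws[anticipatory] = rng.uniform(0.0, ANTICIPATORY_CUTOFF_S - 1e-3, int(anticipatory.sum()))
    rt[responded] = draws
    trials = t.copy()
    trials["responded"] = responded
    trials["rt_s"] = rt
    return BehavioralRecord(trials=trials, soa_s=schedule.soa_s)


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian-windowed half-sine deflection added to every trial."""

    label: str          # 'N2' or 'P3'
    latency_s: float    # center relative to stimulus onset
    width_s: float      # half-width: the deflection spans latency +- width
    amplitude_uv: float
    sign: int           # -1 for N2-like, +1 for P3-like

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude_uv must be non-negative")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


DEFAULT_ERP_COMPONENTS = (
    ErpComponent("N2", 0.200, 0.050, 4.0, -1),
    ErpComponent("P3", 0.380, 0.080, 6.0, +1),
)


@dataclass(frozen=True)
class GenParams:
    """Ground-truth parameters of the synthetic EEG.

    Amplitudes are in microvolts.  ``phase_reset_strength`` in [0, 1] is the
    fraction by which the alpha phase is pulled toward a fixed target phase
    ``reset_latency_s`` after each stimulus onset (0 = no reset, 1 = full
    reset).  ``phase_diffusion`` (rad^2/s) controls how quickly oscillatory
    phase decorrelates between trials; at the default, phase is close to
    uniform across 2-s trials, so prestimulus ITC sits at chance.

    Theta modulations are amplitude envelopes on ongoing oscillations:
    8 Hz is raised from ``theta8_base_amp`` to ``theta8_pre_amp`` during the
    600 ms before each onset, 4 Hz from ``theta4_base_amp`` to
    ``theta4_post_amp`` during ``theta4_post_duration_s`` after onset.  The
    recoverable ERSP at 4 Hz is therefore 20*log10(theta4_post_amp /
    theta4_base_amp) dB.
    """

    fs_hz: float = FS_HZ
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_amp_uv: float = 8.0
    noise_exponent: float = 1.0
    alpha_hz: float = 10.0
    alpha_amp_pre: float = 5.0
    alpha_post_factor: float = 1.0
    alpha_post_duration_s: float = 1.0
    phase_reset_strength: float = 0.5
    reset_latency_s: float = 0.05
    phase_diffusion: float = 8.0
    erp_components: tuple[ErpComponent, ...] = DEFAULT_ERP_COMPONENTS
    theta8_base_amp: float = 1.0
    theta8_pre_amp: float = 2.0
    theta8_pre_duration_s: float = 0.6
    theta4_base_amp: float = 1.0
    theta4_post_amp: float = 2.0
    theta4_post_duration_s: float = 0.4
    blink_rate_per_min: float = 3.0
    # `alpha_post_factor` scales the ongoing alpha amplitude during
    # `alpha_post_duration_s` after each onset: < 1 emulates the classic
    # poststimulus alpha desynchronization, > 1 a 10-Hz ERS probe.
    blink_amp_uv: float = 150.0
    pad_s: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_reset_strength <= 1.0:
            raise ValueError("phase_reset_strength must be in [0, 1]")
        highest = max(self.alpha_hz, 8.0, 4.0)
        if self.fs_hz <= 2 * highest:
            raise ValueError("fs_hz must exceed twice the highest synthesized frequency")
        for name in (
            "noise_amp_uv", "alpha_amp_pre", "theta8_base_amp", "theta8_pre_amp",
            "theta4_base_amp", "theta4_post_amp", "blink_amp_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "GenParams":
        return replace(self, **kwargs)


#: Illustrative group presets.  They reproduce the *direction* of the group
#: contrasts the pipeline is designed to detect — controls with stronger and
#: earlier alpha phase reset, larger evoked components and a larger 4-Hz
#: poststimulus ERS — not any measured effect size.
GROUP_PRESETS: dict[str, GenParams] = {
    "control": GenParams(
        phase_reset_strength=0.7,
        reset_latency_s=0.05,
        alpha_amp_pre=6.0,
        theta4_post_amp=2.0,
        erp_components=(
            ErpComponent("N2", 0.200, 0.050, 4.0, -1),
            ErpComponent("P3", 0.380, 0.080, 6.0, +1),
        ),
    ),
    "adhd": GenParams(
        phase_reset_strength=0.3,
        reset_latency_s=0.09,
        alpha_amp_pre=5.0,
        theta4_post_amp=1.5,
        erp_components=(
            ErpComponent("N2", 0.200, 0.050, 2.5, -1),
            ErpComponent("P3", 0.380, 0.080, 4.0, +1),
        ),
    ),
}

BEHAVIOR_PRESETS: dict[str, BehaviorModel] = {
    "control": BehaviorModel(p_hit=0.98, p_commission=0.05, rt_median_s=0.38,
                             rt_sigma=0.18, p_anticipatory=0.005),
    "adhd": BehaviorModel(p_hit=0.92, p_commission=0.15, rt_median_s=0.42,
                          rt_sigma=0.30, p_anticipatory=0.03),
}


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG with events and annotations.

    ``data`` is channels x samples in microvolts.  ``events`` carries one row
    per trial (onset_s relative to recording start, stim, half, responded,
    rt_s).  ``annotations`` has columns kind ('blink'|'bad_segment'),
    start_s, end_s.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame
    annotations: pd.DataFrame
    params: GenParams | None = None
    history: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, amp_uv: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, SD = amp_uv."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amp_uv * shaped / sd


def _wrap(phi: np.ndarray | float) -> np.ndarray | float:
    return (phi + np.pi) % (2 * np.pi) - np.pi


def _phase_trajectory(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    freq: float,
    diffusion: float,
    reset_samples: np.ndarray | None = None,
    reset_strength: float = 0.0,
    target_phase: float = 0.0,
) -> np.ndarray:
    """Diffusing oscillatory phase with optional stimulus-locked resets.

    Phase advances at ``freq`` with Brownian jitter of variance
    ``diffusion`` rad^2 per second.  At each reset sample the phase is pulled
    a fraction ``reset_strength`` of the (wrapped) way toward
    ``target_phase``.
    """
    dphi = 2 * np.pi * freq / fs + rng.normal(
        0.0, math.sqrt(max(diffusion, 0.0) / fs), n_samples
    )
    reset_mask = np.zeros(n_samples, dtype=bool)
    if reset_samples is not None and reset_strength > 0:
        idx = reset_samples[(reset_samples >= 0) & (reset_samples < n_samples)]
        reset_mask[idx] = True
    phi = np.empty(n_samples)
    phi[0] = rng.uniform(-np.pi, np.pi)
    if not reset_mask.any():
        phi = phi[0] + np.concatenate(([0.0], np.cumsum(dphi[1:])))
        return phi
    p = phi[0]
    for k in range(1, n_samples):
        p = p + dphi[k]
        if reset_mask[k]:
            p = p + reset_strength * _wrap(target_phase - p)
        phi[k] = p
    phi[0] = phi[1] - dphi[1] if n_samples > 1 else phi[0]
    return phi


def _envelope(n_samples: int, fs: float, onsets_s: np.ndarray,
              lo_s: float, hi_s: float, base: float, boosted: float,
              ramp_s: float = 0.05) -> np.ndarray:
    """Amplitude envelope: ``boosted`` inside [onset+lo, onset+hi], else base.

    Edges are raised-cosine ramps of ``ramp_s`` so the envelope is smooth.
    """
    env = np.full(n_samples, float(base))
    if boosted == base:
        return env
    t = np.arange(n_samples) / fs
    bump = np.zeros(n_samples)
    for onset in onsets_s:
        a, b = onset + lo_s, onset + hi_s
        inside = (t >= a) & (t < b)
        bump[inside] = 1.0
        rise = (t >= a - ramp_s) & (t < a)
        bump[rise] = np.maximum(bump[rise], 0.5 * (1 + np.cos(np.pi * (a - t[rise]) / ramp_s)))
        fall = (t >= b) & (t < b + ramp_s)
        bump[fall] = np.maximum(bump[fall], 0.5 * (1 + np.cos(np.pi * (t[fall] - b) / ramp_s)))
    return env + (boosted - base) * bump


def _erp_kernel(comp: ErpComponent, fs: float) -> tuple[np.ndarray, int]:
    """Sampled deflection and its onset offset (samples) relative to latency.

    A half-sine over [latency - width, latency + width] windowed by a
    Gaussian (SD = width/2) centered on the latency.
    """
    half = int(round(comp.width_s * fs))
    k = np.arange(-half, half + 1)
    tau = k / fs
    half_sine = np.cos(np.pi * tau / (2 * comp.width_s))
    gauss = np.exp(-0.5 * (tau / (comp.width_s / 2.0)) ** 2)
    kernel = comp.sign * comp.amplitude_uv * half_sine * gauss
    return kernel, -half


def synthesize_eeg(
    schedule: TrialSchedule,
    behavior: BehavioralRecord | None = None,
    params: GenParams = GenParams(),
) -> ContinuousRecording:
    """Render a schedule (and optional behavior) into continuous EEG.

    The recording is padded by ``params.pad_s`` before the first and after
    the last trial so that 2-s epochs at the edges stay inside the
    recording; event onsets in the returned recording are shifted
    accordingly.  Identical parameters (including seed) give bit-identical
    output.
    """
    fs = params.fs_hz
    rng = np.random.default_rng(params.seed)
    n_trials = schedule.n_trials
    duration = schedule.duration_s + 2 * params.pad_s
    n_samples = int(round(duration * fs))
    labels = tuple(params.channels)
    n_ch = len(labels)
    is_eog = np.array([lbl in NON_SIGNAL_CHANNELS for lbl in labels])

    onsets = schedule.trials["onset_s"].to_numpy() + params.pad_s
    onset_samples = np.round(onsets * fs).astype(int)

    data = _pink_noise(rng, n_ch, n_samples, params.noise_exponent, params.noise_amp_uv)

    if n_trials:
        # ongoing alpha with stimulus-locked phase reset (shared across EEG channels)
        reset_samples = np.round((onsets + params.reset_latency_s) * fs).astype(int)
        phi_a = _phase_trajectory(
            rng, n_samples, fs, params.alpha_hz, params.phase_diffusion,
            reset_samples, params.phase_reset_strength, target_phase=0.0,
        )
        env_a = _envelope(
            n_samples, fs, onsets, 0.0, params.alpha_post_duration_s,
            params.alpha_amp_pre, params.alpha_amp_pre * params.alpha_post_factor,
        )
        alpha = env_a * np.sin(phi_a)

        # theta oscillations with event-locked amplitude envelopes
        phi8 = _phase_trajectory(rng, n_samples, fs, 8.0, params.phase_diffusion)
        env8 = _envelope(n_samples, fs, onsets, -params.theta8_pre_duration_s, 0.0,
                         params.theta8_base_amp, params.theta8_pre_amp)
        theta8 = env8 * np.sin(phi8)

        phi4 = _phase_trajectory(rng, n_samples, fs, 4.0, params.phase_diffusion)
        env4 = _envelope(n_samples, fs, onsets, 0.0, params.theta4_post_duration_s,
                         params.theta4_base_amp, params.theta4_post_amp)
        theta4 = env4 * np.sin(phi4)

        # evoked transients, identical on every trial
        evoked = np.zeros(n_samples)
        for comp in params.erp_components:
            kernel, k0 = _erp_kernel(comp, fs)
            for s0 in onset_samples:
                c = s0 + int(round(comp.latency_s * fs)) + k0
                lo, hi = max(c, 0), min(c + len(kernel), n_samples)
                if hi > lo:
                    evoked[lo:hi] += kernel[lo - c:hi - c]

        signal = alpha + theta8 + theta4 + evoked
        data[~is_eog] += signal[None, :]

    # blinks on VEOG with frontal spread, annotated
    ann_rows = []
    n_blinks = rng.poisson(params.blink_rate_per_min * duration / 60.0)
    blink_dur = 0.30
    blink_starts = np.sort(rng.uniform(0.0, duration - blink_dur, n_blinks))
    if n_blinks and params.blink_amp_uv > 0:
        nb = int(round(blink_dur * fs))
        shape = np.hanning(nb) * params.blink_amp_uv
        frontal_gain = np.array(
            [0.25 if lbl in FRONTAL_CHANNELS else 0.0 for lbl in labels]
        )
        try:
            frontal_gain[labels.index("VEOG")] = 1.0
        except ValueError:
            pass
        for start in blink_starts:
            s0 = int(round(start * fs))
            hi = min(s0 + nb, n_samples)
            data[:, s0:hi] += frontal_gain[:, None] * shape[None, : hi - s0]
            ann_rows.append(("blink", start, start + blink_dur))
    annotations = pd.DataFrame(ann_rows, columns=["kind", "start_s", "end_s"])

    events = schedule.trials.copy()
    events["onset_s"] = onsets
    if behavior is not None:
        if len(behavior.trials) != n_trials:
            raise ValueError("behavior record does not match schedule length")
        events["responded"] = behavior.trials["responded"].to_numpy()
        events["rt_s"] = behavior.trials["rt_s"].to_numpy()
    else:
        events["responded"] = False
        events["rt_s"] = np.nan

    return ContinuousRecording(
        data=data, fs_hz=fs, channel_labels=labels,
        events=events, annotations=annotations, params=params,
    )


def make_norm_table(groups, measures=None):
    """Build a normative lookup table from per-group summary rows.

    ``groups`` is an iterable of mappings with keys ``measure``, ``age_lo``,
    ``age_hi``, ``gender``, ``mean``, ``sd``.  Overlapping age ranges within
    a (measure, gender) cell raise a validation error.  See
    :class:`tovaosc.behavior.NormTable`.
    """
    from .behavior import NormTable

    rows = pd.DataFrame(list(groups))
    if measures is not None:
        rows = rows[rows["measure"].isin(measures)].reset_index(drop=True)
    return NormTable(rows)
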