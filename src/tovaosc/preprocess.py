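"""From continuous recordings to clean, balanced epoch sets.

The preprocessing chain is: mastoid re-referencing, 2-45 Hz zero-phase
band-pass, epoching to [-1, +1) s around stimulus onset with trial
classification, blink-window and amplitude rejection, baseline correction,
and participant-wise balancing to fixed epoch quotas (36 for infrequent
conditions — responses in H1 and inhibitions in H2 — and 72 for frequent
ones), so a fully retained participant contributes 108 epochs per half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import classify_trials
from .simulate import (
    ANTICIPATORY_CUTOFF_S,
    BehavioralRecord,
    ContinuousRecording,
    FRONTAL_CHANNELS,
    MASTOID_CHANNELS,
    PARIETAL_CHANNELS,
)

logger = logging.getLogger(__name__)

EPOCH_WINDOW_S = (-1.0, 1.0)
BLINK_GUARD_S = (-0.4, 0.6)
AMPLITUDE_THRESHOLD_UV = 80.0
DEFAULT_QUOTAS = {"infrequent": 36, "frequent": 72}
BASELINE_FULL_S = (-1.0, 0.0)       # default baseline: whole prestimulus second
BASELINE_PHASE_S = (-1.0, -0.9)     # baseline used by prestimulus-phase analyses


@dataclass(frozen=True)
class ROISpec:
    """A named region of interest: a set of 10-5 electrode labels."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ROI channel list must be non-empty")


FRONTAL_ROI = ROISpec("frontal", FRONTAL_CHANNELS)
PARIETAL_ROI = ROISpec("parietal", PARIETAL_CHANNELS)


@dataclass
class EpochSet:
    """Trials x channels x samples with a common time axis and metadata.

    ``time_s`` holds per-sample offsets from the lock event (stimulus onset
    unless re-locked); the default window is the half-open [-1.0, +1.0) s,
    i.e. 1024 samples at 512 Hz with t = 0 the first poststimulus sample.
    ``meta`` has one row per trial: condition, half, rt_s, onset_s (in
    recording coordinates) and any upstream columns.
    """

    data: np.ndarray
    time_s: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    meta: pd.DataFrame
    baseline_interval_s: tuple[float, float] | None = None
    lock: str = "target"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta length must equal trial count")
        if self.data.shape[2] != len(self.time_s):
            raise ValueError("time axis length must equal sample count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_indices(self, labels) -> np.ndarray:
        out = []
        for lbl in labels:
            try:
                out.append(self.channel_labels.index(lbl))
            except ValueError:
                raise KeyError(f"channel {lbl!r} not in epoch set") from None
        return np.asarray(out, dtype=int)

    def select(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            data=self.data[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def where(self, condition: str | None = None, half: str | None = None) -> "EpochSet":
        m = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            m &= (self.meta["condition"] == condition).to_numpy()
        if half is not None:
            m &= (self.meta["half"] == half).to_numpy()
        return self.select(m)

    def sample_at(self, t_s: float) -> int:
        """Index of the sample whose time is closest to ``t_s``."""
        return int(np.argmin(np.abs(self.time_s - t_s)))


def _bandpass_kernel(fs: float, hp_hz: float, lp_hz: float,
                     transition_hz: float = 1.0) -> np.ndarray:
    """Odd-length windowed-sinc band-pass (linear phase, Hamming window)."""
    numtaps = int(round(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2
    return sps.firwin(numtaps, [hp_hz, lp_hz], pass_zero=False, fs=fs)


def filter_band(
    rec: ContinuousRecording, hp_hz: float = 2.0, lp_hz: float = 45.0,
    transition_hz: float = 1.0,
) -> ContinuousRecording:
    """Zero-phase FIR band-pass, applied per channel.

    The symmetric windowed-sinc kernel is applied by centered convolution,
    which is zero-phase; the transition band is ~1 Hz on each edge.
    """
    if not 0 < hp_hz < lp_hz < rec.fs_hz / 2:
        raise ValueError(
            f"invalid band ({hp_hz}, {lp_hz}) for fs={rec.fs_hz}"
        )
    kernel = _bandpass_kernel(rec.fs_hz, hp_hz, lp_hz, transition_hz)
    filtered = sps.fftconvolve(rec.data, kernel[None, :], mode="same", axes=1)
    return replace(
        rec,
        data=filtered,
        history=rec.history + [f"filter_band(hp={hp_hz},lp={lp_hz},taps={len(kernel)})"],
    )


def rereference(
    rec: ContinuousRecording, ref_labels=MASTOID_CHANNELS
) -> ContinuousRecording:
    """Re-reference to the average of two mastoid channels."""
    if len(ref_labels) != 2:
        raise ValueError("expected exactly two reference labels")
    idx = [rec.channel_index(lbl) for lbl in ref_labels]
    ref = rec.data[idx].mean(axis=0)
    return replace(
        rec,
        data=rec.data - ref[None, :],
        history=rec.history + [f"rereference({','.join(ref_labels)})"],
    )


def epoch(
    rec: ContinuousRecording,
    events: pd.DataFrame | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> EpochSet:
    """Cut one epoch per stimulus event and classify it from behavior.

    The time axis is the half-open [window_s[0], window_s[1]): exactly
    ``(hi - lo) * fs`` samples, with the t=0 sample counted as poststimulus.
    Events whose window would cross a recording edge are dropped with a
    warning.  Trial classes follow the Go/NoGo contingencies; responses
    faster than 150 ms mark the trial invalid.
    """
    if events is None:
        events = rec.events
    fs = rec.fs_hz
    lo, hi = window_s
    if not lo < hi:
        raise ValueError("window_s must be increasing")
    n_win = int(round((hi - lo) * fs))
    time_s = lo + np.arange(n_win) / fs

    if len(events) == 0:
        return EpochSet(
            data=np.empty((0, len(rec.channel_labels), n_win)),
            time_s=time_s, fs_hz=fs, channel_labels=tuple(rec.channel_labels),
            meta=pd.DataFrame(columns=["condition", "half", "rt_s", "onset_s"]),
        )

    classes = classify_trials(
        BehavioralRecord(trials=events.reset_index(drop=True))
    )
    slabs, rows = [], []
    for i, (_, ev) in enumerate(events.iterrows()):
        start = int(round((ev["onset_s"] + lo) * fs))
        if start < 0 or start + n_win > rec.n_samples:
            logger.warning(
                "event at %.3f s too close to recording edge; epoch dropped",
                ev["onset_s"],
            )
            continue
        slabs.append(rec.data[:, start:start + n_win])
        rows.append(
            {
                "condition": classes.iloc[i],
                "half": ev.get("half", "?"),
                "stim": ev.get("stim", "?"),
                "rt_s": ev.get("rt_s", np.nan),
                "onset_s": ev["onset_s"],
            }
        )
    data = np.stack(slabs) if slabs else np.empty((0, len(rec.channel_labels), n_win))
    return EpochSet(
        data=data, time_s=time_s, fs_hz=fs,
        channel_labels=tuple(rec.channel_labels),
        meta=pd.DataFrame(rows, columns=["condition", "half", "stim", "rt_s", "onset_s"]),
    )


@dataclass
class RejectionLog:
    rule: str
    n_in: int
    n_rejected: int
    rejected_index: np.ndarray

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_rejected


def reject_blink_epochs(
    epochs: EpochSet,
    annotations: pd.DataFrame,
    guard_s: tuple[float, float] = BLINK_GUARD_S,
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs whose blink-guard window overlaps any blink annotation.

    The guard runs from 400 ms before to 600 ms after stimulus onset; an
    epoch is rejected when any annotated blink interval intersects
    [onset + guard_s[0], onset + guard_s[1]].
    """
    blinks = annotations[annotations["kind"] == "blink"]
    onsets = epochs.meta["onset_s"].to_numpy()
    win_lo = onsets + guard_s[0]
    win_hi = onsets + guard_s[1]
    bad = np.zeros(epochs.n_trials, dtype=bool)
    for _, b in blinks.iterrows():
        bad |= (b["start_s"] < win_hi) & (b["end_s"] > win_lo)
    log = RejectionLog("blink", epochs.n_trials, int(bad.sum()), np.flatnonzero(bad))
    return epochs.select(~bad), log


def reject_amplitude(
    epochs: EpochSet,
    threshold_uv: float = AMPLITUDE_THRESHOLD_UV,
    channel_fraction: float = 0.5,
    channels=None,
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs exceeding +-threshold on more than half the channels.

    An epoch is discarded iff |amplitude| exceeds ``threshold_uv`` at any
    sample on *strictly more* than ``channel_fraction`` of the considered
    channels (EEG channels by default: EOG leads legitimately exceed the
    threshold during blinks).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    if channels is None:
        idx = np.array(
            [i for i, lbl in enumerate(epochs.channel_labels)
             if lbl not in ("VEOG", "HEOG")],
            dtype=int,
        )
    else:
        idx = epochs.channel_indices(channels)
    exceeds = (np.abs(epochs.data[:, idx, :]) > threshold_uv).any(axis=2)
    frac = exceeds.mean(axis=1)
    bad = frac > channel_fraction
    log = RejectionLog("amplitude", epochs.n_trials, int(bad.sum()), np.flatnonzero(bad))
    return epochs.select(~bad), log


def reject_invalid_trials(epochs: EpochSet) -> tuple[EpochSet, RejectionLog]:
    """Drop anticipatory-response (invalid) trials from an epoch set."""
    bad = (epochs.meta["condition"] == "invalid").to_numpy()
    log = RejectionLog("invalid", epochs.n_trials, int(bad.sum()), np.flatnonzero(bad))
    return epochs.select(~bad), log


def baseline_correct(
    epochs: EpochSet, interval_s: tuple[float, float] = BASELINE_FULL_S
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``interval_s``.

    Phase-focused analyses use the (-1.0, -0.9) s interval so the baseline
    does not absorb prestimulus oscillatory structure; everything else uses
    the full prestimulus second.
    """
    lo, hi = interval_s
    mask = (epochs.time_s >= lo) & (epochs.time_s < hi)
    if not mask.any():
        raise ValueError(f"baseline interval {interval_s} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, baseline_interval_s=tuple(interval_s))


def quota_for(condition: str, half: str, quotas: dict[str, int] = DEFAULT_QUOTAS) -> int:
    """Epoch quota for a (condition, half) cell.

    Responses are infrequent in H1 (72 targets of 324 trials) and frequent
    in H2; inhibitions vice versa.
    """
    infrequent = (condition == "correct_response" and half == "H1") or (
        condition == "correct_inhibition" and half == "H2"
    )
    return quotas["infrequent"] if infrequent else quotas["frequent"]


@dataclass
class BalanceReport:
    """Outcome of quota balancing, one row per (condition, half) cell."""

    table: pd.DataFrame     # condition, half, available, quota, drawn, included
    seed: int | None
    draw_index: int = 0

    def included(self, condition: str, half: str) -> bool:
        t = self.table
        row = t[(t["condition"] == condition) & (t["half"] == half)]
        return bool(row["included"].iloc[0]) if len(row) else False


def balance_epochs(
    epochs: EpochSet,
    quotas: dict[str, int] = DEFAULT_QUOTAS,
    seed: int | None = None,
    draw_index: int = 0,
    conditions=("correct_response", "correct_inhibition"),
) -> tuple[EpochSet, BalanceReport]:
    """Draw exactly the quota of epochs per (condition, half), or exclude.

    Sampling is uniform without replacement within each cell.  A cell with
    fewer available epochs than its quota contributes nothing and is marked
    excluded (an outcome, not an error).  A participant retained in both
    cells of a half contributes 36 + 72 = 108 epochs for that half.
    """
    if any(q <= 0 for q in quotas.values()):
        raise ValueError("quotas must be positive")
    rng = np.random.default_rng(None if seed is None else seed + draw_index)
    meta = epochs.meta
    keep: list[np.ndarray] = []
    rows = []
    for half in pd.unique(meta["half"]):
        for cond in conditions:
            cell = np.flatnonzero(
                (meta["condition"] == cond).to_numpy()
                & (meta["half"] == half).to_numpy()
            )
            q = quota_for(cond, half, quotas)
            if len(cell) >= q:
                drawn = np.sort(rng.choice(cell, size=q, replace=False))
                keep.append(drawn)
                rows.append((cond, half, len(cell), q, q, True))
            else:
                rows.append((cond, half, len(cell), q, 0, False))
    idx = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)
    report = BalanceReport(
        table=pd.DataFrame(
            rows, columns=["condition", "half", "available", "quota", "drawn", "included"]
        ),
        seed=seed,
        draw_index=draw_index,
    )
    return epochs.select(idx), report


def _default_stability_statistic(epochs: EpochSet) -> np.ndarray:
    """Mean log10 band power (4-16 Hz) per parietal-ROI trial average."""
    from .spectral import welch_psd

    psd = welch_psd(epochs, roi=PARIETAL_ROI, band_hz=(4.0, 16.0))
    return psd.log_power


def sampling_stability(
    epochs: EpochSet,
    quotas: dict[str, int] = DEFAULT_QUOTAS,
    n_draws: int = 11,
    statistic=None,
    seed: int | None = 0,
) -> float:
    """Across-draw variance of a spectral statistic under quota resampling.

    Repeats :func:`balance_epochs` with ``n_draws`` distinct sub-seeds,
    evaluates ``statistic`` (default: parietal 4-16 Hz mean log power
    spectrum) on each draw, and returns the mean over statistic elements of
    the across-draw variance.  Raises if any quota cell cannot be filled.
    """
    if statistic is None:
        statistic = _default_stability_statistic
    values = []
    for d in range(n_draws):
        drawn, report = balance_epochs(epochs, quotas, seed=seed, draw_index=d)
        if not report.table["included"].all():
            raise ValueError("participant does not pass quotas in every cell")
        values.append(np.asarray(statistic(drawn), dtype=float))
    stacked = np.stack(values)
    return float(stacked.var(axis=0, ddof=1).mean())


def split_early_late(epochs: EpochSet) -> tuple[EpochSet, EpochSet]:
    """Split trials into early and late halves by onset time.

    Sizes differ by at most one; with an odd count the extra trial goes to
    the early set.
    """
    n = epochs.n_trials
    if n < 2:
        raise ValueError("need at least 2 epochs to split")
    order = np.argsort(epochs.meta["onset_s"].to_numpy(), kind="stable")
    n_early = (n + 1) // 2
    return epochs.select(order[:n_early]), epochs.select(order[n_early:])


def detect_blinks_veog(
    rec: ContinuousRecording,
    threshold_uv: float = 75.0,
    veog_label: str = "VEOG",
    min_separation_s: float = 0.2,
) -> pd.DataFrame:
    """Convenience threshold blink detector on the VEOG lead.

    This is a simple amplitude-crossing detector provided for pipelines
    without external blink annotations; it is not a validated ocular
    artifact method.  Returns an annotation table (kind='blink').
    """
    v = rec.data[rec.channel_index(veog_label)]
    above = v > threshold_uv
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    rows = []
    last = -np.inf
    for s in edges:
        t0 = s / rec.fs_hz
        if t0 - last < min_separation_s:
            continue
        e = s
        while e < len(v) and above[e]:
            e += 1
        rows.append(("blink", t0, e / rec.fs_hz))
        last = t0
    return pd.DataFrame(rows, columns=["kind", "start_s", "end_s"])
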