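"""Time-frequency analysis: Morlet TFRs, ERSP/evoked/induced power, ITC, PSD.

Spectral power is estimated with complex Morlet wavelets on a 54-point
log-spaced grid from 4 to 30 Hz.  The number of cycles per wavelet scales
linearly in frequency from 3 at 4 Hz, with a scaling factor of 0.5, up to
3 * (30/4) * 0.5 = 11.25 at 30 Hz — a fixed trade between temporal and
spectral resolution.  Power is evaluated at 200 time centers spanning the
region of the epoch where the largest wavelet fits without padding.

Three event-related power estimates are computed per region of interest
(ROI), always by averaging *per-electrode* TFRs rather than computing one
TFR of the channel average (which underestimates power when electrodes are
at different phases):

* total power (ERSP): average over trials of per-trial TFR power;
* evoked power: TFR power of the across-trial time-domain average (the ERP);
* induced power: per-trial TFR power after subtracting the grand ERP from
  every epoch, averaged over trials.

dB values are 10*log10(P / P_baseline) with a per-frequency divisive
baseline taken from the mean prestimulus power.  Intertrial coherence
(ITC) at a single frequency is the magnitude of the across-trial mean unit
phase vector, computed per channel and then channel-averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet, ROISpec

N_FREQS = 54
F_MIN_HZ, F_MAX_HZ = 4.0, 30.0
CYCLES_SPEC = (3.0, 0.5)
N_TIMES = 200
WELCH_WINDOW = 512
WELCH_OVERLAP = 384
PSD_BAND_HZ = (4.0, 16.0)
ITC_FREQ_HZ = 10.0


@dataclass(frozen=True)
class FreqGrid:
    """Analysis frequencies with per-frequency cycle counts and windows."""

    freqs_hz: np.ndarray
    cycles: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if len(self.cycles) != len(self.freqs_hz):
            raise ValueError("cycles and freqs must align")

    @property
    def n_freqs(self) -> int:
        return len(self.freqs_hz)

    @property
    def window_samples(self) -> np.ndarray:
        """Wavelet support in samples: round(cycles * fs / f)."""
        return np.round(self.cycles * self.fs_hz / self.freqs_hz).astype(int)

    def nearest(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - freq_hz)))


def build_freq_grid(
    f_min: float = F_MIN_HZ,
    f_max: float = F_MAX_HZ,
    n: int = N_FREQS,
    cycles_spec: tuple[float, float] = CYCLES_SPEC,
    fs_hz: float = 512.0,
    spacing: str = "log",
) -> FreqGrid:
    """Frequency grid with cycles scaling linearly in frequency.

    With ``cycles_spec = (c0, s)`` the cycle count interpolates linearly
    from ``c0`` at ``f_min`` to ``c0 * (f_max / f_min) * s`` at ``f_max``;
    the default (3, 0.5) over 4-30 Hz gives 3 cycles at 4 Hz and 11.25 at
    30 Hz.  ``spacing`` is 'log' (default, matching log-frequency display)
    or 'linear'.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least two frequencies")
    c0, sf = cycles_spec
    if c0 <= 0 or sf <= 0:
        raise ValueError("cycles_spec entries must be positive")
    if spacing == "log":
        freqs = np.geomspace(f_min, f_max, n)
    elif spacing == "linear":
        freqs = np.linspace(f_min, f_max, n)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    c_max = c0 * (f_max / f_min) * sf
    cycles = c0 + (c_max - c0) * (freqs - f_min) / (f_max - f_min)
    return FreqGrid(freqs_hz=freqs, cycles=cycles, fs_hz=fs_hz)


def morlet_wavelet(freq_hz: float, cycles: float, fs_hz: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet of support ``cycles / freq`` s.

    A complex exponential under a Gaussian taper whose FWHM equals the
    support, truncated at the support edges and normalized to unit L2
    energy so power is comparable across frequencies.
    """
    n = int(round(cycles * fs_hz / freq_hz))
    n += 1 - n % 2  # odd length, symmetric around 0
    t = (np.arange(n) - n // 2) / fs_hz
    support_s = n / fs_hz
    sigma = support_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    w = np.exp(2j * np.pi * freq_hz * t) * np.exp(-0.5 * (t / sigma) ** 2)
    return w / np.linalg.norm(w)


def default_time_centers(
    grid: FreqGrid, time_s: np.ndarray, n_times: int = N_TIMES
) -> np.ndarray:
    """Indices of ``n_times`` centers across the region clear of padding.

    The valid region excludes half the largest wavelet support at each end
    of the epoch, so no wavelet ever extends past the data.
    """
    half = int(grid.window_samples.max()) // 2 + 1
    n = len(time_s)
    if n - 2 * half < n_times:
        raise ValueError("epoch too short for the largest wavelet")
    return np.unique(np.round(np.linspace(half, n - 1 - half, n_times)).astype(int))


def morlet_tfr(
    signal: np.ndarray, grid: FreqGrid, center_idx: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
) -> np.ndarray:
    """Complex Morlet transform of 1-D (or stacked 2-D) signals.

    Returns an array of shape (..., n_freqs, n_centers); power is
    ``abs(.)**2`` and phase ``angle(.)``.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if time_s is None:
        time_s = np.arange(x.shape[1]) / grid.fs_hz
    if center_idx is None:
        center_idx = default_time_centers(grid, time_s)
    if x.shape[1] < int(grid.window_samples.max()):
        raise ValueError("signal shorter than the largest wavelet")
    out = np.empty((x.shape[0], grid.n_freqs, len(center_idx)), dtype=complex)
    for fi in range(grid.n_freqs):
        w = morlet_wavelet(grid.freqs_hz[fi], grid.cycles[fi], grid.fs_hz)
        conv = sps.fftconvolve(x, np.conj(w[::-1])[None, :], mode="same", axes=1)
        out[:, fi, :] = conv[:, center_idx]
    if np.asarray(signal).ndim == 1:
        return out[0]
    return out


@dataclass
class TrialPower:
    """Per-trial, electrode-averaged linear TFR power for one ROI."""

    power: np.ndarray          # trials x freqs x times, linear (uV^2-scaled)
    freqs_hz: np.ndarray
    times_s: np.ndarray
    roi: ROISpec | None = None

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]


def roi_tfr(
    epochs: EpochSet, roi: ROISpec, grid: FreqGrid,
    center_idx: np.ndarray | None = None,
) -> TrialPower:
    """Per-trial power: TFR per electrode, power averaged across electrodes.

    The electrode-then-average order is deliberate: averaging channels in
    the time domain first would cancel activity that is out of phase
    between electrodes and underestimate power.
    """
    idx = epochs.channel_indices(roi.channels)
    if center_idx is None:
        center_idx = default_time_centers(grid, epochs.time_s)
    n_tr, n_ch = epochs.n_trials, len(idx)
    x = epochs.data[:, idx, :].reshape(n_tr * n_ch, epochs.n_samples)
    coeff = morlet_tfr(x, grid, center_idx, epochs.time_s)
    power = (np.abs(coeff) ** 2).reshape(n_tr, n_ch, grid.n_freqs, len(center_idx))
    return TrialPower(
        power=power.mean(axis=1),
        freqs_hz=grid.freqs_hz.copy(),
        times_s=epochs.time_s[center_idx],
        roi=roi,
    )


@dataclass
class TFRSet:
    """Trial-averaged time-frequency power for one ROI.

    ``power`` is linear; ``power_db`` is 10*log10(power / baseline) with a
    per-frequency divisive baseline (``baseline`` holds the reference power
    per frequency, NaN-free).  ``kind`` is 'total', 'evoked' or 'induced'.
    """

    kind: str
    power: np.ndarray          # freqs x times, linear
    freqs_hz: np.ndarray
    times_s: np.ndarray
    roi: ROISpec | None = None
    baseline: np.ndarray | None = None
    baseline_interval_s: tuple[float, float] | None = None

    @property
    def power_db(self) -> np.ndarray:
        if self.baseline is None:
            raise ValueError("no baseline set; call with_baseline() first")
        return 10.0 * np.log10(self.power / self.baseline[:, None])

    def with_baseline(self, interval_s: tuple[float, float] | None = None,
                      baseline: np.ndarray | None = None) -> "TFRSet":
        """Attach a per-frequency divisive baseline.

        Default interval: all time centers before stimulus onset.  An
        explicit ``baseline`` array (e.g. total-power baseline reused for
        the evoked/induced decomposition) overrides the interval.
        """
        if baseline is not None:
            return replace(self, baseline=np.asarray(baseline, dtype=float),
                           baseline_interval_s=interval_s)
        if interval_s is None:
            mask = self.times_s < 0
            interval_s = (float(self.times_s[0]), 0.0)
        else:
            mask = (self.times_s >= interval_s[0]) & (self.times_s < interval_s[1])
        if not mask.any():
            raise ValueError(f"baseline interval {interval_s} has no time centers")
        base = self.power[:, mask].mean(axis=1)
        base = np.where(base > 0, base, np.finfo(float).tiny)
        return replace(self, baseline=base, baseline_interval_s=tuple(interval_s))


def ersp(
    trial_power: TrialPower,
    baseline_interval_s: tuple[float, float] | None = None,
) -> TFRSet:
    """Total power: across-trial mean of per-trial TFRs, in dB vs baseline."""
    if trial_power.n_trials < 1:
        raise ValueError("need at least one trial")
    mean_power = trial_power.power.mean(axis=0)
    tfr = TFRSet(
        kind="total", power=mean_power,
        freqs_hz=trial_power.freqs_hz, times_s=trial_power.times_s,
        roi=trial_power.roi,
    )
    return tfr.with_baseline(baseline_interval_s)


def evoked_power(
    epochs: EpochSet, roi: ROISpec, grid: FreqGrid,
    center_idx: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
) -> TFRSet:
    """TFR power of the across-trial time-domain average (the ERP).

    Computed per electrode on each electrode's own ERP, then
    electrode-averaged.  Pass the total-power baseline via ``baseline`` to
    express evoked dB on the same reference as the ERSP.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    idx = epochs.channel_indices(roi.channels)
    if center_idx is None:
        center_idx = default_time_centers(grid, epochs.time_s)
    erp_per_channel = epochs.data[:, idx, :].mean(axis=0)
    coeff = morlet_tfr(erp_per_channel, grid, center_idx, epochs.time_s)
    power = (np.abs(coeff) ** 2).mean(axis=0)
    tfr = TFRSet(
        kind="evoked", power=power, freqs_hz=grid.freqs_hz.copy(),
        times_s=epochs.time_s[center_idx], roi=roi,
    )
    return tfr.with_baseline(baseline=baseline) if baseline is not None \
        else tfr.with_baseline()


def induced_power(
    epochs: EpochSet, roi: ROISpec, grid: FreqGrid,
    center_idx: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
) -> TFRSet:
    """Non-phase-locked power: grand ERP removed per electrode in the time
    domain, then per-trial TFRs averaged as for total power.

    Note total power only approximately equals induced + evoked; the
    decomposition residual is data, not an identity to be assumed.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials for induced power")
    idx = epochs.channel_indices(roi.channels)
    if center_idx is None:
        center_idx = default_time_centers(grid, epochs.time_s)
    sub = epochs.data[:, idx, :] - epochs.data[:, idx, :].mean(axis=0, keepdims=True)
    n_tr, n_ch = sub.shape[0], sub.shape[1]
    coeff = morlet_tfr(sub.reshape(n_tr * n_ch, -1), grid, center_idx, epochs.time_s)
    power = (np.abs(coeff) ** 2).reshape(n_tr, n_ch, grid.n_freqs, len(center_idx))
    mean_power = power.mean(axis=(0, 1))
    tfr = TFRSet(
        kind="induced", power=mean_power, freqs_hz=grid.freqs_hz.copy(),
        times_s=epochs.time_s[center_idx], roi=roi,
    )
    return tfr.with_baseline(baseline=baseline) if baseline is not None \
        else tfr.with_baseline()


@dataclass
class ITCSeries:
    """Time course of intertrial coherence at one frequency.

    ITC(t) = |mean over trials of exp(i*phase)| in [0, 1]; 0 is random
    phase, 1 perfect locking.  ``sig_mask`` (optional) marks time points
    where ITC exceeds a permutation null at level ``alpha``.
    """

    freq_hz: float
    times_s: np.ndarray
    itc: np.ndarray
    n_trials: int
    sig_mask: np.ndarray | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.itc < -1e-9) or np.any(self.itc > 1 + 1e-9):
            raise ValueError("ITC must lie in [0, 1]")


def trial_phases(
    epochs: EpochSet, channels, freq_hz: float = ITC_FREQ_HZ,
    cycles: float | None = None, center_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(trial, channel, time) instantaneous phase at one frequency.

    ``cycles`` defaults to the grid rule evaluated at ``freq_hz``.
    Returns (phases with shape trials x channels x times, times_s).
    """
    if cycles is None:
        c0, sf = CYCLES_SPEC
        c_max = c0 * (F_MAX_HZ / F_MIN_HZ) * sf
        cycles = c0 + (c_max - c0) * (freq_hz - F_MIN_HZ) / (F_MAX_HZ - F_MIN_HZ)
    w = morlet_wavelet(freq_hz, cycles, epochs.fs_hz)
    if center_idx is None:
        half = len(w) // 2 + 1
        n = epochs.n_samples
        n_t = min(N_TIMES, max(2, n - 2 * half))
        center_idx = np.unique(
            np.round(np.linspace(half, n - 1 - half, n_t)).astype(int)
        )
    if isinstance(channels, ROISpec):
        channels = channels.channels
    idx = epochs.channel_indices(channels)
    n_tr, n_ch = epochs.n_trials, len(idx)
    x = epochs.data[:, idx, :].reshape(n_tr * n_ch, epochs.n_samples)
    conv = sps.fftconvolve(x, np.conj(w[::-1])[None, :], mode="same", axes=1)
    coeff = conv[:, center_idx]
    phases = np.angle(coeff).reshape(n_tr, n_ch, len(center_idx))
    return phases, epochs.time_s[center_idx]


def itc_from_phases(phases: np.ndarray) -> np.ndarray:
    """Channel-averaged ITC from a trials x channels x times phase array."""
    vectors = np.exp(1j * phases)
    per_channel = np.abs(vectors.mean(axis=0))   # channels x times
    return per_channel.mean(axis=0)


def itc(
    epochs: EpochSet, channels, freq_hz: float = ITC_FREQ_HZ,
    cycles: float | None = None, center_idx: np.ndarray | None = None,
) -> ITCSeries:
    """Intertrial coherence at one frequency, per channel then averaged."""
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials for ITC")
    phases, times = trial_phases(epochs, channels, freq_hz, cycles, center_idx)
    return ITCSeries(
        freq_hz=freq_hz, times_s=times,
        itc=itc_from_phases(phases), n_trials=epochs.n_trials,
    )


@dataclass
class PSD:
    """Welch power spectral density in 1-Hz bins over a band.

    ``log_power`` is 10*log10 of the trial- and channel-averaged linear
    power density per bin; ``power`` keeps the linear values.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    log_power: np.ndarray
    segment: str
    window_samples: int
    overlap_samples: int

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Band-integrated linear power (trapezoid over the density)."""
        m = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        return float(np.trapezoid(self.power[m], self.freqs_hz[m]))


def welch_psd(
    epochs: EpochSet | np.ndarray,
    roi: ROISpec | None = None,
    interval_s: tuple[float, float] | None = None,
    segment: str = "baseline",
    window: int = WELCH_WINDOW,
    overlap: int = WELCH_OVERLAP,
    band_hz: tuple[float, float] = PSD_BAND_HZ,
    fs_hz: float | None = None,
) -> PSD:
    """Averaged-periodogram PSD with Hann taper in 1-Hz bins.

    On an :class:`EpochSet`, ``segment`` selects the prestimulus second
    ('baseline'), the poststimulus second ('poststimulus'), or the 500-ms
    prestimulus period ('prestim500' — the alpha-power analysis window);
    an explicit ``interval_s`` overrides it.  When a segment is shorter
    than the FFT window, the window is clipped to the segment length and
    the spectrum zero-padded back to 1-Hz resolution.  A raw 1- or 2-D
    array is treated as (segments x) samples at ``fs_hz``.
    """
    if isinstance(epochs, EpochSet):
        fs = epochs.fs_hz
        if interval_s is None:
            interval_s = {
                "baseline": (-1.0, 0.0),
                "poststimulus": (0.0, 1.0),
                "prestim500": (-0.5, 0.0),
            }.get(segment)
            if interval_s is None:
                raise ValueError(f"unknown segment {segment!r}")
        mask = (epochs.time_s >= interval_s[0]) & (epochs.time_s < interval_s[1])
        if roi is None:
            idx = np.arange(epochs.n_channels)
        else:
            idx = epochs.channel_indices(roi.channels)
        x = epochs.data[:, idx, :][:, :, mask].reshape(-1, int(mask.sum()))
    else:
        if fs_hz is None:
            raise ValueError("fs_hz is required for raw-array input")
        fs = fs_hz
        x = np.atleast_2d(np.asarray(epochs, dtype=float))
    n = x.shape[1]
    nperseg = min(window, n)
    if n < 2:
        raise ValueError("segment too short for PSD")
    nov = overlap if nperseg == window else int(round(nperseg * overlap / window))
    nfft = max(window, nperseg)  # zero-pad clipped windows back to 1-Hz bins
    freqs, pxx = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nov, nfft=nfft, axis=1
    )
    mean_pxx = pxx.mean(axis=0)
    bmask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    power = mean_pxx[bmask]
    return PSD(
        freqs_hz=freqs[bmask], power=power,
        log_power=10.0 * np.log10(np.where(power > 0, power, np.finfo(float).tiny)),
        segment=segment, window_samples=nperseg, overlap_samples=nov,
    )
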