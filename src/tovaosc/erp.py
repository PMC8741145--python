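"""ERP images, median-split ERPs, phase sorting, and windowed amplitude tests.

An ERP image is the trials x time amplitude matrix of a condition with
trials sorted by a covariate (response time or prestimulus alpha phase) and
smoothed across trials with a moving Gaussian whose width tracks the trial
count: SD = n/30 trials, window width = n/5 trials.  The smoothing matrix
is normalized to be doubly stochastic, so (a) identical input trials come
out unchanged and (b) the column means of the image equal the grand ERP
exactly, whatever the sorting.

Group differences in ERP amplitude are tested with two-sample
Kolmogorov-Smirnov tests on trial-level mean amplitudes inside fixed
windows around the N2 and P3 deflections (150-250 and 330-430 ms
target-locked; -170 to -70 and 0-100 ms response-locked), corrected with
Benjamini-Hochberg FDR at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import EpochSet, ROISpec
from .spectral import morlet_wavelet
from .stats import fdr_correct, ks_two_sample

TARGET_LOCKED_WINDOWS_S = ((0.150, 0.250), (0.330, 0.430))
RESPONSE_LOCKED_WINDOWS_S = ((-0.170, -0.070), (0.0, 0.100))
PHASE_SORT_TIME_S = -0.080
ALPHA_BAND_HZ = (8.0, 12.0)
PHASE_RETAIN_FRACTION = 0.95


def roi_signal(epochs: EpochSet, roi: ROISpec) -> np.ndarray:
    """Per-trial mean over ROI channels: trials x time, in microvolts."""
    idx = epochs.channel_indices(roi.channels)
    return epochs.data[:, idx, :].mean(axis=1)


def grand_erp(trials: np.ndarray) -> np.ndarray:
    return np.asarray(trials).mean(axis=0)


def relock_to_response(
    epochs: EpochSet, window_s: tuple[float, float] = (-0.5, 0.5)
) -> EpochSet:
    """Re-epoch so time zero is the response instant.

    Trials without a response, and trials whose response-locked window
    would leave the original epoch, are excluded.  The stimulus onset
    appears at -rt in the new time axis and the RT is kept in the metadata,
    so the operation is invertible for the retained trials.
    """
    lo, hi = window_s
    if not lo < hi:
        raise ValueError("window_s must be increasing")
    fs = epochs.fs_hz
    n_win = int(round((hi - lo) * fs))
    time_s = lo + np.arange(n_win) / fs
    rt = epochs.meta["rt_s"].to_numpy(dtype=float)
    slabs, keep = [], []
    for i in range(epochs.n_trials):
        if not np.isfinite(rt[i]):
            continue
        start = int(round((rt[i] + lo - epochs.time_s[0]) * fs))
        if start < 0 or start + n_win > epochs.n_samples:
            continue
        slabs.append(epochs.data[i, :, start:start + n_win])
        keep.append(i)
    data = np.stack(slabs) if slabs else np.empty((0, epochs.n_channels, n_win))
    meta = epochs.meta.iloc[keep].reset_index(drop=True)
    return replace(epochs, data=data, time_s=time_s, meta=meta, lock="response")


def _gaussian_band(n: int, sd: float, window: int) -> np.ndarray:
    """Truncated-Gaussian band matrix, rows i weight trials j, |i-j| <= w/2."""
    half = max(int(round(window / 2.0)), 1)
    offsets = np.arange(-half, half + 1)
    taps = np.exp(-0.5 * (offsets / sd) ** 2)
    mat = np.zeros((n, n))
    for k, off in enumerate(offsets):
        d = np.diagonal(mat, offset=off)
        idx = np.arange(len(d))
        if off >= 0:
            mat[idx, idx + off] = taps[k]
        else:
            mat[idx - off, idx] = taps[k]
    return mat


def smoothing_matrix(n: int, sd: float | None = None, window: float | None = None,
                     tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Doubly stochastic moving-Gaussian smoother over n sorted trials.

    Defaults follow the trial-count rule sd = n/30, window = n/5.  The
    truncated Gaussian band matrix is balanced by Sinkhorn iteration so
    every row and column sums to one: rows remain weighted averages of
    nearby trials, and column sums of one make the image's trial mean equal
    the grand ERP exactly.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    sd = n / 30.0 if sd is None else sd
    window = n / 5.0 if window is None else window
    if sd <= 0 or int(round(window / 2.0)) < 1 or n == 1:
        return np.eye(n)
    mat = _gaussian_band(n, sd, int(round(window)))
    for _ in range(max_iter):
        mat /= mat.sum(axis=1, keepdims=True)
        col = mat.sum(axis=0, keepdims=True)
        mat /= col
        if np.abs(col - 1.0).max() < tol:
            break
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


@dataclass
class ERPImage:
    """Sorted, trial-smoothed amplitude matrix with its sorting covariate."""

    matrix: np.ndarray          # sorted trials x time, smoothed (uV)
    time_s: np.ndarray
    sort_key: str               # 'rt' | 'phase' | 'none'
    sort_values: np.ndarray     # per retained trial, non-decreasing
    smoothing_sd_trials: float
    smoothing_window_trials: float
    lock: str = "target"

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def column_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def erp_image(
    trials: np.ndarray,
    sort_values: np.ndarray,
    time_s: np.ndarray | None = None,
    sort_key: str = "rt",
    lock: str = "target",
) -> ERPImage:
    """Sort trials by a covariate and smooth across trials.

    Smoothing uses the trial-count rule (Gaussian SD = n/30 trials, window
    width = n/5 trials).  Ties in the covariate are broken by trial index
    (stable sort).
    """
    trials = np.asarray(trials, dtype=float)
    sort_values = np.asarray(sort_values, dtype=float)
    if trials.ndim != 2:
        raise ValueError("trials must be a trials x time matrix")
    n = trials.shape[0]
    if n < 2:
        raise ValueError("need at least two trials for an ERP image")
    if len(sort_values) != n:
        raise ValueError("sort_values length must equal trial count")
    order = np.argsort(sort_values, kind="stable")
    smoother = smoothing_matrix(n)
    return ERPImage(
        matrix=smoother @ trials[order],
        time_s=np.arange(trials.shape[1]) if time_s is None else np.asarray(time_s),
        sort_key=sort_key,
        sort_values=sort_values[order],
        smoothing_sd_trials=n / 30.0,
        smoothing_window_trials=n / 5.0,
        lock=lock,
    )


def median_split_erps(
    trials: np.ndarray, key: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grand ERPs of the below-median and above-median halves of ``key``.

    Trials are ordered by the key (stable sort) and split in the middle;
    with an odd count the middle trial goes to the below-median half.
    """
    trials = np.asarray(trials, dtype=float)
    key = np.asarray(key, dtype=float)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("cannot median-split fewer than two trials")
    if np.any(~np.isfinite(key)):
        raise ValueError("sort key must be defined for every trial")
    order = np.argsort(key, kind="stable")
    n_lo = (n + 1) // 2
    return trials[order[:n_lo]].mean(axis=0), trials[order[n_lo:]].mean(axis=0)


@dataclass
class PhaseSortInfo:
    """Per-trial phase/power estimates behind a phase-sorted ERP image."""

    phase: np.ndarray           # rad at the sort time, per retained trial
    peak_freq_hz: np.ndarray
    power: np.ndarray
    retained_index: np.ndarray  # indices into the input epoch set


def phase_sort(
    epochs: EpochSet,
    roi: ROISpec,
    phase_time_s: float = PHASE_SORT_TIME_S,
    band_hz: tuple[float, float] = ALPHA_BAND_HZ,
    retain_fraction: float = PHASE_RETAIN_FRACTION,
    n_band_freqs: int = 9,
    display_window_s: tuple[float, float] | None = None,
) -> tuple[ERPImage, PhaseSortInfo]:
    """Alpha-phase-sorted ERP image.

    For every trial the ROI-average signal is probed with single Morlet
    wavelets at ``n_band_freqs`` frequencies spanning the alpha band; the
    band frequency with maximum power at ``phase_time_s`` (-80 ms) defines
    the trial's phase.  The 5% of trials with lowest power are discarded,
    the rest sorted by phase ascending from -pi (ties by trial index) and
    smoothed by the trial-count rule.  ``display_window_s`` optionally
    crops the image columns (the first 400 ms poststimulus in the standard
    rendering).
    """
    if not 0 < band_hz[0] < band_hz[1] < epochs.fs_hz / 2:
        raise ValueError(f"band {band_hz} outside (0, Nyquist)")
    x = roi_signal(epochs, roi)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two trials")
    t0 = epochs.sample_at(phase_time_s)
    band = np.linspace(band_hz[0], band_hz[1], n_band_freqs)
    coeffs = np.empty((n, n_band_freqs), dtype=complex)
    for k, f in enumerate(band):
        w = morlet_wavelet(f, 3.0, epochs.fs_hz)
        half = len(w) // 2
        lo, hi = t0 - half, t0 + half + 1
        if lo < 0 or hi > x.shape[1]:
            raise ValueError("phase_time_s too close to the epoch edge")
        coeffs[:, k] = x[:, lo:hi] @ np.conj(w)
    power = np.abs(coeffs) ** 2
    best = np.argmax(power, axis=1)
    best_power = power[np.arange(n), best]
    best_phase = np.angle(coeffs[np.arange(n), best])

    n_keep = int(np.ceil(retain_fraction * n))
    retained = np.sort(np.argsort(-best_power, kind="stable")[:n_keep])
    image = erp_image(
        x[retained], best_phase[retained],
        time_s=epochs.time_s, sort_key="phase", lock="target",
    )
    if display_window_s is not None:
        m = (image.time_s >= display_window_s[0]) & (image.time_s < display_window_s[1])
        image = replace(image, matrix=image.matrix[:, m], time_s=image.time_s[m])
    info = PhaseSortInfo(
        phase=best_phase[retained],
        peak_freq_hz=band[best[retained]],
        power=best_power[retained],
        retained_index=retained,
    )
    return image, info


def window_amplitude_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    time_s: np.ndarray,
    windows_s=TARGET_LOCKED_WINDOWS_S,
    lock: str = "target",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KS tests of trial-level window-mean amplitudes between two groups.

    Each trial is reduced to its mean amplitude inside each window; the
    two groups' trial-level distributions are compared with a two-sample
    KS test per window, and p-values are BH-FDR corrected across the
    tested windows.  Returns one row per window: window_lo_s, window_hi_s,
    lock, mean_a_uv, mean_b_uv, ks_d, p_raw, p_fdr, significant.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must contain trials")
    rows = []
    for lo, hi in windows_s:
        m = (time_s >= lo) & (time_s < hi)
        if not m.any():
            raise ValueError(f"window ({lo}, {hi}) has no samples")
        va, vb = a[:, m].mean(axis=1), b[:, m].mean(axis=1)
        d, p = ks_two_sample(va, vb)
        rows.append(
            {
                "window_lo_s": lo, "window_hi_s": hi, "lock": lock,
                "mean_a_uv": float(va.mean()), "mean_b_uv": float(vb.mean()),
                "ks_d": d, "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    reject, p_fdr = fdr_correct(table["p_raw"].to_numpy(), alpha=alpha)
    table["p_fdr"] = p_fdr
    table["significant"] = reject
    return table
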