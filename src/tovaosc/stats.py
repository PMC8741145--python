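"""Permutation inference for spectral contrasts, ITC significance, FDR, KS.

Group ERSP differences are tested tile-wise on the time-frequency grid: the
statistic is the difference of 10*log10 mean linear power between groups,
and the null is built by shuffling trial group labels.  Two significance
levels are run by default — alpha = 0.05 with 200 permutations and alpha =
0.0005 with 2000 — and the stricter mask is nested inside the looser one by
deriving both from the largest permutation null.  Tests are deliberately
uncorrected across tiles.

ITC significance uses a circular-time-shift surrogate: each trial's phase
time series is rotated by an independent random offset, which destroys
stimulus locking while preserving each trial's phase dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet
from .spectral import ITCSeries, TrialPower, itc_from_phases, trial_phases

DEFAULT_LEVELS = ((0.05, 200), (0.0005, 2000))


def _diff_log_mean_power(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    tiny = np.finfo(float).tiny
    return 10.0 * (
        np.log10(np.maximum(mean_a, tiny)) - np.log10(np.maximum(mean_b, tiny))
    )


@dataclass
class PermutationResult:
    """Tile-wise permutation contrast of log mean spectral power.

    ``observed_diff_db`` is group A minus group B.  ``masks`` maps each
    alpha level to a boolean grid where the observed difference falls
    outside the two-sided null interval; ``null_quantiles`` maps alpha to
    the (lower, upper) bound grids.  Masks at stricter alphas are subsets
    of looser ones because all levels share the largest null.
    """

    observed_diff_db: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    masks: dict[float, np.ndarray]
    null_quantiles: dict[float, tuple[np.ndarray, np.ndarray]]
    n_perm: dict[float, int]
    seed: int | None

    def mask(self, alpha: float) -> np.ndarray:
        return self.masks[alpha]

    def significant_fraction(self, alpha: float) -> float:
        return float(self.masks[alpha].mean())


def permutation_ersp_diff(
    trials_a: TrialPower | np.ndarray,
    trials_b: TrialPower | np.ndarray,
    levels=DEFAULT_LEVELS,
    seed: int | None = None,
    freqs_hz: np.ndarray | None = None,
    times_s: np.ndarray | None = None,
) -> PermutationResult:
    """Two-sided label-shuffling test of the group power difference.

    ``levels`` is a sequence of (alpha, n_perm) pairs; the null is computed
    once with the largest requested n_perm and every alpha's two-sided
    quantile bounds are read from it, which makes stricter masks nested in
    looser ones by construction.  A warning is issued when n_perm < 1/alpha
    for a requested level.
    """
    pa = trials_a.power if isinstance(trials_a, TrialPower) else np.asarray(trials_a)
    pb = trials_b.power if isinstance(trials_b, TrialPower) else np.asarray(trials_b)
    if isinstance(trials_a, TrialPower):
        freqs_hz = trials_a.freqs_hz if freqs_hz is None else freqs_hz
        times_s = trials_a.times_s if times_s is None else times_s
    if pa.shape[0] < 2 or pb.shape[0] < 2:
        raise ValueError("both groups need at least two trials")
    if pa.shape[1:] != pb.shape[1:]:
        raise ValueError("group power grids do not match")
    grid_shape = pa.shape[1:]
    n_a, n_b = pa.shape[0], pb.shape[0]
    x = np.concatenate([pa, pb]).reshape(n_a + n_b, -1)
    observed = _diff_log_mean_power(x[:n_a].mean(axis=0), x[n_a:].mean(axis=0))

    levels = sorted(levels, key=lambda av: av[0], reverse=True)
    n_perm_max = max(n for _, n in levels)
    for alpha, n_perm in levels:
        if n_perm + 1 < 2.0 / alpha:
            warnings.warn(
                f"n_perm={n_perm} is below 2/alpha-1={2 / alpha - 1:.0f}; "
                "the two-sided null tail is under-resolved and the realized "
                "level is bounded below by 2/(n_perm+1)",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm_max, x.shape[1]))
    total = x.sum(axis=0)
    for p in range(n_perm_max):
        idx_a = rng.choice(n_a + n_b, size=n_a, replace=False)
        sum_a = x[idx_a].sum(axis=0)
        null[p] = _diff_log_mean_power(sum_a / n_a, (total - sum_a) / n_b)

    # exact order-statistic thresholds with the (n_perm + 1) convention:
    # P(obs > k-th of n order stats) = (n - k + 1)/(n + 1) under the null
    null.sort(axis=0)
    masks: dict[float, np.ndarray] = {}
    quantiles: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    n_perm_used: dict[float, int] = {}
    for alpha, n_perm in levels:
        k_hi = min(int(np.ceil((1.0 - alpha / 2.0) * (n_perm_max + 1))), n_perm_max)
        k_lo = max(int(np.floor((alpha / 2.0) * (n_perm_max + 1))), 1)
        hi = null[k_hi - 1]
        lo = null[k_lo - 1]
        masks[alpha] = ((observed < lo) | (observed > hi)).reshape(grid_shape)
        quantiles[alpha] = (lo.reshape(grid_shape), hi.reshape(grid_shape))
        n_perm_used[alpha] = n_perm_max
    return PermutationResult(
        observed_diff_db=observed.reshape(grid_shape),
        freqs_hz=np.asarray(freqs_hz) if freqs_hz is not None else np.array([]),
        times_s=np.asarray(times_s) if times_s is not None else np.array([]),
        masks=masks, null_quantiles=quantiles, n_perm=n_perm_used, seed=seed,
    )


def itc_significance(
    epochs: EpochSet,
    channels,
    freq_hz: float = 10.0,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    center_idx: np.ndarray | None = None,
) -> ITCSeries:
    """ITC with a pointwise circular-shift permutation significance mask.

    The null rotates each trial's phase time series by an independent
    uniform offset; ITC(t) is significant where it exceeds the null's
    (1 - alpha) quantile at that time point.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials")
    phases, times = trial_phases(epochs, channels, freq_hz, center_idx=center_idx)
    observed = itc_from_phases(phases)
    rng = np.random.default_rng(seed)
    n_tr, _, n_t = phases.shape
    null = np.empty((n_perm, n_t))
    for p in range(n_perm):
        shifts = rng.integers(0, n_t, n_tr)
        rolled = np.stack([np.roll(phases[i], shifts[i], axis=-1) for i in range(n_tr)])
        null[p] = itc_from_phases(rolled)
    threshold = np.quantile(null, 1.0 - alpha, axis=0)
    return ITCSeries(
        freq_hz=freq_hz, times_s=times, itc=observed, n_trials=n_tr,
        sig_mask=observed > threshold, alpha=alpha,
    )


def fdr_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, p).

    D is the supremum distance between the two empirical CDFs; the p-value
    is exact for small samples and asymptotic otherwise (scipy's 'auto').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sstats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)
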