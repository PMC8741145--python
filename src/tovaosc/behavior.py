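"""TOVA performance scoring and norm-referenced standardization.

Five measures are derived per participant and test half: mean correct
response time (RT, ms), RT variability (RTV, the SD of correct RTs, ms),
commission errors (responses to nontargets), omission errors (missed
targets), and d' (signal-detection sensitivity separating hits from false
alarms).  Raw measures are standardized against a normative table to a
scale with mean 100 and SD 15, signed so that scores below 100 always mean
worse-than-normative performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .simulate import ANTICIPATORY_CUTOFF_S, BehavioralRecord

TRIAL_CLASSES = (
    "correct_response",
    "correct_inhibition",
    "commission",
    "omission",
    "invalid",
)

#: Measures where a larger raw value means worse performance.
HIGHER_IS_WORSE = {"mean_rt_ms": True, "rtv_ms": True, "n_commission": True,
                   "n_omission": True, "d_prime": False}


def classify_trials(
    record: BehavioralRecord,
    anticipatory_cutoff_s: float = ANTICIPATORY_CUTOFF_S,
) -> pd.Series:
    """Assign each trial to one of the four TOVA classes, or 'invalid'.

    Targets with a response are correct responses, without one omissions;
    nontargets with a response are commissions, without one correct
    inhibitions.  Any response faster than the anticipatory cutoff (150 ms)
    makes the trial invalid and excludes it from all four classes.
    """
    t = record.trials
    is_target = (t["stim"] == "target").to_numpy()
    responded = t["responded"].to_numpy().astype(bool)
    rt = t["rt_s"].to_numpy()
    anticipatory = responded & (rt < anticipatory_cutoff_s)
    out = np.where(
        anticipatory,
        "invalid",
        np.where(
            is_target,
            np.where(responded, "correct_response", "omission"),
            np.where(responded, "commission", "correct_inhibition"),
        ),
    )
    return pd.Series(out, index=t.index, name="condition")


def d_prime(n_hit: int, n_target: int, n_fa: int, n_nontarget: int,
            mode: str = "zdiff") -> float:
    """Signal-detection sensitivity from hit and false-alarm counts.

    mode='zdiff' (default): d' = z(H) - z(FA) with the log-linear
    correction H = (hits + 0.5)/(targets + 1), FA = (fa + 0.5)/(nontargets
    + 1), which keeps extreme rates finite.  mode='ratio' returns the
    hit/false-alarm *rate* ratio (an alternative reading of "ratio of hits
    to false alarms"); it is monotone in the same direction but not on the
    d' scale.
    """
    if n_target <= 0 or n_nontarget <= 0:
        raise ValueError("need at least one target and one nontarget trial")
    h = (n_hit + 0.5) / (n_target + 1.0)
    fa = (n_fa + 0.5) / (n_nontarget + 1.0)
    if mode == "zdiff":
        return float(_norm.ppf(h) - _norm.ppf(fa))
    if mode == "ratio":
        return float(h / fa)
    raise ValueError(f"unknown d' mode {mode!r}")


@dataclass
class BehavioralScores:
    """Raw (and optionally standardized) TOVA measures for one half."""

    half: str
    n_trials: int
    n_correct_response: int
    n_correct_inhibition: int
    n_commission: int
    n_omission: int
    n_invalid: int
    mean_rt_ms: float          # NaN when no valid correct responses
    rtv_ms: float              # NaN when fewer than 2 correct responses
    d_prime: float
    standard_scores: dict[str, float] = field(default_factory=dict)
    classification: str | None = None

    def raw_measures(self) -> dict[str, float]:
        return {
            "mean_rt_ms": self.mean_rt_ms,
            "rtv_ms": self.rtv_ms,
            "n_commission": float(self.n_commission),
            "n_omission": float(self.n_omission),
            "d_prime": self.d_prime,
        }

    def to_row(self) -> dict:
        row = {
            "half": self.half,
            "n_trials": self.n_trials,
            "n_correct_response": self.n_correct_response,
            "n_correct_inhibition": self.n_correct_inhibition,
            "n_commission": self.n_commission,
            "n_omission": self.n_omission,
            "n_invalid": self.n_invalid,
            "mean_rt_ms": self.mean_rt_ms,
            "rtv_ms": self.rtv_ms,
            "d_prime": self.d_prime,
        }
        for k, v in self.standard_scores.items():
            row[f"ss_{k}"] = v
        if self.classification is not None:
            row["classification"] = self.classification
        return row


def raw_scores(record: BehavioralRecord, classes: pd.Series | None = None,
               d_prime_mode: str = "zdiff") -> BehavioralScores:
    """Raw TOVA measures from a behavioral record.

    Anticipatory (invalid) trials count toward none of the four classes and
    their RTs are excluded from the RT statistics.
    """
    if classes is None:
        classes = classify_trials(record)
    t = record.trials
    counts = classes.value_counts()
    n_cr = int(counts.get("correct_response", 0))
    n_ci = int(counts.get("correct_inhibition", 0))
    n_com = int(counts.get("commission", 0))
    n_om = int(counts.get("omission", 0))
    n_inv = int(counts.get("invalid", 0))

    rts = t.loc[classes == "correct_response", "rt_s"].to_numpy()
    mean_rt = float(np.mean(rts) * 1e3) if len(rts) >= 1 else float("nan")
    rtv = float(np.std(rts, ddof=1) * 1e3) if len(rts) >= 2 else float("nan")

    n_target = n_cr + n_om
    n_nontarget = n_ci + n_com
    if n_target > 0 and n_nontarget > 0:
        dp = d_prime(n_cr, n_target, n_com, n_nontarget, mode=d_prime_mode)
    else:
        dp = float("nan")

    half = t["half"].iloc[0] if "half" in t and len(t) else "?"
    return BehavioralScores(
        half=str(half), n_trials=len(t),
        n_correct_response=n_cr, n_correct_inhibition=n_ci,
        n_commission=n_com, n_omission=n_om, n_invalid=n_inv,
        mean_rt_ms=mean_rt, rtv_ms=rtv, d_prime=dp,
    )


class NormTable:
    """Normative means/SDs keyed by (measure, age range, gender).

    Rows: measure, age_lo, age_hi (half-open [age_lo, age_hi)), gender,
    mean, sd.  Overlapping age ranges within a (measure, gender) cell are a
    validation error; sd must be positive.
    """

    COLUMNS = ("measure", "age_lo", "age_hi", "gender", "mean", "sd")

    def __init__(self, rows: pd.DataFrame):
        missing = set(self.COLUMNS) - set(rows.columns)
        if missing:
            raise ValueError(f"norm table missing columns: {sorted(missing)}")
        if (rows["sd"] <= 0).any():
            raise ValueError("norm table sd values must be positive")
        if (rows["age_lo"] >= rows["age_hi"]).any():
            raise ValueError("age_lo must be below age_hi")
        for (m, g), grp in rows.groupby(["measure", "gender"]):
            grp = grp.sort_values("age_lo")
            lo = grp["age_lo"].to_numpy()
            hi = grp["age_hi"].to_numpy()
            if (lo[1:] < hi[:-1]).any():
                raise ValueError(f"overlapping age ranges for ({m}, {g})")
        self.rows = rows.reset_index(drop=True)

    def lookup(self, measure: str, age: float, gender: str) -> tuple[float, float]:
        """(mean, sd) for the matching cell; KeyError if none covers `age`."""
        r = self.rows
        hit = r[
            (r["measure"] == measure)
            & (r["gender"] == gender)
            & (r["age_lo"] <= age)
            & (age < r["age_hi"])
        ]
        if hit.empty:
            raise KeyError(
                f"no norm row for measure={measure!r}, age={age}, gender={gender!r}"
            )
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NormTable":
        return cls(pd.read_csv(path, sep="\t"))


def standardize(
    scores: BehavioralScores,
    norms: NormTable,
    age: float,
    gender: str,
    scale_mean: float = 100.0,
    scale_sd: float = 15.0,
) -> BehavioralScores:
    """Norm-referenced standard scores on the 100/15 scale.

    The z score is signed so that lower standard scores always indicate
    worse performance: for error counts, RT and RTV (higher raw = worse)
    the z is negated; for d' it is kept.  A raw value at the normative
    mean maps to exactly 100.
    """
    ss = {}
    for measure, raw in scores.raw_measures().items():
        if np.isnan(raw):
            continue
        mean, sd = norms.lookup(measure, age, gender)
        z = (raw - mean) / sd
        if HIGHER_IS_WORSE[measure]:
            z = -z
        ss[measure] = scale_mean + scale_sd * z
    scores.standard_scores = ss
    return scores


#: Default cutoffs for normative classification (package surrogates for the
#: proprietary TOVA rules): any standard score below `low` -> not within
#: normal limits; any in [low, borderline) -> borderline; else normal.
DEFAULT_THRESHOLDS = {"low": 70.0, "borderline": 85.0}


def classify_performance(
    scores: BehavioralScores, thresholds: dict[str, float] = DEFAULT_THRESHOLDS
) -> str:
    """Label performance from standard scores with half-open cutoffs.

    A score exactly at `low` counts as borderline, exactly at `borderline`
    as normal.
    """
    if not scores.standard_scores:
        raise ValueError("standardize() must be applied before classification")
    values = np.array(list(scores.standard_scores.values()))
    if (values < thresholds["low"]).any():
        label = "not_within_normal"
    elif (values < thresholds["borderline"]).any():
        label = "borderline"
    else:
        label = "normal"
    scores.classification = label
    return label
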