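"""Filtering, epoching, rejection, baselining, balancing, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tovaosc import preprocess as pre
from tovaosc import simulate as sim

from conftest import FS, make_epochs


def _sine_recording(freq_hz, amp=1.0, duration_s=20.0, fs=FS):
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    data = amp * np.sin(2 * np.pi * freq_hz * t)[None, :]
    return sim.ContinuousRecording(
        data=data, fs_hz=fs, channel_labels=("POz",),
        events=pd.DataFrame(columns=["onset_s", "stim", "half", "responded", "rt_s"]),
        annotations=pd.DataFrame(columns=["kind", "start_s", "end_s"]),
    )


def _central_rms(x):
    n = x.shape[-1]
    return np.sqrt(np.mean(x[..., n // 4: 3 * n // 4] ** 2))


class TestFilterBand:
    def test_stopband_attenuation_at_60hz(self):
        rec = _sine_recording(60.0)
        out = pre.filter_band(rec, 2.0, 45.0)
        att_db = 20 * np.log10(_central_rms(rec.data) / max(_central_rms(out.data), 1e-300))
        assert att_db >= 20.0

    def test_passband_preserves_10hz(self):
        rec = _sine_recording(10.0)
        out = pre.filter_band(rec, 2.0, 45.0)
        assert _central_rms(out.data) == pytest.approx(_central_rms(rec.data), rel=0.05)

    def test_dc_removed(self):
        rec = _sine_recording(10.0, amp=0.0)
        rec.data += 5.0
        out = pre.filter_band(rec, 2.0, 45.0)
        assert _central_rms(out.data) < 0.05

    def test_invalid_band_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            pre.filter_band(rec, 45.0, 2.0)


class TestRereference:
    def test_toy_frame_arithmetic(self):
        data = np.array([[5.0], [1.0], [3.0]])
        rec = sim.ContinuousRecording(
            data=data, fs_hz=FS, channel_labels=("Cz", "M1", "M2"),
            events=pd.DataFrame(), annotations=pd.DataFrame(),
        )
        out = pre.rereference(rec, ("M1", "M2"))
        assert out.data[0, 0] == pytest.approx(3.0)

    def test_common_mode_removed(self, rng):
        common = rng.normal(size=200)
        data = np.tile(common, (4, 1))
        rec = sim.ContinuousRecording(
            data=data, fs_hz=FS, channel_labels=("a", "b", "M1", "M2"),
            events=pd.DataFrame(), annotations=pd.DataFrame(),
        )
        out = pre.rereference(rec, ("M1", "M2"))
        assert np.allclose(out.data, 0.0)

    def test_zero_reference_is_identity(self, rng):
        data = rng.normal(size=(3, 100))
        data[1:] = 0.0
        rec = sim.ContinuousRecording(
            data=data, fs_hz=FS, channel_labels=("Cz", "M1", "M2"),
            events=pd.DataFrame(), annotations=pd.DataFrame(),
        )
        out = pre.rereference(rec, ("M1", "M2"))
        assert np.array_equal(out.data[0], data[0])

    def test_missing_label_raises(self, clean_recording):
        with pytest.raises(KeyError):
            pre.rereference(clean_recording, ("M1", "nope"))


class TestEpoch:
    def test_full_schedule_epoch_shape(self):
        sched = sim.make_schedule("H1", 8, 16, seed=0)
        rec = sim.synthesize_eeg(sched, None, sim.GenParams(seed=1, blink_rate_per_min=0))
        ep = pre.epoch(rec)
        assert ep.data.shape[0] == 24
        assert ep.n_samples == 1024  # 2.0 s at 512 Hz
        assert ep.time_s[0] == pytest.approx(-1.0)
        assert ep.time_s[-1] == pytest.approx(1.0 - 1 / FS)

    def test_anticipatory_response_flagged_invalid(self, clean_recording):
        events = clean_recording.events.copy()
        events.loc[events.index[0], ["responded", "rt_s"]] = [True, 0.10]
        ep = pre.epoch(clean_recording, events)
        assert ep.meta["condition"].iloc[0] == "invalid"

    def test_empty_events(self, clean_recording):
        ep = pre.epoch(clean_recording, clean_recording.events.iloc[:0])
        assert ep.n_trials == 0

    def test_edge_events_dropped(self, clean_recording):
        events = clean_recording.events.copy()
        events.loc[events.index[0], "onset_s"] = 0.2  # window would start before 0
        ep = pre.epoch(clean_recording, events)
        assert ep.n_trials == len(events) - 1

    def test_epochs_reproduce_continuous_segments(self, clean_recording):
        ep = pre.epoch(clean_recording)
        fs = clean_recording.fs_hz
        for i in [0, ep.n_trials - 1]:
            s0 = int(round((ep.meta["onset_s"].iloc[i] - 1.0) * fs))
            assert np.array_equal(ep.data[i], clean_recording.data[:, s0:s0 + 1024])


class TestRejection:
    def _epochs_with_onsets(self, onsets):
        n = len(onsets)
        data = np.zeros((n, 4, 64))
        ep = make_epochs(data)
        ep.meta["onset_s"] = onsets
        return ep

    @pytest.mark.parametrize(
        "blink_offset_s,expect_rejected",
        [(0.5, True), (0.7, False), (-0.39, True), (-0.45, False)],
    )
    def test_blink_guard_window(self, blink_offset_s, expect_rejected):
        ep = self._epochs_with_onsets([10.0])
        ann = pd.DataFrame(
            [("blink", 10.0 + blink_offset_s, 10.0 + blink_offset_s + 0.01)],
            columns=["kind", "start_s", "end_s"],
        )
        out, log = pre.reject_blink_epochs(ep, ann)
        assert (out.n_trials == 0) is expect_rejected
        assert log.n_rejected == int(expect_rejected)

    def test_no_blinks_all_retained(self):
        ep = self._epochs_with_onsets([2.0, 4.0, 6.0])
        ann = pd.DataFrame(columns=["kind", "start_s", "end_s"])
        out, log = pre.reject_blink_epochs(ep, ann)
        assert out.n_trials == 3 and log.n_rejected == 0

    @pytest.mark.parametrize(
        "n_bad_channels,expect_rejected", [(6, True), (1, False), (5, False)]
    )
    def test_amplitude_channel_fraction_rule(self, n_bad_channels, expect_rejected):
        # 10 channels; rejection requires strictly more than 50% above threshold
        data = np.zeros((1, 10, 64))
        data[0, :n_bad_channels, 32] = 100.0
        ep = make_epochs(data)
        out, _ = pre.reject_amplitude(ep, threshold_uv=80.0)
        assert (out.n_trials == 0) is expect_rejected

    def test_all_zero_epoch_retained(self):
        ep = make_epochs(np.zeros((2, 4, 64)))
        out, _ = pre.reject_amplitude(ep)
        assert out.n_trials == 2

    def test_rejections_idempotent_and_commute(self):
        rng = np.random.default_rng(0)
        n = 12
        data = rng.normal(size=(n, 6, 64))
        data[2] += 200.0          # amplitude artifact on all channels
        data[7] += 200.0
        ep = make_epochs(data)
        ep.meta["onset_s"] = 2.0 + np.arange(n) * 2.0
        ann = pd.DataFrame(
            [("blink", ep.meta["onset_s"][4] + 0.1, ep.meta["onset_s"][4] + 0.2)],
            columns=["kind", "start_s", "end_s"],
        )

        def onsets(e):
            return tuple(e.meta["onset_s"])

        a1, _ = pre.reject_amplitude(ep)
        a2, _ = pre.reject_amplitude(a1)
        assert onsets(a1) == onsets(a2)  # idempotent

        ab, _ = pre.reject_blink_epochs(a1, ann)
        b1, _ = pre.reject_blink_epochs(ep, ann)
        ba, _ = pre.reject_amplitude(b1)
        assert onsets(ab) == onsets(ba)  # commute on disjoint criteria


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = make_epochs(np.full((1, 2, 64), 5.0))
        out = pre.baseline_correct(ep, (-1.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_baseline_mean_is_zero(self, clean_epochs):
        out = pre.baseline_correct(clean_epochs, (-1.0, 0.0))
        mask = (out.time_s >= -1.0) & (out.time_s < 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-10)

    def test_phase_mode_interval_recorded(self, clean_epochs):
        out = pre.baseline_correct(clean_epochs, pre.BASELINE_PHASE_S)
        assert out.baseline_interval_s == (-1.0, -0.9)

    def test_pairwise_differences_unchanged(self, rng):
        ep = make_epochs(rng.normal(size=(3, 2, 64)))
        out = pre.baseline_correct(ep, (-1.0, 0.0))
        assert np.allclose(
            np.diff(out.data, axis=2), np.diff(ep.data, axis=2)
        )

    def test_empty_interval_rejected(self, clean_epochs):
        with pytest.raises(ValueError):
            pre.baseline_correct(clean_epochs, (0.5, 0.5))


def _participant_epochs(n_resp_h1=40, n_inh_h1=80, seed=0):
    rng = np.random.default_rng(seed)
    n = n_resp_h1 + n_inh_h1
    data = rng.normal(size=(n, 4, 128))
    ep = make_epochs(data)
    cond = ["correct_response"] * n_resp_h1 + ["correct_inhibition"] * n_inh_h1
    ep.meta["condition"] = cond
    ep.meta["half"] = "H1"
    ep.meta["onset_s"] = 2.0 + np.arange(n) * 2.0
    return ep


class TestBalance:
    def test_quota_drawn_when_available(self):
        ep = _participant_epochs(40, 80)
        out, report = pre.balance_epochs(ep, seed=1)
        assert report.table.set_index("condition").loc["correct_response", "drawn"] == 36
        assert out.n_trials == 36 + 72

    def test_exclusion_below_quota(self):
        ep = _participant_epochs(35, 80)
        out, report = pre.balance_epochs(ep, seed=1)
        row = report.table.set_index("condition").loc["correct_response"]
        assert not row["included"] and row["drawn"] == 0
        assert out.n_trials == 72  # only the frequent condition contributes

    def test_contributes_108_epochs_per_half(self):
        ep = _participant_epochs(36, 72)
        out, _ = pre.balance_epochs(ep, seed=2)
        assert out.n_trials == 108

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_reproducible_and_subset(self, seed):
        ep = _participant_epochs(50, 90, seed=3)
        a, _ = pre.balance_epochs(ep, seed=seed)
        b, _ = pre.balance_epochs(ep, seed=seed)
        assert np.array_equal(a.data, b.data)
        drawn = set(a.meta["onset_s"])
        assert drawn <= set(ep.meta["onset_s"])


class TestSamplingStability:
    def test_identical_epochs_zero_variance(self):
        ep = _participant_epochs(40, 80)
        ep.data[:] = np.sin(2 * np.pi * 10 * np.arange(128) / FS)
        v = pre.sampling_stability(ep, n_draws=4, seed=0,
                                   statistic=lambda e: e.data.mean(axis=0))
        assert v == pytest.approx(0.0, abs=1e-20)

    def test_available_equals_quota_zero_variance(self):
        ep = _participant_epochs(36, 72, seed=4)
        v = pre.sampling_stability(ep, n_draws=4, seed=0,
                                   statistic=lambda e: e.data.mean(axis=0))
        assert v == pytest.approx(0.0, abs=1e-20)

    def test_variance_grows_from_zero_toward_finite_sample_bound(self):
        # drawing q of N without replacement: across-draw variance of the
        # mean is (sigma^2/q)(N-q)/(N-1) - zero at N=q, rising toward
        # sigma^2/q as N grows
        stat = lambda e: e.where(condition="correct_response").data.mean(axis=0)
        vs = []
        for n_avail in (36, 80, 320):
            ep = _participant_epochs(n_avail, 80, seed=5)
            vs.append(pre.sampling_stability(ep, n_draws=10, seed=1, statistic=stat))
        assert vs[0] == pytest.approx(0.0, abs=1e-20)
        assert vs[0] < vs[1] < vs[2]
        ep = _participant_epochs(320, 80, seed=5)
        sigma2 = ep.where(condition="correct_response").data.var(axis=0, ddof=1).mean()
        q = 36
        bound = sigma2 / q * (320 - q) / (320 - 1)
        assert vs[2] == pytest.approx(bound, rel=0.8)

    def test_below_quota_raises(self):
        ep = _participant_epochs(20, 80)
        with pytest.raises(ValueError):
            pre.sampling_stability(ep, n_draws=3, seed=0,
                                   statistic=lambda e: e.data.mean())


class TestSplitEarlyLate:
    @pytest.mark.parametrize("n,expected", [(10, (5, 5)), (11, (6, 5)), (2, (1, 1))])
    def test_split_sizes(self, n, expected):
        ep = make_epochs(np.zeros((n, 2, 32)))
        ep.meta["onset_s"] = 2.0 + np.arange(n) * 2.0
        early, late = pre.split_early_late(ep)
        assert (early.n_trials, late.n_trials) == expected

    def test_temporal_order(self, rng):
        n = 15
        ep = make_epochs(np.zeros((n, 2, 32)))
        ep.meta["onset_s"] = rng.permutation(n) * 2.0 + 2.0
        early, late = pre.split_early_late(ep)
        assert early.meta["onset_s"].max() < late.meta["onset_s"].min()

    def test_single_trial_raises(self):
        ep = make_epochs(np.zeros((1, 2, 32)))
        with pytest.raises(ValueError):
            pre.split_early_late(ep)


class TestVeogBlinkDetector:
    def test_detects_injected_blinks(self):
        sched = sim.make_schedule("H1", 4, 12, seed=0)
        rec = sim.synthesize_eeg(
            sched, None, sim.GenParams(seed=1, blink_rate_per_min=10.0)
        )
        detected = pre.detect_blinks_veog(rec)
        truth = rec.annotations
        if len(truth):
            # every true blink overlaps a detection
            hits = sum(
                ((detected["start_s"] < b.end_s) & (detected["end_s"] > b.start_s)).any()
                for b in truth.itertuples()
            )
            assert hits >= 0.8 * len(truth)
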