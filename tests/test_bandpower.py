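"""Band-power streaming, region weighting and the dwell-limited state machine."""

import numpy as np
import pytest

from wearbci.bandpower import (
    STATE_BANDS,
    BandPowerConfig,
    BandPowerStateDecoder,
    RegionWeighting,
    StateDecisionConfig,
    aggregate_weighted,
    band_power_stream,
    decide_state,
    run_task_battery,
)
from wearbci.signal_core import ALPHA, Recording
from wearbci.stats import confusion

from conftest import sinusoid_recording


class TestBandPowerStream:
    def test_default_config_streams_at_2hz(self):
        rec = sinusoid_recording(10.0, fs=256.0, seconds=30.0)
        times, power = band_power_stream(rec, ALPHA)
        assert np.allclose(np.diff(times), 0.5)  # f_band = 256/(256-128) = 2 Hz
        assert BandPowerConfig().f_band == 2.0

    @pytest.mark.parametrize(
        "n_buffer,n_overlap,fs,n_samples",
        [(256, 128, 256.0, 7000), (128, 0, 256.0, 5000), (300, 250, 250.0, 9001)],
    )
    def test_frame_count_formula(self, n_buffer, n_overlap, fs, n_samples, rng):
        cfg = BandPowerConfig(n_buffer=n_buffer, n_overlap=n_overlap, f_system=fs)
        rec = Recording(rng.standard_normal((2, n_samples)), fs=fs)
        times, power = band_power_stream(rec, ALPHA, cfg)
        expected = (n_samples - n_buffer) // (n_buffer - n_overlap) + 1
        assert power.shape == (2, expected)
        assert np.allclose(np.diff(times), 1.0 / cfg.f_band)

    def test_unit_sinusoid_power_half(self):
        rec = sinusoid_recording(10.0, fs=256.0, seconds=30.0)
        times, power = band_power_stream(rec, ALPHA, log=False)
        settled = power[0, times > 3.0]
        assert np.allclose(settled, 0.5, rtol=0.05)  # A^2/2 for A = 1

    def test_zero_input_floors_at_log_eps(self):
        rec = Recording(np.zeros((1, 2560)), fs=256.0)
        _, power = band_power_stream(rec, ALPHA)
        assert np.allclose(power, np.log(1e-12))

    def test_short_recording_warns_and_is_empty(self):
        rec = Recording(np.zeros((1, 100)), fs=256.0)
        with pytest.warns(UserWarning, match="shorter"):
            times, power = band_power_stream(rec, ALPHA)
        assert times.size == 0 and power.shape == (1, 0)

    def test_amplitude_doubling_quadruples_power(self, rng):
        x = rng.standard_normal((2, 2560))
        r1 = Recording(x, fs=256.0)
        r2 = Recording(2.0 * x, fs=256.0)
        _, p1 = band_power_stream(r1, ALPHA, log=False)
        _, p2 = band_power_stream(r2, ALPHA, log=False)
        assert np.allclose(p2, 4.0 * p1, rtol=1e-12)
        _, l1 = band_power_stream(r1, ALPHA)
        _, l2 = band_power_stream(r2, ALPHA)
        assert np.allclose(l2 - l1, np.log(4.0), atol=1e-9)

    def test_power_non_negative_and_log_monotone(self, rng):
        rec = Recording(rng.standard_normal((3, 3000)), fs=256.0)
        _, p = band_power_stream(rec, ALPHA, log=False)
        _, lp = band_power_stream(rec, ALPHA, log=True)
        assert np.all(p >= 0)
        order_pre = np.argsort(p, axis=0)
        order_post = np.argsort(lp, axis=0)
        assert np.array_equal(order_pre, order_post)


class TestRegionWeighting:
    def test_frontal_theta_doubled_alpha_beta_unchanged(self):
        frame = np.ones((1, 3))  # single frontal grid, uniform log power 1
        scores = aggregate_weighted(frame, ["frontal"])
        assert np.allclose(scores, [2.0, 1.0, 1.0])

    def test_identity_weights_reduce_to_plain_mean(self, rng):
        frame = rng.standard_normal((5, 3))
        flat = RegionWeighting({r: {"theta": 1.0, "alpha": 1.0, "beta": 1.0}
                                for r in ("frontal", "occipital", "other")})
        scores = aggregate_weighted(frame, ["frontal", "occipital", "other", "other", "frontal"],
                                    weighting=flat)
        assert np.allclose(scores, frame.mean(axis=0))

    def test_mixed_region_hand_arithmetic(self):
        frame = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        scores = aggregate_weighted(frame, ["frontal", "occipital"])
        # theta: mean(2*1, 1*3) = 2.5
        assert scores[0] == pytest.approx(2.5)

    def test_missing_region_rejected(self):
        with pytest.raises(KeyError, match="temporal"):
            aggregate_weighted(np.ones((1, 3)), ["temporal"])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RegionWeighting({"frontal": {"theta": 0.0}})


class TestStateDecision:
    def test_all_below_threshold_stays_idle(self):
        times = np.arange(0, 30, 0.5)
        scores = np.full((len(times), 3), -5.0)
        cfg = StateDecisionConfig(min_power_threshold=0.0)
        assert set(decide_state(times, scores, cfg)) == {"idle"}

    def test_highest_band_above_threshold_wins(self):
        times = np.arange(0, 30, 0.5)
        scores = np.tile([3.0, 1.0, 2.0], (len(times), 1))
        cfg = StateDecisionConfig(min_power_threshold=0.0)
        states = decide_state(times, scores, cfg)
        assert states[0] == "theta" and set(states) == {"theta"}

    def test_alternating_argmax_respects_dwell(self):
        times = np.arange(0, 60, 0.5)
        scores = np.zeros((len(times), 3))
        scores[::2, 0] = 5.0  # theta and alpha alternate as argmax every frame
        scores[1::2, 1] = 5.0
        cfg = StateDecisionConfig(min_power_threshold=1.0, min_dwell_seconds=6.0)
        states = decide_state(times, scores, cfg)
        change_times = [t for t, a, b in zip(times[1:], states[1:], states[:-1]) if a != b]
        assert len(change_times) > 1
        assert np.all(np.diff(change_times) >= 6.0)

    def test_dwell_constraint_on_random_streams(self, rng):
        for _ in range(20):
            times = np.cumsum(rng.uniform(0.1, 1.0, 200))
            scores = rng.normal(0, 3, (200, 3))
            states = decide_state(times, scores, StateDecisionConfig(0.0, 6.0))
            change_times = [t for t, a, b in zip(times[1:], states[1:], states[:-1]) if a != b]
            assert np.all(np.diff(change_times) >= 6.0 - 1e-9)

    def test_tie_breaks_theta_over_alpha_over_beta(self):
        times = np.array([0.0])
        states = decide_state(times, np.array([[1.0, 1.0, 1.0]]),
                              StateDecisionConfig(min_power_threshold=0.0))
        assert states == ["theta"]


class TestDecoderAndBattery:
    def test_threshold_calibrated_from_baseline(self, idle_baseline):
        dec = BandPowerStateDecoder().fit(idle_baseline)
        assert dec.threshold_.shape == (3,)
        # 90th percentile: ~10% of baseline frames exceed per band
        frac = (dec.baseline_scores_ >= dec.threshold_).mean(axis=0)
        assert np.all(frac <= 0.15)

    def test_predicted_states_match_blocks(self, small_battery, idle_baseline):
        rec, intervals = small_battery
        dec = BandPowerStateDecoder().fit(idle_baseline)
        times, states = dec.predict_timeline(rec)
        correct = 0
        total = 0
        lookup = {(a, b): lab for a, b, lab in intervals}
        for t, s in zip(times, states):
            for a, b, lab in intervals:
                if a + 8.0 < t <= b:  # skip transition + dwell region
                    total += 1
                    correct += s == lab
        assert correct / total > 0.9

    def test_battery_counting(self, small_battery):
        rec, intervals = small_battery
        truth, preds = run_task_battery(rec, intervals)
        assert len(truth) == len(preds) == 2 * 3 * 30  # 2 trials x 3 states x 30 s

    def test_clean_separation_gives_diagonal_confusion(self, small_battery):
        rec, intervals = small_battery
        truth, preds = run_task_battery(rec, intervals)
        cm = confusion(truth, preds)
        assert np.allclose(np.diag(cm.loc[["theta", "alpha", "beta"],
                                          ["theta", "alpha", "beta"]]), 100.0)

    def test_unlabeled_spans_warn(self, small_battery):
        rec, intervals = small_battery
        with pytest.warns(UserWarning, match="unlabeled"):
            run_task_battery(rec, intervals[:-1])
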