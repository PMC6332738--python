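"""Detection, epoching and the two baseline corrections."""

import numpy as np
import pytest

from dhmea.io import SpikeTable, TraceSet
from dhmea.preprocess import (
    DegenerateThresholdError,
    DetectionSpec,
    EpochSpec,
    EpochTensor,
    StageError,
    blank_artifact,
    detect_crossings,
    extract_epochs,
    load_tensor,
    per_stimulus_baseline,
    save_tensor,
    whole_channel_baseline,
)
from dhmea.synth import inject_pulses

from conftest import dummy_events


class TestDetect:
    def test_flat_trace_degenerate(self):
        tr = TraceSet(np.zeros((1, 40000 * 11)), 40000.0, "wideband")
        with pytest.raises(DegenerateThresholdError):
            detect_crossings(tr)

    def test_single_pulse_after_noisy_baseline(self):
        # noise in [-1, 0] V during the threshold-setting prelude, then
        # silence with one -5 V pulse: exactly one captured spike
        fs = 40000.0
        truth = SpikeTable([10.5], [1], n_channels=1)
        tr = inject_pulses(truth, duration_s=11.0, sampling_rate_hz=fs, baseline_quiet=True, seed=0)
        out = detect_crossings(tr)
        assert len(out) == 1
        assert out.time_s[0] == pytest.approx(10.5, abs=1 / fs)

    def test_recovers_injected_pulse_train(self):
        fs = 40000.0
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(10.5, 29.5, 100))
        times = times[np.concatenate(([True], np.diff(times) > 2e-3))]
        times = np.round(times * fs) / fs
        truth = SpikeTable(times, np.ones(times.size, dtype=int), n_channels=1)
        tr = inject_pulses(truth, duration_s=30.0, sampling_rate_hz=fs, baseline_quiet=True, seed=1)
        out = detect_crossings(tr)
        np.testing.assert_allclose(out.time_s, truth.time_s, atol=1 / fs)

    def test_matches_brute_force_scan(self):
        # noisy trace: detector equals a literal sample-by-sample scan
        fs = 40000.0
        rng = np.random.default_rng(11)
        n = int(15 * fs)
        x = rng.uniform(-1.0, 0.0, n)
        for i in rng.integers(int(10.2 * fs), n - 10, 100):
            x[i : i + 4] = -5.0
        spec = DetectionSpec()
        tr = TraceSet(x[None, :], fs, "wideband")
        out = detect_crossings(tr, spec)

        n_base = int(spec.baseline_window_s * fs)
        mu, mn = x[:n_base].mean(), x[:n_base].min()
        vth = mu - spec.threshold_fraction * (mu - mn)
        expected = []
        last = -np.inf
        for i in range(n_base, n):
            if x[i] < vth and x[i - 1] >= vth and (i - last) >= spec.dead_time_ms / 1000 * fs:
                expected.append(i / fs)
                last = i
        np.testing.assert_allclose(out.time_s, expected)

    def test_dead_time_merges_close_crossings(self):
        fs = 40000.0
        x = np.zeros(int(11 * fs))
        x[: int(10 * fs)] = np.linspace(-1, 0, int(10 * fs))  # non-flat baseline
        i0 = int(10.5 * fs)
        x[i0 : i0 + 2] = -5.0
        x[i0 + 8 : i0 + 10] = -5.0  # 0.2 ms later: inside 1 ms dead time
        out = detect_crossings(TraceSet(x[None, :], fs, "wideband"))
        assert len(out) == 1


class TestExtract:
    def test_single_spike_lands_in_correct_bin(self):
        events = dummy_events(1, start_s=10.0)
        spikes = SpikeTable([10.003], [4])
        t = extract_epochs(spikes, events)
        assert t.values.sum() == 1
        # +3 ms -> bin 103 with 100 ms pre
        assert t.values[0, 3, 103] == 1

    def test_pre_stimulus_spike(self):
        events = dummy_events(1, start_s=10.0)
        spikes = SpikeTable([9.950], [1])
        t = extract_epochs(spikes, events)
        assert t.values[0, 0, 50] == 1  # bin covering -50 ms

    def test_count_conservation_vs_brute_force(self, random_spikes):
        rng = np.random.default_rng(2)
        spikes = random_spikes(rng, n=10_000, t_max=150.0)
        events = dummy_events(10, gap_s=12.0, start_s=5.0)
        spec = EpochSpec()
        t = extract_epochs(spikes, events, spec)
        total = 0
        for ev in events:
            lo, hi = ev.time_s - 0.1, ev.time_s + 1.0
            total += int(np.sum((spikes.time_s >= lo) & (spikes.time_s < hi)))
        assert t.values.sum() == total

    def test_overlapping_epochs_double_count(self):
        # two events 0.5 s apart: a spike between them joins both epochs
        events = dummy_events(2, gap_s=0.5, start_s=10.0, freq=2.0)
        # 10.45 s sits at +450 ms of the first epoch and -50 ms of the second
        spikes = SpikeTable([10.45], [1])
        t = extract_epochs(spikes, events)
        assert t.values.sum() == 2

    def test_hdf5_round_trip(self, tmp_path, make_tensor):
        tensor = make_tensor(np.random.default_rng(0))
        p = tmp_path / "t.h5"
        save_tensor(p, tensor)
        back = load_tensor(p)
        assert np.array_equal(back.values, tensor.values)
        assert back.stage == tensor.stage
        assert back.events == tensor.events


class TestBlank:
    def test_default_window_zeroes_first_two_post_bins(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(1), pre_ms=10, post_ms=40)
        out = blank_artifact(tensor, (0.0, 2.0))
        assert (out.values[:, :, 10:12] == 0).all()
        assert np.array_equal(out.values[:, :, 12:], tensor.values[:, :, 12:])
        assert np.array_equal(out.values[:, :, :10], tensor.values[:, :, :10])

    def test_empty_window_is_identity(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(1))
        out = blank_artifact(tensor, (0.0, 0.0))
        assert np.array_equal(out.values, tensor.values)

    def test_window_outside_epoch_rejected(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(1), post_ms=40)
        with pytest.raises(ValueError):
            blank_artifact(tensor, (30.0, 50.0))


class TestBaselines:
    def test_constant_reference_subtracts_rate(self, make_tensor):
        spec = EpochSpec(pre_ms=10, post_ms=40, bin_ms=1.0)
        values = np.zeros((4, 2, 50), dtype=np.int64)
        values[:2, :, :10] = 1  # reference pre-stimulus counts: 1/bin
        tensor = EpochTensor(values, spec, dummy_events(4), stage="raw")
        out, base = whole_channel_baseline(tensor, np.array([0, 1]))
        np.testing.assert_allclose(base, 1.0)
        np.testing.assert_allclose(out.values, values - 1.0)
        assert out.stage == "channel_corrected"

    def test_zero_reference_is_identity(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(3))
        tensor.values[:2, :, :10] = 0
        out, base = whole_channel_baseline(tensor, np.array([0, 1]))
        np.testing.assert_allclose(base, 0.0)
        np.testing.assert_allclose(out.values, tensor.values)

    def test_matches_brute_force(self, make_tensor):
        rng = np.random.default_rng(4)
        tensor = make_tensor(rng, n_stim=8)
        ref = np.array([0, 2, 5])
        out, base = whole_channel_baseline(tensor, ref)
        for c in range(tensor.n_channels):
            vals = [tensor.values[s, c, b] for s in ref for b in range(10)]
            assert base[c] == pytest.approx(np.mean(vals))
            for s in range(tensor.n_stimuli):
                np.testing.assert_allclose(out.values[s, c], tensor.values[s, c] - base[c])

    def test_reference_pre_stimulus_mean_zeroed(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(5), n_stim=10)
        ref = np.arange(4)
        out, _ = whole_channel_baseline(tensor, ref)
        per_channel = out.values[ref][:, :, :10].mean(axis=(0, 2))
        np.testing.assert_allclose(per_channel, 0.0, atol=1e-12)

    def test_empty_reference_rejected(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(5))
        with pytest.raises(ValueError):
            whole_channel_baseline(tensor, np.array([], dtype=int))

    def test_per_stimulus_zeroes_every_epoch(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(6), n_stim=7)
        corrected, _ = whole_channel_baseline(tensor, np.array([0]))
        out = per_stimulus_baseline(corrected)
        pre_means = out.values[:, :, :10].mean(axis=2)
        np.testing.assert_allclose(pre_means, 0.0, atol=1e-12)
        assert out.stage == "stimulus_corrected"

    def test_per_stimulus_matches_brute_force(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(7))
        corrected, _ = whole_channel_baseline(tensor, np.array([0]))
        out = per_stimulus_baseline(corrected)
        for s in range(tensor.n_stimuli):
            for c in range(tensor.n_channels):
                m = corrected.values[s, c, :10].mean()
                np.testing.assert_allclose(out.values[s, c], corrected.values[s, c] - m)

    def test_stage_order_enforced(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(8))
        with pytest.raises(StageError):
            per_stimulus_baseline(tensor)  # skipping channel correction
        corrected, _ = whole_channel_baseline(tensor, np.array([0]))
        with pytest.raises(StageError):
            whole_channel_baseline(corrected, np.array([0]))
        with pytest.raises(StageError):
            blank_artifact(corrected, (0.0, 2.0))

    def test_negative_corrected_values_retained(self, make_tensor):
        tensor = make_tensor(np.random.default_rng(9), lam=1.0)
        out, _ = whole_channel_baseline(tensor, np.arange(tensor.n_stimuli))
        assert (out.values < 0).any()
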