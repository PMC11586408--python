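import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import npap
from npap.perievent import UndefinedRateError


def _train(times, t0=0.0, t1=100.0, uid="u"):
    return npap.SpikeTrain(uid, np.asarray(times, float), t0, t1)


class TestBinarize:
    def test_no_spikes_gives_zero_vector(self):
        out = npap.binarize(_train([]), 0.0, 0.01, 0.001)
        assert out.shape == (10,) and not out.any()

    def test_one_ms_bins_count_each_spike(self):
        out = npap.binarize(_train([0.0005, 0.0015]), 0.0, 0.005, 0.001)
        assert out.tolist() == [1, 1, 0, 0, 0]

    def test_spike_on_edge_lands_in_right_bin(self):
        out = npap.binarize(_train([0.002]), 0.0, 0.004, 0.001)
        assert out.tolist() == [0, 0, 1, 0]

    @given(st.lists(st.floats(0.001, 9.999), min_size=0, max_size=60, unique=True))
    def test_count_conservation(self, times):
        tr = _train(sorted(times), 0.0, 10.0)
        counts = npap.binarize(tr, 0.0, 10.0, 0.001)
        assert counts.sum() == tr.n_spikes

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            npap.binarize(_train([1.0]), 0.0, 1.0, 0.0)


class TestPeth:
    def test_single_event_single_spike(self):
        pm = npap.peth(_train([5.05]), np.array([5.0]), (-0.1, 0.2), 0.01)
        assert pm.counts.sum() == 1 and (pm.counts > 0).sum() == 1

    def test_row_sums_equal_window_counts(self, stim_session):
        tr = stim_session.spike_trains[0]
        onsets = stim_session.train_onsets(300)
        pm = npap.peth(tr, onsets, (-1.0, 1.5), 0.001)
        for row, t in zip(pm.counts, onsets):
            n = np.sum((tr.times >= t - 1.0) & (tr.times < t + 1.5))
            assert row.sum() == n

    def test_event_order_does_not_change_column_sums(self):
        tr = _train(np.sort(np.random.default_rng(0).uniform(1, 99, 200)))
        events = np.array([10.0, 30.0, 50.0])
        a = npap.peth(tr, events, (-1.0, 1.0), 0.01)
        b = npap.peth(tr, events[::-1], (-1.0, 1.0), 0.01)
        assert np.array_equal(a.counts.sum(axis=0), b.counts.sum(axis=0))

    def test_out_of_session_events_excluded(self):
        pm = npap.peth(_train([5.0]), np.array([0.5, 50.0]), (-1.0, 1.0), 0.01)
        assert pm.excluded_trials == [0] and pm.n_trials == 1

    def test_planted_excitation_peaks_after_pulse(self, stim_session):
        """A unit with the sharp-activation template peaks 10-40 ms post pulse."""
        gt = stim_session.ground_truth
        uid = next(u for u in stim_session.unit_ids
                   if gt[u]["pattern"] == 3 and gt[u]["rate_hz"] > 2.0)
        pulses = np.concatenate(stim_session.stim_trains(300))
        pm = npap.peth(stim_session.unit(uid), pulses, (-0.05, 0.25), 0.005)
        peak = pm.bin_lefts[np.argmax(pm.trial_average())]
        assert 0.005 <= peak <= 0.045


class TestFiringRate:
    def test_regular_spikes(self):
        assert npap.isi_firing_rate(_train(np.arange(0.1, 10, 0.1))) == pytest.approx(10.0)

    def test_single_spike_signals_undefined(self):
        with pytest.raises(UndefinedRateError):
            npap.isi_firing_rate(_train([1.0]))

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 600, rng.poisson(3.0 * 600)))
        r = npap.isi_firing_rate(npap.SpikeTrain("u", times, 0.0, 600.0))
        assert abs(r - 3.0) / 3.0 < 0.05


class TestStabilityFilter:
    def test_silent_unit_dropped(self):
        res = npap.stability_filter(_train([]), np.arange(5.0, 50.0, 5.0))
        assert not res.keep and res.silent_fraction == 1.0

    def test_homogeneous_unit_kept(self):
        rng = np.random.default_rng(2)
        tr = _train(np.sort(rng.uniform(0, 300, rng.poisson(5.0 * 300))), 0.0, 300.0)
        events = np.arange(5.0, 255.0, 5.0)
        res = npap.stability_filter(tr, events)
        counts = [np.sum((tr.times >= t) & (tr.times < t + 5.0)) for t in events]
        assert res.silent_fraction == np.mean([c / 5.0 < 0.1 for c in counts])
        assert res.keep

    def test_exactly_forty_percent_silent_is_kept(self):
        # 4 of 10 windows empty: boundary stays on the keep side
        spikes = np.concatenate([np.arange(t + 0.5, t + 4.5, 0.5) for t in range(0, 30, 5)])
        tr = _train(np.sort(spikes), 0.0, 60.0)
        res = npap.stability_filter(tr, np.arange(0.0, 50.0, 5.0))
        assert res.silent_fraction == pytest.approx(0.4)
        assert res.keep

    @given(st.integers(0, 2**31 - 1))
    def test_adding_spikes_never_flips_keep_to_drop(self, seed):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.uniform(0, 100, 30))
        extra = np.sort(np.concatenate([base, rng.uniform(0, 100, 30)]))
        extra = np.unique(extra)
        events = np.arange(0.0, 95.0, 5.0)
        a = npap.stability_filter(_train(base), events)
        b = npap.stability_filter(_train(extra), events)
        assert b.silent_fraction <= a.silent_fraction
        if a.keep:
            assert b.keep


class TestZScore:
    def test_affine_counts_produce_identical_z(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(20, 300))
        pm = npap.PerieventMatrix(counts, (-1.0, 2.0), 0.01)
        z1 = npap.zscore_peth(pm)
        pm2 = npap.PerieventMatrix(counts * 7 + 3, (-1.0, 2.0), 0.01)
        z2 = npap.zscore_peth(pm2)
        assert np.allclose(z1.values, z2.values)

    def test_zero_baseline_sd_flagged(self):
        pm = npap.PerieventMatrix(np.zeros((5, 300)), (-1.0, 2.0), 0.01)
        z = npap.zscore_peth(pm)
        assert not z.valid and np.isnan(z.values).all()

    def test_baseline_mean_of_output_near_zero(self, stim_session):
        tr = stim_session.spike_trains[0]
        pm = npap.peth(tr, stim_session.train_onsets(300), (-1.0, 1.5), 0.01)
        z = npap.zscore_peth(pm)
        if z.valid:
            assert abs(z.values[z.bin_lefts < 0].mean()) < 1e-9

    def test_planted_excitation_peak_in_early_window(self, stim_session):
        gt = stim_session.ground_truth
        uid = next(u for u in stim_session.unit_ids
                   if gt[u]["pattern"] == 3 and gt[u]["rate_hz"] > 2.0)
        pulses = np.concatenate(stim_session.stim_trains(300))
        pm = npap.peth(stim_session.unit(uid), pulses, (-0.1, 0.3), 0.005)
        z = npap.zscore_peth(pm, baseline=(-0.1, 0.0))
        t_peak = z.bin_lefts[np.argmax(np.abs(z.values))]
        assert 0.0 <= t_peak <= 0.045


class TestResponseLatency:
    def _excitation_unit(self, seed, base=8.0, onset=0.010, width=0.030, gain=12.0):
        from npap.simulate import _segment_modulated_spikes
        onsets = 10.0 + 5.0 * np.arange(50)
        segs = [(t + onset, t + onset + width, gain) for t in onsets]
        times = _segment_modulated_spikes(np.random.default_rng(seed), base, 300.0, segs, 1.0)
        return npap.SpikeTrain("u", times, 0.0, 300.0), onsets

    def test_planted_10ms_excitation_recovered(self):
        lats = []
        for seed in range(15):
            tr, onsets = self._excitation_unit(seed)
            pm = npap.peth(tr, onsets, (-1.0, 1.5), 0.001)
            res = npap.response_latency(pm, search_s=0.3)
            lats.append(res.increase_latency_ms)
        lats = [l for l in lats if l is not None]
        assert len(lats) >= 13
        assert abs(np.median(lats) - 10.0) <= 2.0

    def test_pure_suppression_yields_decrease_only(self):
        from npap.simulate import _segment_modulated_spikes
        onsets = 10.0 + 5.0 * np.arange(50)
        segs = [(t + 0.010, t + 0.150, 0.0) for t in onsets]
        hit = inc_false = 0
        for seed in range(8):
            times = _segment_modulated_spikes(np.random.default_rng(seed), 8.0, 300.0, segs, 1.0)
            pm = npap.peth(npap.SpikeTrain("u", times, 0.0, 300.0), onsets, (-1.0, 1.5), 0.001)
            res = npap.response_latency(pm, consecutive=2, search_s=0.3)
            hit += res.decrease_latency_ms is not None
            inc_false += res.increase_latency_ms is not None
        assert hit >= 7
        assert inc_false <= 2

    def test_no_crossing_reports_absent_latency(self):
        rng = np.random.default_rng(0)
        pm = npap.PerieventMatrix(rng.poisson(0.1, (30, 2500)), (-1.0, 1.5), 0.001)
        res = npap.response_latency(pm, consecutive=3)
        assert res.increase_latency_ms is None

    def test_coarse_bins_rejected(self):
        pm = npap.PerieventMatrix(np.zeros((3, 250)), (-1.0, 1.5), 0.01)
        with pytest.raises(ValueError, match="1 ms"):
            npap.response_latency(pm)


class TestComponentAmplitudes:
    def test_flat_z_gives_zero_amplitudes(self):
        z = npap.ZScoredTrace(np.zeros(2500), (-1.0, 1.5), 0.001)
        amp = npap.component_amplitudes(z, 0.3 * np.arange(5))
        assert not amp.short.any() and not amp.decremental.any() and not amp.long.any()

    def test_planted_triphasic_signs_on_every_pulse(self, stim_session):
        gt = stim_session.ground_truth
        uid = next(u for u in stim_session.unit_ids
                   if gt[u]["pattern"] == 5 and gt[u]["rate_hz"] > 3.0)
        pm = npap.peth(stim_session.unit(uid), stim_session.train_onsets(300),
                       (-1.0, 1.5), 0.001)
        amp = npap.component_amplitudes(npap.zscore_peth(pm), 0.3 * np.arange(5))
        assert np.all(amp.short > 0)
        assert np.all(amp.decremental < 0)
        assert np.all(amp.long > 0)

    def test_facilitation_knob_raises_second_pulse(self):
        cfg = npap.GenConfig(n_neurons=25, n_trains_300=50, n_trains_500=0, seed=6,
                             proportions=(0.0, 0.0, 1.0, 0.0, 0.0),
                             pulse_gains=(1.0, 1.5, 1.0, 1.0, 1.0))
        s = npap.generate_session(cfg)
        diffs = []
        for uid in s.unit_ids:
            if s.ground_truth[uid]["rate_hz"] < 2.0:
                continue
            pm = npap.peth(s.unit(uid), s.train_onsets(300), (-1.0, 1.5), 0.001)
            z = npap.zscore_peth(pm)
            if not z.valid:
                continue
            amp = npap.component_amplitudes(z, 0.3 * np.arange(5))
            diffs.append(amp.short[1] - amp.short[0])
        assert np.median(diffs) > 0

    def test_requires_five_pulses(self):
        z = npap.ZScoredTrace(np.zeros(2500), (-1.0, 1.5), 0.001)
        with pytest.raises(ValueError):
            npap.component_amplitudes(z, np.arange(4) * 0.3)
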