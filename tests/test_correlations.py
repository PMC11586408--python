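import numpy as np
import pytest

import npap


class TestEvokedPairCorrelation:
    def test_unit_against_itself_is_one(self, stim_session):
        uid = next(u for u in stim_session.unit_ids
                   if stim_session.unit(u).n_spikes > 100)
        r = npap.evoked_pair_correlation(stim_session, uid, uid)
        assert r == pytest.approx(1.0)

    def test_symmetric_in_pair_order(self, stim_session):
        ids = [u for u in stim_session.unit_ids if stim_session.unit(u).n_spikes > 100][:2]
        r_ab = npap.evoked_pair_correlation(stim_session, ids[0], ids[1])
        r_ba = npap.evoked_pair_correlation(stim_session, ids[1], ids[0])
        assert r_ab == pytest.approx(r_ba)

    def test_shared_template_pair_correlates_positively(self, stim_session):
        gt = stim_session.ground_truth
        ids = [u for u in stim_session.unit_ids
               if gt[u]["pattern"] == 3 and gt[u]["rate_hz"] > 2.0][:2]
        r = npap.evoked_pair_correlation(stim_session, ids[0], ids[1])
        assert r > 0.3


class TestSpontaneousPairCorrelation:
    def _pair(self, rho_drive=0.0, seed=0, span=200.0):
        """Two units; optional common slow rate modulation."""
        rng = np.random.default_rng(seed)
        edges = np.arange(0.0, span, 1.0)
        drive = 1.0 + 0.8 * np.sin(2 * np.pi * edges / 20.0)
        trains = []
        for k in range(2):
            rates = 4.0 * (drive if rho_drive else np.ones_like(edges))
            times = []
            for t0, lam in zip(edges, rates):
                n = rng.poisson(lam)
                times.append(t0 + np.sort(rng.uniform(0, 1.0, n)))
            t = np.unique(np.concatenate(times))
            trains.append(npap.SpikeTrain(f"u{k}", t, 0.0, span))
        return trains

    def test_identical_trains_correlate_perfectly(self):
        a, _ = self._pair(seed=1)
        r, warned = npap.spontaneous_pair_correlation(a, a, [(0.0, 200.0)])
        assert r == pytest.approx(1.0)
        assert not warned

    def test_common_slow_modulation_detected(self):
        a, b = self._pair(rho_drive=1.0, seed=2)
        r, _ = npap.spontaneous_pair_correlation(a, b, [(0.0, 200.0)])
        a0, b0 = self._pair(rho_drive=0.0, seed=3)
        r0, _ = npap.spontaneous_pair_correlation(a0, b0, [(0.0, 200.0)])
        assert r > 0.3
        assert r > r0 + 0.2

    def test_zero_smoothing_reduces_to_raw_binned(self):
        a, b = self._pair(rho_drive=1.0, seed=4)
        r_raw, _ = npap.spontaneous_pair_correlation(a, b, [(0.0, 200.0)], smooth_sd_s=0.0)
        ca = npap.binarize(a, 0.0, 200.0, 0.1).astype(float)
        cb = npap.binarize(b, 0.0, 200.0, 0.1).astype(float)
        assert r_raw == pytest.approx(np.corrcoef(ca, cb)[0, 1])

    def test_short_segments_warn(self):
        a, b = self._pair(seed=5, span=30.0)
        with pytest.warns(UserWarning, match="60"):
            _, warned = npap.spontaneous_pair_correlation(a, b, [(0.0, 30.0)])
        assert warned


class TestCrossConditionCorrelation:
    def test_same_condition_correlates_perfectly(self, stim_session):
        uid = next(u for u in stim_session.unit_ids
                   if stim_session.unit(u).n_spikes > 200)
        res = npap.cross_condition_response_correlation(stim_session, uid, 300, 300)
        assert np.allclose(res.r_per_stimulus, 1.0)

    def test_matched_templates_beat_surrogate(self, stim_session):
        gt = stim_session.ground_truth
        obs, null = [], []
        for uid in stim_session.unit_ids:
            if gt[uid]["pattern"] == 1 or gt[uid]["rate_hz"] < 2.0:
                continue
            try:
                res = npap.cross_condition_response_correlation(
                    stim_session, uid, n_surrogates=8, surrogate_seed=1)
            except ValueError:
                continue
            obs += list(res.r_per_stimulus)
            null += list(res.null_values)
        assert np.median(obs) > np.median(null) + 0.3

    def test_flat_unit_indistinguishable_from_surrogate(self, stim_session):
        gt = stim_session.ground_truth
        rs = []
        for uid in stim_session.unit_ids:
            if gt[uid]["pattern"] != 1 or gt[uid]["rate_hz"] < 2.0:
                continue
            try:
                res = npap.cross_condition_response_correlation(stim_session, uid)
            except ValueError:
                continue
            rs += list(res.r_per_stimulus)
        assert abs(np.median(rs)) < 0.25

    def test_percentile_requires_null(self, stim_session):
        uid = stim_session.unit_ids[0]
        res = npap.cross_condition_response_correlation(stim_session, uid)
        with pytest.raises(ValueError):
            res.percentile()


class TestSignedAmplitude:
    def test_flat_trace_gives_zero(self):
        lefts = np.arange(-0.5, 0.5, 0.01)
        assert npap.signed_amplitude(np.zeros(lefts.size), lefts) == 0.0

    def test_suppression_yields_negative_amplitude(self):
        lefts = np.arange(-0.5, 0.5, 0.01)
        z = np.where((lefts >= 0.0) & (lefts < 0.1), -3.0, 0.1)
        assert npap.signed_amplitude(z, lefts) == -3.0

    def test_largest_magnitude_wins_with_sign(self):
        lefts = np.arange(-0.2, 0.2, 0.01)
        z = np.zeros(lefts.size)
        z[5], z[30] = 2.0, -4.0
        assert npap.signed_amplitude(z, lefts) == -4.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            npap.signed_amplitude(np.zeros(10), np.arange(10.0), window=(-0.5, -0.4))


class TestCrosscorrLag:
    def test_self_lag_within_one_bin(self):
        s = npap.generate_latency_linked_session(
            latencies_ms=np.array([20.0, 120.0]), n_trains=5, n_movements=60, seed=9)
        mov = s.events["movement_onset"].times
        lag = npap.crosscorr_lag(s.unit("u0000"), s.unit("u0000"), mov)
        assert abs(lag) <= 0.010

    def test_planted_100ms_offset_recovered(self):
        s = npap.generate_latency_linked_session(
            latencies_ms=np.array([20.0, 120.0]), n_trains=5, n_movements=60, seed=9)
        mov = s.events["movement_onset"].times
        lag = npap.crosscorr_lag(s.unit("u0000"), s.unit("u0001"), mov)
        assert lag == pytest.approx(0.100, abs=0.015)
        # antisymmetric under pair swap
        rev = npap.crosscorr_lag(s.unit("u0001"), s.unit("u0000"), mov)
        assert rev == pytest.approx(-lag, abs=0.015)

    def test_no_onsets_rejected(self):
        tr = npap.SpikeTrain("u", np.array([1.0]), 0.0, 10.0)
        with pytest.raises(ValueError):
            npap.crosscorr_lag(tr, tr, np.array([]))


def test_pair_classification_against_null():
    null = np.linspace(-0.5, 0.5, 200)
    assert npap.classify_pair(0.9, null)
    assert not npap.classify_pair(0.2, null)
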