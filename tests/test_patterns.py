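import dataclasses

import numpy as np
import pytest

import npap
from npap.patterns import DegenerateFeaturesError, random_trajectory
from conftest import matched_accuracy


class TestFeatureMatrix:
    def test_300_isi_window_has_150_columns(self, stim_session):
        fm = npap.evoked_feature_matrix(stim_session, 300)
        assert fm.values.shape[1] == 150  # 1.5 s at 10 ms

    def test_500_isi_window_has_250_columns(self, stim_session):
        fm = npap.evoked_feature_matrix(stim_session, 500)
        assert fm.values.shape[1] == 250  # 2.5 s at 10 ms

    def test_cross_isi_mode_equalizes_columns(self, stim_session):
        a = npap.evoked_feature_matrix(stim_session, 300, cross_isi=True)
        b = npap.evoked_feature_matrix(stim_session, 500, cross_isi=True)
        assert a.values.shape[1] == b.values.shape[1] == 150

    def test_flat_population_gives_near_zero_matrix(self):
        cfg = npap.GenConfig(n_neurons=30, n_trains_300=30, n_trains_500=0, seed=4,
                             proportions=(1.0, 0.0, 0.0, 0.0, 0.0))
        s = npap.generate_session(cfg)
        fm = npap.evoked_feature_matrix(s, 300)
        # z traces of non-responsive units stay at noise level
        assert np.abs(fm.values.mean(axis=0)).max() < 1.5
        assert np.abs(fm.values).mean() < 1.2


class TestClassifyPatterns:
    def test_three_planted_templates_recovered(self):
        # high SNR so even low-rate units separate cleanly in shape space
        cfg = npap.GenConfig(n_neurons=90, n_trains_300=50, n_trains_500=0, seed=5,
                             snr=2.0, proportions=(0.0, 1 / 3, 1 / 3, 0.0, 1 / 3))
        s = npap.generate_session(cfg)
        fm = npap.evoked_feature_matrix(s, 300)
        asg = npap.classify_patterns(fm, k_range=range(2, 7), n_runs=50, seed=2)
        assert asg.chosen_k == 3
        truth = {u: s.ground_truth[u]["pattern"] for u in fm.unit_ids}
        assert matched_accuracy(asg, truth, nonflat_only=False) >= 0.95

    def test_duplicating_rows_keeps_k_and_templates(self, classified_cohort):
        _, fm, asg = classified_cohort
        doubled = npap.FeatureMatrix(
            np.vstack([fm.values, fm.values]),
            fm.unit_ids + [f"{u}+" for u in fm.unit_ids],
            fm.bin_width_s, fm.isi_ms,
        )
        asg2 = npap.classify_patterns(doubled, n_runs=40, seed=2)
        assert asg2.chosen_k == asg.chosen_k
        # same partition geometry: templates pair up 1:1 with high correlation
        match = npap.match_clusters(asg, asg2)
        assert all(c > 0.98 for c in match.correlations.values())

    def test_pure_noise_reports_low_flat_silhouette(self):
        """No planted structure: the silhouette stays at the noise floor
        (k-means on isotropic 3-PC noise plateaus near 0.3, far below the
        >0.6 of structured cohorts) and is flat across k."""
        rng = np.random.default_rng(8)
        fm = npap.FeatureMatrix(rng.normal(size=(80, 150)),
                                [f"u{i}" for i in range(80)], 0.01, 300)
        asg = npap.classify_patterns(fm, k_range=range(2, 7), n_runs=30, seed=1)
        assert asg.silhouette < 0.45
        sils = list(asg.silhouette_by_k.values())
        assert max(sils) - min(sils) < 0.15

    def test_row_order_invariance(self, classified_cohort):
        _, fm, asg = classified_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fm.unit_ids))
        shuffled = npap.FeatureMatrix(fm.values[perm],
                                      [fm.unit_ids[i] for i in perm],
                                      fm.bin_width_s, fm.isi_ms)
        asg2 = npap.classify_patterns(shuffled, n_runs=40, seed=2)
        assert asg2.chosen_k == asg.chosen_k
        agree = np.mean([asg2.labels[u] == asg.labels[u] for u in fm.unit_ids])
        assert agree >= 0.95

    def test_selected_silhouette_dominates_all_k(self, classified_cohort):
        _, _, asg = classified_cohort
        assert asg.silhouette == max(asg.silhouette_by_k.values())

    def test_too_few_units_rejected(self):
        fm = npap.FeatureMatrix(np.random.default_rng(0).normal(size=(6, 20)),
                                [f"u{i}" for i in range(6)], 0.01, 300)
        with pytest.raises(DegenerateFeaturesError):
            npap.classify_patterns(fm)

    def test_rank_deficient_matrix_rejected(self):
        fm = npap.FeatureMatrix(np.ones((30, 20)), [f"u{i}" for i in range(30)], 0.01, 300)
        with pytest.raises(DegenerateFeaturesError):
            npap.classify_patterns(fm, k_range=range(2, 5), n_runs=5)


class TestPrevalence:
    def _assignment(self, labels):
        n = len(labels)
        return npap.PatternAssignment(
            labels={f"u{i}": l for i, l in enumerate(labels)},
            chosen_k=max(labels), silhouette=0.5,
            templates=np.zeros((max(labels), 4)), pc_loadings=np.zeros((3, 4)),
            silhouette_by_k={}, unit_ids=[f"u{i}" for i in range(n)],
        )

    def test_single_label_session_is_100_percent(self):
        asg = self._assignment([2] * 10)
        percent, animals = npap.pattern_prevalence(asg, {f"u{i}": "s0" for i in range(10)})
        assert percent.loc["s0", 2] == 100.0
        assert animals[2] == 1

    def test_small_sessions_excluded_from_percentages(self):
        labels = [1] * 7 + [2] * 9
        unit_session = {f"u{i}": ("small" if i < 7 else "big") for i in range(16)}
        asg = self._assignment(labels)
        percent, _ = npap.pattern_prevalence(asg, unit_session, min_units=8)
        assert "small" not in percent.index and "big" in percent.index

    def test_planted_mixture_recovered_within_binomial_error(self, classified_cohort):
        session, fm, asg = classified_cohort
        truth = {u: session.ground_truth[u]["pattern"] for u in fm.unit_ids}
        labs = asg.label_array()
        # cluster 1 is the non-responsive pattern by the naming convention
        frac_flat = float(np.mean(labs == 1))
        n = len(labs)
        assert abs(frac_flat - 0.5) < 3 * np.sqrt(0.25 / n) + 0.02

    def test_percentages_sum_to_100(self, classified_cohort):
        _, fm, asg = classified_cohort
        percent, _ = npap.pattern_prevalence(asg, {u: "s0" for u in fm.unit_ids})
        assert percent.sum(axis=1).iloc[0] == pytest.approx(100.0)


class TestMatchClusters:
    def test_self_match_is_identity(self, classified_cohort):
        _, _, asg = classified_cohort
        res = npap.match_clusters(asg, asg)
        assert res.mapping == {c: c for c in res.mapping}
        assert all(c == pytest.approx(1.0) for c in res.correlations.values())

    def test_independent_draws_match_with_high_correlation(self, classified_cohort):
        _, _, asg_a = classified_cohort
        cfg = npap.GenConfig(n_neurons=200, n_trains_300=50, n_trains_500=0, seed=4)
        s = npap.generate_session(cfg)
        fm = npap.evoked_feature_matrix(s, 300)
        asg_b = npap.classify_patterns(fm, n_runs=100, seed=7)
        res = npap.match_clusters(asg_a, asg_b)
        # responsive clusters carry a stable shape; the non-responsive
        # template is near-zero noise and has no correlation to preserve
        assert all(c > 0.8 for lab, c in res.correlations.items() if lab != 1)
        assert len(res.correlations) == asg_a.chosen_k

    def test_incompatible_bins_rejected(self, classified_cohort):
        _, _, asg = classified_cohort
        other = dataclasses.replace(asg, templates=asg.templates[:, :10])
        with pytest.raises(ValueError):
            npap.match_clusters(asg, other)


class TestGlm:
    def _templates(self, rng, n_bins=150):
        return np.vstack([random_trajectory(n_bins, rng) for _ in range(5)])

    def test_exact_template_copy_wins_with_unit_coefficient(self):
        rng = np.random.default_rng(0)
        tpl = self._templates(rng)
        rates = {"u0": np.tile(tpl[2], 10)}
        asg = npap.glm_pattern_assignment(rates, tpl, seed=1)
        assert asg.best["u0"] == 3
        assert asg.coefficients.loc["u0", "pred3"] == pytest.approx(1.0, abs=0.05)

    def test_constant_rate_unit_flagged(self):
        rng = np.random.default_rng(0)
        tpl = self._templates(rng)
        asg = npap.glm_pattern_assignment({"u0": np.ones(1500)}, tpl, seed=1)
        assert asg.flagged == ["u0"] and "u0" not in asg.best

    def test_random_predictor_wins_only_for_flat_units(self):
        rng = np.random.default_rng(3)
        tpl = self._templates(rng)
        rates = {}
        for i in range(10):  # template-driven units
            j = i % 5
            rates[f"t{i}"] = np.tile(tpl[j], 8) + rng.normal(0, 0.3, 8 * tpl.shape[1])
        for i in range(10):  # flat units: pure noise
            rates[f"f{i}"] = rng.normal(0, 1.0, 8 * tpl.shape[1])
        asg = npap.glm_pattern_assignment(rates, tpl, seed=1)
        template_best = [asg.best[f"t{i}"] for i in range(10)]
        assert all(b != 6 for b in template_best)
        flat_random = np.mean([asg.best[f"f{i}"] == 6 for i in range(10)])
        assert flat_random <= 0.5  # near the 1/6 chance level

    def test_glm_agrees_with_cluster_labels(self, classified_cohort):
        """Trajectory regression recovers the silhouette clustering labels."""
        session, fm, asg = classified_cohort
        # order templates 1..5 and restrict to confidently clustered units
        rates = {u: fm.values[i] for i, u in enumerate(fm.unit_ids)}
        glm = npap.glm_pattern_assignment(rates, asg.templates[:5], seed=2)
        resp = [u for u in fm.unit_ids if asg.labels[u] != 1 and u in glm.best]
        agree = np.mean([glm.best[u] == asg.labels[u] for u in resp])
        assert agree >= 0.8
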