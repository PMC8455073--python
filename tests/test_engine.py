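"""Semi-supervised training: normalization, direction choice, the
iterative loop, fold-score merging, and the cross-validated pipeline."""

import warnings

import numpy as np
import pytest

from rescore.confidence import count_accepted, tdc_qvalues
from rescore.engine import (
    TrainConfig,
    brew,
    choose_initial_direction,
    fit_semisupervised,
    normalize_features,
    normalize_fold_scores,
)
from rescore.exceptions import RescoreError, SmallExperimentWarning
from rescore.pin_io import PsmTable
from rescore.synthetic import SyntheticConfig, simulate_psms

from conftest import make_table

T, D = True, False


def quiet_brew(table, config, eval_fdr=0.01):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExperimentWarning)
        return brew(table, config, eval_fdr)


class TestNormalizeFeatures:
    def test_zscore_definition(self):
        table = make_table([[1.0], [2.0], [3.0]], [T, T, D])
        zed, mean, scale = normalize_features(table)
        assert mean[0] == 2.0
        assert scale[0] == pytest.approx(np.sqrt(2 / 3))  # population SD
        np.testing.assert_allclose(zed[:, 0], [-zed[2, 0], 0.0, zed[2, 0]])
        np.testing.assert_allclose(zed[:, 0].mean(), 0, atol=1e-15)

    def test_constant_column_rule(self):
        table = make_table([[5.0], [5.0], [5.0]], [T, T, D])
        zed, _, scale = normalize_features(table)
        assert scale[0] == 1.0
        np.testing.assert_array_equal(zed[:, 0], [0.0, 0.0, 0.0])

    def test_round_trip_algebra(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.standard_normal((20, 3)), rng.random(20) < 0.5)
        zed, mean, scale = normalize_features(table)
        np.testing.assert_allclose(zed * scale + mean, table.feature_matrix, rtol=1e-12)


class TestChooseInitialDirection:
    def test_perfect_separation_and_symmetry(self):
        feats = np.array([[3.0], [2.5], [2.0], [-1.0], [-2.0]])
        table = make_table(feats, [T, T, T, D, D])
        assert choose_initial_direction(table, 0.5)[:2] == (0, 1)
        table_neg = make_table(-feats, [T, T, T, D, D])
        assert choose_initial_direction(table_neg, 0.5)[:2] == (0, -1)

    def test_picks_more_separable_feature_vs_bruteforce(self):
        rng = np.random.default_rng(42)
        n = 400
        labels = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        feats = rng.standard_normal((n, 2))
        feats[labels, 0] += 1.0  # weak
        feats[labels, 1] += 3.0  # strong
        table = make_table(feats, labels)
        j, sign, fallback = choose_initial_direction(table, 0.05)
        # independent brute force over all (feature, sign) pairs
        best = max(
            ((int((tdc_qvalues(s * feats[:, k], labels) <= 0.05).sum()), k, s)
             for k in (0, 1) for s in (1, -1)),
        )
        assert (j, sign) == (best[1], best[2]) == (1, 1)
        assert not fallback

    def test_fallback_flag_when_nothing_accepted(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((20, 2))
        table = make_table(feats, [T] * 10 + [D] * 10)
        j, sign, fallback = choose_initial_direction(table, 0.001)
        assert fallback
        assert sign in (1, -1)


class TestFitSemisupervised:
    def test_separable_data_accepts_all_correct(self):
        table, truth = simulate_psms(
            SyntheticConfig(n_targets=500, n_decoys=500, pi1=1.0, seed=5,
                            n_features=3, effect_sizes=[6.0, 4.0, 2.0],
                            peptide_effect_sd=0.0)
        )
        model = fit_semisupervised(table, TrainConfig(seed=1))
        assert not model.degraded
        counts = model.provenance["iteration_positives"]
        qv = tdc_qvalues(model.score_table(table), table.is_target)
        assert (qv <= 0.01).sum() >= 0.98 * truth.is_correct.sum()
        assert counts[-1] >= counts[0]

    def test_null_data_degrades(self):
        table, _ = simulate_psms(
            SyntheticConfig(n_targets=300, n_decoys=300, pi1=0.0, seed=6)
        )
        model = fit_semisupervised(table, TrainConfig(seed=2))
        if not model.degraded:  # if it trained at all, it must find ~nothing
            qv = tdc_qvalues(model.score_table(table), table.is_target)
            assert (qv <= 0.01).sum() <= 5
        else:
            assert model.provenance["mode"] == "single-feature-fallback"

    def test_deterministic_weights(self, small_experiment):
        table, _ = small_experiment
        m1 = fit_semisupervised(table, TrainConfig(seed=3))
        m2 = fit_semisupervised(table, TrainConfig(seed=3))
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.intercept == m2.intercept

    def test_weights_mapped_to_original_space(self, tiny_experiment):
        table, _ = tiny_experiment
        model = fit_semisupervised(table, TrainConfig(seed=4))
        # scoring via original-space weights == scoring normalized features
        zed = (table.feature_matrix - model.norm_mean) / model.norm_scale
        w_n = model.weights * model.norm_scale
        b_n = model.intercept + float((model.weights * model.norm_mean).sum())
        np.testing.assert_allclose(model.score_table(table), zed @ w_n + b_n, rtol=1e-8, atol=1e-10)


class TestNormalizeFoldScores:
    def test_anchors(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(4, 1, 300), rng.normal(0, 1, 300)])
        labels = np.concatenate([np.ones(300, bool), np.zeros(300, bool)])
        out = normalize_fold_scores(scores, labels, 0.01)
        assert np.median(out[~labels]) == pytest.approx(-1.0)
        qv = tdc_qvalues(out, labels)
        accepted = out[labels][qv <= 0.01]
        assert accepted.min() == pytest.approx(0.0, abs=1e-12)

    def test_identity_when_anchors_already_satisfied(self):
        scores = np.array([2.0, 1.5, 1.0, 0.0, -1.0, -1.0, -1.0])
        labels = np.array([T, T, T, T, D, D, D])
        out = normalize_fold_scores(scores, labels, 0.5)
        np.testing.assert_allclose(out, scores)

    def test_zero_decoys_rejected(self):
        with pytest.raises(RescoreError, match="decoy"):
            normalize_fold_scores([1.0, 2.0], [T, T], 0.01)

    def test_two_folds_agree_in_location(self):
        cfg = dict(n_targets=1500, n_decoys=1500)
        t1, _ = simulate_psms(SyntheticConfig(seed=21, **cfg))
        t2, _ = simulate_psms(SyntheticConfig(seed=22, **cfg))
        model = fit_semisupervised(t1, TrainConfig(seed=0))
        s1 = normalize_fold_scores(model.score_table(t1), t1.is_target, 0.01)
        s2 = normalize_fold_scores(model.score_table(t2), t2.is_target, 0.01)
        from scipy.stats import ks_2samp

        assert ks_2samp(s1, s2).statistic < 0.06


class TestBrew:
    def test_fold_sizes_balanced(self):
        table, _ = simulate_psms(SyntheticConfig(n_targets=50, n_decoys=49, seed=8))
        result = quiet_brew(table, TrainConfig(seed=1, min_positives=1))
        sizes = np.bincount(result.fold_assignment, minlength=3)
        assert sizes.sum() == 99
        assert sizes.max() - sizes.min() <= 1

    def test_spectrum_ranks_stay_in_one_fold(self):
        rng = np.random.default_rng(13)
        n = 600
        scans = np.repeat(np.arange(n // 2), 2)  # two candidate ranks per scan
        feats = rng.standard_normal((n, 2))
        labels = rng.random(n) < 0.5
        feats[labels] += 2.5
        table = make_table(feats, labels, scan_nr=scans, rank=np.tile([1, 2], n // 2))
        result = quiet_brew(table, TrainConfig(seed=2, min_positives=1))
        for scan in np.unique(scans):
            assert len(set(result.fold_assignment[scans == scan])) == 1

    def test_no_psm_scored_by_its_training_model(self, small_experiment):
        table, _ = small_experiment
        result = quiet_brew(table, TrainConfig(seed=5))
        for f, model in enumerate(result.fold_models):
            held = result.fold_assignment == f
            assert model.provenance["n_psms"] == (~held).sum()
            recomputed = model.decision_function(table.features[held])
            np.testing.assert_allclose(result.merged_scores[held], recomputed, rtol=1e-9, atol=1e-9)

    def test_bit_identical_reruns(self, small_experiment):
        table, _ = small_experiment
        r1 = quiet_brew(table, TrainConfig(seed=6))
        r2 = quiet_brew(table, TrainConfig(seed=6))
        assert np.array_equal(r1.merged_scores, r2.merged_scores)
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)
        for m1, m2 in zip(r1.fold_models, r2.fold_models):
            assert np.array_equal(m1.weights, m2.weights)
            assert m1.intercept == m2.intercept

    def test_feature_scale_invariance(self, small_experiment):
        table, _ = small_experiment
        scaled = PsmTable(
            spec_id=table.spec_id,
            is_target=table.is_target,
            scan_nr=table.scan_nr,
            features=table.features * np.where(np.arange(table.features.shape[1]) == 0, 1000.0, 1.0),
            peptide=table.peptide,
            proteins=table.proteins,
            rank=table.rank,
        )
        q1 = quiet_brew(table, TrainConfig(seed=7)).confidence.psm_table["qvalue"]
        q2 = quiet_brew(scaled, TrainConfig(seed=7)).confidence.psm_table["qvalue"]
        np.testing.assert_allclose(q1, q2, rtol=1e-9)

    def test_improves_on_initial_direction(self, small_experiment):
        table, truth = small_experiment
        result = quiet_brew(table, TrainConfig(seed=8))
        brewed = count_accepted(result.confidence, 0.01, "psm")
        j, sign, _ = choose_initial_direction(table, 0.01)
        q0 = tdc_qvalues(sign * table.feature_matrix[:, j], table.is_target)
        assert brewed >= (q0 <= 0.01).sum()

    def test_fold_without_decoys_rejected(self):
        feats = np.arange(12, dtype=float).reshape(-1, 1)
        table = make_table(feats, [T] * 10 + [D] * 2)
        with pytest.raises(RescoreError, match="fold"):
            quiet_brew(table, TrainConfig(seed=1, folds=3, min_positives=1))

    def test_small_dataset_warning(self, tiny_experiment):
        table, _ = tiny_experiment
        with pytest.warns(SmallExperimentWarning):
            brew(table, TrainConfig(seed=9))


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(train_fdr=0.0), dict(train_fdr=1.0), dict(folds=1), dict(max_iter=0)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
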