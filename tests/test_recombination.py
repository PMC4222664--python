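"""Model combination, discriminant remixing, and NNLS reweighting."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import repgeom as rg

from conftest import spawn_seeds


def _models(n_models, n_stimuli=24, n_features=40, entropy=91):
    seeds = spawn_seeds(entropy, n_models, n=n_models)
    return [
        rg.generate_model_features(
            rg.SyntheticSpec(n_stimuli=n_stimuli, n_features=n_features, seed=s),
            f"m{k}")
        for k, s in enumerate(seeds)
    ]


def _normalized(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    return Xc / np.linalg.norm(Xc, axis=1, keepdims=True)


class TestCombineModels:
    def test_width_is_pcs_times_models(self):
        models = _models(4, n_stimuli=24, n_features=30)
        combi = rg.combine_models(models, n_pcs=20)
        assert combi.n_features == 80

    def test_single_model_rdm_matches_pc_projection(self):
        (m,) = _models(1, n_stimuli=24, n_features=30)
        combi = rg.combine_models([m], n_pcs=15)
        from sklearn.decomposition import PCA

        scores = PCA(n_components=15, svd_solver="full").fit_transform(m.values)
        r1 = rg.compute_rdm(combi)
        r2 = rg.compute_rdm(rg.FeatureMatrix(m.stimulus_ids, scores))
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-8)

    def test_blocks_contribute_equal_variance(self):
        models = _models(3, n_stimuli=24, n_features=50)
        combi = rg.combine_models(models, n_pcs=10)
        variances = [
            combi.values[:, k * 10:(k + 1) * 10].var(axis=0, ddof=1).sum()
            for k in range(3)
        ]
        assert np.ptp(variances) < 1e-8

    def test_n_pcs_exceeding_rank_errors(self):
        models = _models(1, n_stimuli=16, n_features=30)
        with pytest.raises(ValueError, match="non-zero covariance eigenvalues"):
            rg.combine_models(models, n_pcs=20)


class TestTrainDiscriminant:
    def _clusters(self, seed, n_train=60, n_test=20, gap=6.0):
        rng = np.random.default_rng(seed)
        y_train = np.repeat([0, 1], n_train // 2)
        X_train = rng.standard_normal((n_train, 5))
        X_train[y_train == 1, 0] += gap
        y_test = np.repeat([0, 1], n_test // 2)
        X_test = rng.standard_normal((n_test, 5))
        X_test[y_test == 1, 0] += gap
        train = rg.FeatureMatrix(tuple(f"tr{i}" for i in range(n_train)), X_train)
        test = rg.FeatureMatrix(tuple(f"te{i}" for i in range(n_test)), X_test)
        return train, y_train, test, y_test

    def test_separable_clusters_get_correct_signs(self):
        train, y_train, test, y_test = self._clusters(0)
        dv = rg.train_discriminant(train, y_train, test)
        assert dv.n_features == 1
        acc = np.mean((dv.values[:, 0] > 0).astype(int) == y_test)
        assert acc >= 0.95

    def test_duplicated_training_points_leave_decision_unchanged(self):
        train, y_train, test, _ = self._clusters(1)
        dv1 = rg.train_discriminant(train, y_train, test)
        dbl = rg.FeatureMatrix(
            tuple(f"tr{i}" for i in range(2 * train.n_stimuli)),
            np.vstack([train.values, train.values]))
        dv2 = rg.train_discriminant(dbl, np.concatenate([y_train, y_train]), test)
        np.testing.assert_allclose(dv1.values, dv2.values, atol=1e-6)

    def test_overlapping_ids_rejected(self):
        train, y_train, test, _ = self._clusters(2)
        leaky = rg.FeatureMatrix(train.stimulus_ids[:test.n_stimuli], test.values)
        with pytest.raises(ValueError, match="overlap"):
            rg.train_discriminant(train, y_train, leaky)

    def test_single_class_rejected(self):
        train, y_train, test, _ = self._clusters(3)
        with pytest.raises(ValueError, match="single class"):
            rg.train_discriminant(train, np.zeros_like(y_train), test)

    def test_three_discriminants_yield_three_single_feature_rdms(self):
        train, y_train, test, _ = self._clusters(4)
        rdms = []
        for task in range(3):
            y = np.roll(y_train, task * 7)
            dv = rg.train_discriminant(train, y, test, name=f"disc{task}")
            rdms.append(rg.compute_rdm(dv, "sqeuclidean_normalized"))
        assert len(rdms) == 3
        for r in rdms:
            assert r.n_stimuli == test.n_stimuli


class TestWeightedCombinationIdentity:
    def test_weighted_feature_rdm_equals_weighted_rdm_sum(self):
        models = _models(3)
        cs = rg.ComponentSet.from_items([(m.model_name, m) for m in models])
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = rng.uniform(0.0, 2.0, 3)
            concat = np.hstack([np.sqrt(w[k]) * _normalized(models[k].values)
                                for k in range(3)])
            direct = squareform(pdist(concat, "sqeuclidean"))
            mix = rg.mixture_rdm(cs, w)
            assert np.abs(direct - mix.values).max() < 1e-8


class TestNnlsWeights:
    def test_exact_member_gets_unit_weight(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(3, entropy=92)])
        ref = cs.rdms[1]
        w = rg.nnls_weights(cs, ref)
        np.testing.assert_allclose(w.w, [0.0, 1.0, 0.0], atol=1e-8)

    def test_two_component_mixture_recovered(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(2, entropy=93)])
        ref = rg.mixture_rdm(cs, np.array([0.3, 0.7]))
        w = rg.nnls_weights(cs, ref)
        np.testing.assert_allclose(w.w, [0.3, 0.7], atol=1e-6)

    def test_kkt_conditions_hold_at_solution(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(3, entropy=94)])
        rng = np.random.default_rng(11)
        ref = rg.generate_mixture(cs, np.array([1.0, 0.5, 0.0]),
                                  cell_noise_sd=0.2, seed=12)
        w = rg.nnls_weights(cs, ref).w
        X, _ = cs.design_matrix()
        resid = ref.vectorize().values - X @ w
        grad = X.T @ resid  # positive gradient would mean w_k should grow
        for k in range(3):
            if w[k] > 0:
                assert abs(grad[k]) < 1e-6  # active components at stationarity
            else:
                assert grad[k] <= 1e-6  # inactive only if increase cannot help

    def test_objective_beats_naive_weightings(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(4, entropy=95)])
        rng = np.random.default_rng(6)
        ref = rg.generate_mixture(cs, rng.uniform(0, 1, 4), cell_noise_sd=0.05,
                                  seed=7)
        X, mask = cs.design_matrix()
        y = ref.vectorize().values
        w = rg.nnls_weights(cs, ref).w

        def sse(weights):
            return float(np.sum((y - X @ weights) ** 2))

        assert sse(w) <= sse(np.ones(4)) + 1e-10
        for k in range(4):
            one_hot = np.zeros(4)
            one_hot[k] = 1.0
            assert sse(w) <= sse(one_hot) + 1e-10


class TestCrossValidatedReweighting:
    def test_single_component_reference_reassembled_exactly(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(1, entropy=96)])
        strata = rg.default_stimulus_set(24).members("animate").astype(int)
        cv = rg.CrossValidatedReweighting(holdout_size=4, seed=8).fit(
            cs, cs.rdms[0], strata)
        np.testing.assert_allclose(cv.rdm_.values, cs.rdms[0].values, atol=1e-8)

    def test_each_fold_predicts_choose2_cells(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(2, entropy=97)])
        strata = rg.default_stimulus_set(24).members("animate").astype(int)
        cv = rg.CrossValidatedReweighting(holdout_size=8, seed=9).fit(
            cs, cs.rdms[0], strata)
        # 8 held-out stimuli -> 8*7/2 = 28 predicted cells per fold
        assert int(cv.coverage_counts_.sum()) == 28 * cv.n_folds_

    def test_coverage_failure_reports(self):
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(1, entropy=98)])
        strata = rg.default_stimulus_set(24).members("animate").astype(int)
        with pytest.raises(RuntimeError, match="coverage"):
            rg.CrossValidatedReweighting(holdout_size=4, max_folds=2,
                                         seed=10).fit(cs, cs.rdms[0], strata)

    def test_assembled_rdm_beats_components_on_noisy_mixture(self):
        seeds = spawn_seeds(99, n=4)
        cs = rg.ComponentSet.from_items(
            [(m.model_name, m) for m in _models(4, entropy=seeds[0])])
        rng = np.random.default_rng(seeds[1])
        w = rng.uniform(0.2, 1.0, 4)
        truth = rg.generate_mixture(cs, w)
        sd = truth.vectorize().valid_values.std()
        ref = rg.generate_mixture(cs, w, cell_noise_sd=0.1 * sd, seed=seeds[2])
        strata = rg.default_stimulus_set(24).members("animate").astype(int)
        cv = rg.CrossValidatedReweighting(holdout_size=4, seed=seeds[3]).fit(
            cs, ref, strata)
        t_asm = rg.rdm_correlation(cv.rdm_, truth)
        t_best = max(rg.rdm_correlation(r, truth) for r in cs.rdms)
        assert t_asm > t_best
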