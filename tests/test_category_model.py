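"""Category-cluster predictors, the categoricality index, and noise equating."""

import numpy as np
import pytest

import repgeom as rg
from repgeom.category_model import build_category_model

from conftest import spawn_seeds


def _block_rdm(stimuli, within=0.4, between=1.0):
    """Two-cluster RDM: animate/animate and inanimate/inanimate pairs close,
    cross pairs far."""
    animate = stimuli.members("animate")
    n = len(stimuli)
    d = np.where(animate[:, None] == animate[None, :], within, between)
    np.fill_diagonal(d, 0.0)
    return rg.RDM(stimuli.ids, d)


class TestBuildCategoryModel:
    def test_ten_predictors_plus_constant(self, stimuli48):
        model = build_category_model(stimuli48)
        assert model.n_predictors == 11
        assert model.names[-1] == "constant"
        assert np.all(model.design[:, -1] == 1.0)

    def test_within_pair_counts(self, stimuli48):
        model = build_category_model(stimuli48)
        for j, name in enumerate(rg.CATEGORY_NAMES):
            k = int(stimuli48.members(name).sum())
            assert int((model.design[:, j] == -1.0).sum()) == k * (k - 1) // 2

    def test_animate_inanimate_predictors_disjoint(self, stimuli48):
        model = build_category_model(stimuli48)
        a = model.design[:, list(rg.CATEGORY_NAMES).index("animate")] != 0
        i = model.design[:, list(rg.CATEGORY_NAMES).index("inanimate")] != 0
        assert not np.any(a & i)

    def test_empty_category_errors(self):
        stim = rg.default_stimulus_set(16)
        sub = stim.subset(~stim.members("human_face"))
        with pytest.raises(ValueError, match="human_face"):
            build_category_model(sub)


class TestCategoryFit:
    def test_exact_linear_combination_recovered(self, stimuli48):
        model = build_category_model(stimuli48)
        beta_true = np.array([0.5, 0.2, 0.3, 0, 0, 0.1, 0, 0, 0, 0, 1.5])
        vec = model.design @ beta_true
        r = rg.RDM.from_vector(stimuli48.ids, vec)
        fit = rg.fit_category_model(r, stimuli48)
        assert fit.cci_ == pytest.approx(1.0, abs=1e-10)
        resid = fit.residual_rdm_.vectorize().valid_values
        assert np.abs(resid).max() < 1e-10

    def test_noise_rdm_has_near_zero_cci(self):
        ccis = []
        stim = rg.default_stimulus_set(96)
        for seed in spawn_seeds(71, n=50):
            r = np.random.default_rng(seed)
            d = r.random((96, 96))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ccis.append(rg.categoricality_index(rg.RDM(stim.ids, d), stim))
        assert np.mean(ccis) < 0.05

    def test_block_design_loads_animacy_not_subcategories(self, stimuli48):
        fit = rg.fit_category_model(_block_rdm(stimuli48), stimuli48)
        betas = dict(zip(fit.predictor_names_, fit.coef_))
        assert betas["animate"] > 0.1 and betas["inanimate"] > 0.1
        assert abs(betas["human_face"]) < 1e-8
        assert abs(betas["nonhuman_face"]) < 1e-8

    def test_residuals_orthogonal_to_design(self, stimuli48):
        seeds = spawn_seeds(72, n=1)
        spec = rg.SyntheticSpec(n_stimuli=48, n_features=40,
                                tightness={"animate": 1.0}, seed=seeds[0])
        r = rg.compute_rdm(rg.generate_model_features(spec))
        fit = rg.fit_category_model(r, stimuli48)
        model = build_category_model(stimuli48)
        resid = fit.residual_rdm_.vectorize()
        dots = model.design[resid.mask].T @ resid.values[resid.mask]
        assert np.abs(dots).max() < 1e-8

    def test_fitted_plus_residual_equals_observed(self, stimuli48):
        r = _block_rdm(stimuli48)
        fit = rg.fit_category_model(r, stimuli48)
        total = fit.fitted_rdm_.values + fit.residual_rdm_.values
        np.testing.assert_allclose(total, r.values, atol=1e-10)

    def test_cci_bounded(self, stimuli16, rng):
        d = rng.random((16, 16))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        cci = rg.categoricality_index(rg.RDM(stimuli16.ids, d), stimuli16)
        assert 0.0 <= cci <= 1.0


class TestCategoricalityTest:
    def test_blocked_rdm_maximally_significant(self, stimuli48):
        res = rg.categoricality_test(_block_rdm(stimuli48), stimuli48,
                                     n_rand=200, seed=1)
        assert res.p_value == pytest.approx(1.0 / 201.0)

    def test_label_independent_rdm_calibrated(self):
        stim = rg.default_stimulus_set(16)
        ps = []
        for seed in spawn_seeds(73, n=40):
            r = np.random.default_rng(seed)
            d = r.random((16, 16))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ps.append(rg.categoricality_test(rg.RDM(stim.ids, d), stim,
                                             n_rand=99, seed=seed).p_value)
        # roughly uniform: mean near 0.5, some spread
        assert 0.3 < np.mean(ps) < 0.7

    def test_label_permutation_preserves_hierarchy(self, stimuli48, rng):
        perm = rng.permutation(48)
        permuted = stimuli48.permuted(perm)  # would raise if invariants broke
        assert permuted.members("animate").sum() == 24


class TestClusteringStrengthCI:
    def test_blocked_categories_exclude_zero(self, stimuli48):
        out = rg.clustering_strength_ci(_block_rdm(stimuli48), stimuli48,
                                        n_boot=200, seed=2)
        assert out["categories"]["animate"]["ci_low"] > 0
        assert out["categories"]["inanimate"]["ci_low"] > 0

    def test_ci_width_shrinks_with_stimulus_count(self):
        widths = []
        for n in (16, 48):
            stim = rg.default_stimulus_set(n)
            seeds = spawn_seeds(74, n, n=1)
            spec = rg.SyntheticSpec(n_stimuli=n, n_features=40,
                                    tightness={"animate": 1.0}, seed=seeds[0])
            r = rg.compute_rdm(rg.generate_model_features(spec))
            out = rg.clustering_strength_ci(r, stim, n_boot=200, seed=3)
            c = out["categories"]["animate"]
            widths.append(c["ci_high"] - c["ci_low"])
        assert widths[1] < widths[0]


class TestNoiseEquating:
    def test_target_one_returns_noiseless_rdm(self, features16):
        eq = rg.NoiseEquating(target_q=1.0, seed=0).fit(features16)
        assert eq.alpha_ == 0.0
        noiseless = rg.compute_rdm(features16)
        np.testing.assert_allclose(eq.rdm_.values, noiseless.values, atol=1e-12)

    @pytest.mark.parametrize("target", [0.3, 0.6, 0.85])
    def test_achieved_q_within_tolerance(self, features16, target):
        eq = rg.NoiseEquating(target_q=target, tol=0.01, seed=1).fit(features16)
        assert abs(eq.achieved_q_ - target) <= 0.01

    def test_q_decreases_with_alpha(self, features16):
        eq = rg.NoiseEquating(target_q=0.5, seed=2).fit(features16)
        # reuse the fitted instantiation machinery indirectly: lower target
        # must need more noise
        eq_low = rg.NoiseEquating(target_q=0.3, seed=2).fit(features16)
        assert eq_low.alpha_ > eq.alpha_

    def test_equated_fit_loses_categoricality(self, stimuli48):
        # statistical property, so average over several generator seeds
        diffs = []
        for seed in spawn_seeds(75, n=5):
            spec = rg.SyntheticSpec(n_stimuli=48, n_features=40,
                                    tightness={"animate": 1.5}, seed=seed)
            fm = rg.generate_model_features(spec)
            noiseless = rg.categoricality_index(rg.compute_rdm(fm), stimuli48)
            noisy_rdm = rg.equate_noise(fm, target_q=0.3, seed=seed)
            diffs.append(noiseless - rg.categoricality_index(noisy_rdm, stimuli48))
        assert np.mean(diffs) > 0

    def test_invalid_target_errors(self, features16):
        with pytest.raises(ValueError):
            rg.NoiseEquating(target_q=1.5).fit(features16)
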