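"""Whole-genome regression samplers: design building, fitting, GEBVs, h2."""

import numpy as np
import pandas as pd
import pytest

from merinogp.containers import GRM
from merinogp.grm import allele_freqs, center_dosages, vanraden_grm
from merinogp.models import (
    FitResult,
    McmcSettings,
    PriorSpec,
    build_design,
    fit,
    gebv,
    heritability,
)

FAST = McmcSettings(n_iter=600, burn_in=200, thin=2, seed=3)


def pheno_frame(herds, sexes):
    n = len(herds)
    return pd.DataFrame(
        {"id": [f"i{k}" for k in range(n)], "herd": herds, "sex": sexes,
         "trait1": np.arange(n, dtype=float)}
    )


class TestBuildDesign:
    def test_two_herds_two_sexes(self):
        df = pheno_frame(["h1", "h1", "h2", "h2"], ["F", "M", "F", "M"])
        design = build_design(df)
        assert design.matrix.shape == (4, 3)
        assert design.coefficient_names == ["intercept", "herd[h2]", "sex[M]"]

    def test_single_level_factor_collapses(self):
        df = pheno_frame(["h1", "h1", "h1"], ["F", "M", "F"])
        design = build_design(df)
        assert design.coefficient_names == ["intercept", "sex[M]"]

    def test_unknown_label_rejected_when_levels_fixed(self):
        df = pheno_frame(["h1", "h2"], ["F", "X"])
        with pytest.raises(ValueError, match="unknown sex"):
            build_design(df, levels={"herd": ["h1", "h2"], "sex": ["F", "M"]})

    def test_unseen_label_maps_to_reference(self):
        df = pheno_frame(["h1", "h2", "h3"], ["F", "M", "F"])
        design = build_design(
            df, levels={"herd": ["h1", "h2"], "sex": ["F", "M"]}, unseen="reference"
        )
        # h3 treated as the h1 reference: its herd[h2] dummy is zero
        col = design.coefficient_names.index("herd[h2]")
        assert design.matrix[2, col] == 0.0
        assert design.matrix[1, col] == 1.0

    def test_confounded_factor_column_dropped(self):
        df = pheno_frame(["h1", "h1", "h2", "h2"], ["F", "F", "M", "M"])
        design = build_design(df)  # sex completely confounded with herd
        assert design.matrix.shape[1] == 2


class TestSettingsValidation:
    def test_mcmc_invariants(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(thin=0)
        assert McmcSettings(15000, 5000, 5).n_stored == 2000

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec("bayesQ")
        with pytest.raises(ValueError):
            PriorSpec("bayesA", df_marker=2.0)
        with pytest.raises(ValueError):
            PriorSpec("bayesB", pi=1.5)
        assert PriorSpec("bayesB").pi == 0.95
        assert PriorSpec("bayesCpi").estimate_pi is True


class TestFitMechanics:
    @pytest.mark.parametrize("family", ["bayesA", "bayesB", "bayesCpi", "blasso", "ridge"])
    def test_chains_reproducible_and_stored_counts(self, small_dataset, family):
        gm, phenos, _ = small_dataset
        y = phenos["trait1"].to_numpy()
        design = build_design(phenos)
        w = center_dosages(gm.dosages, allele_freqs(gm))
        a = fit(y, design, W=w, prior=PriorSpec(family), mcmc=FAST, debug=True)
        b = fit(y, design, W=w, prior=PriorSpec(family), mcmc=FAST)
        assert a.draws["sigma2_e"].size == FAST.n_stored
        np.testing.assert_array_equal(a.draws["sigma2_e"], b.draws["sigma2_e"])
        np.testing.assert_array_equal(a.alpha_mean, b.alpha_mean)
        assert np.all(a.draws["sigma2_a"] >= 0)
        assert np.all(a.draws["sigma2_e"] > 0)
        if "pi" in a.draws:
            assert np.all((a.draws["pi"] >= 0) & (a.draws["pi"] <= 1))

    def test_gblup_reproducible_with_candidates(self, small_dataset):
        gm, phenos, _ = small_dataset
        y = phenos["trait1"].to_numpy().copy()
        y[:30] = np.nan  # candidate individuals ride inside the sampler
        design = build_design(phenos)
        grm = vanraden_grm(gm)
        a = fit(y, design, G=grm, prior=PriorSpec("gblup"), mcmc=FAST, debug=True)
        b = fit(y, design, G=grm, prior=PriorSpec("gblup"), mcmc=FAST)
        np.testing.assert_array_equal(a.u_mean, b.u_mean)
        assert np.isfinite(a.u_mean).all()
        assert a.individual_ids == grm.individual_ids

    def test_zero_variance_phenotype_rejected(self, small_dataset):
        gm, phenos, _ = small_dataset
        w = center_dosages(gm.dosages, allele_freqs(gm))
        with pytest.raises(ValueError, match="zero variance"):
            fit(np.ones(gm.n_individuals), build_design(phenos), W=w,
                prior=PriorSpec("bayesA"), mcmc=FAST)

    def test_marker_family_requires_w_and_gblup_requires_g(self, small_dataset):
        gm, phenos, _ = small_dataset
        y = phenos["trait1"].to_numpy()
        with pytest.raises(ValueError, match="requires"):
            fit(y, build_design(phenos), prior=PriorSpec("bayesA"), mcmc=FAST)
        with pytest.raises(ValueError, match="requires"):
            fit(y, build_design(phenos), prior=PriorSpec("gblup"), mcmc=FAST)

    def test_marker_order_exchangeable(self, small_dataset):
        """Permuting markers permutes effects and leaves GEBVs equivalent."""
        gm, phenos, _ = small_dataset
        y = phenos["trait1"].to_numpy()
        design = build_design(phenos)
        w = center_dosages(gm.dosages, allele_freqs(gm))
        rng = np.random.default_rng(0)
        perm = rng.permutation(w.shape[1])
        mc = McmcSettings(4000, 1000, 3, seed=5)
        a = fit(y, design, W=w, prior=PriorSpec("ridge"), mcmc=mc)
        b = fit(y, design, W=w[:, perm], prior=PriorSpec("ridge"), mcmc=mc)
        # posterior means agree within Monte Carlo error
        assert np.corrcoef(gebv(a), gebv(b))[0, 1] > 0.98
        assert np.corrcoef(a.alpha_mean[perm], b.alpha_mean)[0, 1] > 0.9


class TestGebv:
    def test_zero_effects_give_zero_gebv(self):
        res = FitResult("bayesA", draws={}, alpha_mean=np.zeros(5))
        out = gebv(res, W_new=np.ones((3, 5)))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_training_w_matches_fitted_values(self, small_dataset):
        gm, phenos, _ = small_dataset
        y = phenos["trait1"].to_numpy()
        w = center_dosages(gm.dosages, allele_freqs(gm))
        res = fit(y, build_design(phenos), W=w, prior=PriorSpec("ridge"), mcmc=FAST)
        np.testing.assert_allclose(gebv(res, W_new=w), res.gebv_mean, atol=1e-8)

    def test_duplicate_rows_identical_predictions(self):
        res = FitResult("bayesA", draws={}, alpha_mean=np.array([1.0, -2.0]))
        w = np.array([[1.0, 0.5], [1.0, 0.5]])
        out = gebv(res, W_new=w)
        assert out[0] == out[1]

    def test_marker_mismatch_rejected(self):
        res = FitResult("bayesA", draws={}, alpha_mean=np.zeros(4))
        with pytest.raises(ValueError, match="marker count"):
            gebv(res, W_new=np.zeros((2, 5)))

    def test_gblup_rejects_new_individuals(self):
        res = FitResult("gblup", draws={}, u_mean=np.zeros(3))
        with pytest.raises(ValueError, match="present in G"):
            gebv(res, W_new=np.zeros((2, 5)))


class TestHeritability:
    def test_ratio_formed_per_draw(self):
        s2a = np.array([2.0, 4.0])
        s2e = np.array([2.0, 1.0])
        res = FitResult("gblup", draws={"sigma2_a": s2a, "sigma2_e": s2e})
        est, sd = heritability(res)
        expected = np.array([0.5, 0.8])
        assert est == pytest.approx(expected.mean())
        assert sd == pytest.approx(expected.std(ddof=1))

    def test_zero_additive_variance(self):
        res = FitResult("gblup", draws={"sigma2_a": np.zeros(5), "sigma2_e": np.ones(5)})
        assert heritability(res) == (0.0, 0.0)

    def test_missing_draws_rejected(self):
        with pytest.raises(ValueError):
            heritability(FitResult("gblup", draws={}))


class TestSparsityRecovery:
    def test_bayescpi_estimates_qtl_proportion(self):
        """With 1% of markers causal, posterior (1 - pi) lands within a
        factor of three of the simulated proportion."""
        from merinogp.sim import SimConfig, simulate_dataset

        cfg = SimConfig(500, 1000, n_markers_low=100, architecture="point_normal",
                        prop_qtl=0.01, h2_target=0.5, missing_rate=0.0, seed=17)
        gm, phenos, _ = simulate_dataset(cfg)
        w = center_dosages(gm.dosages, allele_freqs(gm))
        res = fit(phenos["trait1"].to_numpy(), build_design(phenos), W=w,
                  prior=PriorSpec("bayesCpi"), mcmc=McmcSettings(4000, 1500, 3, seed=7))
        incl = 1.0 - res.draws["pi"].mean()
        assert 0.01 / 3 < incl < 0.01 * 3
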