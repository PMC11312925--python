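"""Twin variance decomposition: univariate, bivariate, shared heritability."""

import numpy as np
import pandas as pd
import pytest

import glycotwin as gt
from glycotwin.twin import UNIVARIATE_MODELS

from conftest import exact_corr_pairs


def _pairs_with_exact_moments(r_mz, r_dz, n_mz=2000, n_dz=2000, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.vstack([exact_corr_pairs(n_mz, r_mz, rng),
                      exact_corr_pairs(n_dz, r_dz, rng)])
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)
    return gt.TwinPairSet(vals, zyg)


class TestUnivariate:
    def test_falconer_oracle_on_exact_moments(self):
        # sample moments r_MZ=0.7, r_DZ=0.45 -> a2 = 2(0.7-0.45) = 0.5, c2 = 0.2
        pairs = _pairs_with_exact_moments(0.70, 0.45)
        fit = gt.fit_univariate_twin(pairs, "ACE")
        assert fit.a2 == pytest.approx(0.5, abs=0.02)
        assert fit.c2 == pytest.approx(0.2, abs=0.02)
        assert fit.e2 == pytest.approx(0.3, abs=0.02)
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-6)

    def test_no_familial_covariance_yields_zero_a2_c2(self):
        pairs = _pairs_with_exact_moments(0.0, 0.0, 500, 500, seed=1)
        fit = gt.fit_univariate_twin(pairs, "ACE")
        assert fit.a2 == pytest.approx(0.0, abs=0.03)
        assert fit.c2 == pytest.approx(0.0, abs=0.03)

    def test_loglik_nesting(self):
        pairs = _pairs_with_exact_moments(0.6, 0.4, 500, 500, seed=2)
        fits = {m: gt.fit_univariate_twin(pairs, m) for m in UNIVARIATE_MODELS}
        assert fits["ACE"].loglik >= fits["AE"].loglik - 1e-6
        assert fits["AE"].loglik >= fits["E"].loglik - 1e-6
        assert fits["ACE"].loglik >= fits["CE"].loglik - 1e-6
        assert fits["CE"].loglik >= fits["E"].loglik - 1e-6

    def test_invariant_to_twin_order_swap(self):
        pairs = _pairs_with_exact_moments(0.6, 0.4, 300, 300, seed=3)
        swapped = gt.TwinPairSet(pairs.values[:, ::-1], pairs.zygosity)
        f1 = gt.fit_univariate_twin(pairs, "ACE")
        f2 = gt.fit_univariate_twin(swapped, "ACE")
        assert f1.a2 == pytest.approx(f2.a2, abs=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_requires_enough_pairs(self):
        pairs = _pairs_with_exact_moments(0.5, 0.3, 10, 50, seed=4)
        with pytest.raises(ValueError, match="pairs"):
            gt.fit_univariate_twin(pairs, "ACE")

    def test_covariate_adjustment_removes_age_signal(self):
        rng = np.random.default_rng(5)
        pairs = _pairs_with_exact_moments(0.7, 0.45, 1000, 1000, seed=5)
        age = np.repeat(rng.uniform(20, 80, 2000), 2)  # co-twins share age
        vals = pairs.values + 0.05 * age.reshape(-1, 2)
        noisy = gt.TwinPairSet(vals, pairs.zygosity)
        fit = gt.fit_univariate_twin(noisy, "ACE",
                                     covariates=pd.DataFrame({"age": age}))
        assert fit.a2 == pytest.approx(0.5, abs=0.05)
        assert fit.c2 == pytest.approx(0.2, abs=0.05)

    def test_unbiased_h2_over_replicates(self):
        """Median recovered h2 over simulated traits stays near the truth."""
        h2s = []
        for s in range(40):
            pairs = _pairs_with_exact_moments(0.5, 0.25, 500, 500, seed=100 + s)
            # exact moments jittered: redraw with sampling noise
            rng = np.random.default_rng(200 + s)
            vals = pairs.values + 0.01 * rng.standard_normal(pairs.values.shape)
            fit = gt.fit_univariate_twin(gt.TwinPairSet(vals, pairs.zygosity), "AE")
            h2s.append(fit.a2)
        assert abs(np.median(h2s) - 0.5) < 0.02


class TestModelSelection:
    def test_aic_tie_prefers_fewer_parameters(self):
        pairs = _pairs_with_exact_moments(0.6, 0.3, 200, 200, seed=6)
        ace = gt.fit_univariate_twin(pairs, "ACE")
        ae = gt.fit_univariate_twin(pairs, "AE")
        ace.aic = ae.aic  # force an exact tie
        assert gt.select_model([ace, ae]).model == "AE"

    def test_pure_environment_selects_e(self):
        pairs = _pairs_with_exact_moments(0.0, 0.0, 1000, 1000, seed=7)
        fits = [gt.fit_univariate_twin(pairs, m) for m in UNIVARIATE_MODELS]
        assert gt.select_model(fits).model == "E"

    def test_nonconverged_excluded_with_warning(self):
        pairs = _pairs_with_exact_moments(0.6, 0.3, 200, 200, seed=8)
        good = gt.fit_univariate_twin(pairs, "AE")
        bad = gt.fit_univariate_twin(pairs, "ACE")
        bad.converged = False
        bad.aic = -np.inf
        with pytest.warns(UserWarning, match="converged"):
            assert gt.select_model([bad, good]).model == "AE"


class TestBivariate:
    def test_recovers_cross_trait_structure(self):
        design = gt.CohortDesign(n_mz_pairs=1500, n_dz_pairs=1500,
                                 n_singletons=0, seed=9)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                    gt.TraitModel(0.5, 0, 0.5),
                                    rho_g=0.6, rho_e=0.2)
        ph = gt.simulate_bivariate_traits(design, bm, seed=10)
        pairs = gt.TwinPairSet.from_tables(ph, gt.build_sample_sheet(design),
                                           ["trait_x", "trait_y"])
        fit = gt.fit_bivariate_twin(pairs)
        assert fit.rho_g == pytest.approx(0.6, abs=0.1)
        assert fit.rho_e == pytest.approx(0.2, abs=0.1)
        assert fit.h2_x == pytest.approx(0.5, abs=0.07)
        assert fit.h2_y == pytest.approx(0.5, abs=0.07)
        assert fit.p_rho_g < 1e-6

    def test_identical_trait_is_degenerate_unit_correlations(self):
        pairs = _pairs_with_exact_moments(0.7, 0.45, 200, 200, seed=11)
        vals = np.stack([pairs.values, pairs.values], axis=2)
        fit = gt.fit_bivariate_twin(gt.TwinPairSet(vals, pairs.zygosity))
        assert fit.degenerate
        assert fit.rho_g == fit.rho_e == fit.rho_p == 1.0

    def test_marginal_matches_univariate_under_independence(self):
        design = gt.CohortDesign(n_mz_pairs=400, n_dz_pairs=400,
                                 n_singletons=0, seed=12)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                    gt.TraitModel(0.4, 0, 0.6),
                                    rho_g=0.0, rho_e=0.0)
        ph = gt.simulate_bivariate_traits(design, bm, seed=13)
        pairs = gt.TwinPairSet.from_tables(ph, gt.build_sample_sheet(design),
                                           ["trait_x", "trait_y"])
        biv = gt.fit_bivariate_twin(pairs, constrain="independent")
        uni = gt.fit_univariate_twin(
            gt.TwinPairSet(pairs.values[:, :, 0], pairs.zygosity), "AE")
        assert biv.h2_x == pytest.approx(uni.a2, abs=1e-3)

    def test_estimator_wrapper(self):
        design = gt.CohortDesign(n_mz_pairs=200, n_dz_pairs=200,
                                 n_singletons=0, seed=14)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                    gt.TraitModel(0.5, 0, 0.5),
                                    rho_g=0.5, rho_e=0.0)
        ph = gt.simulate_bivariate_traits(design, bm, seed=15)
        pairs = gt.TwinPairSet.from_tables(ph, gt.build_sample_sheet(design),
                                           ["trait_x", "trait_y"])
        est = gt.BivariateTwinModel(lrt=False).fit(pairs.values,
                                                   zygosity=pairs.zygosity)
        assert 0 <= est.h2_x_ <= 1
        assert -1 <= est.rho_g_ <= 1


class TestSharedHeritability:
    def test_pure_genetic_covariance(self):
        sh = gt.shared_heritability(1.0, 0.0, 0.5, 0.5, p_rho_g=0.001,
                                    p_rho_e=0.001)
        assert sh.cov_g == pytest.approx(0.5)
        assert sh.cov_e == 0.0
        assert sh.h2_xy == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        sh = gt.shared_heritability(0.8, 0.2, 0.5, 0.5, p_rho_g=0.01,
                                    p_rho_e=0.01)
        assert sh.cov_g == pytest.approx(0.4)
        assert sh.cov_e == pytest.approx(0.1)
        assert sh.h2_xy == pytest.approx(0.8)

    def test_nonsignificant_rho_g_zeroed(self):
        sh = gt.shared_heritability(0.8, 0.2, 0.5, 0.5, p_rho_g=0.2,
                                    p_rho_e=0.01)
        assert sh.cov_g == 0.0 and sh.constrained_g
        assert sh.h2_xy == 0.0

    def test_boundary_p_value_is_kept(self):
        # zeroed only when p is strictly larger than alpha
        sh = gt.shared_heritability(0.8, 0.0, 0.5, 0.5, p_rho_g=0.05,
                                    p_rho_e=0.01)
        assert sh.cov_g == pytest.approx(0.4)

    def test_zero_total_covariance_flagged_undefined(self):
        sh = gt.shared_heritability(0.0, 0.0, 0.5, 0.5)
        assert sh.h2_xy is None

    def test_opposite_signs_flagged(self):
        sh = gt.shared_heritability(0.5, -0.5, 0.5, 0.5)
        assert sh.out_of_range

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gt.shared_heritability(0.5, 0.0, 1.5, 0.5)
        with pytest.raises(ValueError):
            gt.shared_heritability(1.5, 0.0, 0.5, 0.5)


@pytest.fixture(scope="module")
def shared_snp_cohort():
    design = gt.CohortDesign(n_mz_pairs=800, n_dz_pairs=800,
                             n_singletons=0, seed=16)
    geno = gt.simulate_genotypes(design, n_snp=20, seed=17)
    beta = np.sqrt(0.2)
    # the shared SNP carries ALL the genetic covariance:
    # rho_g target = beta^2 / sqrt(a2_x a2_y) = 0.2 / 0.5 = 0.4
    bm = gt.BivariateTraitModel(
        gt.TraitModel(0.5, 0, 0.5, snp_effects=[(3, beta)]),
        gt.TraitModel(0.5, 0, 0.5, snp_effects=[(3, beta)]),
        rho_g=0.4, rho_e=0.0)
    ph = gt.simulate_bivariate_traits(design, bm, genotypes=geno, seed=18)
    return design, geno, ph


class TestConditionalCovariance:
    def test_direct_formula(self):
        # Cov_G = A_x * A_y * rhoG with A = sqrt(h2)
        sh = gt.shared_heritability(0.5, 0.0, 0.49, 0.49, p_rho_g=0.01)
        assert sh.cov_g == pytest.approx(0.7 * 0.7 * 0.5)

    def test_conditioning_on_shared_causal_snp_removes_cov_g(self, shared_snp_cohort):
        design, geno, ph = shared_snp_cohort
        samples = gt.build_sample_sheet(design)
        dos = geno.dosage_of("snp00003")
        resid = ph.copy()
        for c in ("trait_x", "trait_y"):
            r = ph[c] - np.polyval(np.polyfit(dos, ph[c], 1), dos)
            resid[c] = (r - r.mean()) / r.std()
        pairs0 = gt.TwinPairSet.from_tables(ph, samples, ["trait_x", "trait_y"])
        base = gt.conditional_genetic_covariance(pairs0)
        pairs1 = gt.TwinPairSet.from_tables(resid, samples,
                                            ["trait_x", "trait_y"])
        cond = gt.conditional_genetic_covariance(pairs1,
                                                 baseline_cov_g=base["cov_g"])
        assert base["cov_g"] == pytest.approx(0.2, abs=0.05)
        assert cond["cov_g"] == pytest.approx(0.0, abs=0.05)
        assert cond["proportion_removed"] > 0.7

    def test_conditioning_on_null_snp_changes_nothing(self, shared_snp_cohort):
        design, geno, ph = shared_snp_cohort
        samples = gt.build_sample_sheet(design)
        dos = geno.dosage_of("snp00015")  # not causal
        resid = ph.copy()
        for c in ("trait_x", "trait_y"):
            r = ph[c] - np.polyval(np.polyfit(dos, ph[c], 1), dos)
            resid[c] = (r - r.mean()) / r.std()
        pairs0 = gt.TwinPairSet.from_tables(ph, samples, ["trait_x", "trait_y"])
        base = gt.conditional_genetic_covariance(pairs0)
        pairs1 = gt.TwinPairSet.from_tables(resid, samples,
                                            ["trait_x", "trait_y"])
        cond = gt.conditional_genetic_covariance(pairs1)
        assert cond["cov_g"] == pytest.approx(base["cov_g"], abs=0.05)
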