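"""Synthetic-cohort generator: genotypes, traits, glycoform panels."""

import numpy as np
import pandas as pd
import pytest

import glycotwin as gt


class TestSampleSheet:
    def test_counts_and_structure(self, small_design):
        samples = gt.build_sample_sheet(small_design)
        assert len(samples) == small_design.n_individuals
        zyg = samples.groupby("family_id")["zygosity"].first()
        assert (zyg == "MZ").sum() == small_design.n_mz_pairs
        # co-twins share family, age; MZ co-twins share sex
        for _, grp in samples[samples["zygosity"] == "MZ"].groupby("family_id"):
            assert grp["age"].nunique() == 1
            assert grp["sex"].nunique() == 1

    def test_plates_round_robin_by_family(self, small_design):
        samples = gt.build_sample_sheet(small_design)
        per_fam = samples.groupby("family_id")["plate"].nunique()
        assert (per_fam == 1).all()
        assert samples["plate"].nunique() == small_design.n_plates

    def test_design_validation(self):
        with pytest.raises(ValueError):
            gt.CohortDesign(n_mz_pairs=-1)
        with pytest.raises(ValueError):
            gt.CohortDesign(age_range=(80, 20))
        with pytest.raises(ValueError):
            gt.CohortDesign(sex_fraction_female=1.4)


class TestGenotypes:
    def test_mz_pairs_identical(self, small_cohort):
        samples, geno, _ = small_cohort
        pos = {i: k for k, i in enumerate(geno.individuals)}
        for _, grp in samples[samples["zygosity"] == "MZ"].groupby("family_id"):
            a, b = [pos[i] for i in grp["individual_id"]]
            assert np.array_equal(geno.dosages[a], geno.dosages[b])

    def test_dz_within_pair_correlation_half(self):
        design = gt.CohortDesign(n_mz_pairs=0, n_dz_pairs=500, n_singletons=0,
                                 seed=1)
        geno = gt.simulate_genotypes(design, 1000, maf_range=(0.3, 0.3), seed=2)
        d = geno.dosages.reshape(500, 2, 1000).astype(float)
        cors = [np.corrcoef(d[i, 0], d[i, 1])[0, 1] for i in range(500)]
        assert np.mean(cors) == pytest.approx(0.5, abs=0.05)

    def test_recomputed_maf_near_target(self):
        design = gt.CohortDesign(n_mz_pairs=0, n_dz_pairs=0,
                                 n_singletons=2000, seed=3)
        geno = gt.simulate_genotypes(design, 200, maf_range=(0.2, 0.2), seed=4)
        assert np.abs(geno.maf - 0.2).max() < 0.05

    def test_invalid_maf_bounds(self, small_design):
        with pytest.raises(ValueError, match="maf_range"):
            gt.simulate_genotypes(small_design, 10, maf_range=(0.6, 0.7))
        with pytest.raises(ValueError, match="maf_range"):
            gt.simulate_genotypes(small_design, 10, maf_range=(0.0, 0.1))

    def test_zero_individuals_rejected(self):
        empty = gt.CohortDesign(n_mz_pairs=0, n_dz_pairs=0, n_singletons=0)
        with pytest.raises(ValueError, match="zero individuals"):
            gt.simulate_genotypes(empty, 10)

    def test_determinism(self, small_design):
        g1 = gt.simulate_genotypes(small_design, 50, seed=5)
        g2 = gt.simulate_genotypes(small_design, 50, seed=5)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestTwinTraits:
    def test_no_familial_component_no_twin_correlation(self):
        design = gt.CohortDesign(n_mz_pairs=1000, n_dz_pairs=1000,
                                 n_singletons=0, seed=6)
        ph = gt.simulate_twin_traits(design, gt.TraitModel(0.0, 0.0, 1.0),
                                     seed=7)
        pairs = gt.TwinPairSet.from_tables(ph[["value"]],
                                           gt.build_sample_sheet(design),
                                           "value")
        for z in ("MZ", "DZ"):
            v = pairs.values[pairs.zygosity == z]
            assert abs(np.corrcoef(v[:, 0], v[:, 1])[0, 1]) < 0.05

    def test_twin_correlations_match_ace_expectation(self):
        design = gt.CohortDesign(n_mz_pairs=2000, n_dz_pairs=2000,
                                 n_singletons=0, seed=8)
        ph = gt.simulate_twin_traits(design, gt.TraitModel(0.6, 0.2, 0.2),
                                     seed=9)
        pairs = gt.TwinPairSet.from_tables(ph[["value"]],
                                           gt.build_sample_sheet(design),
                                           "value")
        v_mz = pairs.values[pairs.zygosity == "MZ"]
        v_dz = pairs.values[pairs.zygosity == "DZ"]
        assert np.corrcoef(v_mz[:, 0], v_mz[:, 1])[0, 1] == pytest.approx(0.8, abs=0.03)
        assert np.corrcoef(v_dz[:, 0], v_dz[:, 1])[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_realized_variance_decomposition(self):
        design = gt.CohortDesign(n_mz_pairs=1000, n_dz_pairs=1000,
                                 n_singletons=0, seed=10)
        ph = gt.simulate_twin_traits(design, gt.TraitModel(0.5, 0.2, 0.3),
                                     seed=11)
        assert ph["genetic"].var() == pytest.approx(0.5, abs=0.05)
        assert ph["shared_env"].var() == pytest.approx(0.2, abs=0.03)
        assert ph["unique_env"].var() == pytest.approx(0.3, abs=0.03)

    def test_determinism(self, small_design):
        m = gt.TraitModel(0.5, 0.2, 0.3)
        t1 = gt.simulate_twin_traits(small_design, m, seed=12)
        t2 = gt.simulate_twin_traits(small_design, m, seed=12)
        pd.testing.assert_frame_equal(t1, t2)

    def test_snp_effects_need_genotypes_and_valid_index(self, small_cohort):
        _, geno, _ = small_cohort
        design = gt.CohortDesign(n_mz_pairs=60, n_dz_pairs=60,
                                 n_singletons=20, n_plates=5, seed=42)
        model = gt.TraitModel(0.5, 0.2, 0.3, snp_effects=[(10_000, 0.1)])
        with pytest.raises(IndexError, match="outside"):
            gt.simulate_twin_traits(design, model, genotypes=geno)
        with pytest.raises(ValueError, match="no genotypes"):
            gt.simulate_twin_traits(design,
                                    gt.TraitModel(0.5, 0.2, 0.3,
                                                  snp_effects=[(1, 0.1)]))

    def test_excess_snp_variance_rejected(self, small_cohort):
        _, geno, _ = small_cohort
        design = gt.CohortDesign(n_mz_pairs=60, n_dz_pairs=60,
                                 n_singletons=20, n_plates=5, seed=42)
        model = gt.TraitModel(0.1, 0.4, 0.5, snp_effects=[(0, 0.9)])
        with pytest.raises(ValueError, match="more additive variance"):
            gt.simulate_twin_traits(design, model, genotypes=geno)

    def test_invalid_variance_shares(self):
        with pytest.raises(ValueError):
            gt.TraitModel(0.5, 0.2, 0.4)
        with pytest.raises(ValueError):
            gt.TraitModel(-0.1, 0.4, 0.7)


class TestBivariateTraits:
    def test_independent_traits_uncorrelated(self):
        design = gt.CohortDesign(n_mz_pairs=1000, n_dz_pairs=1000,
                                 n_singletons=0, seed=13)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                    gt.TraitModel(0.5, 0, 0.5),
                                    rho_g=0.0, rho_e=0.0)
        ph = gt.simulate_bivariate_traits(design, bm, seed=14)
        assert abs(np.corrcoef(ph["trait_x"], ph["trait_y"])[0, 1]) < 0.05

    def test_phenotypic_correlation_composes_g_and_e(self):
        # rho_P = rho_g * sqrt(h2x h2y) + rho_e * sqrt((1-h2x)(1-h2y))
        design = gt.CohortDesign(n_mz_pairs=2000, n_dz_pairs=2000,
                                 n_singletons=0, seed=15)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                    gt.TraitModel(0.5, 0, 0.5),
                                    rho_g=0.8, rho_e=0.2)
        ph = gt.simulate_bivariate_traits(design, bm, seed=16)
        r = np.corrcoef(ph["trait_x"], ph["trait_y"])[0, 1]
        assert r == pytest.approx(0.8 * 0.5 + 0.2 * 0.5, abs=0.05)

    def test_mz_cross_covariance_twice_dz_without_shared_env(self):
        design = gt.CohortDesign(n_mz_pairs=3000, n_dz_pairs=3000,
                                 n_singletons=0, seed=17)
        bm = gt.BivariateTraitModel(gt.TraitModel(0.6, 0, 0.4),
                                    gt.TraitModel(0.6, 0, 0.4),
                                    rho_g=0.7, rho_e=0.0)
        ph = gt.simulate_bivariate_traits(design, bm, seed=18)
        pairs = gt.TwinPairSet.from_tables(ph, gt.build_sample_sheet(design),
                                           ["trait_x", "trait_y"])
        covs = {}
        for z in ("MZ", "DZ"):
            v = pairs.values[pairs.zygosity == z]
            c1 = np.cov(v[:, 0, 0], v[:, 1, 1])[0, 1]
            c2 = np.cov(v[:, 0, 1], v[:, 1, 0])[0, 1]
            covs[z] = 0.5 * (c1 + c2)
        expected_mz = 0.7 * 0.6  # rho_g * sqrt(a2_x a2_y)
        assert covs["MZ"] == pytest.approx(expected_mz, abs=0.04)
        assert covs["MZ"] == pytest.approx(2 * covs["DZ"], abs=0.07)

    def test_non_psd_snp_specification_rejected(self, small_cohort):
        _, geno, _ = small_cohort
        design = gt.CohortDesign(n_mz_pairs=60, n_dz_pairs=60,
                                 n_singletons=20, n_plates=5, seed=42)
        # shared SNP covariance 0.3 exceeds the rho_g=0 target of 0
        bm = gt.BivariateTraitModel(
            gt.TraitModel(0.5, 0, 0.5, snp_effects=[(0, np.sqrt(0.3))]),
            gt.TraitModel(0.5, 0, 0.5, snp_effects=[(0, np.sqrt(0.3))]),
            rho_g=0.0, rho_e=0.0)
        with pytest.raises(ValueError, match="non-PSD"):
            gt.simulate_bivariate_traits(design, bm, genotypes=geno)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            gt.BivariateTraitModel(gt.TraitModel(0.5, 0, 0.5),
                                   gt.TraitModel(0.5, 0, 0.5),
                                   rho_g=1.5, rho_e=0.0)


class TestGlycoformPanel:
    LAYOUT = {"HYT": ["HYT_H3N5F0S0", "HYT_H3N5F0S1", "HYT_H3N5F0S2"]}

    def _latent(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"HYT": rng.standard_normal(n)},
                            index=[f"i{k}" for k in range(n)])

    def test_positive_abundances(self):
        raw, _ = gt.simulate_glycoform_panel(self._latent(100), self.LAYOUT,
                                             seed=1)
        assert (raw.to_numpy() > 0).all()

    def test_single_glycoform_peptide_rejected(self):
        with pytest.raises(ValueError, match="single glycoform"):
            gt.simulate_glycoform_panel(self._latent(10),
                                        {"HYT": ["HYT_H3N5F0S0"]}, seed=2)

    def test_saturation_in_the_latent_limit(self):
        latent = pd.DataFrame({"HYT": np.full(5, 80.0)})
        raw, truth = gt.simulate_glycoform_panel(
            latent, {"HYT": ["HYT_H3N5F0S0", "HYT_H3N5F0S2"]},
            seed=3, noise_sd=0.0)
        props = truth["proportions"]
        # huge latent pushes everything onto the more sialylated form
        np.testing.assert_allclose(props["HYT_H3N5F0S2"], 1.0, atol=1e-10)
        np.testing.assert_allclose(props["HYT_H3N5F0S0"], 0.0, atol=1e-10)

    def test_total_area_normalization_recovers_truth_exactly(self):
        raw, truth = gt.simulate_glycoform_panel(self._latent(200, seed=4),
                                                 self.LAYOUT, seed=5)
        rel = gt.total_area_normalize(gt.AbundanceTable(raw))
        np.testing.assert_allclose(rel.data.to_numpy(),
                                   truth["proportions"].to_numpy(), atol=1e-12)

    def test_target_sialylation_recovered(self):
        # base composition with 30% sialylated mass; mean recomputed derived
        # trait should sit on the target
        base = {"HYT": np.array([0.7, 0.2, 0.1])}
        raw, _ = gt.simulate_glycoform_panel(self._latent(2000, seed=6),
                                             self.LAYOUT, seed=7,
                                             base_props=base,
                                             coupling_scale=0.0)
        rel = gt.total_area_normalize(gt.AbundanceTable(raw))
        frac_s = (rel.data["HYT_H3N5F0S1"] + rel.data["HYT_H3N5F0S2"])
        assert frac_s.mean() == pytest.approx(0.3, abs=0.02)

    def test_monotone_link(self):
        latent = self._latent(500, seed=8)
        raw, truth = gt.simulate_glycoform_panel(latent, self.LAYOUT, seed=9,
                                                 noise_sd=0.0)
        s_frac = (truth["proportions"]["HYT_H3N5F0S1"]
                  + truth["proportions"]["HYT_H3N5F0S2"])
        order = np.argsort(latent["HYT"].to_numpy())
        assert np.all(np.diff(s_frac.to_numpy()[order]) > -1e-12)


def test_snp_variance_sum_recovers_configured_share():
    design = gt.CohortDesign(n_mz_pairs=0, n_dz_pairs=0, n_singletons=4000,
                             seed=19)
    effects = [(2, 0.15), (5, -0.2), (9, 0.1)]
    share = sum(b * b for _, b in effects)
    geno = gt.simulate_genotypes(design, 20, seed=20)
    ph = gt.simulate_twin_traits(design, gt.TraitModel(0.5, 0.0, 0.5,
                                                       snp_effects=effects),
                                 genotypes=geno, seed=21)
    y = ph["value"].to_numpy()
    y = (y - y.mean()) / y.std()
    total = 0.0
    for idx, _ in effects:
        g = geno.dosages[:, idx].astype(float)
        beta = np.polyfit(g, y, 1)[0]
        p = g.mean() / 2
        total += gt.snp_variance_explained(beta, min(p, 1 - p))
    assert total == pytest.approx(share, abs=0.02)
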