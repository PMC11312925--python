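import numpy as np
import pandas as pd
import pytest

import glycotwin as gt


@pytest.fixture(scope="session")
def small_design():
    return gt.CohortDesign(n_mz_pairs=60, n_dz_pairs=60, n_singletons=20,
                           n_plates=5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """Sample sheet, genotypes and one heritable trait for a small cohort."""
    samples = gt.build_sample_sheet(small_design)
    geno = gt.simulate_genotypes(small_design, n_snp=150, seed=1)
    model = gt.TraitModel(a2=0.5, c2=0.2, e2=0.3, beta_age=0.01,
                          beta_sex=0.2, plate_sd=0.3)
    pheno = gt.simulate_twin_traits(small_design, model, genotypes=geno, seed=2)
    return samples, geno, pheno


@pytest.fixture()
def toy_panel():
    """Three-glycoform HYT panel with hand-set relative abundances."""
    cols = ["HYT_H3N5F0S0", "HYT_H3N5F0S1", "HYT_H3N5F0S2"]
    data = pd.DataFrame(
        [[0.5, 0.3, 0.2],
         [0.2, 0.3, 0.5],
         [0.6, 0.4, 0.0]],
        index=["i1", "i2", "i3"], columns=cols)
    return data


def exact_corr_pairs(n_pairs, r, rng):
    """Twin-pair values whose sample within-pair correlation is exactly r."""
    z = rng.standard_normal((n_pairs, 2))
    z -= z.mean(axis=0)
    # whiten empirically, then impose the target correlation
    cov = z.T @ z / n_pairs
    L = np.linalg.cholesky(cov)
    w = z @ np.linalg.inv(L).T
    target = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
    return w @ target.T
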