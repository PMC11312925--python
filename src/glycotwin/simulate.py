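"""Synthetic twin-cohort generator with known ground truth.

Generates MZ/DZ twin pairs and singletons, genotypes under a
parental-gamete model, quantitative traits with a configurable
additive-genetic / shared-environment / unique-environment (ACE)
decomposition plus SNP, age, sex and plate effects, bivariate trait pairs
with specified genetic and environmental cross-trait correlations, and
compositional glycoform panels driven by the latent traits through a
logistic-normal (softmax of Gaussian logits) allocation.

Default cohort shape follows a large adult twin registry: 513 MZ pairs,
615 DZ pairs and 167 singletons, 78% female, ages 19-88.  Every simulated
quantity is recorded so downstream estimators can be tested for parameter
recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .glycoforms import parse_glycoform_name

__all__ = [
    "CohortDesign",
    "TraitModel",
    "BivariateTraitModel",
    "build_sample_sheet",
    "simulate_genotypes",
    "simulate_twin_traits",
    "simulate_bivariate_traits",
    "simulate_glycoform_panel",
]


@dataclass
class CohortDesign:
    """Cohort shape: twin-pair counts, demographics, plate layout."""

    n_mz_pairs: int = 513
    n_dz_pairs: int = 615
    n_singletons: int = 167
    sex_fraction_female: float = 0.78
    age_range: tuple[float, float] = (19.0, 88.0)
    n_plates: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_plates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sex_fraction_female <= 1:
            raise ValueError("sex_fraction_female must be in [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min must be <= max")

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons

    @property
    def n_families(self) -> int:
        return self.n_mz_pairs + self.n_dz_pairs + self.n_singletons


@dataclass
class TraitModel:
    """Generative ACE decomposition plus SNP and covariate effects.

    ``a2 + c2 + e2`` must equal 1: they are the variance shares of the
    latent trait before covariate effects.  SNP effects are per
    standardized allele (dosage scaled by sqrt(2pq)) and count toward the
    additive share: the polygenic residual is rescaled so the total
    additive variance stays a2.
    """

    a2: float
    c2: float
    e2: float
    snp_effects: list[tuple[int, float]] = field(default_factory=list)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    plate_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValueError("variance components must be >= 0")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ValueError("a2 + c2 + e2 must equal 1")

    @property
    def snp_variance(self) -> float:
        return float(sum(b * b for _, b in self.snp_effects))


@dataclass
class BivariateTraitModel:
    """Two ACE traits with cross-trait genetic/environmental correlations."""

    model_x: TraitModel
    model_y: TraitModel
    rho_g: float
    rho_e: float
    rho_c: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_g", "rho_e", "rho_c"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")


def build_sample_sheet(design: CohortDesign) -> pd.DataFrame:
    """Deterministic sample sheet for a design (uses ``design.seed``).

    Co-twins share age (twins are born together) and MZ co-twins share sex;
    plates are assigned round-robin by family so zygosity is never
    confounded with plate.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.age_range
    n_fam = design.n_families
    fam_zyg = np.array(["MZ"] * design.n_mz_pairs + ["DZ"] * design.n_dz_pairs
                       + ["NA"] * design.n_singletons)
    members = np.where(fam_zyg == "NA", 1, 2)
    fam_age = rng.uniform(lo, hi, n_fam)
    fam_plate = (np.arange(n_fam) % design.n_plates) if design.n_plates else np.zeros(n_fam, int)
    sex1 = rng.random(n_fam) < design.sex_fraction_female
    sex2_draw = rng.random(n_fam) < design.sex_fraction_female
    sex2 = np.where(fam_zyg == "MZ", sex1, sex2_draw)

    fam_idx = np.repeat(np.arange(n_fam), members)
    member_no = np.concatenate([np.arange(1, m + 1) for m in members])
    female = np.where(member_no == 1, sex1[fam_idx], sex2[fam_idx])
    fam_names = np.array([f"F{i + 1:05d}" for i in range(n_fam)])
    return pd.DataFrame({
        "individual_id": [f"{fam_names[i]}_{m}" for i, m in zip(fam_idx, member_no)],
        "family_id": fam_names[fam_idx],
        "zygosity": fam_zyg[fam_idx],
        "sex": np.where(female, "F", "M"),
        "age": fam_age[fam_idx],
        "plate": [f"P{p:03d}" for p in fam_plate[fam_idx]],
    })


def simulate_genotypes(
    design: CohortDesign,
    n_snp: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Family-structured genotypes under a parental-gamete model.

    Each family gets two simulated parents with Hardy-Weinberg genotypes at
    the target allele frequency; MZ co-twins share one sampled genome, DZ
    co-twins draw independent gametes from the same parents (expected
    dosage correlation 1/2).  Returned MAFs are recomputed from dosages.
    """
    low, high = maf_range
    if not 0 < low <= high <= 0.5:
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    if design.n_individuals == 0:
        raise ValueError("design has zero individuals")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(low, high, size=n_snp)
    samples = build_sample_sheet(design)
    n_fam = design.n_families

    # parental allele pairs, shape (n_fam, n_snp, 2) per parent
    mother = rng.random((n_fam, n_snp, 2)) < maf[None, :, None]
    father = rng.random((n_fam, n_snp, 2)) < maf[None, :, None]

    def gametes(parent, fam_idx):
        pick = rng.integers(0, 2, size=(len(fam_idx), n_snp))
        sel = parent[fam_idx]
        return np.take_along_axis(sel, pick[:, :, None], axis=2)[:, :, 0]

    fam_ids = samples["family_id"].to_numpy()
    fam_codes = pd.factorize(fam_ids, sort=False)[0]
    zyg = samples["zygosity"].to_numpy()
    dosages = np.zeros((len(samples), n_snp), dtype=np.int8)
    # MZ: one draw per family, copied to both twins
    mz_first = np.flatnonzero((zyg == "MZ") & ~pd.Series(fam_ids).duplicated().to_numpy())
    if len(mz_first):
        fidx = fam_codes[mz_first]
        child = gametes(mother, fidx).astype(np.int8) + gametes(father, fidx).astype(np.int8)
        dosages[mz_first] = child
        dosages[mz_first + 1] = child
    # DZ and singletons: independent draws per individual
    indep = np.flatnonzero(zyg != "MZ")
    if len(indep):
        fidx = fam_codes[indep]
        dosages[indep] = (gametes(mother, fidx).astype(np.int8)
                          + gametes(father, fidx).astype(np.int8))

    return GenotypeMatrix(
        individuals=list(samples["individual_id"]),
        snp_ids=[f"snp{j:05d}" for j in range(n_snp)],
        dosages=dosages,
    )


def _pair_correlated_component(samples: pd.DataFrame, var: float, phi_dz: float,
                               rng) -> np.ndarray:
    """Per-individual Gaussian with cross-twin correlation 1 (MZ) / phi_dz (DZ)."""
    n = len(samples)
    out = np.zeros(n)
    if var <= 0:
        return out
    sd = np.sqrt(var)
    zyg = samples["zygosity"].to_numpy()
    fam = pd.factorize(samples["family_id"], sort=False)[0]
    shared = rng.standard_normal(fam.max() + 1)
    own = rng.standard_normal(n)
    is_mz = zyg == "MZ"
    is_dz = zyg == "DZ"
    out[is_mz] = sd * shared[fam[is_mz]]
    out[is_dz] = sd * (np.sqrt(phi_dz) * shared[fam[is_dz]]
                       + np.sqrt(1 - phi_dz) * own[is_dz])
    rest = ~(is_mz | is_dz)
    out[rest] = sd * own[rest]
    return out


def _covariate_effects(samples: pd.DataFrame, model: TraitModel, rng) -> np.ndarray:
    eff = (model.beta_age * samples["age"].to_numpy(float)
           + model.beta_sex * (samples["sex"] == "F").to_numpy(float))
    if model.plate_sd > 0:
        plates, codes = np.unique(samples["plate"], return_inverse=True)
        eff = eff + model.plate_sd * rng.standard_normal(len(plates))[codes]
    return eff


def _snp_component(model: TraitModel, genotypes: GenotypeMatrix | None) -> np.ndarray:
    if not model.snp_effects:
        return 0.0
    if genotypes is None:
        raise ValueError("trait model has SNP effects but no genotypes supplied")
    Xs = genotypes.standardized()
    comp = np.zeros(genotypes.n_individuals)
    for idx, beta in model.snp_effects:
        if not 0 <= idx < genotypes.n_snps:
            raise IndexError(f"SNP effect index {idx} outside the genotype matrix")
        comp += beta * Xs[:, idx]
    return comp


def simulate_twin_traits(
    design: CohortDesign,
    model: TraitModel,
    genotypes: GenotypeMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One quantitative trait over the cohort, with component bookkeeping.

    The latent trait is SNP effects + polygenic A + C + E; the polygenic
    additive variance is ``a2`` minus the configured SNP variance so the
    total additive share stays ``a2``.  Covariate effects (age, sex, plate)
    are added on top.  Returns a frame indexed by individual_id with the
    trait ``value`` and its generative components.
    """
    samples = build_sample_sheet(design)
    rng = np.random.default_rng(seed)
    resid_a2 = model.a2 - model.snp_variance
    if resid_a2 < -1e-12:
        raise ValueError("SNP effects imply more additive variance than a2")
    snp_part = _snp_component(model, genotypes)
    poly = _pair_correlated_component(samples, max(resid_a2, 0.0), 0.5, rng)
    shared = _pair_correlated_component(samples, model.c2, 1.0, rng)
    unique = np.sqrt(model.e2) * rng.standard_normal(len(samples))
    covar = _covariate_effects(samples, model, rng)
    value = snp_part + poly + shared + unique + covar
    return pd.DataFrame({
        "value": value,
        "genetic": snp_part + poly,
        "shared_env": shared,
        "unique_env": unique,
        "covariate_part": covar,
    }, index=pd.Index(samples["individual_id"], name="individual_id"))


def _bivariate_latents(samples: pd.DataFrame, A: np.ndarray, C: np.ndarray,
                       E: np.ndarray, rng) -> np.ndarray:
    """Draw (n, 2) latent trait pairs with twin-structured covariance."""
    n = len(samples)
    out = np.zeros((n, 2))
    zyg = samples["zygosity"].to_numpy()
    P = A + C + E

    def chol(M, label):
        try:
            return np.linalg.cholesky(M + 1e-12 * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            raise ValueError(f"non-PSD covariance specification ({label})")

    for z, phi in (("MZ", 1.0), ("DZ", 0.5)):
        idx = np.flatnonzero(zyg == z)
        first = idx[::2]
        if len(first) == 0:
            continue
        B = phi * A + C
        sigma = np.block([[P, B], [B, P]])
        L = chol(sigma, f"{z} pair")
        draws = rng.standard_normal((len(first), 4)) @ L.T
        out[first] = draws[:, :2]
        out[first + 1] = draws[:, 2:]
    rest = np.flatnonzero(~np.isin(zyg, ("MZ", "DZ")))
    if len(rest):
        L = chol(P, "within person")
        out[rest] = rng.standard_normal((len(rest), 2)) @ L.T
    return out


def simulate_bivariate_traits(
    design: CohortDesign,
    model: BivariateTraitModel,
    genotypes: GenotypeMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two traits with specified h2 and cross-trait correlations.

    The cross-twin cross-trait covariance is rho_g * sqrt(a2_x a2_y) for MZ
    pairs and half that for DZ pairs, plus shared-environment terms when
    c2 and rho_c are non-zero.  Shared causal SNPs (same index in both
    trait models) contribute beta_x * beta_y to the genetic covariance and
    are subtracted from the polygenic residual covariance.
    """
    mx, my = model.model_x, model.model_y
    ax = np.sqrt([mx.a2, my.a2])
    A_target = np.array([[mx.a2, model.rho_g * ax[0] * ax[1]],
                         [model.rho_g * ax[0] * ax[1], my.a2]])
    shared_cov = 0.0
    snp_idx_x = dict(mx.snp_effects)
    for idx, by in my.snp_effects:
        if idx in snp_idx_x:
            shared_cov += snp_idx_x[idx] * by
    A_resid = A_target - np.array([[mx.snp_variance, shared_cov],
                                   [shared_cov, my.snp_variance]])
    cx = np.sqrt([mx.c2, my.c2])
    C = np.array([[mx.c2, model.rho_c * cx[0] * cx[1]],
                  [model.rho_c * cx[0] * cx[1], my.c2]])
    ex = np.sqrt([mx.e2, my.e2])
    E = np.array([[mx.e2, model.rho_e * ex[0] * ex[1]],
                  [model.rho_e * ex[0] * ex[1], my.e2]])
    if np.linalg.eigvalsh(A_resid).min() < -1e-9:
        raise ValueError("SNP effects imply a non-PSD residual genetic covariance")

    samples = build_sample_sheet(design)
    rng = np.random.default_rng(seed)
    latent = _bivariate_latents(samples, A_resid, C, E, rng)
    sx = np.asarray(_snp_component(mx, genotypes))
    sy = np.asarray(_snp_component(my, genotypes))
    x = latent[:, 0] + sx + _covariate_effects(samples, mx, rng)
    y = latent[:, 1] + sy + _covariate_effects(samples, my, rng)
    return pd.DataFrame({"trait_x": x, "trait_y": y},
                        index=pd.Index(samples["individual_id"],
                                       name="individual_id"))


def simulate_glycoform_panel(
    latent: pd.DataFrame,
    peptide_layout: dict[str, list[str]],
    seed: int = 0,
    base_props: dict[str, np.ndarray] | None = None,
    coupling_scale: float = 0.5,
    noise_sd: float = 0.2,
    intensity_log_mean: float = 11.0,
    intensity_log_sd: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Raw glycoform intensities from latent traits via logistic-normal allocation.

    For each peptide the glycoform proportions of an individual are
    softmax(log base_props + latent * coupling_scale * u + noise) where the
    coupling direction ``u`` is the centred sialic-acid count of each
    glycoform — a higher latent trait shifts abundance toward more
    sialylated forms, monotonically.  Proportions are then scaled by a
    lognormal total intensity to produce arbitrary-unit raw signals.

    ``latent`` is individuals x peptides; ``base_props`` fixes the target
    mean composition per peptide (Dirichlet-drawn when omitted).  Returns
    the raw intensity table and a truth dict holding the realized
    proportions (exactly recoverable by total-area normalisation) and all
    allocation parameters.
    """
    rng = np.random.default_rng(seed)
    for pep, forms in peptide_layout.items():
        if len(forms) < 2:
            raise ValueError(f"peptide {pep!r} has a single glycoform")
        for f in forms:
            if parse_glycoform_name(f).peptide != pep:
                raise ValueError(f"glycoform {f} is not on peptide {pep}")
        if pep not in latent.columns:
            raise KeyError(f"no latent trait column for peptide {pep!r}")

    n = len(latent)
    intensity_cols = {}
    truth_props = {}
    params = {"coupling_scale": coupling_scale, "noise_sd": noise_sd,
              "base_props": {}, "coupling": {}}
    for pep, forms in peptide_layout.items():
        k = len(forms)
        if base_props is not None and pep in base_props:
            pi = np.asarray(base_props[pep], dtype=float)
            if len(pi) != k or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-9:
                raise ValueError(f"invalid base proportions for {pep!r}")
        else:
            pi = rng.dirichlet(np.full(k, 5.0))
        s_counts = np.array([parse_glycoform_name(f).S for f in forms], dtype=float)
        u = s_counts - s_counts.mean()
        lam = latent[pep].to_numpy(float)
        logits = (np.log(pi)[None, :] + coupling_scale * lam[:, None] * u[None, :]
                  + noise_sd * rng.standard_normal((n, k)))
        logits -= logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        props = ex / ex.sum(axis=1, keepdims=True)
        total = np.exp(intensity_log_mean
                       + intensity_log_sd * rng.standard_normal(n))
        for j, f in enumerate(forms):
            intensity_cols[f] = props[:, j] * total
            truth_props[f] = props[:, j]
        params["base_props"][pep] = pi.tolist()
        params["coupling"][pep] = u.tolist()
    raw = pd.DataFrame(intensity_cols, index=latent.index)
    truth = {"proportions": pd.DataFrame(truth_props, index=latent.index),
             "params": params}
    return raw, truth
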