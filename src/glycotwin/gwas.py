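"""Kinship-aware single-SNP association, conditional scans and replication.

The association model is a linear mixed model with covariance
``V = sigma_g^2 K + sigma_e^2 I`` where K is either the expected pedigree
relatedness (1 within MZ pairs, 0.5 within DZ pairs) or an empirical GRM
from standardized dosages.  Variance components are estimated once per
trait under the null (no SNP) and held fixed across SNPs — the usual
two-step approximation — so each SNP reduces to a weighted regression in
the eigenbasis of K.  Downstream utilities cover genomic-control lambda,
stepwise conditional scans for independent signals, per-SNP variance
explained (2pq beta^2) and discovery->replication classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    from .preprocess import BaseEstimator  # type: ignore[assignment]

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipModel",
    "ReplicationVerdict",
    "build_kinship",
    "run_gwas",
    "genomic_inflation",
    "conditional_scan",
    "snp_variance_explained",
    "check_replication",
    "MixedModelGWAS",
]

_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class KinshipModel:
    """Relatedness matrix with cached eigendecomposition."""

    matrix: np.ndarray
    individuals: list[str]
    mode: str  # "pedigree" | "grm"
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.individuals):
            raise ValueError("kinship matrix dimensions do not match individuals")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.matrix = K

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            d, U = np.linalg.eigh(self.matrix)
            self._eig = (np.clip(d, 0.0, None), U)
        return self._eig


def build_kinship(
    samples: pd.DataFrame | None = None,
    genotypes: GenotypeMatrix | None = None,
    mode: str = "pedigree",
) -> KinshipModel:
    """Expected pedigree relatedness or empirical GRM.

    Pedigree mode needs a sample sheet (individual_id, family_id, zygosity):
    co-twins get off-diagonal 1 (MZ) or 0.5 (DZ).  GRM mode computes
    X X^T / m on standardized dosages and needs >= 100 SNPs.
    """
    if mode == "pedigree":
        if samples is None:
            raise ValueError("pedigree mode needs a sample sheet")
        ids = [str(i) for i in samples["individual_id"]]
        n = len(ids)
        K = np.eye(n)
        pos = {i: k for k, i in enumerate(ids)}
        for fam, grp in samples.groupby("family_id"):
            zyg = grp["zygosity"].iloc[0]
            members = [str(i) for i in grp["individual_id"]]
            if len(members) < 2:
                continue
            if zyg not in ("MZ", "DZ"):
                raise ValueError(f"family {fam}: unknown zygosity {zyg!r}")
            r = 1.0 if zyg == "MZ" else 0.5
            for a in members:
                for b in members:
                    if a != b:
                        K[pos[a], pos[b]] = r
        return KinshipModel(K, ids, "pedigree")
    if mode == "grm":
        if genotypes is None:
            raise ValueError("grm mode needs genotypes")
        if genotypes.n_snps < 100:
            raise ValueError("grm mode needs >= 100 SNPs")
        poly = genotypes.maf > 0  # monomorphic SNPs carry no relatedness signal
        p = genotypes.alt_freq[poly]
        X = (genotypes.dosages[:, poly] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        K = X @ X.T / X.shape[1]
        return KinshipModel(K, list(genotypes.individuals), "grm")
    raise ValueError(f"unknown kinship mode {mode!r}")


def _fit_null(y: np.ndarray, X: np.ndarray, kinship: KinshipModel):
    """REML of sigma_g^2, sigma_e^2 under the null; returns rotation and weights.

    Parameterized by the genetic fraction h = sigma_g^2 / (sigma_g^2 + sigma_e^2)
    with the total variance profiled out (EMMA-style 1-D optimization in the
    eigenbasis of K).
    """
    d, U = kinship.eig()
    yr = U.T @ y
    Xr = U.T @ X
    n, p = Xr.shape
    dof = n - p

    def nll(h):
        v = h * d + (1.0 - h)
        w = 1.0 / v
        Xw = Xr * w[:, None]
        XtVX = Xr.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ yr)
        r = yr - Xr @ beta
        q = float(r @ (w * r))
        s2 = max(q / dof, 1e-300)
        _, ld = np.linalg.slogdet(XtVX)
        return 0.5 * (dof * (np.log(2 * np.pi * s2) + 1) + np.log(v).sum() + ld)

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0 - 1e-6), method="bounded")
    h = float(res.x)
    v = h * d + (1.0 - h)
    return U, 1.0 / v, h


def run_gwas(
    trait: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    kinship: KinshipModel | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Single-SNP association of one (quantile-normalized) trait.

    Per SNP: GLS regression of the trait on the minor-allele dosage under
    the null-estimated covariance (variance components fixed across SNPs),
    giving Wald beta, SE and p.  SNPs with MAF <= ``maf_min`` are excluded
    and counted in ``result.attrs['n_excluded_maf']``.  The effect allele is
    always the minor allele; dosages are flipped accordingly before testing.

    With ``kinship=None`` and no covariates this reduces to per-SNP
    ordinary least squares.
    """
    if isinstance(trait, pd.Series):
        if not trait.index.equals(pd.Index(genotypes.individuals)):
            try:
                trait = trait.loc[genotypes.individuals]
            except KeyError as exc:
                raise ValueError("trait and genotype samples do not match") from exc
        y = trait.to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if len(y) != genotypes.n_individuals:
        raise ValueError("trait and genotype samples do not match")
    if not np.isfinite(y).all():
        raise ValueError("missing trait values; drop them before the scan")
    n = len(y)

    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        X = np.column_stack([X, C])

    p_alt = genotypes.alt_freq
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep = maf > maf_min
    n_excluded = int((~keep).sum())
    G = genotypes.dosages[:, keep].astype(float)
    if G.shape[1] == 0:
        raise ValueError("no SNPs pass the MAF filter")
    if np.any(G.std(axis=0) == 0):
        raise ValueError("zero-variance SNP in the tested set")
    flip = p_alt[keep] > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    kept_idx = np.flatnonzero(keep)
    ea = [genotypes.ref[i] if f else genotypes.alt[i]
          for i, f in zip(kept_idx, flip)]
    oa = [genotypes.alt[i] if f else genotypes.ref[i]
          for i, f in zip(kept_idx, flip)]
    eaf = maf[keep]

    if kinship is not None:
        U, w, h_null = _fit_null(y, X, kinship)
        yr, Xr, Gr = U.T @ y, U.T @ X, U.T @ G
    else:
        w, h_null = np.ones(n), 0.0
        yr, Xr, Gr = y, X, G

    sw = np.sqrt(w)
    yw = yr * sw
    Xw = Xr * sw[:, None]
    Gw = Gr * sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RG = Gw - Q @ (Q.T @ Gw)

    gtg = np.einsum("ij,ij->j", RG, RG)
    gty = RG.T @ ry
    beta = gty / gtg
    dof = n - X.shape[1] - 1
    rss = float(ry @ ry) - beta * gty
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / gtg)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({
        "snp": [genotypes.snp_ids[i] for i in kept_idx],
        "chr": [genotypes.chrom[i] for i in kept_idx],
        "pos": [genotypes.pos[i] for i in kept_idx],
        "ea": ea, "oa": oa, "eaf": eaf,
        "beta": beta, "se": se, "p": pvals, "n": n,
    })
    out.attrs["n_excluded_maf"] = n_excluded
    out.attrs["h_null"] = h_null
    return out


def genomic_inflation(pvalues: np.ndarray | None = None,
                      chisq: np.ndarray | None = None) -> float:
    """Genomic-control lambda: median association chi2 over the chi2(1) median."""
    if chisq is None:
        if pvalues is None:
            raise ValueError("provide p-values or chi-square statistics")
        pvalues = np.asarray(pvalues, dtype=float)
        chisq = stats.chi2.isf(pvalues, df=1)
    chisq = np.asarray(chisq, dtype=float)
    if chisq.size < 100:
        raise ValueError("need >= 100 tests for a stable lambda")
    return float(np.median(chisq) / _CHI2_MEDIAN)


def conditional_scan(
    trait: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    window_snps: list[str],
    covariates: pd.DataFrame | np.ndarray | None = None,
    kinship: KinshipModel | None = None,
    gw_threshold: float = 5e-8,
    maf_min: float = 0.05,
    max_steps: int = 25,
) -> list[str]:
    """Stepwise conditional analysis within one locus window.

    Repeatedly takes the top genome-wide-significant SNP, adds its dosage to
    the covariates, and rescans the window; stops when no SNP remains below
    ``gw_threshold``.  Returns the ordered list of independent lead SNPs
    (empty when nothing reaches the threshold).
    """
    if not window_snps:
        raise ValueError("locus window contains no SNPs")
    window = genotypes.subset_snps(window_snps)
    base = (np.empty((window.n_individuals, 0)) if covariates is None
            else np.asarray(pd.DataFrame(covariates), dtype=float))
    leads: list[str] = []
    for _ in range(max_steps):
        remaining = [s for s in window.snp_ids if s not in leads]
        if not remaining:
            break
        cov = base
        if leads:
            cov = np.column_stack([base] + [window.dosage_of(s) for s in leads])
        res = run_gwas(trait, window.subset_snps(remaining), covariates=cov,
                       kinship=kinship, maf_min=maf_min)
        top = res.loc[res["p"].idxmin()]
        if top["p"] >= gw_threshold:
            break
        leads.append(str(top["snp"]))
    return leads


def snp_variance_explained(beta, eaf):
    """Phenotypic variance explained by an additive biallelic SNP: 2 p q beta^2.

    ``eaf`` is the minor (effect) allele frequency; arrays broadcast, and
    summing over independent lead SNPs gives the total SNP-based variance
    explained.
    """
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(eaf, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must be in (0, 1)")
    out = 2.0 * p * (1.0 - p) * beta ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class ReplicationVerdict:
    snp: str
    trait: str
    beta_discovery: float
    beta_replication: float
    p_replication: float
    threshold: float
    concordant: bool
    replicated: bool


def check_replication(
    beta_discovery: float,
    beta_replication: float,
    p_replication: float,
    m_pairs: int,
    alpha: float = 0.05,
    snp: str = "",
    trait: str = "",
    ea_discovery: str | None = None,
    ea_replication: str | None = None,
    oa_replication: str | None = None,
) -> ReplicationVerdict:
    """Discovery->replication classification for one trait-locus pair.

    Replicated iff the effect directions are concordant AND the replication
    p-value is strictly below alpha / m_pairs.  When allele labels are
    supplied, the replication beta is flipped onto the discovery effect
    allele first; mismatched alleles raise.
    """
    if ea_discovery is not None and ea_replication is not None:
        if ea_replication == ea_discovery:
            pass
        elif oa_replication == ea_discovery:
            beta_replication = -beta_replication
        else:
            raise ValueError("replication alleles do not match the discovery SNP")
    threshold = alpha / m_pairs
    concordant = bool(np.sign(beta_discovery) == np.sign(beta_replication)
                      and beta_discovery != 0 and beta_replication != 0)
    replicated = bool(concordant and p_replication < threshold)
    return ReplicationVerdict(
        snp=snp, trait=trait, beta_discovery=float(beta_discovery),
        beta_replication=float(beta_replication),
        p_replication=float(p_replication), threshold=float(threshold),
        concordant=concordant, replicated=replicated,
    )


class MixedModelGWAS(BaseEstimator):
    """sklearn-style estimator over :func:`run_gwas`.

    ``fit`` scans all SNPs of a :class:`GenotypeMatrix`; fitted attributes
    expose the summary-statistics table and the genomic-control lambda.
    """

    def __init__(self, kinship: KinshipModel | None = None,
                 maf_min: float = 0.05, gw_threshold: float = 5e-8):
        self.kinship = kinship
        self.maf_min = maf_min
        self.gw_threshold = gw_threshold

    def fit(self, X: GenotypeMatrix, y, covariates=None):
        res = run_gwas(y, X, covariates=covariates, kinship=self.kinship,
                       maf_min=self.maf_min)
        self.results_ = res
        self.lambda_ = genomic_inflation(res["p"].to_numpy()) \
            if len(res) >= 100 else np.nan
        self.n_significant_ = int((res["p"] < self.gw_threshold).sum())
        return self
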