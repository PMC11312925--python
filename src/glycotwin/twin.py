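"""Classical twin variance decomposition (univariate and bivariate).

The univariate ACE model partitions the variance of a standardized trait
into additive genetic (a2), shared environment (c2) and unique environment
(e2) components from the contrast between monozygotic (MZ) and dizygotic
(DZ) co-twin covariances: the expected within-pair correlation is a2 + c2
for MZ and a2/2 + c2 for DZ pairs.  Sub-models (AE, CE, E) fix c2, a2 or
both to zero and are compared by AIC.

The bivariate model fits two traits jointly per pair under a 4-variate
normal with Cholesky-parameterized genetic and environmental (co)variance
matrices, yielding per-trait heritabilities plus the genetic (rhoG),
environmental (rhoE) and phenotypic (rhoP) cross-trait correlations, with
likelihood-ratio tests for each correlation against zero.  The genetic and
environmental covariances then combine into the shared heritability

    COV_G = rhoG * sqrt(h2_x) * sqrt(h2_y)
    COV_E = rhoE * sqrt(1 - h2_x) * sqrt(1 - h2_y)
    h2_xy = COV_G / (COV_G + COV_E)

with each correlation constrained to zero when its LRT p-value exceeds 0.05.

Because all pairs of a zygosity group share one covariance matrix, every
likelihood evaluation works from the per-group sufficient statistics
(pair count and scatter matrix) and is O(1) in the number of pairs.
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

__all__ = [
    "TwinPairSet",
    "VarianceComponents",
    "SharedHeritability",
    "fit_univariate_twin",
    "select_model",
    "fit_bivariate_twin",
    "shared_heritability",
    "conditional_genetic_covariance",
    "TwinACEModel",
    "BivariateTwinModel",
]

UNIVARIATE_MODELS = ("ACE", "AE", "CE", "E")
_MIN_PAIRS = 20


@dataclass
class TwinPairSet:
    """Complete twin pairs with zygosity.

    ``values`` has shape (n_pairs, 2) for one trait or (n_pairs, 2, n_traits)
    for trait pairs; axis 1 indexes the two co-twins.
    """

    values: np.ndarray
    zygosity: np.ndarray  # "MZ" / "DZ" per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.zygosity = np.asarray(self.zygosity)
        if self.values.shape[0] != self.zygosity.shape[0]:
            raise ValueError("values and zygosity lengths differ")
        bad = set(np.unique(self.zygosity)) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")

    @property
    def n_mz(self) -> int:
        return int((self.zygosity == "MZ").sum())

    @property
    def n_dz(self) -> int:
        return int((self.zygosity == "DZ").sum())

    @classmethod
    def from_tables(
        cls,
        phenotypes: pd.DataFrame,
        samples: pd.DataFrame,
        traits: list[str] | str,
        drop_incomplete: bool = True,
        seed: int = 0,
    ) -> "TwinPairSet":
        """Pair individuals by family from a sample sheet.

        ``samples`` needs columns individual_id, family_id, zygosity;
        ``phenotypes`` is indexed by individual_id.  Co-twin order within a
        pair is randomized once with ``seed`` (the likelihood is symmetric;
        this guards against birth-order artifacts in the input ordering).
        Families without exactly two phenotyped twins are dropped when
        ``drop_incomplete`` (the default).
        """
        if isinstance(traits, str):
            traits = [traits]
        rng = np.random.default_rng(seed)
        sub = samples[samples["zygosity"].isin(["MZ", "DZ"])]
        sub = sub[sub["individual_id"].isin(phenotypes.index)]
        vals = phenotypes.loc[sub["individual_id"], traits].to_numpy(dtype=float)
        ok = np.isfinite(vals).all(axis=1)
        sub, vals = sub[ok], vals[ok]
        sub = sub.sort_values("family_id", kind="stable")
        vals = phenotypes.loc[sub["individual_id"], traits].to_numpy(dtype=float)
        fam = sub["family_id"].to_numpy()
        counts = pd.Series(fam).value_counts()
        incomplete = counts[counts != 2]
        if len(incomplete) and not drop_incomplete:
            raise ValueError(
                f"{len(incomplete)} families lack exactly two phenotyped twins")
        complete = np.isin(fam, counts[counts == 2].index)
        vals = vals[complete]
        zyg = sub["zygosity"].to_numpy()[complete][::2]
        values = vals.reshape(-1, 2, len(traits))
        swap = rng.random(len(values)) < 0.5
        values[swap] = values[swap][:, ::-1]
        if len(traits) == 1:
            values = values[:, :, 0]
        return cls(values=values, zygosity=zyg)


@dataclass
class VarianceComponents:
    """Fitted variance decomposition (univariate, or bivariate cross-trait)."""

    model: str
    a2: float
    c2: float
    e2: float
    loglik: float
    aic: float
    n_free: int
    n_mz: int
    n_dz: int
    converged: bool
    se: dict[str, float] = field(default_factory=dict)
    # bivariate extras
    h2_x: float | None = None
    h2_y: float | None = None
    rho_g: float | None = None
    rho_e: float | None = None
    rho_p: float | None = None
    p_rho_g: float | None = None
    p_rho_e: float | None = None
    p_rho_p: float | None = None
    A: np.ndarray | None = None
    E: np.ndarray | None = None
    degenerate: bool = False

    @property
    def h2(self) -> float:
        return self.a2


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

def _suff_stats_uni(pairs: TwinPairSet):
    out = {}
    for z in ("MZ", "DZ"):
        v = pairs.values[pairs.zygosity == z]
        out[z] = (len(v), v.T @ v if len(v) else np.zeros((2, 2)))
    return out


def _uni_profile_nll(r_mz: float, r_dz: float, ss) -> tuple[float, float]:
    """Profile (over sigma^2) negative log-likelihood; returns (nll, sigma2_hat)."""
    tr_total = 0.0
    logdet_total = 0.0
    n_total = 0
    for r, (n, S) in zip((r_mz, r_dz), (ss["MZ"], ss["DZ"])):
        if n == 0:
            continue
        r = min(max(r, -1 + 1e-10), 1 - 1e-10)
        det = 1.0 - r * r
        tr_total += (S[0, 0] + S[1, 1] - r * (S[0, 1] + S[1, 0])) / det
        logdet_total += n * np.log(det)
        n_total += n
    s2 = max(tr_total / (2 * n_total), 1e-300)
    nll = 0.5 * (2 * n_total * (np.log(2 * np.pi * s2) + 1) + logdet_total)
    return nll, s2


def _uni_params_to_corr(model: str, x: np.ndarray) -> tuple[float, float, float, float]:
    """Map free parameters to (r_mz, r_dz, a2, c2) for each sub-model."""
    if model == "ACE":
        s, t = x
    elif model == "AE":
        s, t = x[0], 1.0
    elif model == "CE":
        s, t = x[0], 0.0
    elif model == "E":
        s, t = 0.0, 1.0
    else:
        raise ValueError(f"unknown twin model {model!r}")
    a2 = s * t
    c2 = s * (1.0 - t)
    return a2 + c2, 0.5 * a2 + c2, a2, c2


def fit_univariate_twin(
    pairs: TwinPairSet,
    model: str = "ACE",
    covariates: pd.DataFrame | np.ndarray | None = None,
    min_pairs: int = _MIN_PAIRS,
) -> VarianceComponents:
    """ML fit of one of the ACE/AE/CE/E twin models.

    The trait is optionally residualized on covariates (two-stage OLS across
    all twins) and standardized; the pair likelihood is bivariate normal
    with expected co-twin correlation a2 + c2 (MZ) and a2/2 + c2 (DZ).
    Variance proportions are bounded to [0, 1]; standard errors come from
    the observed information of the profile likelihood via the delta method
    (undefined at a boundary).
    """
    if pairs.values.ndim != 2:
        raise ValueError("univariate fit needs values of shape (n_pairs, 2)")
    if pairs.n_mz < min_pairs or pairs.n_dz < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} MZ and DZ pairs (got {pairs.n_mz} MZ, {pairs.n_dz} DZ)")
    vals = pairs.values.copy()
    if covariates is not None:
        X = np.column_stack([np.ones(2 * len(vals)),
                             np.asarray(pd.DataFrame(covariates), dtype=float)])
        flat = vals.reshape(-1)
        beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
        vals = (flat - X @ beta).reshape(vals.shape)
    vals = vals - vals.mean()
    vals = vals / vals.std(ddof=1)
    ss = _suff_stats_uni(TwinPairSet(vals, pairs.zygosity))

    def nll(x):
        r_mz, r_dz, _, _ = _uni_params_to_corr(model, np.atleast_1d(x))
        return _uni_profile_nll(r_mz, r_dz, ss)[0]

    n_free = {"ACE": 3, "AE": 2, "CE": 2, "E": 1}[model]
    if model == "E":
        xopt = np.empty(0)
        converged = True
    else:
        ndim = n_free - 1  # sigma^2 is profiled out
        x0 = np.full(ndim, 0.5)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(0.0, 1.0)] * ndim)
        xopt, converged = res.x, bool(res.success)
        if not converged:
            warnings.warn(f"{model} twin fit did not converge", UserWarning)
    r_mz, r_dz, a2, c2 = _uni_params_to_corr(model, xopt)
    neg, _s2 = _uni_profile_nll(r_mz, r_dz, ss)
    ll = -neg
    se = _uni_se(model, xopt, nll) if model != "E" else {}
    return VarianceComponents(
        model=model, a2=a2, c2=c2, e2=1.0 - a2 - c2, loglik=float(ll),
        aic=float(2 * n_free - 2 * ll), n_free=n_free,
        n_mz=pairs.n_mz, n_dz=pairs.n_dz, converged=converged, se=se,
    )


def _uni_se(model: str, xopt: np.ndarray, nll) -> dict[str, float]:
    """Delta-method SEs for (a2, c2, e2) from the profile-likelihood Hessian."""
    ndim = len(xopt)
    if np.any(xopt <= 1e-6) or np.any(xopt >= 1 - 1e-6):
        return {}  # boundary: observed information invalid
    h = 1e-4
    H = np.zeros((ndim, ndim))
    f0 = nll(xopt)
    for i in range(ndim):
        for j in range(i, ndim):
            ei = np.eye(ndim)[i] * h
            ej = np.eye(ndim)[j] * h
            H[i, j] = H[j, i] = (
                nll(xopt + ei + ej) - nll(xopt + ei - ej)
                - nll(xopt - ei + ej) + nll(xopt - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {}
    if np.any(np.diag(cov) < 0):
        return {}
    if model == "ACE":
        s, t = xopt
        J = np.array([[t, s], [1 - t, -s]])  # d(a2,c2)/d(s,t)
        cab = J @ cov @ J.T
        se_a2, se_c2 = np.sqrt(np.diag(cab))
        se_e2 = float(np.sqrt(cov[0, 0]))  # e2 = 1 - s
        return {"a2": float(se_a2), "c2": float(se_c2), "e2": se_e2}
    se_s = float(np.sqrt(cov[0, 0]))
    if model == "AE":
        return {"a2": se_s, "c2": 0.0, "e2": se_s}
    return {"a2": 0.0, "c2": se_s, "e2": se_s}


def select_model(fits: list[VarianceComponents]) -> VarianceComponents:
    """Pick the fit with minimal AIC; ties go to fewer free parameters.

    Non-convergent fits are excluded with a warning.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    if len(ok) < len(fits):
        warnings.warn("model selection proceeds over converged fits only", UserWarning)
    return min(ok, key=lambda f: (round(f.aic, 12), f.n_free))


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

def _suff_stats_biv(values: np.ndarray, zygosity: np.ndarray):
    out = {}
    for z in ("MZ", "DZ"):
        v = values[zygosity == z]
        stacked = v.reshape(len(v), 4)  # (x1, y1, x2, y2)
        out[z] = (len(v), stacked.T @ stacked if len(v) else np.zeros((4, 4)))
    return out


def _chol2(l11: float, l21: float, l22: float) -> np.ndarray:
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def _biv_sigma(A: np.ndarray, E: np.ndarray, phi: float) -> np.ndarray:
    P = A + E
    B = phi * A
    return np.block([[P, B], [B, P]])


def _biv_nll_from_AE(A: np.ndarray, E: np.ndarray, ss) -> float:
    total = 0.0
    for phi, (n, S) in zip((1.0, 0.5), (ss["MZ"], ss["DZ"])):
        if n == 0:
            continue
        sig = _biv_sigma(A, E, phi)
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return 1e12
        total += 0.5 * (n * (4 * np.log(2 * np.pi) + logdet)
                        + np.trace(np.linalg.solve(sig, S)))
    return total


def _biv_theta_to_AE(theta: np.ndarray, constraint: str | None):
    if constraint is None:
        la11, la21, la22, le11, le21, le22 = theta
    elif constraint == "rho_g":
        la11, la22, le11, le21, le22 = theta
        la21 = 0.0
    elif constraint == "rho_e":
        la11, la21, la22, le11, le22 = theta
        le21 = 0.0
    elif constraint == "independent":  # rho_g = rho_e = 0 jointly
        la11, la22, le11, le22 = theta
        la21 = le21 = 0.0
    elif constraint == "rho_p":
        la11, la21, la22, le11, le22 = theta
        # total cross-trait covariance forced to zero: E01 = -A01
        le21 = -(la11 * la21) / (le11 if abs(le11) > 1e-8 else 1e-8)
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return _chol2(la11, la21, la22), _chol2(le11, le21, le22)


def _biv_init(values: np.ndarray, zygosity: np.ndarray) -> np.ndarray:
    """Moment-based (Falconer-style) starting values, clipped to PD."""
    within = values.reshape(-1, 2)
    Cw = np.cov(within.T)
    cross = {}
    for z in ("MZ", "DZ"):
        v = values[zygosity == z]
        if len(v) < 2:
            cross[z] = 0.5 * Cw
            continue
        C = (v[:, 0, :].T @ v[:, 1, :]) / len(v)
        cross[z] = 0.5 * (C + C.T)
    A = 2.0 * (cross["MZ"] - cross["DZ"])
    E = Cw - cross["MZ"]

    def pd_clip(M):
        lam, Q = np.linalg.eigh(0.5 * (M + M.T))
        lam = np.clip(lam, 0.05 * max(np.trace(Cw), 1e-3), None)
        return Q @ np.diag(lam) @ Q.T

    La = np.linalg.cholesky(pd_clip(A))
    Le = np.linalg.cholesky(pd_clip(E))
    return np.array([La[0, 0], La[1, 0], La[1, 1], Le[0, 0], Le[1, 0], Le[1, 1]])


def _safe_corr(cov: np.ndarray, i: int, j: int) -> float:
    d = cov[i, i] * cov[j, j]
    return float(cov[i, j] / np.sqrt(d)) if d > 1e-20 else 0.0


def fit_bivariate_twin(
    pairs: TwinPairSet,
    covariates: pd.DataFrame | np.ndarray | None = None,
    lrt: bool = True,
    min_pairs: int = _MIN_PAIRS,
    constrain: str | None = None,
) -> VarianceComponents:
    """ML bivariate AE twin decomposition of two traits.

    Fits the 4-variate normal pair likelihood with Cholesky-parameterized
    genetic (A) and environmental (E) covariance matrices; the cross-twin
    block is A for MZ and A/2 for DZ pairs.  Returns per-trait h2, the
    genetic/environmental/phenotypic correlations, and (with ``lrt=True``)
    chi2(1) likelihood-ratio p-values for each correlation against zero.
    """
    if pairs.values.ndim != 3 or pairs.values.shape[2] != 2:
        raise ValueError("bivariate fit needs values of shape (n_pairs, 2, 2)")
    if pairs.n_mz < min_pairs or pairs.n_dz < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} MZ and DZ pairs (got {pairs.n_mz} MZ, {pairs.n_dz} DZ)")
    vals = pairs.values.copy()
    if covariates is not None:
        X = np.column_stack([np.ones(2 * len(vals)),
                             np.asarray(pd.DataFrame(covariates), dtype=float)])
        for k in range(2):
            flat = vals[:, :, k].reshape(-1)
            beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
            vals[:, :, k] = (flat - X @ beta).reshape(vals[:, :, k].shape)
    for k in range(2):
        vals[:, :, k] = (vals[:, :, k] - vals[:, :, k].mean()) / vals[:, :, k].std(ddof=1)

    # a trait paired with itself makes the 4-variate covariance singular
    within = vals.reshape(-1, 2)
    r_xy = np.corrcoef(within.T)[0, 1]
    if abs(r_xy) > 1 - 1e-8:
        uni = fit_univariate_twin(TwinPairSet(vals[:, :, 0], pairs.zygosity),
                                  model="AE", min_pairs=min_pairs)
        sgn = float(np.sign(r_xy))
        return VarianceComponents(
            model="AE-bivariate", a2=uni.a2, c2=0.0, e2=uni.e2,
            loglik=np.nan, aic=np.nan, n_free=6, n_mz=pairs.n_mz,
            n_dz=pairs.n_dz, converged=True, h2_x=uni.a2, h2_y=uni.a2,
            rho_g=sgn, rho_e=sgn, rho_p=sgn, p_rho_g=0.0, p_rho_e=0.0,
            p_rho_p=0.0, degenerate=True,
        )

    ss = _suff_stats_biv(vals, pairs.zygosity)

    def make_obj(constraint):
        def obj(theta):
            A, E = _biv_theta_to_AE(theta, constraint)
            return _biv_nll_from_AE(A, E, ss)
        return obj

    def run(constraint, x0):
        res = optimize.minimize(make_obj(constraint), x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-7,
                                         "fatol": 1e-9})
        res2 = optimize.minimize(make_obj(constraint), res.x, method="BFGS",
                                 options={"maxiter": 500})
        best = res2 if res2.fun <= res.fun else res
        return best

    x_full0 = _biv_init(vals, pairs.zygosity)
    if constrain is not None:
        drop0 = {"rho_g": [1], "rho_e": [4], "rho_p": [4],
                 "independent": [1, 4]}[constrain]
        x_full0 = np.delete(x_full0, drop0)
        lrt = False
    full = run(constrain, x_full0)
    A, E = _biv_theta_to_AE(full.x, constrain)
    ll_full = -full.fun
    converged = bool(np.isfinite(ll_full))

    h2_x = A[0, 0] / (A[0, 0] + E[0, 0])
    h2_y = A[1, 1] / (A[1, 1] + E[1, 1])
    rho_g = _safe_corr(A, 0, 1)
    rho_e = _safe_corr(E, 0, 1)
    P = A + E
    rho_p = _safe_corr(P, 0, 1)

    p_g = p_e = p_p = None
    if lrt:
        drop = {"rho_g": 1, "rho_e": 4}
        null_ps = {}
        for cname in ("rho_g", "rho_e", "rho_p"):
            if cname == "rho_p":
                x0 = np.array([full.x[0], full.x[1], full.x[2], full.x[3], full.x[5]])
            else:
                x0 = np.delete(full.x, drop[cname])
            nullfit = run(cname, x0)
            lr = max(2.0 * (ll_full - (-nullfit.fun)), 0.0)
            null_ps[cname] = float(stats.chi2.sf(lr, df=1))
        p_g, p_e, p_p = null_ps["rho_g"], null_ps["rho_e"], null_ps["rho_p"]

    # h2 here is the mean per-trait heritability (bivariate summary)
    n_free = len(full.x)
    return VarianceComponents(
        model="AE-bivariate", a2=float(0.5 * (h2_x + h2_y)), c2=0.0,
        e2=float(1 - 0.5 * (h2_x + h2_y)), loglik=float(ll_full),
        aic=float(2 * n_free - 2 * ll_full), n_free=n_free, n_mz=pairs.n_mz,
        n_dz=pairs.n_dz, converged=converged, h2_x=float(h2_x),
        h2_y=float(h2_y), rho_g=rho_g, rho_e=rho_e, rho_p=rho_p,
        p_rho_g=p_g, p_rho_e=p_e, p_rho_p=p_p, A=A, E=E,
    )


# ---------------------------------------------------------------------------
# shared-heritability arithmetic
# ---------------------------------------------------------------------------

@dataclass
class SharedHeritability:
    """Genetic / environmental covariance split of a phenotypic correlation."""

    cov_g: float
    cov_e: float
    h2_xy: float | None    # None when cov_g + cov_e == 0 (undefined)
    constrained_g: bool    # rhoG zeroed because its p-value exceeded alpha
    constrained_e: bool
    out_of_range: bool     # cov_g and cov_e of opposite sign => h2_xy outside [0,1]


def shared_heritability(
    rho_g: float,
    rho_e: float,
    h2_x: float,
    h2_y: float,
    p_rho_g: float | None = None,
    p_rho_e: float | None = None,
    alpha: float = 0.05,
) -> SharedHeritability:
    """Genetic and environmental covariance of two traits, and their ratio.

    COV_G = rhoG * sqrt(h2_x * h2_y); COV_E = rhoE * sqrt((1-h2_x)(1-h2_y));
    h2_xy = COV_G / (COV_G + COV_E).  A correlation whose p-value is larger
    than ``alpha`` is constrained to zero before the covariances are formed.
    """
    for h2 in (h2_x, h2_y):
        if not 0 <= h2 <= 1:
            raise ValueError("heritabilities must be in [0, 1]")
    for rho in (rho_g, rho_e):
        if not -1 <= rho <= 1:
            raise ValueError("correlations must be in [-1, 1]")
    cg_zero = p_rho_g is not None and p_rho_g > alpha
    ce_zero = p_rho_e is not None and p_rho_e > alpha
    cov_g = 0.0 if cg_zero else rho_g * np.sqrt(h2_x) * np.sqrt(h2_y)
    cov_e = 0.0 if ce_zero else rho_e * np.sqrt(1 - h2_x) * np.sqrt(1 - h2_y)
    denom = cov_g + cov_e
    h2_xy = None if denom == 0 else float(cov_g / denom)
    out_of_range = (cov_g * cov_e) < 0
    return SharedHeritability(
        cov_g=float(cov_g), cov_e=float(cov_e), h2_xy=h2_xy,
        constrained_g=cg_zero, constrained_e=ce_zero, out_of_range=out_of_range,
    )


def conditional_genetic_covariance(
    pairs: TwinPairSet,
    baseline_cov_g: float | None = None,
    min_pairs: int = _MIN_PAIRS,
) -> dict:
    """Genetic covariance of two traits after conditioning.

    ``pairs`` holds standardized residuals of both traits after adjusting
    each for covariates and the lead-SNP dosages; the bivariate model is
    refit on the residuals and the conditional genetic covariance is
    Cov_G = A_x * A_y * rhoG with A = sqrt(h2).  When ``baseline_cov_g``
    (the unconditional value) is supplied, the proportion of genetic
    covariance removed by conditioning is reported too.
    """
    fit = fit_bivariate_twin(pairs, lrt=False, min_pairs=min_pairs)
    cov_g = float(np.sqrt(fit.h2_x) * np.sqrt(fit.h2_y) * fit.rho_g)
    out = {"cov_g": cov_g, "rho_g": fit.rho_g, "h2_x": fit.h2_x,
           "h2_y": fit.h2_y, "fit": fit, "proportion_removed": None}
    if baseline_cov_g is not None and baseline_cov_g != 0:
        out["proportion_removed"] = float(1.0 - cov_g / baseline_cov_g)
    return out


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class TwinACEModel(BaseEstimator):
    """Univariate twin decomposition as an sklearn-style estimator.

    ``model='auto'`` fits ACE, AE, CE and E and keeps the AIC winner.
    """

    def __init__(self, model: str = "auto", min_pairs: int = _MIN_PAIRS):
        self.model = model
        self.min_pairs = min_pairs

    def fit(self, X, y=None, zygosity=None):
        if zygosity is None:
            raise ValueError("zygosity labels are required")
        pairs = TwinPairSet(np.asarray(X, dtype=float), np.asarray(zygosity))
        if self.model == "auto":
            fits = [fit_univariate_twin(pairs, m, min_pairs=self.min_pairs)
                    for m in UNIVARIATE_MODELS]
            res = select_model(fits)
            self.candidates_ = {f.model: f for f in fits}
        else:
            res = fit_univariate_twin(pairs, self.model, min_pairs=self.min_pairs)
        self.result_ = res
        self.a2_, self.c2_, self.e2_ = res.a2, res.c2, res.e2
        self.h2_ = res.a2
        self.loglik_, self.aic_ = res.loglik, res.aic
        self.selected_model_ = res.model
        return self


class BivariateTwinModel(BaseEstimator):
    """Bivariate AE twin decomposition as an sklearn-style estimator."""

    def __init__(self, lrt: bool = True, min_pairs: int = _MIN_PAIRS):
        self.lrt = lrt
        self.min_pairs = min_pairs

    def fit(self, X, y=None, zygosity=None):
        if zygosity is None:
            raise ValueError("zygosity labels are required")
        pairs = TwinPairSet(np.asarray(X, dtype=float), np.asarray(zygosity))
        res = fit_bivariate_twin(pairs, lrt=self.lrt, min_pairs=self.min_pairs)
        self.result_ = res
        self.h2_x_, self.h2_y_ = res.h2_x, res.h2_y
        self.rho_g_, self.rho_e_, self.rho_p_ = res.rho_g, res.rho_e, res.rho_p
        return self
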