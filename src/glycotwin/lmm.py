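"""Linear mixed models with crossed random intercepts (REML).

Used for covariate association (age/sex fixed effects with plate and
family random intercepts) and for residualizing traits before correlation
and twin analyses.  The model is

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma_k^2 I),  eps ~ N(0, sigma_e^2 I)

with each Z_k a 0/1 indicator matrix of one grouping factor.  The REML
criterion is profiled over sigma_e^2 and optimized over the variance
ratios gamma_k = sigma_k^2 / sigma_e^2 on the log scale; all matrix work
goes through the Woodbury identity, so the per-iteration cost is one
Cholesky of a (total levels) x (total levels) matrix regardless of n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    from .preprocess import BaseEstimator  # type: ignore[assignment]

__all__ = ["LmmFit", "fit_lmm", "LinearMixedModel", "ConvergenceWarning"]

_LOG_GAMMA_BOUND = 13.0  # gamma in [e^-13, e^13]; effectively [0, inf)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LmmFit:
    """REML fit: GLS fixed effects, variance components, BLUPs, residuals."""

    beta: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    vc: dict[str, float]          # per-grouping random-intercept variances
    sigma2: float                 # residual variance
    loglik: float                 # REML log-likelihood at the optimum
    n: int
    converged: bool
    n_iter: int
    resid_marginal: np.ndarray    # y - X beta
    resid_conditional: np.ndarray  # y - X beta - Z u  (BLUP-subtracted)
    blups: dict[str, pd.Series]
    trace: list[float] = field(default_factory=list)  # best -2ll so far, per eval

    @property
    def icc(self) -> dict[str, float]:
        """Intra-class correlation of each grouping factor."""
        tot = sum(self.vc.values()) + self.sigma2
        return {k: v / tot for k, v in self.vc.items()}


def _design(y, X, groups):
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not np.isfinite(y).all():
        raise ValueError("missing values in y; drop them before fitting")
    if X is None:
        Xdf = pd.DataFrame(index=np.arange(n))
    else:
        Xdf = pd.DataFrame(X).reset_index(drop=True)
    Xdf.insert(0, "(Intercept)", 1.0)
    Xm = Xdf.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("fixed-effect design is not full column rank")
    blocks, level_index, names = [], [], []
    if groups is not None:
        gdf = pd.DataFrame(groups).reset_index(drop=True)
        for name in gdf.columns:
            codes, levels = pd.factorize(gdf[name], sort=True)
            if len(levels) < 2:
                raise ValueError(f"grouping {name!r} has a single level")
            Zk = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
            )
            blocks.append(Zk)
            level_index.append(levels)
            names.append(str(name))
    return y, Xdf, Xm, blocks, level_index, names


def fit_lmm(y, X=None, groups=None, reml: bool = True, max_iter: int = 500) -> LmmFit:
    """Fit a linear mixed model with random intercepts per grouping factor.

    Parameters
    ----------
    y : response vector (no missing values).
    X : DataFrame / array of fixed covariates; an intercept is always added.
    groups : DataFrame / dict of grouping factors (one random intercept each);
        ``None`` reduces to ordinary least squares.
    reml : use the REML criterion (default); ML otherwise.

    Fixed-effect p-values are Wald (normal approximation), matching common
    mixed-model reporting for single coefficients.
    """
    y, Xdf, Xm, blocks, level_index, names = _design(y, X, groups)
    n, p = Xm.shape

    if not blocks:  # OLS reduction
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ beta
        dof = n - p
        s2 = float(r @ r / dof)
        cov = s2 * np.linalg.inv(Xm.T @ Xm)
        bse = np.sqrt(np.diag(cov))
        z = beta / bse
        ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1)
                     + np.linalg.slogdet(Xm.T @ Xm / s2)[1]) if reml else \
             -0.5 * n * (np.log(2 * np.pi * r @ r / n) + 1)
        return LmmFit(
            beta=pd.Series(beta, index=Xdf.columns),
            bse=pd.Series(bse, index=Xdf.columns),
            pvalues=pd.Series(2 * stats.norm.sf(np.abs(z)), index=Xdf.columns),
            vc={}, sigma2=s2, loglik=float(ll), n=n, converged=True, n_iter=0,
            resid_marginal=r, resid_conditional=r.copy(), blups={},
        )

    Z = sparse.hstack(blocks, format="csr")
    qk = [b.shape[1] for b in blocks]
    q = sum(qk)
    owner = np.repeat(np.arange(len(blocks)), qk)  # which factor owns each column

    ZtZ = (Z.T @ Z).toarray()
    ZtX = (Z.T @ Xm)
    Zty = Z.T @ y
    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)
    dof = n - p if reml else n

    trace: list[float] = []

    def core(loggam):
        gam = np.exp(np.clip(loggam, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
        gvec = gam[owner]
        M = ZtZ + np.diag(1.0 / gvec)
        c, low = cho_factor(M, lower=True)
        logdetM = 2.0 * np.log(np.diag(c)).sum()
        logdetW = logdetM + float(np.log(gvec).sum())
        MiZtX = cho_solve((c, low), ZtX)
        MiZty = cho_solve((c, low), Zty)
        XtWiX = XtX - ZtX.T @ MiZtX
        XtWiy = Xty - ZtX.T @ MiZty
        ytWiy = yty - float(Zty @ MiZty)
        beta = np.linalg.solve(XtWiX, XtWiy)
        qform = max(ytWiy - float(beta @ XtWiy), 1e-300)
        s2 = qform / dof
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        nll = 0.5 * (dof * (np.log(2 * np.pi * s2) + 1) + logdetW)
        if reml:
            nll += 0.5 * logdetXtWiX
        return nll, gam, gvec, (c, low), beta, s2, XtWiX

    def objective(loggam):
        nll = core(loggam)[0]
        trace.append(min(nll, trace[-1]) if trace else nll)
        return nll

    k = len(blocks)
    res = optimize.minimize(
        objective, np.zeros(k), method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-9},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn("mixed-model optimizer did not converge; fit is flagged",
                      ConvergenceWarning)

    nll, gam, gvec, chol, beta, s2, XtWiX = core(res.x)
    # BLUPs and residuals at the optimum
    r = y - Xm @ beta
    Ztr = Z.T @ r
    u = gvec * (Ztr - ZtZ @ cho_solve(chol, Ztr))
    resid_cond = r - Z @ u
    cov_beta = s2 * np.linalg.inv(XtWiX)
    bse = np.sqrt(np.diag(cov_beta))
    zstat = beta / bse
    vc = {names[i]: float(gam[i] * s2) for i in range(k)}
    # gamma at its lower bound is an estimated zero variance
    for i in range(k):
        if res.x[i] <= -_LOG_GAMMA_BOUND:
            vc[names[i]] = 0.0
    blups = {}
    off = 0
    for i, name in enumerate(names):
        blups[name] = pd.Series(u[off:off + qk[i]], index=level_index[i])
        off += qk[i]
    return LmmFit(
        beta=pd.Series(beta, index=Xdf.columns),
        bse=pd.Series(bse, index=Xdf.columns),
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(zstat)), index=Xdf.columns),
        vc=vc, sigma2=float(s2), loglik=float(-nll), n=n,
        converged=converged, n_iter=int(res.nit), resid_marginal=r,
        resid_conditional=np.asarray(resid_cond).ravel(), blups=blups,
        trace=[-t for t in trace],
    )


class LinearMixedModel(BaseEstimator):
    """sklearn-style estimator wrapping :func:`fit_lmm`.

    Parameters
    ----------
    group_cols : names of the grouping columns to pull out of the ``groups``
        frame passed to :meth:`fit` (all columns when None).
    reml : REML (default) vs ML.
    """

    def __init__(self, group_cols: list[str] | None = None, reml: bool = True,
                 max_iter: int = 500):
        self.group_cols = group_cols
        self.reml = reml
        self.max_iter = max_iter

    def fit(self, X, y, groups=None):
        g = groups
        if g is not None and self.group_cols is not None:
            g = pd.DataFrame(g)[self.group_cols]
        fit = fit_lmm(y, X, g, reml=self.reml, max_iter=self.max_iter)
        self.fit_ = fit
        self.coef_ = fit.beta.to_numpy()
        self.feature_names_in_ = fit.beta.index.to_numpy()
        self.bse_ = fit.bse.to_numpy()
        self.pvalues_ = fit.pvalues.to_numpy()
        self.vc_ = dict(fit.vc)
        self.sigma2_ = fit.sigma2
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        return self

    def predict(self, X):
        Xdf = pd.DataFrame(X).reset_index(drop=True)
        Xdf.insert(0, "(Intercept)", 1.0)
        return Xdf.to_numpy(dtype=float) @ self.coef_
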