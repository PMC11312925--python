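"""Glycopeptide abundance preprocessing.

Pipeline order is fixed: total-area normalisation within each tryptic
peptide (raw intensities -> relative abundances that close to 1 per
peptide), single-pass 4-SD outlier masking per trait, then a rank-based
inverse-normal (quantile) transform.  Each step exists both as a plain
function and as an sklearn-compatible transformer so the whole chain
composes with ``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glycoforms import parse_glycoform_name

try:  # sklearn is optional at runtime; the transformers degrade gracefully
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

    class TransformerMixin:  # type: ignore[no-redef]
        def fit_transform(self, X, y=None, **kw):
            return self.fit(X, y, **kw).transform(X)

__all__ = [
    "AbundanceTable",
    "total_area_normalize",
    "remove_outliers",
    "mask_outliers",
    "quantile_normalize",
    "quantile_normalize_table",
    "residualize",
    "PeptideTotalAreaNormalizer",
    "OutlierMasker",
    "RankInverseNormal",
]

STAGES = ("raw", "relative", "outlier-filtered", "quantile-normalized")


@dataclass
class AbundanceTable:
    """Individuals x glycoforms abundance matrix with a processing-stage tag."""

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def peptides(self) -> dict[str, list[str]]:
        """Columns grouped by tryptic peptide."""
        groups: dict[str, list[str]] = {}
        for col in self.data.columns:
            groups.setdefault(parse_glycoform_name(col).peptide, []).append(col)
        return groups

    def check_closure(self, tol: float = 1e-9) -> bool:
        """At stage 'relative': non-missing abundances of each peptide sum to 1."""
        for cols in self.peptides.values():
            sums = self.data[cols].sum(axis=1, skipna=True)
            has_any = self.data[cols].notna().any(axis=1)
            if not np.allclose(sums[has_any], 1.0, atol=tol):
                return False
        return True


def total_area_normalize(table: AbundanceTable) -> AbundanceTable:
    """Divide each glycoform intensity by the summed intensity of its peptide.

    Groups sharing a tryptic peptide are normalised independently; a peptide
    whose intensities are all zero (or all missing) for an individual yields
    missing values rather than 0/0.
    """
    df = table.data
    if (df < 0).any().any():
        bad = df.columns[(df < 0).any()][0]
        raise ValueError(f"negative intensity in column {bad!r}")
    out = df.copy().astype(float)
    for cols in table.peptides.values():
        sums = df[cols].sum(axis=1, skipna=True)
        sums = sums.where(sums > 0)  # zero-sum group -> NaN -> whole group missing
        out[cols] = df[cols].div(sums, axis=0)
    return AbundanceTable(out, stage="relative")


def remove_outliers(values: np.ndarray | pd.Series, k: float = 4.0) -> np.ndarray:
    """Single-pass k-SD outlier mask.

    Returns a boolean array, True where the entry is retained: non-missing
    and with ``|x - mean| <= k * SD`` (strictly more than k SDs away is
    masked; a value exactly at the boundary is retained).  Mean and SD are
    computed once from all non-missing values (sample SD, ddof=1).  A
    constant vector (SD = 0) masks nothing.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    m = x[finite].mean()
    s = x[finite].std(ddof=1)
    keep = finite.copy()
    if s > 0:
        keep[finite] = np.abs(x[finite] - m) <= k * s
    return keep


def mask_outliers(table: AbundanceTable, k: float = 4.0) -> AbundanceTable:
    """Apply :func:`remove_outliers` column-wise, setting masked entries missing."""
    out = table.data.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        if np.isfinite(x).sum() < 2:
            continue
        keep = remove_outliers(x, k=k)
        x[~keep & np.isfinite(x)] = np.nan
        out[col] = x
    return AbundanceTable(out, stage="outlier-filtered")


def quantile_normalize(values: np.ndarray | pd.Series, offset: str = "rankit") -> np.ndarray:
    """Rank-based inverse-normal transform.

    Ties receive their average rank; rank r among n non-missing values maps
    to the standard-normal quantile at ``r / (n + 1)`` (``offset='rankit'``)
    or at ``(r - 3/8) / (n + 1/4)`` (``offset='blom'``).  Missing entries
    stay missing; the transform is monotone.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    r = stats.rankdata(x[finite], method="average")
    if offset == "rankit":
        q = r / (n + 1.0)
    elif offset == "blom":
        q = (r - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    out = np.full_like(x, np.nan)
    out[finite] = stats.norm.ppf(q)
    return out


def quantile_normalize_table(table: AbundanceTable, offset: str = "rankit") -> AbundanceTable:
    out = table.data.copy().astype(float)
    for col in out.columns:
        out[col] = quantile_normalize(out[col].to_numpy(), offset=offset)
    return AbundanceTable(out, stage="quantile-normalized")


class PeptideTotalAreaNormalizer(TransformerMixin, BaseEstimator):
    """Transformer view of :func:`total_area_normalize` (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return total_area_normalize(AbundanceTable(X, stage="raw")).data


class OutlierMasker(TransformerMixin, BaseEstimator):
    """Transformer view of :func:`mask_outliers`: entries beyond k SDs -> NaN."""

    def __init__(self, k: float = 4.0):
        self.k = k

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        tbl = AbundanceTable(pd.DataFrame(X), stage="relative")
        return mask_outliers(tbl, k=self.k).data


class RankInverseNormal(TransformerMixin, BaseEstimator):
    """Column-wise rank-based inverse-normal transform."""

    def __init__(self, offset: str = "rankit"):
        self.offset = offset

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        df = pd.DataFrame(X).astype(float)
        for col in df.columns:
            df[col] = quantile_normalize(df[col].to_numpy(), offset=self.offset)
        return df


def residualize(
    trait: np.ndarray | pd.Series,
    fixed: pd.DataFrame | np.ndarray | None,
    groups: pd.DataFrame | dict | None,
    standardize: bool = True,
):
    """Mixed-model residualization of one trait.

    Fits the trait on fixed covariates (with intercept) and random
    intercepts per grouping factor, subtracts both the fixed-effect fit
    and the BLUPs (conditional residuals), and standardizes the result.
    With zero random-effect variance this reduces to OLS residuals.
    Rows with a missing trait value are returned as missing.
    """
    from .lmm import fit_lmm

    y = np.asarray(trait, dtype=float)
    keep = np.isfinite(y)
    if fixed is None:
        Xdf = pd.DataFrame(index=np.arange(len(y)))
    else:
        Xdf = pd.DataFrame(fixed).reset_index(drop=True)
    gdf = pd.DataFrame(groups).reset_index(drop=True) if groups is not None else None
    fit = fit_lmm(
        y[keep],
        Xdf.loc[keep].reset_index(drop=True) if len(Xdf.columns) else None,
        gdf.loc[keep].reset_index(drop=True) if gdf is not None else None,
    )
    out = np.full_like(y, np.nan)
    res = fit.resid_conditional
    if standardize:
        res = (res - res.mean()) / res.std(ddof=1)
    out[keep] = res
    return out
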