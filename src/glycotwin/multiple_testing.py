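"""Effective number of independent tests (Li-Ji) and Bonferroni thresholds."""

from __future__ import annotations

import numpy as np

__all__ = ["effective_tests_li_ji", "li_ji_score", "bonferroni_threshold"]


def li_ji_score(eigenvalues: np.ndarray) -> float:
    """Sum of f(|lambda|) = I(|lambda| >= 1) + fractional part, over eigenvalues.

    The scoring function behind the effective-number-of-tests estimate: an
    eigenvalue of k (a block of k perfectly correlated traits) contributes 1,
    while k partially correlated traits contribute between 1 and k.
    """
    lam = np.abs(np.asarray(eigenvalues, dtype=float))
    # the integer-part split is discontinuous at whole numbers; round away
    # floating-point noise so an exact multiplicity-k block scores 1, not 2
    lam = np.round(lam, 9)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_tests_li_ji(corr: np.ndarray, rounding: str = "round") -> tuple[float, int]:
    """Effective number of independent tests from a trait correlation matrix.

    Eigenvalues lambda_i of the correlation matrix are scored with
    f(lambda) = I(|lambda| >= 1) + (|lambda| - floor(|lambda|)) and summed:
    a block of perfectly correlated traits contributes a single test, while
    uncorrelated traits each count fully.

    Returns ``(m_eff_raw, m_eff_int)``; the integer (used as the Bonferroni
    denominator) is the raw value rounded to nearest by default, or floored
    with ``rounding='floor'``.  Invariant to trait reordering; equals the
    dimension for an identity matrix and 1 for an all-ones matrix.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    m_raw = li_ji_score(np.linalg.eigvalsh(corr))
    if rounding == "round":
        m_int = int(round(m_raw))
    elif rounding == "floor":
        m_int = int(np.floor(m_raw))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return m_raw, max(m_int, 1)


def bonferroni_threshold(alpha: float, m_tests: float) -> float:
    """Family-wise significance threshold alpha / m (exact)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests
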