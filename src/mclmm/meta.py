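"""Correlated fixed-effects meta-analysis of per-context effect estimates.

Fitting a joint multi-context LMM yields one effect estimate of the tested
covariate per context; because every context shares individuals, those
estimates are correlated, with correlation given by the corresponding
sub-block of the coefficient covariance.  The combiner here is the
generalized (Lin-Sullivan) inverse-variance fixed-effects estimator: GLS of
the estimate vector on a column of ones under the full estimate covariance.
With an identity correlation it reduces to the classical inverse-variance
fixed-effects meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import FitResult

#: eigenvalue floor used when repairing an indefinite correlation matrix
CORR_EIG_FLOOR = 1e-8


@dataclass
class ContextEffects:
    """Per-context estimates of one covariate and their correlation."""

    betas: np.ndarray
    ses: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        t = len(self.betas)
        if self.ses.shape != (t,) or self.corr.shape != (t, t):
            raise ValueError("betas, ses, corr must have shapes (t,), (t,), (t,t)")
        if (self.ses <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def t(self) -> int:
        return len(self.betas)


@dataclass
class MetaResult:
    beta_meta: float
    se_meta: float
    z: float
    p: float
    singular: bool = False


def repair_correlation(corr: np.ndarray, floor: float = CORR_EIG_FLOOR) -> np.ndarray:
    """Project a numerically indefinite correlation matrix back to PSD.

    Eigenvalues are floored at ``floor`` and the diagonal re-normalized to
    one; a matrix that is already PSD is returned unchanged.
    """
    corr = np.asarray(corr, dtype=float)
    corr = 0.5 * (corr + corr.T)
    w, V = np.linalg.eigh(corr)
    if w.min() >= floor:
        return corr
    w = np.maximum(w, floor)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def effect_correlation(fit: FitResult, covariate_index: int) -> ContextEffects:
    """Extract one covariate's per-context effects from a joint fit.

    With context-fastest column layout, covariate ``q`` occupies columns
    ``q*t .. q*t + t - 1`` of the coefficient vector; the correlation of
    the estimates is the normalized sub-block of ``beta_cov``.
    """
    t, c = fit.t, fit.c
    if not 0 <= covariate_index < c:
        raise IndexError(f"covariate index {covariate_index} out of range [0, {c})")
    cols = covariate_index * t + np.arange(t)
    betas = fit.beta_hat[cols]
    cov = fit.beta_cov[np.ix_(cols, cols)]
    ses = np.sqrt(np.diag(cov))
    corr = cov / np.outer(ses, ses)
    np.fill_diagonal(corr, 1.0)
    return ContextEffects(betas=betas, ses=ses, corr=repair_correlation(corr))


def fixed_effects_meta(effects: ContextEffects) -> MetaResult:
    """Inverse-variance fixed-effects combination of correlated estimates.

    Let Omega = diag(se) * corr * diag(se).  Then
    ``beta_meta = (1' Omega^-1 beta) / (1' Omega^-1 1)`` and
    ``se_meta = (1' Omega^-1 1)^{-1/2}``; the p-value is two-sided normal.
    A singular Omega falls back to the Moore-Penrose pseudo-inverse and is
    flagged.
    """
    omega = np.outer(effects.ses, effects.ses) * effects.corr
    ones = np.ones(effects.t)
    singular = False
    try:
        oinv_b = np.linalg.solve(omega, effects.betas)
        oinv_1 = np.linalg.solve(omega, ones)
    except np.linalg.LinAlgError:
        singular = True
        pinv = np.linalg.pinv(omega)
        oinv_b = pinv @ effects.betas
        oinv_1 = pinv @ ones
    denom = float(ones @ oinv_1)
    if denom <= 0 or not np.isfinite(denom):
        singular = True
        pinv = np.linalg.pinv(omega)
        oinv_b = pinv @ effects.betas
        oinv_1 = pinv @ ones
        denom = float(ones @ oinv_1)
        if denom <= 0:
            raise np.linalg.LinAlgError("meta-analysis weight sum is not positive")
    beta_meta = float(ones @ oinv_b) / denom
    se_meta = denom**-0.5
    z = beta_meta / se_meta
    return MetaResult(
        beta_meta=beta_meta,
        se_meta=se_meta,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        singular=singular,
    )


def meta_analyze_fit(fit: FitResult, covariate_index: int) -> MetaResult:
    """Convenience: extract effects for one covariate and combine them."""
    return fixed_effects_meta(effect_correlation(fit, covariate_index))
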