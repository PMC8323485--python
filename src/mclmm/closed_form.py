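"""Exact non-iterative solution for complete (no-missing) data.

With every individual observed in every context, H and X factor as
Kronecker products (``H = (1_t + delta*I) (x) I_n``,
``X = I_t (x) X_dense``), which makes the GLS coefficients equal to
independent per-context OLS fits — delta drops out entirely — and reduces
the profile likelihood in delta to a one-parameter function of two residual
summaries u and v whose stationary point is available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data_model import CollinearityError, FitResult, MultiContextData
from .likelihood_general import DELTA_MAX, DELTA_MIN, fit_general


@dataclass
class ResidualSummary:
    """Scalar residual summaries driving the closed-form variance ratio.

    u = sum of all squared OLS residuals (>= 0);
    v = minus the sum of squared per-individual residual totals (<= 0).
    The profiled residual quadratic form is
    ``R(delta) = u/delta + v/(delta*(t+delta))``.
    """

    u: float
    v: float
    t: int
    n: int

    def R(self, delta: float) -> float:
        return self.u / delta + self.v / (delta * (self.t + delta))


def per_context_ols(data: MultiContextData) -> np.ndarray:
    """Concatenated per-context OLS coefficients (the exact GLS solution).

    Returns the coefficient vector in stacked-design layout
    (context-fastest): entry ``q*t + r`` is covariate q's effect in
    context r.
    """
    if not data.is_complete:
        raise ValueError("per_context_ols requires complete data (no missing responses)")
    Xd = data.covariates
    if np.linalg.matrix_rank(Xd) < data.c:
        raise CollinearityError("X_dense is rank deficient")
    # (X'X)^-1 X' y for all contexts at once: coef is c x t
    coef, *_ = np.linalg.lstsq(Xd, data.responses, rcond=None)
    return coef.reshape(-1)  # row-major: covariate-major, context-fastest


def residuals_from_ols(data: MultiContextData, beta: np.ndarray) -> np.ndarray:
    """(n, t) residual matrix s = y - X beta for complete data."""
    coef = beta.reshape(data.c, data.t)
    return data.responses - data.covariates @ coef


def residual_summary(residuals: np.ndarray, n: int, t: int) -> ResidualSummary:
    """Collapse an (n, t) residual matrix to the summaries (u, v)."""
    s = np.asarray(residuals, dtype=float)
    if s.shape != (n, t):
        raise ValueError(f"residuals must have shape ({n}, {t}), got {s.shape}")
    u = float((s**2).sum())
    row = s.sum(axis=1)
    return ResidualSummary(u=u, v=-float(row @ row), t=t, n=n)


def delta_closed_form(
    summary: ResidualSummary,
    delta_min: float = DELTA_MIN,
    delta_max: float = DELTA_MAX,
) -> tuple[float, bool]:
    """Closed-form stationary point ``delta = (-t*u - v) / (u + v)``.

    Both the ML and REML profile derivatives share this root.  When the
    formula falls outside ``(delta_min, delta_max)`` — weak or absent
    within-individual correlation pushes it negative (sigma_g^2 -> 0), and
    near-perfect correlation pushes it to 0 — the estimate is clamped to
    the nearer bound and flagged.
    """
    u, v, t = summary.u, summary.v, summary.t
    if not u > 0:
        raise ValueError("u must be positive (all-zero residuals are degenerate)")
    denom = u + v
    if denom == 0:
        return delta_min, True
    delta = (-t * u - v) / denom
    if delta <= 0:
        # negative root: no evidence of within-individual variance; the
        # likelihood is maximized at the sigma_g^2 -> 0 boundary
        return delta_max, True
    if delta <= delta_min:
        return delta_min, True
    if delta >= delta_max:
        return delta_max, True
    return float(delta), False


def fit_complete(
    data: MultiContextData,
    method: str = "REML",
    delta_min: float = DELTA_MIN,
    delta_max: float = DELTA_MAX,
) -> FitResult:
    """Exact complete-data fit: OLS coefficients + closed-form delta.

    ``beta_cov`` uses the Kronecker identity
    ``(X^T H^-1 X)^-1 = (1_t + delta*I_t) (x) (X_dense^T X_dense)^-1``
    scaled by sigma_g^2.  Cost is ``O(c^3 + n c^2 + t c n)``; no iteration.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    if not data.is_complete:
        raise ValueError(
            "fit_complete requires complete data; use fit_general for missing responses"
        )
    n, t, c = data.n, data.t, data.c
    N, tc = n * t, t * c
    beta = per_context_ols(data)
    s = residuals_from_ols(data, beta)
    summ = residual_summary(s, n, t)
    delta_hat, boundary = delta_closed_form(summ, delta_min, delta_max)
    if not boundary:
        # accept the stationary point only if it is a local maximum
        eps = 1e-4 * delta_hat
        mid = _profile_obj(summ, delta_hat, method, N, tc, c)
        if not (
            _profile_obj(summ, delta_hat - eps, method, N, tc, c) <= mid
            and _profile_obj(summ, delta_hat + eps, method, N, tc, c) <= mid
        ):
            return fit_general(data, method, delta_min, delta_max)
    R = summ.R(delta_hat)
    sigma_g2 = R / N if method == "ML" else R / (N - tc)
    Xd = data.covariates
    xtx_inv = linalg.inv(Xd.T @ Xd)
    kron_block = np.ones((t, t)) + delta_hat * np.eye(t)
    beta_cov = sigma_g2 * np.kron(xtx_inv, kron_block)  # covariate-major layout
    return FitResult(
        delta_hat=delta_hat,
        sigma_g2=sigma_g2,
        sigma_e2=delta_hat * sigma_g2,
        beta_hat=beta,
        beta_cov=beta_cov,
        loglik=0.5 * _profile_obj(summ, delta_hat, method, N, tc, c),
        method=method,
        converged=True,
        boundary=boundary,
        n=n,
        t=t,
        c=c,
    )


def _profile_obj(
    summ: ResidualSummary, delta: float, method: str, N: int, tc: int, c: int
) -> float:
    """Profile log-likelihood in delta up to additive constants (not negated).

    ML:   -N log(u + v/(t+delta)) + n log(delta/(t+delta))
    REML: (tc - N) log(u + v/(t+delta)) + (c - n) log((t+delta)/delta)
    """
    t, n = summ.t, summ.n
    core = np.log(summ.u + summ.v / (t + delta))
    if method == "ML":
        return -N * core + n * np.log(delta / (t + delta))
    return (tc - N) * core + (c - n) * np.log((t + delta) / delta)


def log_det_xhx_inv(summary_t: int, c: int, delta: float, xtx: np.ndarray) -> float:
    """log|(X^T H^-1 X)^-1| via the Kronecker determinant identity.

    ``|(1_t + delta*I) (x) (Xd^T Xd)^-1| = |1_t + delta*I|^c |Xd^T Xd|^-t``
    with ``|1_t + delta*I| = (t+delta) * delta^(t-1)``, so the value is
    ``c*(log(t+delta) + (t-1)*log(delta)) - t*log|X_dense^T X_dense|``.
    """
    t = summary_t
    sign, ld = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise CollinearityError("X_dense^T X_dense is not positive definite")
    return c * (np.log(t + delta) + (t - 1) * np.log(delta)) - t * ld
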