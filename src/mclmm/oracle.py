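"""Brute-force dense reference implementation, for testing only.

Builds the full N x N covariance H = K + delta*I explicitly, evaluates the
exact full/restricted log-likelihoods (constants included), and maximizes
them by grid search with GLS profiling.  This is the EMMA-style ground
truth the fast solvers are validated against; it is O(N^3) per evaluation
and refuses instances above a configurable size cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data_model import FitResult, MultiContextData, StackedDesign, stack_design

DENSE_CAP = 2000


@dataclass
class DenseModel:
    """Explicit N x N representation of the indicator-kinship LMM."""

    K: np.ndarray
    X: np.ndarray
    y: np.ndarray
    n: int
    t: int
    c: int

    def H(self, delta: float) -> np.ndarray:
        return self.K + delta * np.eye(self.K.shape[0])


def dense_model(data: MultiContextData) -> DenseModel:
    design = stack_design(data)
    return dense_model_from_design(design)


def dense_model_from_design(design: StackedDesign) -> DenseModel:
    ind = design.row_individual
    K = (ind[:, None] == ind[None, :]).astype(float)
    return DenseModel(
        K=K, X=design.X_stacked, y=design.y_stacked, n=design.n, t=design.t, c=design.c
    )


def dense_loglik(
    model: DenseModel,
    beta: np.ndarray,
    sigma_g2: float,
    delta: float,
    method: str = "ML",
) -> float:
    """Literal full or restricted log-likelihood, constants included."""
    if delta <= 0 or sigma_g2 <= 0:
        raise ValueError("delta and sigma_g2 must be positive")
    H = model.H(delta)
    Hinv = linalg.inv(H)
    sign, ldH = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("H is numerically singular")
    r = model.y - model.X @ beta
    N = len(model.y)
    quad = float(r @ Hinv @ r)
    lf = 0.5 * (-N * np.log(2 * np.pi * sigma_g2) - ldH - quad / sigma_g2)
    if method.upper() == "ML":
        return lf
    tc = model.X.shape[1]
    _, ld_xx = np.linalg.slogdet(model.X.T @ model.X)
    _, ld_xhx = np.linalg.slogdet(model.X.T @ Hinv @ model.X)
    return lf + 0.5 * (tc * np.log(2 * np.pi * sigma_g2) + ld_xx - ld_xhx)


def dense_profile_loglik(model: DenseModel, delta: float, method: str = "ML") -> float:
    """Log-likelihood at one delta with beta and sigma_g2 profiled out."""
    beta, sigma_g2, _ = dense_gls(model, delta, method)
    return dense_loglik(model, beta, sigma_g2, delta, method)


def dense_gls(model: DenseModel, delta: float, method: str = "ML"):
    """GLS beta, profiled sigma_g2 and (X^T H^-1 X)^-1 at one delta."""
    Hinv = linalg.inv(model.H(delta))
    A = model.X.T @ Hinv @ model.X
    Ainv = linalg.inv(A)
    beta = Ainv @ (model.X.T @ (Hinv @ model.y))
    r = model.y - model.X @ beta
    R = float(r @ Hinv @ r)
    N, tc = model.X.shape
    dof = N if method.upper() == "ML" else N - tc
    return beta, R / dof, Ainv


def dense_fit(
    model: DenseModel,
    method: str = "REML",
    grid: np.ndarray | None = None,
    cap: int = DENSE_CAP,
) -> FitResult:
    """Grid-search maximization of the exact likelihood (testing oracle)."""
    N = len(model.y)
    if N > cap:
        raise ValueError(
            f"dense oracle capped at N={cap} (got {N}); use fit_general instead"
        )
    if grid is None:
        grid = np.logspace(-5, 5, 1000)
    vals = np.array([dense_profile_loglik(model, d, method) for d in grid])
    boundary = bool(vals.max() - vals.min() < 1e-10)
    k = len(grid) - 1 if boundary else int(np.argmax(vals))
    delta = float(grid[k])
    beta, sigma_g2, Ainv = dense_gls(model, delta, method)
    return FitResult(
        delta_hat=delta,
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        beta_hat=beta,
        beta_cov=sigma_g2 * Ainv,
        loglik=float(vals[k]),
        method=method.upper(),
        converged=True,
        boundary=boundary or k in (0, len(grid) - 1),
        n=model.n,
        t=model.t,
        c=model.c,
    )
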