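"""Canonical containers for multiple-context response data.

A *context* is a repeated-measurement condition within an individual — a
tissue in a multi-tissue eQTL study, or a phenotype in a multi-phenotype
GWAS.  Responses form an ``n x t`` matrix (individuals by contexts) with
``NaN`` marking unobserved pairs; covariates are complete per individual
and are expanded so that an intercept and every covariate effect are fit
separately *within* each context.

Column layout of the stacked design is context-fastest: for 0-indexed
column ``i``, ``f(i) = i % t`` is its context and ``g(i) = i // t`` its
covariate.  Columns ``0..t-1`` are the per-context intercepts, ``t..2t-1``
the second covariate, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the (weighted) design matrix is rank deficient."""


@dataclass
class MultiContextData:
    """Responses and covariates for ``n`` individuals across ``t`` contexts.

    Parameters
    ----------
    responses
        ``(n, t)`` float array; ``NaN`` marks a missing (individual,
        context) observation.
    covariates
        ``(n, c)`` float array, complete (no NaN).  Column 0 must be the
        constant intercept.
    context_labels, individual_ids
        Optional string labels; defaults are generated.
    """

    responses: np.ndarray
    covariates: np.ndarray
    context_labels: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D (individuals x contexts) array")
        n, t = self.responses.shape
        if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
            raise ValueError(
                f"covariates must be 2-D with {n} rows, got shape {self.covariates.shape}"
            )
        if not np.isfinite(self.covariates).all():
            raise ValueError("covariates must be finite and complete (no NaN/inf)")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise ValueError("covariate column 0 must be the constant intercept (all 1)")
        obs = self.observed_mask
        if not obs.any(axis=1).all():
            bad = [i for i in range(n) if not obs[i].any()]
            raise ValueError(f"individuals with zero observed contexts: {bad}")
        if not obs.any(axis=0).all():
            labels = self.context_labels or [f"context{j}" for j in range(t)]
            bad = [labels[j] for j in range(t) if not obs[:, j].any()]
            raise ValueError(f"contexts with zero observations: {bad}")
        finite = self.responses[obs]
        if not np.isfinite(finite).all():
            raise ValueError("observed responses must be finite")
        if not self.context_labels:
            self.context_labels = [f"context{j}" for j in range(t)]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        if len(self.context_labels) != t or len(self.individual_ids) != n:
            raise ValueError("label lengths must match responses shape")

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def t(self) -> int:
        return self.responses.shape[1]

    @property
    def c(self) -> int:
        return self.covariates.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.responses)

    @property
    def context_counts(self) -> np.ndarray:
        """t_i: number of observed contexts per individual."""
        return self.observed_mask.sum(axis=1)

    @property
    def n_obs(self) -> int:
        """Total observation count N = sum_i t_i."""
        return int(self.observed_mask.sum())

    @property
    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())


@dataclass
class StackedDesign:
    """Observation-level (stacked) view of a :class:`MultiContextData`.

    ``X_stacked`` has ``t*c`` columns laid out context-fastest; row ``r``
    has nonzero entries only in the columns of ``row_context[r]``.  Rows
    are sorted context-major, so that with complete data ``X_stacked``
    equals the Kronecker product ``I_t (x) X_dense``.
    """

    y_stacked: np.ndarray
    X_stacked: np.ndarray
    row_individual: np.ndarray
    row_context: np.ndarray
    n: int
    t: int
    c: int

    @property
    def n_obs(self) -> int:
        return self.y_stacked.shape[0]

    @property
    def context_counts(self) -> np.ndarray:
        return np.bincount(self.row_individual, minlength=self.n)


def column_context(i: int | np.ndarray, t: int):
    """Context index f(i) = i % t of stacked-design column i."""
    return i % t

def column_covariate(i: int | np.ndarray, t: int):
    """Covariate index g(i) = i // t of stacked-design column i."""
    return i // t


def stack_design(data: MultiContextData) -> StackedDesign:
    """Expand an ``(n, t)`` response table into the stacked GLS design.

    Each observed (individual, context) pair contributes one row; missing
    pairs contribute none.  Rows are ordered context-major (all
    individuals of context 0, then context 1, ...), which makes the
    complete-data design literally ``I_t (x) X_dense``.
    """
    n, t, c = data.n, data.t, data.c
    obs = data.observed_mask
    # context-major ordering: iterate contexts, individuals within
    ctx_idx, ind_idx = np.nonzero(obs.T)
    y = data.responses[ind_idx, ctx_idx]
    N = y.shape[0]
    X = np.zeros((N, t * c))
    cols = ctx_idx[:, None] + t * np.arange(c)[None, :]
    rows = np.broadcast_to(np.arange(N)[:, None], cols.shape)
    X[rows, cols] = data.covariates[ind_idx]
    return StackedDesign(
        y_stacked=y,
        X_stacked=X,
        row_individual=ind_idx,
        row_context=ctx_idx,
        n=n,
        t=t,
        c=c,
    )


def unstack_design(design: StackedDesign, covariates: np.ndarray) -> MultiContextData:
    """Inverse of :func:`stack_design` (row order is not preserved)."""
    responses = np.full((design.n, design.t), np.nan)
    responses[design.row_individual, design.row_context] = design.y_stacked
    return MultiContextData(responses=responses, covariates=covariates)


@dataclass
class GroupIndex:
    """Delta-independent sufficient statistics for fast likelihood evaluation.

    A *group* g is the set of individuals sharing the same observed-context
    count ``t_g``.  Everything the refactored likelihood needs at a given
    variance ratio delta is a weighted combination (weights ``1/(t_g+delta)``)
    of the per-group sums stored here, so each likelihood evaluation costs
    ``O(groups * (tc)^2)`` instead of a pass over all individuals.

    Attributes
    ----------
    E
        ``(tc, tc)`` matrix ``X^T X`` (block diagonal by context).
    xty
        ``X^T y``.
    y_total_sq
        ``sum(y_i^2)``.
    group_counts
        ``t_g`` values, one per group.
    group_sizes
        number of individuals in each group.
    group_vvT
        per-group sum of ``v_ind v_ind^T`` where ``v_ind = X_ind^T 1`` is the
        within-individual column sum of the design rows.
    group_vy
        per-group sum of ``v_ind * (sum of y over the individual)``.
    group_ysum_sq
        per-group sum of squared per-individual response totals.
    y_indiv_sums
        per-individual response totals (length n).
    """

    E: np.ndarray
    xty: np.ndarray
    y_total_sq: float
    group_counts: np.ndarray
    group_sizes: np.ndarray
    group_vvT: np.ndarray
    group_vy: np.ndarray
    group_ysum_sq: np.ndarray
    y_indiv_sums: np.ndarray
    n: int
    t: int
    c: int

    @property
    def n_obs(self) -> int:
        return int(self.group_counts @ self.group_sizes)

    @property
    def n_groups(self) -> int:
        return len(self.group_counts)


def build_group_index(design: StackedDesign) -> GroupIndex:
    """Precompute every delta-independent sum the refactored likelihood uses.

    Individuals are bucketed by observed-context count t_g; within each
    bucket the rank-one contributions ``v_ind v_ind^T`` (v = per-individual
    column sums of X) are accumulated, because they all share the same
    ``1/(t_g+delta)`` weight.  Grouping by count alone is sufficient: each
    individual's v is zero outside its own observed contexts, so the
    "observed set includes contexts i and j" restriction is enforced by the
    zeros themselves.
    """
    X, y = design.X_stacked, design.y_stacked
    n, tc = design.n, design.t * design.c
    E = X.T @ X
    xty = X.T @ y
    y_total_sq = float(y @ y)
    # per-individual aggregates
    V = np.zeros((n, tc))
    np.add.at(V, design.row_individual, X)
    y_sums = np.bincount(design.row_individual, weights=y, minlength=n)
    t_i = design.context_counts
    counts = np.unique(t_i)
    sizes = np.empty(len(counts), dtype=int)
    vvT = np.empty((len(counts), tc, tc))
    vy = np.empty((len(counts), tc))
    ysum_sq = np.empty(len(counts))
    for k, tg in enumerate(counts):
        members = t_i == tg
        Vg = V[members]
        sizes[k] = members.sum()
        vvT[k] = Vg.T @ Vg
        vy[k] = Vg.T @ y_sums[members]
        ysum_sq[k] = float(y_sums[members] @ y_sums[members])
    return GroupIndex(
        E=E,
        xty=xty,
        y_total_sq=y_total_sq,
        group_counts=counts,
        group_sizes=sizes,
        group_vvT=vvT,
        group_vy=vy,
        group_ysum_sq=ysum_sq,
        y_indiv_sums=y_sums,
        n=n,
        t=design.t,
        c=design.c,
    )


@dataclass
class FitResult:
    """Variance-component and coefficient estimates from an LMM fit.

    ``delta_hat`` is the variance ratio sigma_e^2 / sigma_g^2 profiled
    during optimization; ``beta_hat`` follows the stacked-design column
    layout (context-fastest).  ``loglik`` is reported up to an additive
    constant (the delta-independent terms dropped by the refactoring).
    """

    delta_hat: float
    sigma_g2: float
    sigma_e2: float
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    method: str
    converged: bool
    boundary: bool
    n: int = 0
    t: int = 0
    c: int = 0

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def beta_table(self):
        """Coefficient table: one row per (context, covariate)."""
        import pandas as pd
        from scipy import stats

        t, c = self.t, self.c
        idx = np.arange(t * c)
        se = self.beta_se
        z = np.divide(self.beta_hat, se, out=np.zeros_like(se), where=se > 0)
        return pd.DataFrame(
            {
                "context": column_context(idx, t),
                "covariate": column_covariate(idx, t),
                "beta": self.beta_hat,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )
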