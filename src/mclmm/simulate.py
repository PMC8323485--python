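"""Synthetic data generators for validating the multi-context LMM pipeline.

Three experiment families are emulated:

* **Null eQTL scans** — genotypes as the sum of two Bernoulli(MAF)
  haplotypes; expression drawn from ``N(0, sigma_g^2 K + sigma_e^2 I)``
  with K the within-individual indicator, so that no SNP has any effect.
  Default parameters follow the published null design: MAF 0.3 and both
  component *standard deviations* equal to 0.5 (variances 0.25), giving an
  intraclass correlation of 0.5.
* **True-positive scans** — a per-context effect vector beta_j multiplies
  the genotype and the same correlated noise is added.  Non-null effect
  vectors are drawn either from ``N(0, w * U_k)`` with U_k a structured
  t x t covariance and ``w = |N(0,1)|`` drawn per gene-SNP pair
  (structured sharing), or from ``N(0, 0.01 I)`` (unstructured sharing).
  Built-in synthetic covariance families (identity, equicorrelation,
  rank-one plus diagonal) stand in for data-driven matrices.
* **Resource-style missing-data sets** — ``sigma_g^2 = 0.4``,
  ``sigma_e^2 = 0.2`` and a Bernoulli sampling rate of 0.5, i.e. each
  individual-context pair is observed with probability one half.

Sampling the correlated noise never materializes the N x N covariance:
each individual's block is a shared ``N(0, sigma_g^2)`` effect plus
independent ``N(0, sigma_e^2)`` noise, which is exactly the block
covariance ``sigma_g^2 * 1 + sigma_e^2 * I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import MultiContextData


@dataclass
class SimScenario:
    """Parameters of one simulation experiment."""

    n: int = 500
    t: int = 8
    maf: float = 0.3
    sigma_g2: float = 0.4
    sigma_e2: float = 0.2
    sampling_rate: float = 1.0
    effect_mode: str = "null"  # null | shared_structured | shared_unstructured
    effect_var: float = 0.01  # per-context effect variance, unstructured mode
    n_tests: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.t < 1 or self.n_tests < 1:
            raise ValueError("n, t and n_tests must be positive")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        if not 0 < self.sampling_rate <= 1:
            raise ValueError("sampling_rate must be in (0, 1]")
        if self.effect_mode not in ("null", "shared_structured", "shared_unstructured"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_genotypes(n: int, maf: float, rng) -> np.ndarray:
    """Dosages in {0,1,2} as the sum of two Bernoulli(maf) haplotypes."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = _as_rng(rng)
    hap = rng.random((2, n)) < maf
    return hap.sum(axis=0).astype(float)


def simulate_null_responses(scenario: SimScenario, rng=None) -> MultiContextData:
    """Responses from N(0, sigma_g^2 K + sigma_e^2 I), sampled blockwise.

    Each individual receives a shared Gaussian effect across its contexts
    plus independent noise; marginal variance is sigma_g^2 + sigma_e^2 and
    within-individual covariance sigma_g^2.
    """
    rng = _as_rng(scenario.seed if rng is None else rng)
    y = _correlated_noise(scenario.n, scenario.t, scenario.sigma_g2, scenario.sigma_e2, rng)
    data = MultiContextData(
        responses=y, covariates=np.ones((scenario.n, 1))
    )
    if scenario.sampling_rate < 1:
        data = apply_sampling_mask(data, scenario.sampling_rate, rng)
    return data


def simulate_effect_responses(
    scenario: SimScenario,
    genotypes: np.ndarray,
    beta: np.ndarray,
    rng=None,
) -> MultiContextData:
    """Responses ``y[ind, r] = beta[r] * dosage[ind] + e`` for one test.

    ``e`` follows the null-model covariance; a zero beta vector reduces the
    draw to the null generator.  Covariates carry the intercept and the
    genotype dosage so the result can be fit directly.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if genotypes.shape != (scenario.n,) or beta.shape != (scenario.t,):
        raise ValueError(
            f"expected genotypes ({scenario.n},) and beta ({scenario.t},), "
            f"got {genotypes.shape} and {beta.shape}"
        )
    rng = _as_rng(scenario.seed if rng is None else rng)
    y = genotypes[:, None] * beta[None, :] + _correlated_noise(
        scenario.n, scenario.t, scenario.sigma_g2, scenario.sigma_e2, rng
    )
    covs = np.column_stack([np.ones(scenario.n), genotypes])
    data = MultiContextData(responses=y, covariates=covs)
    if scenario.sampling_rate < 1:
        data = apply_sampling_mask(data, scenario.sampling_rate, rng)
    return data


def apply_sampling_mask(
    data: MultiContextData, sampling_rate: float, rng
) -> MultiContextData:
    """Retain each (individual, context) pair independently with given rate.

    Individuals left with no observation are dropped; contexts left empty
    get one retained observation back (a context with zero observations is
    not a valid design).
    """
    if not 0 < sampling_rate <= 1:
        raise ValueError("sampling_rate must be in (0, 1]")
    if sampling_rate == 1:
        return data
    rng = _as_rng(rng)
    keep = rng.random(data.responses.shape) < sampling_rate
    keep &= data.observed_mask
    # every context needs >= 1 observation: resurrect one per empty context
    for j in np.nonzero(~keep.any(axis=0))[0]:
        candidates = np.nonzero(data.observed_mask[:, j])[0]
        keep[rng.choice(candidates), j] = True
    alive = keep.any(axis=1)
    responses = np.where(keep, data.responses, np.nan)[alive]
    return MultiContextData(
        responses=responses,
        covariates=data.covariates[alive],
        context_labels=list(data.context_labels),
        individual_ids=[iid for iid, a in zip(data.individual_ids, alive) if a],
    )


# ---------------------------------------------------------------------------
# effect-size covariance families and draws


def equicorrelation_cov(t: int, rho: float, scale: float = 1.0) -> np.ndarray:
    """Equicorrelated t x t covariance: scale * ((1-rho) I + rho 11')."""
    if t > 1 and not (-1 / (t - 1) < rho <= 1):
        raise ValueError("rho outside the positive-definite range")
    return scale * ((1 - rho) * np.eye(t) + rho * np.ones((t, t)))


def rank_one_cov(h: np.ndarray, diag: float = 0.0) -> np.ndarray:
    """Rank-one sharing pattern h h' plus an optional diagonal ridge."""
    h = np.asarray(h, dtype=float)
    return np.outer(h, h) + diag * np.eye(len(h))


def default_structured_covariances(t: int, rng=None) -> list[np.ndarray]:
    """A small synthetic family of structured sharing patterns.

    Stand-ins for data-driven covariance matrices: identity, two
    equicorrelation levels, and a rank-one pattern with a diagonal ridge,
    all scaled to unit average variance.
    """
    rng = _as_rng(0 if rng is None else rng)
    h = rng.normal(size=t)
    fams = [
        np.eye(t),
        equicorrelation_cov(t, 0.5),
        equicorrelation_cov(t, 0.9),
        rank_one_cov(h / np.sqrt(h @ h / t), diag=0.05),
    ]
    return [U / np.trace(U) * t for U in fams]


def draw_effects(
    n_tests: int,
    n_nonnull: int,
    t: int,
    mode: str,
    rng,
    covariances: list[np.ndarray] | None = None,
    effect_var: float = 0.01,
) -> np.ndarray:
    """Effect matrix (n_tests x t); the first ``n_nonnull`` rows are non-null.

    Structured mode: each non-null row ~ N(0, w U_k) with U_k picked
    uniformly from ``covariances`` and ``w = |N(0,1)|`` drawn per row.
    Unstructured mode: each non-null row ~ N(0, effect_var * I).
    """
    rng = _as_rng(rng)
    if n_nonnull > n_tests:
        raise ValueError("n_nonnull cannot exceed n_tests")
    beta = np.zeros((n_tests, t))
    if n_nonnull == 0:
        return beta
    if mode == "shared_unstructured":
        beta[:n_nonnull] = rng.normal(scale=np.sqrt(effect_var), size=(n_nonnull, t))
    elif mode == "shared_structured":
        if not covariances:
            covariances = default_structured_covariances(t, rng)
        chols = [np.linalg.cholesky(U + 1e-12 * np.eye(t)) for U in covariances]
        ks = rng.integers(len(chols), size=n_nonnull)
        w = np.abs(rng.normal(size=n_nonnull))
        z = rng.normal(size=(n_nonnull, t))
        for j in range(n_nonnull):
            beta[j] = np.sqrt(w[j]) * (chols[ks[j]] @ z[j])
    else:
        raise ValueError(f"unknown effect mode {mode!r}")
    return beta


def _correlated_noise(n, t, sigma_g2, sigma_e2, rng) -> np.ndarray:
    g = rng.normal(scale=np.sqrt(sigma_g2), size=(n, 1))
    e = rng.normal(scale=np.sqrt(sigma_e2), size=(n, t))
    return g + e


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
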