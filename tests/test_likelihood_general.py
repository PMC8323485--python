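"""Refactored likelihood pieces against dense linear-algebra oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mclmm import (
    DegenerateResidualError,
    MultiContextData,
    build_group_index,
    fit_general,
    log_det_H,
    neg_loglik,
    residual_terms,
    stack_design,
    xtHx,
)
from mclmm.likelihood_general import block_inverse_entries
from mclmm.oracle import dense_model_from_design, dense_profile_loglik

from conftest import random_instance


def _dense_H(context_counts, delta):
    from scipy.linalg import block_diag

    blocks = [np.ones((t, t)) + delta * np.eye(t) for t in context_counts]
    return block_diag(*blocks)


class TestLogDetH:
    @pytest.mark.parametrize(
        "counts, delta, expected",
        [
            ((1,), 1.0, np.log(2)),
            ((2, 3), 1.0, np.log(12)),
            ((1, 1, 1), 2.0, 3 * np.log(3)),
        ],
    )
    def test_known_values(self, counts, delta, expected):
        assert log_det_H(counts, delta) == pytest.approx(expected, abs=1e-12)

    @given(
        counts=st.lists(st.integers(1, 6), min_size=1, max_size=8),
        delta=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_dense_logdet(self, counts, delta):
        sign, ld = np.linalg.slogdet(_dense_H(counts, delta))
        assert sign > 0
        assert log_det_H(counts, delta) == pytest.approx(ld, abs=1e-9)

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            log_det_H((2, 3), 0.0)


class TestBlockInverse:
    @pytest.mark.parametrize(
        "t_i, delta, diag, off",
        [
            (1, 1.0, 0.5, -0.5),
            (2, 1.0, 2 / 3, -1 / 3),
            # Sherman-Morrison: (1/d)(I - 11'/(t+d)); at delta != 1 the 1/d
            # factor on the rank-one term matters
            (3, 0.5, 2 - 1 / (0.5 * 3.5), -1 / (0.5 * 3.5)),
        ],
    )
    def test_entries(self, t_i, delta, diag, off):
        d, o = block_inverse_entries(t_i, delta)
        assert d == pytest.approx(diag, abs=1e-12)
        if t_i > 1:
            assert o == pytest.approx(off, abs=1e-12)

    @given(t_i=st.integers(1, 10), delta=st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_reconstruction_is_identity(self, t_i, delta):
        d, o = block_inverse_entries(t_i, delta)
        block = np.ones((t_i, t_i)) + delta * np.eye(t_i)
        inv = np.full((t_i, t_i), o) + (d - o) * np.eye(t_i)
        np.testing.assert_allclose(block @ inv, np.eye(t_i), atol=1e-9)


class TestXtHx:
    def test_single_observation(self):
        data = MultiContextData(np.array([[1.0]]), np.ones((1, 1)))
        gi = build_group_index(stack_design(data))
        assert xtHx(gi, 1.0)[0, 0] == pytest.approx(0.5)

    def test_complete_intercept_only(self):
        """Complete data, intercept-only: diagonal n*(diag entries of the
        Kronecker inverse block), off-diagonal by shared-individual terms."""
        n, t, delta = 3, 2, 0.8
        data = MultiContextData(np.zeros((n, t)), np.ones((n, 1)))
        design = stack_design(data)
        gi = build_group_index(design)
        model = dense_model_from_design(design)
        dense = model.X.T @ np.linalg.inv(model.H(delta)) @ model.X
        np.testing.assert_allclose(xtHx(gi, delta), dense, atol=1e-12)

    @pytest.mark.parametrize("delta", [0.1, 2.5, 40.0])
    def test_masked_matches_dense(self, rng, delta):
        data = random_instance(rng, n=6, t=4, c=2, missing=0.35)
        design = stack_design(data)
        gi = build_group_index(design)
        model = dense_model_from_design(design)
        dense = model.X.T @ np.linalg.inv(model.H(delta)) @ model.X
        np.testing.assert_allclose(xtHx(gi, delta), dense, atol=1e-10)


class TestResidualTerms:
    def test_scalar_case(self):
        data = MultiContextData(np.array([[2.0]]), np.ones((1, 1)))
        gi = build_group_index(stack_design(data))
        a, b = residual_terms(gi, 1.0)
        assert a == pytest.approx(2.0)
        assert b[0] == pytest.approx(1.0)  # X'H^-1 y = 0.5 * 2

    def test_two_individuals_antisymmetric(self):
        y = np.array([[1.0, 1.0], [-1.0, -1.0]])
        gi = build_group_index(stack_design(MultiContextData(y, np.ones((2, 1)))))
        a, _ = residual_terms(gi, 1.0)
        assert a == pytest.approx(4 / 3)

    @pytest.mark.parametrize("delta", [0.2, 1.7])
    def test_masked_matches_dense(self, rng, delta):
        data = random_instance(rng, n=7, t=3, c=2, missing=0.3)
        design = stack_design(data)
        gi = build_group_index(design)
        model = dense_model_from_design(design)
        Hinv = np.linalg.inv(model.H(delta))
        a, b = residual_terms(gi, delta)
        assert a == pytest.approx(float(model.y @ Hinv @ model.y), abs=1e-10)
        np.testing.assert_allclose(b, model.X.T @ Hinv @ model.y, atol=1e-10)


class TestNegLoglik:
    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_ordering_matches_dense_likelihood(self, rng, method):
        """Dropping constants must preserve the likelihood ordering in delta."""
        data = random_instance(rng, n=4, t=3, c=1, missing=0.25)
        design = stack_design(data)
        gi = build_group_index(design)
        model = dense_model_from_design(design)
        deltas = [0.1, 1.0, 10.0]
        fast = [-neg_loglik(gi, d, method) for d in deltas]
        dense = [dense_profile_loglik(model, d, method) for d in deltas]
        assert np.argsort(fast).tolist() == np.argsort(dense).tolist()
        # stronger: pairwise differences proportional with factor 1/2
        fd = np.diff(fast)
        dd = np.diff(dense)
        np.testing.assert_allclose(fd, 2 * dd, rtol=1e-6)

    def test_complete_data_agrees_with_closed_form_objective(self, rng):
        from mclmm.closed_form import _profile_obj, per_context_ols, residual_summary, residuals_from_ols

        data = random_instance(rng, n=8, t=3, c=2, missing=0.0)
        gi = build_group_index(stack_design(data))
        beta = per_context_ols(data)
        summ = residual_summary(residuals_from_ols(data, beta), data.n, data.t)
        N, tc = data.n * data.t, data.t * data.c
        deltas = [0.3, 1.0, 4.0]
        diff = [
            -neg_loglik(gi, d, "ML") - _profile_obj(summ, d, "ML", N, tc, data.c)
            for d in deltas
        ]
        assert max(diff) - min(diff) < 1e-8  # equal up to an additive constant

    def test_saturated_design_raises(self):
        # N = tc: one individual, both contexts, intercept per context
        data = MultiContextData(np.array([[1.0, 2.0]]), np.ones((1, 1)))
        gi = build_group_index(stack_design(data))
        with pytest.raises(DegenerateResidualError):
            neg_loglik(gi, 1.0, "REML")


class TestFitGeneral:
    def test_complete_data_matches_closed_form(self, rng):
        from mclmm import fit_complete

        data = random_instance(
            rng, n=200, t=5, c=2, missing=0.0, sigma_g2=0.4, sigma_e2=0.2
        )
        fg = fit_general(data, "ML")
        fc = fit_complete(data, "ML")
        assert fg.delta_hat == pytest.approx(fc.delta_hat, abs=1e-4)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_small_masked_matches_dense_grid(self, rng, method):
        from mclmm.oracle import dense_fit, dense_model

        data = random_instance(rng, n=6, t=3, c=1, missing=0.3)
        fit = fit_general(data, method)
        grid = np.logspace(-5, 5, 1000)
        den = dense_fit(dense_model(data), method, grid=grid)
        # grid spacing is ~2.3% in log space
        assert abs(np.log(fit.delta_hat) - np.log(den.delta_hat)) < np.log(
            grid[1] / grid[0]
        )

    def test_unidentifiable_hits_boundary(self):
        """One observation per individual (K = I): delta is not identified;
        the fit reports the sigma_g2 -> 0 boundary."""
        rng = np.random.default_rng(5)
        y = np.full((8, 2), np.nan)
        ctx = rng.integers(2, size=8)
        y[np.arange(8), ctx] = rng.normal(size=8)
        # ensure both contexts observed
        y[0, 0] = rng.normal()
        y[0, 1] = np.nan
        y[1, 1] = rng.normal()
        y[1, 0] = np.nan
        data = MultiContextData(y, np.ones((8, 1)))
        fit = fit_general(data, "ML")
        assert fit.boundary

    def test_scaling_equivariance(self, rng):
        """y -> s*y scales both variance components by s^2, delta unchanged."""
        data = random_instance(rng, n=10, t=4, c=2, missing=0.3)
        s = 3.7
        scaled = MultiContextData(
            responses=s * data.responses, covariates=data.covariates
        )
        f1 = fit_general(data, "REML")
        f2 = fit_general(scaled, "REML")
        assert f2.delta_hat == pytest.approx(f1.delta_hat, rel=1e-5)
        assert f2.sigma_g2 == pytest.approx(s**2 * f1.sigma_g2, rel=1e-5)
        assert f2.sigma_e2 == pytest.approx(s**2 * f1.sigma_e2, rel=1e-5)

    def test_beta_is_gls_at_delta_hat(self, rng):
        data = random_instance(rng, n=8, t=3, c=2, missing=0.3)
        fit = fit_general(data, "REML")
        from mclmm.oracle import dense_gls, dense_model

        beta, sigma_g2, Ainv = dense_gls(dense_model(data), fit.delta_hat, "REML")
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-8)
        assert fit.sigma_g2 == pytest.approx(sigma_g2, rel=1e-8)
        np.testing.assert_allclose(fit.beta_cov, sigma_g2 * Ainv, atol=1e-8)

    def test_sigma_identity(self, rng):
        data = random_instance(rng, n=9, t=3, c=1, missing=0.2)
        fit = fit_general(data, "REML")
        assert fit.sigma_e2 == pytest.approx(fit.delta_hat * fit.sigma_g2, rel=1e-12)
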