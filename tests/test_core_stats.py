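"""Dense-oracle checks of the Woodbury-based candidate statistics,
posterior, and marginal likelihood, plus fast-path/full-recompute
equivalence of the rank-one updates."""

import numpy as np
import pytest

from eblasso.core import (
    FitConfig,
    Hyperparams,
    ModelState,
    _apply_action,
    _loo_stats,
    candidate_stats,
    cinv_woodbury,
    log_marginal,
    posterior_update,
)

from conftest import dense_design, empty_state, explicit_C


def random_state(rng, n=15, k=8, k_r=3):
    """A consistent ModelState with a random active set."""
    X = dense_design(rng.normal(size=(n, k)))
    y = rng.normal(size=n)
    state = empty_state(y, mu=float(np.mean(y)), sigma0_sq=0.5)
    state.active = list(rng.choice(k, size=k_r, replace=False))
    state.alpha = rng.uniform(0.5, 5.0, size=k_r)
    state.Xr = X.columns(np.array(state.active))
    posterior_update(state, X, y)
    st = candidate_stats(X, y, state)
    state.S, state.Q = st.S, st.Q
    return X, y, state


class TestCandidateStats:
    def test_empty_active_set_closed_form(self, rng):
        X = dense_design(rng.normal(size=(10, 4)))
        y = rng.normal(size=10)
        state = empty_state(y, mu=1.0, sigma0_sq=2.0)
        st = candidate_stats(X, y, state)
        cols = X.columns(np.arange(4))
        assert np.allclose(st.S, np.einsum("ij,ij->j", cols, cols) / 2.0)
        assert np.allclose(st.Q, cols.T @ (y - 1.0) / 2.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_definitions(self, rng, trial):
        n, k, k_r = 15 + trial, 10, 2 + trial % 3
        X, y, state = random_state(rng, n=n, k=k, k_r=k_r)
        st = candidate_stats(X, y, state)
        C = explicit_C(state.Xr, state.alpha, state.sigma0_sq, n)
        Ci = np.linalg.inv(C)
        yh = y - state.mu
        cols = X.columns(np.arange(k))
        for i in range(k):
            assert st.S[i] == pytest.approx(cols[:, i] @ Ci @ cols[:, i], rel=1e-8)
            assert st.Q[i] == pytest.approx(cols[:, i] @ Ci @ yh, rel=1e-8)
        # leave-one-out factors against the explicit C_{-i} definition
        for loc, i in enumerate(state.active):
            Cmi = C - np.outer(state.Xr[:, loc], state.Xr[:, loc]) / state.alpha[loc]
            Cmi_inv = np.linalg.inv(Cmi)
            assert st.s[i] == pytest.approx(cols[:, i] @ Cmi_inv @ cols[:, i], rel=1e-6)
            assert st.q[i] == pytest.approx(cols[:, i] @ Cmi_inv @ yh, rel=1e-6)

    def test_inactive_loo_equals_full(self, rng):
        X, y, state = random_state(rng)
        st = candidate_stats(X, y, state)
        inactive = [i for i in range(X.k) if i not in state.active]
        assert np.array_equal(st.s[inactive], st.S[inactive])
        assert np.array_equal(st.q[inactive], st.Q[inactive])

    def test_nonpositive_sigma_rejected(self, rng):
        X = dense_design(rng.normal(size=(8, 3)))
        y = rng.normal(size=8)
        state = empty_state(y, mu=0.0, sigma0_sq=-1.0)
        with pytest.raises(ValueError, match="sigma0_sq"):
            candidate_stats(X, y, state)


class TestWoodburyInverse:
    def test_empty_model_is_division(self, rng):
        y = rng.normal(size=6)
        state = empty_state(y, mu=0.0, sigma0_sq=4.0)
        apply_cinv = cinv_woodbury(state)
        v = rng.normal(size=6)
        assert np.allclose(apply_cinv(v), v / 4.0)

    def test_matches_dense_inverse(self, rng):
        X, y, state = random_state(rng, n=15, k=8, k_r=3)
        apply_cinv = cinv_woodbury(state)
        C = explicit_C(state.Xr, state.alpha, state.sigma0_sq, 15)
        for _ in range(3):
            v = rng.normal(size=15)
            assert np.allclose(apply_cinv(v), np.linalg.solve(C, v), rtol=1e-8, atol=1e-10)

    def test_rank_one_sherman_morrison_eigenvalue(self, rng):
        # one active orthonormal column x with precision alpha:
        # C^-1 x = x / (sigma0^2 + 1/alpha)
        n, alpha, sig = 12, 3.0, 0.7
        x = rng.normal(size=n)
        x /= np.linalg.norm(x)
        y = rng.normal(size=n)
        state = empty_state(y, mu=0.0, sigma0_sq=sig)
        state.active = [0]
        state.alpha = np.array([alpha])
        state.Xr = x[:, None]
        posterior_update(state, dense_design(x[:, None]), y)
        out = cinv_woodbury(state)(x)
        assert np.allclose(out, x / (sig + 1.0 / alpha))


class TestPosterior:
    def test_single_column_scalar_formula(self, rng):
        n, alpha, sig = 20, 2.0, 0.3
        x = rng.normal(size=n)
        c = float(x @ x)
        y = rng.normal(size=n)
        state = empty_state(y, mu=0.0, sigma0_sq=sig)
        state.active = [0]
        state.alpha = np.array([alpha])
        state.Xr = x[:, None]
        posterior_update(state, dense_design(x[:, None]), y)
        assert state.Sigma[0, 0] == pytest.approx(1.0 / (alpha + c / sig))

    def test_infinite_penalty_zeroes_mean(self, rng):
        x = rng.normal(size=25)
        y = 2 * x + rng.normal(size=25)
        state = empty_state(y, mu=0.0, sigma0_sq=1.0)
        state.active = [0]
        state.alpha = np.array([1e14])
        state.Xr = x[:, None]
        posterior_update(state, dense_design(x[:, None]), y)
        assert abs(state.u[0]) < 1e-9

    def test_matches_penalized_normal_equations(self, rng):
        n, k_r = 30, 4
        Xr = rng.normal(size=(n, k_r))
        alpha = rng.uniform(0.5, 3.0, size=k_r)
        y = rng.normal(size=n)
        mu, sig = 0.4, 0.8
        state = empty_state(y, mu=mu, sigma0_sq=sig)
        state.active = list(range(k_r))
        state.alpha = alpha
        state.Xr = Xr
        posterior_update(state, dense_design(Xr), y)
        P = np.diag(alpha) + Xr.T @ Xr / sig
        u_expected = np.linalg.solve(P, Xr.T @ (y - mu) / sig)
        assert np.allclose(state.u, u_expected)
        assert np.allclose(state.Sigma, np.linalg.inv(P))


class TestLogMarginal:
    def test_empty_model_gaussian_density(self, rng):
        y = rng.normal(size=10)
        state = empty_state(y, mu=0.5, sigma0_sq=2.0)
        h = Hyperparams(0.1, 0.1)
        expected = -0.5 * (10 * np.log(2 * np.pi * 2.0) + np.sum((y - 0.5) ** 2) / 2.0)
        assert log_marginal(state, dense_design(np.empty((10, 0))), y, h) == pytest.approx(expected)

    @pytest.mark.parametrize("a,b", [(-1.0, 1.0), (0.1, 0.1), (-0.75, 0.1)])
    def test_matches_explicit_C_evaluation(self, rng, a, b):
        n = 12
        X, y, state = random_state(rng, n=n, k=6, k_r=2)
        h = Hyperparams(a, b)
        C = explicit_C(state.Xr, state.alpha, state.sigma0_sq, n)
        yh = y - state.mu
        sign, logdet = np.linalg.slogdet(C)
        expected = -0.5 * (n * np.log(2 * np.pi) + logdet + yh @ np.linalg.solve(C, yh))
        if a != -1.0:
            expected -= (a + 1.0) * np.sum(np.log1p(1.0 / (state.alpha * b)))
        assert log_marginal(state, X, y, h) == pytest.approx(expected, rel=1e-8)


class TestRankOneFastPath:
    def test_sequence_of_actions_equals_full_recompute(self, rng):
        """Incremental Sigma/u/S/Q after add, re-estimate and delete must
        equal a from-scratch recomputation."""
        n, k = 25, 9
        X = dense_design(rng.normal(size=(n, k)))
        y = rng.normal(size=n)
        state = empty_state(y, mu=float(y.mean()), sigma0_sq=0.6)
        st = candidate_stats(X, y, state)
        state.S, state.Q = st.S, st.Q
        actions = [(2, 1.5), (5, 0.8), (2, 3.0), (7, 2.2), (5, np.inf)]  # add, add, re-est, add, delete
        for j, a_new in actions:
            _apply_action(state, X, j, a_new)
            S_inc, Q_inc = state.S.copy(), state.Q.copy()
            Sig_inc, u_inc = state.Sigma.copy(), state.u.copy()
            posterior_update(state, X, y)
            st = candidate_stats(X, y, state)
            assert np.allclose(Sig_inc, state.Sigma, rtol=1e-9, atol=1e-12)
            assert np.allclose(u_inc, state.u, rtol=1e-9, atol=1e-12)
            assert np.allclose(S_inc, st.S, rtol=1e-8, atol=1e-10)
            assert np.allclose(Q_inc, st.Q, rtol=1e-8, atol=1e-10)
            state.S, state.Q = st.S, st.Q
        assert state.active == [2, 7]
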