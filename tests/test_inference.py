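import numpy as np
import pytest
from scipy.optimize import minimize

from vblmf.inference import (
    FactorPosterior,
    GammaPosterior,
    bounded_elbo,
    fit,
    second_moment_products,
    update_factor,
    update_gamma,
    update_xi,
)
from vblmf.kernels import Kernel, KernelSet, graph_precision, identity_kernelset
from vblmf.model import (
    Hyperparameters,
    InteractionData,
    jaakkola_coefficient,
    likelihood_aux,
)


def diag_posterior(mean, variances):
    """FactorPosterior with diagonal covariance from per-coordinate variances."""
    mean = np.asarray(mean, dtype=float)
    v = np.asarray(variances, dtype=float).T.reshape(-1)  # vec index i*L + l
    return FactorPosterior(mean=mean, covariance=np.diag(v),
                           precision=np.diag(1.0 / v))


def random_kernelset(n, n_kernels, rng, side):
    mats = []
    for _ in range(n_kernels):
        A = rng.random((n, n))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        mats.append(S)
    ids = tuple(f"{side[0]}{i}" for i in range(n))
    return KernelSet(tuple(Kernel(f"k{i}", S, ids) for i, S in enumerate(mats)), side)


def make_data(R):
    R = np.array(R, dtype=float)
    I, J = R.shape
    return InteractionData(R, tuple(f"d{i}" for i in range(I)),
                           tuple(f"t{j}" for j in range(J)))


class TestFactorUpdate:
    def test_no_observations_returns_prior(self):
        data = make_data(np.zeros((3, 2)))  # all masks 0
        aux = likelihood_aux(data, 10.0, np.ones((3, 2)))
        L = 2
        rng = np.random.default_rng(0)
        Q = graph_precision(random_kernelset(3, 1, rng, "drug"), [1.0], 0.5)
        other = diag_posterior(rng.normal(size=(L, 2)), np.full((L, 2), 0.3))
        post = update_factor(aux, Q, other, "drug", L)
        assert np.allclose(post.mean, 0.0)
        assert np.allclose(post.precision, np.kron(Q, np.eye(L)))

    def test_scalar_closed_form(self):
        # 1 drug x 1 target, L = 1, fixed E[v] = E[v^2] = 1, R = 1, c = 1, xi = 1
        data = make_data([[1.0]])
        alpha = 0.7
        aux = likelihood_aux(data, 1.0, np.array([[1.0]]))
        other = FactorPosterior(mean=np.array([[1.0]]),
                                covariance=np.zeros((1, 1)) + 1e-30,
                                precision=np.eye(1) * 1e30)
        Q = np.array([[alpha]])
        post = update_factor(aux, Q, other, "drug", 1)
        lam = alpha - 2.0 * jaakkola_coefficient(1.0) * 1.0
        assert post.precision[0, 0] == pytest.approx(lam, abs=1e-12)
        assert post.mean[0, 0] == pytest.approx(0.5 / lam, rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_mean_matches_numeric_maximizer(self, seed):
        # generic-optimizer oracle for the completed-square Gaussian update;
        # arbitrates the linear-term sign and the prior-precision constant
        rng = np.random.default_rng(seed)
        I, J, L = 3, 2, 2
        R = (rng.random((I, J)) < 0.5).astype(float)
        R[0, 0] = 1.0  # keep masks non-degenerate
        data = make_data(R)
        xi = rng.random((I, J)) * 3
        c = 10.0
        aux = likelihood_aux(data, c, xi)
        ks = random_kernelset(I, 2, rng, "drug")
        Q = graph_precision(ks, rng.random(2), 0.4)
        Ev = rng.normal(size=(L, J))
        Vv = rng.random((L, J)) * 0.5 + 0.05
        other = diag_posterior(Ev, Vv)
        Sv = other.second_moments

        def neg_objective(x):
            U = x.reshape(I, L).T
            val = 0.0
            for i in range(I):
                for j in range(J):
                    val += aux.R_prime[i, j] * U[:, i] @ Ev[:, j]
                    val += (aux.R_hat[i, j] * aux.xi_hat[i, j]
                            * U[:, i] @ Sv[j] @ U[:, i])
            val -= 0.5 * np.einsum("li,ik,lk->", U, Q, U)
            return -val

        post = update_factor(aux, Q, other, "drug", L)
        x0 = np.zeros(I * L)
        res = minimize(neg_objective, x0, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        assert np.max(np.abs(post.mean.T.reshape(-1) - res.x)) < 1e-6

    def test_target_side_swaps_roles(self):
        rng = np.random.default_rng(4)
        data = make_data([[1, 0, 1], [0, 1, 0]])
        aux = likelihood_aux(data, 5.0, np.ones((2, 3)))
        L = 2
        Q = graph_precision(random_kernelset(3, 1, rng, "target"), [0.5], 0.2)
        other = diag_posterior(rng.normal(size=(L, 2)), np.full((L, 2), 0.1))
        post = update_factor(aux, Q, other, "target", L)
        assert post.mean.shape == (L, 3)
        # PD precision (xi_hat <= 0 keeps the correction PSD)
        assert np.linalg.eigvalsh(post.precision).min() > 0


class TestXiUpdate:
    def test_deterministic_factors(self):
        mu_u = np.array([[1.0, -2.0], [0.5, 0.0]])
        mu_v = np.array([[2.0], [1.0]])
        U = diag_posterior(mu_u, np.full((2, 2), 1e-30))
        V = diag_posterior(mu_v, np.full((2, 1), 1e-30))
        xi = update_xi(U, V)
        assert np.allclose(xi, np.abs(mu_u.T @ mu_v), atol=1e-9)

    def test_zero_mean_unit_variance(self):
        U = diag_posterior(np.zeros((2, 1)), np.ones((2, 1)))
        V = diag_posterior(np.zeros((2, 1)), np.ones((2, 1)))
        assert update_xi(U, V)[0, 0] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_matches_monte_carlo_second_moment(self):
        rng = np.random.default_rng(11)
        L = 2
        mu_u = rng.normal(size=(L, 1))
        mu_v = rng.normal(size=(L, 1))
        var_u = rng.random((L, 1)) + 0.2
        var_v = rng.random((L, 1)) + 0.2
        U = diag_posterior(mu_u, var_u)
        V = diag_posterior(mu_v, var_v)
        xi2 = update_xi(U, V)[0, 0] ** 2
        n = 100_000
        us = mu_u.ravel() + rng.normal(size=(n, L)) * np.sqrt(var_u.ravel())
        vs = mu_v.ravel() + rng.normal(size=(n, L)) * np.sqrt(var_v.ravel())
        samples = np.sum(us * vs, axis=1) ** 2
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - xi2) < 3 * se


class TestGammaUpdate:
    def test_shape_depends_only_on_size(self):
        post = diag_posterior(np.zeros((2, 4)), np.full((2, 4), 1e-30))
        ks = identity_kernelset(("a", "b", "c", "d"), "drug")
        g = update_gamma(post, ks, a=1.0, b=5.0)
        assert g.shape[0] == pytest.approx(9.0)  # 1 + 16/2

    def test_identical_factors_leave_rate_at_prior(self):
        mean = np.tile(np.array([[1.5], [-0.5]]), (1, 3))
        post = diag_posterior(mean, np.full((2, 3), 1e-30))
        ones = KernelSet((Kernel("o", np.ones((3, 3)), ("a", "b", "c")),), "drug")
        g = update_gamma(post, ones, a=1.0, b=7.0)
        assert g.rate[0] == pytest.approx(7.0, abs=1e-12)

    def test_explicit_ordered_pair_sum(self):
        # I = 2, L = 1, u = [0, 2], K all-ones: b' = b + (1/2)(4 + 4)
        post = diag_posterior(np.array([[0.0, 2.0]]), np.full((1, 2), 1e-30))
        ones = KernelSet((Kernel("o", np.ones((2, 2)), ("a", "b")),), "drug")
        g = update_gamma(post, ones, a=1.0, b=3.0)
        assert g.rate[0] == pytest.approx(7.0, abs=1e-10)

    def test_rate_matches_monte_carlo_expectation(self, fitted_small):
        # sample vec(U) from a *full-covariance* posterior of a real fit,
        # restricted to a 4-drug instance for speed
        rng = np.random.default_rng(5)
        state = fit(
            make_data((rng.random((4, 5)) < 0.4).astype(float)),
            random_kernelset(4, 1, rng, "drug"),
            random_kernelset(5, 1, rng, "target"),
            Hyperparameters(L=2, iterations=5, seed=3),
            record="none",
        )
        post = state.U_post
        K = state.drug_kernels.kernels[0].S
        b = 2.0
        g = update_gamma(post, state.drug_kernels, a=1.0, b=b)
        n = 100_000
        chol = np.linalg.cholesky(post.covariance)
        z = rng.normal(size=(n, post.covariance.shape[0]))
        X = post.mean.T.reshape(-1) + z @ chol.T
        L, I = post.L, post.n
        us = X.reshape(n, I, L)
        d2 = np.sum((us[:, :, None, :] - us[:, None, :, :]) ** 2, axis=-1)
        vals = 0.5 * np.einsum("ik,nik->n", K, d2)
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - (g.rate[0] - b)) < 3 * se


class TestFit:
    def test_elbo_monotone_within_tolerance(self):
        rng = np.random.default_rng(21)
        for seed in range(3):
            data = make_data((rng.random((10, 8)) < 0.3).astype(float))
            ku = random_kernelset(10, 1, rng, "drug")
            kv = random_kernelset(8, 1, rng, "target")
            st = fit(data, ku, kv, Hyperparameters(L=3, iterations=8, seed=seed),
                     record="update")
            tr = np.array(st.elbo_trace)
            drops = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1.0)
            assert drops.min() > -1e-6

    def test_same_seed_bitwise_identical(self, small_scenario):
        hyper = Hyperparameters(L=3, iterations=4, seed=12)
        s1 = fit(small_scenario.data, small_scenario.drug_kernels,
                 small_scenario.target_kernels, hyper)
        s2 = fit(small_scenario.data, small_scenario.drug_kernels,
                 small_scenario.target_kernels, hyper)
        assert np.array_equal(s1.U_post.mean, s2.U_post.mean)
        assert np.array_equal(s1.V_post.mean, s2.V_post.mean)
        assert s1.elbo_trace == s2.elbo_trace

    def test_prior_dominated_limit_shrinks_to_half(self):
        rng = np.random.default_rng(2)
        data = make_data((rng.random((6, 5)) < 0.4).astype(float))
        st = fit(data, identity_kernelset(data.drug_ids, "drug"),
                 identity_kernelset(data.target_ids, "target"),
                 Hyperparameters(L=2, c=1.0, alpha_u=1e3, alpha_v=1e3,
                                 iterations=10, seed=0),
                 record="none")
        P = 1.0 / (1.0 + np.exp(-(st.U_post.mean.T @ st.V_post.mean)))
        assert np.allclose(P, 0.5, atol=0.01)

    def test_importance_weight_raises_positive_probabilities(self):
        rng = np.random.default_rng(9)
        data = make_data((rng.random((8, 6)) < 0.3).astype(float))
        ku = identity_kernelset(data.drug_ids, "drug")
        kv = identity_kernelset(data.target_ids, "target")
        probs = []
        for c in (1.0, 5.0, 20.0):
            st = fit(data, ku, kv,
                     Hyperparameters(L=2, c=c, iterations=10, seed=0),
                     record="none")
            P = 1.0 / (1.0 + np.exp(-(st.U_post.mean.T @ st.V_post.mean)))
            probs.append(P[data.R == 1].mean())
        assert probs[0] < probs[1] < probs[2]

    def test_good_fit_on_generative_data(self, small_scenario, fitted_small):
        from vblmf import auroc, predict_probabilities

        P = predict_probabilities(fitted_small).P
        assert auroc(P.ravel(), small_scenario.data.R.ravel()) > 0.95

    def test_precisions_remain_pd(self, fitted_small):
        for post in (fitted_small.U_post, fitted_small.V_post):
            assert np.linalg.eigvalsh(post.precision).min() > 0

    def test_second_moment_identity(self, fitted_small):
        post = fitted_small.U_post
        S = post.second_moments
        i = 2
        L = post.L
        block = post.covariance[i * L:(i + 1) * L, i * L:(i + 1) * L]
        expected = block + np.outer(post.mean[:, i], post.mean[:, i])
        assert np.allclose(S[i], expected, atol=1e-12)


class TestGammaPosterior:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            GammaPosterior(np.array([0.0]), np.array([1.0]))

    def test_moments(self):
        g = GammaPosterior(np.array([4.0]), np.array([2.0]))
        assert g.mean[0] == pytest.approx(2.0)
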