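"""Mean-field variational inference for kernel-regularized logistic MF.

The variational family factorizes as q(U) q(V) q(gamma_u) q(gamma_v) with
full Gaussians over vec(U) and vec(V) (columns stacked) and independent
Gamma factors over the kernel weights.  Each coordinate update is the
exact maximizer of the Jaakkola-bounded evidence lower bound:

* q(U): Gaussian with precision
      Lambda = Q (x) I_L  -  2 * blkdiag_i( sum_j R_hat_ij xi_hat_ij E[v_j v_j^T] )
  and mean Lambda^{-1} vec_i( sum_j R_prime_ij E[v_j] ),
  where Q = 2 sum_n E[gamma_n] (D_n - K_n) + alpha I is the prior precision
  per latent dimension.  Since xi_hat <= 0 and R_hat >= 0 the likelihood
  correction is PSD, so Lambda stays positive definite.
* xi_ij^2 = E[(u_i^T v_j)^2] = tr(E[u_i u_i^T] E[v_j v_j^T]) (mean-field
  independence of u and v makes the trace form exact; it reduces to the
  marginal-variance expansion when within-column covariance is diagonal).
* q(gamma_n) = Gamma(a + I^2/2, b + E[sum_ik K_ik ||u_i - u_k||^2]/2);
  the shape offset I^2/2 corresponds to one gamma^(1/2) pseudo-normalizer
  factor per ordered pair in the Laplacian prior, and the same
  pseudo-normalized prior is used in the bounded ELBO so the Gamma step is
  its exact coordinate maximizer.

Monotone non-decrease of the bounded ELBO after every single update is the
central correctness oracle of the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln

from .kernels import KernelSet, graph_precision
from .model import (
    Hyperparameters,
    InteractionData,
    LikelihoodAux,
    likelihood_aux,
    log_sigmoid,
)

logger = logging.getLogger(__name__)

EIG_FLOOR = 1e-10


class NumericalError(RuntimeError):
    """Raised when an update produces a non-PD precision or non-finite values."""


# ---------------------------------------------------------------------------
# posterior containers


@dataclass(frozen=True)
class FactorPosterior:
    """Gaussian posterior over vec(X) for an L x n factor matrix X.

    vec stacks the columns x_1, ..., x_n, so element index is i*L + l.
    """

    mean: np.ndarray        # (L, n): columns are E[x_i]
    covariance: np.ndarray  # (L*n, L*n)
    precision: np.ndarray   # (L*n, L*n)

    @property
    def L(self) -> int:
        return self.mean.shape[0]

    @property
    def n(self) -> int:
        return self.mean.shape[1]

    @property
    def second_moments(self) -> np.ndarray:
        """(n, L, L) array of E[x_i x_i^T] = Cov(x_i) + E[x_i]E[x_i]^T."""
        L, n = self.L, self.n
        cov4 = self.covariance.reshape(n, L, n, L)
        diag_blocks = np.einsum("iaib->iab", cov4)
        outer = np.einsum("ai,bi->iab", self.mean, self.mean)
        return diag_blocks + outer

    @property
    def cross_traces(self) -> np.ndarray:
        """(n, n) matrix of E[x_i^T x_k] = tr Cov(x_i, x_k) + E[x_i]^T E[x_k]."""
        L, n = self.L, self.n
        cov4 = self.covariance.reshape(n, L, n, L)
        return np.einsum("iaka->ik", cov4) + self.mean.T @ self.mean

    def marginal_variances(self) -> np.ndarray:
        """(L, n) per-coordinate variances from the covariance diagonal."""
        return np.diag(self.covariance).reshape(self.n, self.L).T


@dataclass(frozen=True)
class GammaPosterior:
    """Independent Gamma posteriors over the weights of one kernel set."""

    shape: np.ndarray  # (n_kernels,)
    rate: np.ndarray   # (n_kernels,)

    def __post_init__(self) -> None:
        shape = np.atleast_1d(np.asarray(self.shape, dtype=float))
        rate = np.atleast_1d(np.asarray(self.rate, dtype=float))
        if np.any(shape <= 0) or np.any(rate <= 0):
            raise ValueError("Gamma parameters must be strictly positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "rate", rate)

    @property
    def mean(self) -> np.ndarray:
        return self.shape / self.rate

    @property
    def mean_log(self) -> np.ndarray:
        return digamma(self.shape) - np.log(self.rate)

    @property
    def entropy(self) -> float:
        a, b = self.shape, self.rate
        return float(np.sum(a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)))


@dataclass(frozen=True)
class VariationalState:
    """Full variational state of a fit (posteriors, auxiliaries, trace)."""

    data: InteractionData
    hyper: Hyperparameters
    drug_kernels: KernelSet
    target_kernels: KernelSet
    U_post: FactorPosterior
    V_post: FactorPosterior
    gamma_u: GammaPosterior
    gamma_v: GammaPosterior
    aux: LikelihoodAux
    elbo_trace: tuple[float, ...] = ()

    def replace(self, **kw) -> "VariationalState":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# coordinate updates


def _solve_gaussian(Lam: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of N(mu, Lam^{-1}) with mu = Lam^{-1} r.

    Cholesky first; on failure, symmetric eigendecomposition with the
    eigenvalue floor ``1e-10``.
    """
    dim = Lam.shape[0]
    try:
        cf = cho_factor(Lam, lower=True, check_finite=False)
        cov = cho_solve(cf, np.eye(dim), check_finite=False)
        mu = cho_solve(cf, r, check_finite=False)
    except np.linalg.LinAlgError as exc:
        w, E = np.linalg.eigh(Lam)
        bad = float(w.min())
        if bad <= 0:
            logger.warning("precision not PD (min eigenvalue %.3g); flooring", bad)
        w = np.maximum(w, EIG_FLOOR)
        cov = (E / w) @ E.T
        mu = cov @ r
        if not np.all(np.isfinite(mu)):
            raise NumericalError(
                f"Gaussian solve failed (min eigenvalue {bad:.3g})"
            ) from exc
    cov = 0.5 * (cov + cov.T)
    return mu, cov


def update_factor(
    aux: LikelihoodAux,
    Q_total: np.ndarray,
    other: FactorPosterior,
    side: str,
    L: int,
) -> FactorPosterior:
    """Closed-form Gaussian update for one side's factor posterior.

    ``side='drug'`` updates q(vec(U)) given q(V)'s moments; ``side='target'``
    updates q(vec(V)) with the roles of rows and columns exchanged.
    """
    if side == "drug":
        R_hat, R_prime = aux.R_hat, aux.R_prime
        W = R_hat * aux.xi_hat
    elif side == "target":
        R_hat, R_prime = aux.R_hat.T, aux.R_prime.T
        W = R_hat * aux.xi_hat.T
    else:
        raise ValueError(f"side must be 'drug' or 'target', got {side!r}")
    n = R_hat.shape[0]
    if Q_total.shape != (n, n):
        raise ValueError(f"Q_total shape {Q_total.shape} does not match {n} entities")
    S_other = other.second_moments  # (m, L, L)
    B = np.einsum("ij,jab->iab", W, S_other)  # (n, L, L), PSD * nonpositive
    Lam = np.kron(Q_total, np.eye(L))
    for i in range(n):
        sl = slice(i * L, (i + 1) * L)
        Lam[sl, sl] -= 2.0 * B[i]
    r_mat = other.mean @ R_prime.T  # (L, n)
    r = r_mat.T.reshape(-1)  # vec with index i*L + l
    mu, cov = _solve_gaussian(Lam, r)
    mean = mu.reshape(n, L).T
    if not np.all(np.isfinite(mean)):
        raise NumericalError(f"non-finite factor mean in {side} update")
    return FactorPosterior(mean=mean, covariance=cov, precision=Lam)


def update_xi(U_post: FactorPosterior, V_post: FactorPosterior) -> np.ndarray:
    """Optimal local parameters: xi_ij = sqrt(E[(u_i^T v_j)^2])."""
    Z2 = second_moment_products(U_post, V_post)
    neg = Z2 < 0
    if np.any(neg):
        logger.warning("clamping %d negative second moments to 0", int(neg.sum()))
        Z2 = np.where(neg, 0.0, Z2)
    return np.sqrt(Z2)


def second_moment_products(
    U_post: FactorPosterior, V_post: FactorPosterior
) -> np.ndarray:
    """(I, J) matrix of E[(u_i^T v_j)^2] = tr(E[u_i u_i^T] E[v_j v_j^T])."""
    return np.einsum("iab,jab->ij", U_post.second_moments, V_post.second_moments)


def laplacian_quadratic_expectations(
    post: FactorPosterior, kernels: KernelSet
) -> np.ndarray:
    """Per kernel n: E[ sum_i sum_k K_n,ik ||x_i - x_k||^2 ] over ordered pairs."""
    T = post.cross_traces
    d = np.diag(T)
    pair = d[:, None] + d[None, :] - 2.0 * T
    return np.array([float(np.sum(k.S * pair)) for k in kernels])


def update_gamma(
    post: FactorPosterior, kernels: KernelSet, a: float, b: float
) -> GammaPosterior:
    """Conjugate Gamma update: shape a + n^2/2, rate b + E[pair penalty]/2."""
    n = post.n
    P = laplacian_quadratic_expectations(post, kernels)
    rate = b + 0.5 * P
    if np.any(rate <= 0):
        raise NumericalError(
            "nonpositive Gamma rate: covariance corrupted (Laplacian "
            "expectation should be nonnegative)"
        )
    shape = np.full(len(kernels), a + n**2 / 2.0)
    return GammaPosterior(shape=shape, rate=rate)


# ---------------------------------------------------------------------------
# bounded evidence lower bound


def _gaussian_entropy(cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise NumericalError("covariance has nonpositive determinant")
    dim = cov.shape[0]
    return 0.5 * logdet + 0.5 * dim * (1.0 + np.log(2.0 * np.pi))


def _prior_terms(
    post: FactorPosterior, kernels: KernelSet, gamma: GammaPosterior, alpha: float,
    a: float, b: float,
) -> float:
    """E_q[ln p~(X | gamma)] + E_q[ln p(gamma)] for one side (pseudo-normalized
    Laplacian prior, so the Gamma update is its exact maximizer)."""
    n = post.n
    P = laplacian_quadratic_expectations(post, kernels)
    e_ln_prior_x = float(
        np.sum((n**2 / 2.0) * gamma.mean_log - 0.5 * gamma.mean * P)
    ) - 0.5 * alpha * float(np.trace(post.cross_traces))
    e_ln_prior_g = float(
        np.sum(a * np.log(b) - gammaln(a) + (a - 1.0) * gamma.mean_log
               - b * gamma.mean)
    )
    return e_ln_prior_x + e_ln_prior_g


def bounded_elbo(state: VariationalState) -> float:
    """The Jaakkola-bounded evidence lower bound of the current state.

    Used for convergence monitoring and as the monotonicity oracle; every
    coordinate update must not decrease it (up to numerical tolerance).
    """
    aux = state.aux
    hy = state.hyper
    mu = state.U_post.mean.T @ state.V_post.mean
    Z2 = second_moment_products(state.U_post, state.V_post)
    lik = float(
        np.sum(
            aux.R_hat * (log_sigmoid(aux.xi) - aux.xi / 2.0 - aux.xi_hat * aux.xi**2)
            + aux.R_prime * mu
            + aux.R_hat * aux.xi_hat * Z2
        )
    )
    pri_u = _prior_terms(state.U_post, state.drug_kernels, state.gamma_u,
                         hy.alpha_u, hy.a, hy.b)
    pri_v = _prior_terms(state.V_post, state.target_kernels, state.gamma_v,
                         hy.alpha_v, hy.a, hy.b)
    ent = (
        _gaussian_entropy(state.U_post.covariance)
        + _gaussian_entropy(state.V_post.covariance)
        + state.gamma_u.entropy
        + state.gamma_v.entropy
    )
    return lik + pri_u + pri_v + ent


# ---------------------------------------------------------------------------
# the fitting loop


def _prior_posterior(Q: np.ndarray, mean: np.ndarray) -> FactorPosterior:
    """Gaussian with the prior covariance (inverse of Q per dimension) and a
    given mean — the initialization of each factor posterior."""
    L, n = mean.shape
    _, Qinv = _solve_gaussian(Q, np.zeros(n))
    cov = np.kron(Qinv, np.eye(L))
    prec = np.kron(Q, np.eye(L))
    return FactorPosterior(mean=mean, covariance=cov, precision=prec)


def fit(
    data: InteractionData,
    drug_kernels: KernelSet,
    target_kernels: KernelSet,
    hyper: Hyperparameters,
    record: str = "sweep",
) -> VariationalState:
    """Run the full variational sweep schedule and return the final state.

    Each sweep performs: update xi -> update q(U) -> update xi ->
    update q(V) -> update q(gamma_u) -> update q(gamma_v).  Kernels are
    neighbor-truncated with ``hyper.neighbors`` (idempotent, so
    pre-truncated kernels pass through unchanged).  Deterministic given
    ``hyper.seed``.

    Parameters
    ----------
    record
        ``'sweep'`` stores one ELBO value per sweep, ``'update'`` one per
        coordinate update (six per sweep; used by the monotonicity tests),
        ``'none'`` disables the trace.
    """
    if record not in ("sweep", "update", "none"):
        raise ValueError(f"record must be sweep|update|none, got {record!r}")
    I, J = data.shape
    if len(drug_kernels.ids) != I or len(target_kernels.ids) != J:
        raise ValueError("kernel ids do not match interaction matrix shape")
    ku = drug_kernels.truncated(hyper.neighbors)
    kv = target_kernels.truncated(hyper.neighbors)
    L = hyper.L
    rng = np.random.default_rng(hyper.seed)
    n_ku, n_kv = len(ku), len(kv)
    gamma_u = GammaPosterior(np.full(n_ku, hyper.a), np.full(n_ku, hyper.b))
    gamma_v = GammaPosterior(np.full(n_kv, hyper.a), np.full(n_kv, hyper.b))
    Q_u = graph_precision(ku, gamma_u.mean, hyper.alpha_u)
    Q_v = graph_precision(kv, gamma_v.mean, hyper.alpha_v)
    U_post = _prior_posterior(Q_u, rng.standard_normal((L, I)) / np.sqrt(L))
    V_post = _prior_posterior(Q_v, rng.standard_normal((L, J)) / np.sqrt(L))
    xi = update_xi(U_post, V_post)
    aux = likelihood_aux(data, hyper.c, xi)
    state = VariationalState(
        data=data, hyper=hyper, drug_kernels=ku, target_kernels=kv,
        U_post=U_post, V_post=V_post, gamma_u=gamma_u, gamma_v=gamma_v,
        aux=aux,
    )
    trace: list[float] = []

    def _record(st: VariationalState, every_update: bool) -> None:
        if record == "update" or (record == "sweep" and not every_update):
            trace.append(bounded_elbo(st))

    for sweep in range(hyper.iterations):
        # xi then U
        xi = update_xi(state.U_post, state.V_post)
        state = state.replace(aux=likelihood_aux(data, hyper.c, xi))
        _record(state, True)
        Q_u = graph_precision(ku, state.gamma_u.mean, hyper.alpha_u)
        U_post = update_factor(state.aux, Q_u, state.V_post, "drug", L)
        state = state.replace(U_post=U_post)
        _record(state, True)
        # xi then V
        xi = update_xi(state.U_post, state.V_post)
        state = state.replace(aux=likelihood_aux(data, hyper.c, xi))
        _record(state, True)
        Q_v = graph_precision(kv, state.gamma_v.mean, hyper.alpha_v)
        V_post = update_factor(state.aux, Q_v, state.U_post, "target", L)
        state = state.replace(V_post=V_post)
        _record(state, True)
        # kernel weights
        state = state.replace(
            gamma_u=update_gamma(state.U_post, ku, hyper.a, hyper.b))
        _record(state, True)
        state = state.replace(
            gamma_v=update_gamma(state.V_post, kv, hyper.a, hyper.b))
        _record(state, True)
        if record == "sweep":
            _record(state, False)
        if not np.isfinite(trace[-1] if trace else 0.0):
            raise NumericalError(f"non-finite ELBO after sweep {sweep}")
        if trace:
            logger.debug(
                "sweep %d: elbo=%.6f gamma_u=%s gamma_v=%s",
                sweep, trace[-1],
                np.round(state.gamma_u.mean, 4), np.round(state.gamma_v.mean, 4),
            )
    return state.replace(elbo_trace=tuple(trace))
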