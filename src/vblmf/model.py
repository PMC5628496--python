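"""Probabilistic model data structures and likelihood auxiliaries.

The observation model is a positive-importance-weighted Bernoulli on each
cell of the binary interaction matrix R (I drugs x J targets):

    p(R | U, V) ∝ prod_ij [ sigma(u_i^T v_j)^(c R_ij)
                            (1 - sigma(u_i^T v_j))^(1 - R_ij) ]^(m_u_i m_v_j)

with importance weight c >= 1 on observed positives and binary masks m_u,
m_v that switch off the likelihood for empty rows/columns of the training
matrix (their factors are then informed by the kernel prior alone).

The logistic likelihood is made conjugate to the Gaussian factor prior via
the Jaakkola bound

    sigma(z) >= sigma(xi) * exp{ (z - xi)/2 + xi_hat * (z^2 - xi^2) },
    xi_hat = -(sigma(xi) - 1/2) / (2 xi)   (limit -1/8 at xi = 0),

which turns each cell's bounded log-likelihood into
``R_hat * (ln sigma(xi) - xi/2 - xi_hat xi^2) + R_prime * z + R_hat xi_hat z^2``
with augmented count R_hat = m*((c-1)R + 1) and linear coefficient
R_prime = m*(cR - R_hat/2) — i.e. +c/2 at positives and -1/2 at negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DataValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


def derive_masks(R_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/column observation masks: m_u_i = 1 iff row i has any known
    interaction in the *training* matrix (and m_v_j likewise for columns)."""
    R = np.asarray(R_train)
    m_u = (R.sum(axis=1) >= 1).astype(float)
    m_v = (R.sum(axis=0) >= 1).astype(float)
    return m_u, m_v


@dataclass(frozen=True)
class InteractionData:
    """Binary drug-target interaction matrix with identifiers and masks."""

    R: np.ndarray
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    m_u: np.ndarray = field(default=None)  # type: ignore[assignment]
    m_v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2:
            raise DataValidationError(f"R must be 2-D, got shape {R.shape}")
        if not np.isin(R, (0, 1)).all():
            raise DataValidationError("R entries must be binary (0/1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "drug_ids", tuple(str(i) for i in self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(str(i) for i in self.target_ids))
        if len(self.drug_ids) != R.shape[0] or len(self.target_ids) != R.shape[1]:
            raise DataValidationError("identifier lists do not match R's shape")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise DataValidationError("duplicate drug ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise DataValidationError("duplicate target ids")
        if self.m_u is None or self.m_v is None:
            m_u, m_v = derive_masks(R)
            object.__setattr__(self, "m_u", m_u)
            object.__setattr__(self, "m_v", m_v)
        else:
            object.__setattr__(self, "m_u", np.asarray(self.m_u, dtype=float))
            object.__setattr__(self, "m_v", np.asarray(self.m_v, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def blinded(self, rows=None, cols=None, cells=None) -> "InteractionData":
        """Copy with the given rows / columns / (i, j) cells set to 0
        (unobserved) and masks recomputed on the blinded matrix."""
        R = self.R.copy()
        if rows is not None:
            R[np.asarray(rows, dtype=int), :] = 0.0
        if cols is not None:
            R[:, np.asarray(cols, dtype=int)] = 0.0
        if cells is not None:
            cells = np.asarray(cells, dtype=int)
            if cells.size:
                R[cells[:, 0], cells[:, 1]] = 0.0
        return InteractionData(R, self.drug_ids, self.target_ids)


@dataclass(frozen=True)
class Hyperparameters:
    """Model and inference hyperparameters.

    Attributes
    ----------
    L : latent dimension.
    c : importance weight on observed positives (c >= 1).
    alpha_u, alpha_v : ridge precisions of the factor priors.
    a, b : shape/rate of the Gamma hyperprior on kernel weights
        (prior mean a/b; the default 1/1000 keeps kernels weak a priori
        and lets the data promote informative ones).
    neighbors : nearest-neighbor truncation count for every kernel.
    iterations : number of full variational sweeps.
    seed : seed for the factor-mean initialization.
    """

    L: int = 10
    c: float = 10.0
    alpha_u: float = 0.1
    alpha_v: float = 0.1
    a: float = 1.0
    b: float = 1e3
    neighbors: int = 3
    iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L}")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        for nm in ("alpha_u", "alpha_v", "a", "b"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be strictly positive")
        if self.neighbors < 1:
            raise ValueError(f"neighbors must be >= 1, got {self.neighbors}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")

    def replace(self, **kw) -> "Hyperparameters":
        return replace(self, **kw)


def jaakkola_coefficient(xi: np.ndarray) -> np.ndarray:
    """Quadratic coefficient of the Jaakkola bound.

    ``xi_hat = -(sigma(xi) - 1/2) / (2 xi)``, with the analytic limit -1/8
    at xi = 0; always in [-1/8, 0).  Computed as -tanh(xi/2)/(4 xi) for
    numerical stability, with a Taylor series below 1e-6.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("xi must be nonnegative (the bound depends on xi^2)")
    t = xi / 2.0
    small = t < 1e-6
    safe = np.where(small, 1.0, t)
    # tanh(t)/t -> 1 - t^2/3 as t -> 0
    ratio = np.where(small, 1.0 - t**2 / 3.0, np.tanh(safe) / safe)
    out = -0.125 * ratio
    return out if out.shape else float(out)


@dataclass(frozen=True)
class LikelihoodAux:
    """Per-cell coefficients of the Jaakkola-bounded log-likelihood."""

    R_hat: np.ndarray    # augmented counts m*((c-1)R + 1), in {0, 1, c}
    R_prime: np.ndarray  # linear-term coefficients m*(cR - R_hat/2)
    xi: np.ndarray       # local variational parameters, >= 0
    xi_hat: np.ndarray   # quadratic coefficients, in [-1/8, 0)


def likelihood_aux(data: InteractionData, c: float, xi: np.ndarray) -> LikelihoodAux:
    """Build the bounded-likelihood coefficient matrices for given xi."""
    if c < 1:
        raise ValueError(f"c must be >= 1, got {c}")
    xi = np.asarray(xi, dtype=float)
    if xi.shape != data.shape:
        raise DataValidationError(f"xi shape {xi.shape} != R shape {data.shape}")
    m = np.outer(data.m_u, data.m_v)
    R_hat = m * ((c - 1.0) * data.R + 1.0)
    R_prime = m * (c * data.R - R_hat / 2.0)
    return LikelihoodAux(R_hat=R_hat, R_prime=R_prime, xi=xi,
                         xi_hat=jaakkola_coefficient(xi))


def log_sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable ln sigma(z)."""
    z = np.asarray(z, dtype=float)
    return np.where(z > 0, -np.log1p(np.exp(-np.abs(z))),
                    z - np.log1p(np.exp(-np.abs(z))))


def jaakkola_log_bound(z: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """ln sigma_tilde(z, xi): the quadratic lower bound on ln sigma(z)."""
    xi = np.asarray(xi, dtype=float)
    xh = jaakkola_coefficient(xi)
    return log_sigmoid(xi) + (np.asarray(z) - xi) / 2.0 + xh * (np.asarray(z) ** 2 - xi**2)
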