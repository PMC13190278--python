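"""Correlation-matrix parameterizations and the LKJ prior.

Correlation matrices are handled through the Cholesky factor ``L`` (rows of
unit Euclidean norm, ``R = L @ L.T``).  For MCMC the factor is mapped to an
unconstrained vector of length ``d*(d-1)/2`` via canonical partial
correlations: ``z = tanh(y)``, filled row by row so that each row keeps unit
norm.  The log-Jacobian of the map is returned alongside so samplers can work
on the unconstrained scale.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "num_free",
    "unconstrained_to_chol",
    "chol_to_unconstrained",
    "corr_from_chol",
    "chol_from_corr",
    "lkj_chol_logpdf",
    "lkj_corr_logpdf",
    "sample_lkj",
]


def num_free(d: int) -> int:
    """Number of free parameters of a d x d correlation matrix."""
    return d * (d - 1) // 2


def unconstrained_to_chol(y: np.ndarray, d: int) -> tuple[np.ndarray, float]:
    """Map an unconstrained vector to a correlation Cholesky factor.

    Returns ``(L, log_jac)`` where ``log_jac`` is the log absolute Jacobian
    determinant of the transform y -> L (tanh step included).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (num_free(d),):
        raise ValueError(f"expected {num_free(d)} unconstrained values, got {y.shape}")
    z = np.tanh(y).tolist()
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    log_jac = 0.0
    pos = 0
    # scalar loop: for the small fixed dimensions here (d <= 6) this beats
    # any vectorized formulation by a wide margin
    for i in range(1, d):
        rem = 1.0  # 1 - sum of squares of the row so far
        row = L[i]
        for j in range(i):
            zj = z[pos]
            if j > 0:
                # derivative of L[i, j] w.r.t. z is sqrt(rem)
                log_jac += 0.5 * math.log(rem)
            v = zj * math.sqrt(rem)
            row[j] = v
            rem -= v * v
            log_jac += math.log1p(-zj * zj)  # d tanh / dy
            pos += 1
        row[i] = math.sqrt(max(rem, 1e-300))
    return L, log_jac


def chol_to_unconstrained(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unconstrained_to_chol` (Jacobian not needed)."""
    L = np.asarray(L, dtype=float)
    d = L.shape[0]
    y = np.empty(num_free(d))
    pos = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            z = L[i, j] / np.sqrt(rem)
            z = np.clip(z, -1 + 1e-12, 1 - 1e-12)
            y[pos] = np.arctanh(z)
            rem -= L[i, j] ** 2
            rem = max(rem, 1e-300)
            pos += 1
    return y


def corr_from_chol(L: np.ndarray) -> np.ndarray:
    R = L @ L.T
    # enforce exact unit diagonal against roundoff
    np.fill_diagonal(R, 1.0)
    return R


def chol_from_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc


def lkj_chol_logpdf(L: np.ndarray, eta: float) -> float:
    """Unnormalized LKJ(eta) log-density of a correlation Cholesky factor.

    For ``R = L L'`` with LKJ(eta) on R, the density of L is proportional to
    ``prod_{k=2..d} L_kk ** (d - k + 2 eta - 2)`` (1-based row index k).
    """
    d = L.shape[0]
    total = 0.0
    for k in range(2, d + 1):
        diag = L[k - 1, k - 1]
        if diag <= 0:
            return -np.inf
        total += (d - k + 2.0 * eta - 2.0) * math.log(diag)
    return total


def lkj_corr_logpdf(R: np.ndarray, eta: float) -> float:
    """Unnormalized LKJ(eta) log-density of a correlation matrix."""
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    return float((eta - 1.0) * logdet)


def sample_lkj(d: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) (onion method)."""
    beta = eta + (d - 2) / 2.0
    r12 = 2.0 * rng.beta(beta, beta) - 1.0
    R = np.array([[1.0, r12], [r12, 1.0]])
    for k in range(2, d):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        u = rng.standard_normal(k)
        u /= np.linalg.norm(u)
        w = np.sqrt(y) * u
        A = np.linalg.cholesky(R)
        z = A @ w
        R = np.block([[R, z[:, None]], [z[None, :], np.ones((1, 1))]])
    return R
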