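"""The bivariate double-hierarchical GLM: likelihood, priors, joint density.

The model couples two submodels per trait k (distance moved, time to emerge),
observed on the standardized scale:

mean:        mu   = b0_k + bpred_k g + btrial_k t + bint_k g t + bsize_k x_s
                    + sum_j bbatch_jk + bdens_k x_d + a_ik + b_ik t + m_pk
dispersion:  log sigma = d0_k + dpred_k g + w_ik + d_pk

with a censored Gaussian observation density (the emergence-time assay is
capped, so values at the cap contribute tail probabilities rather than
densities).  Each individual carries a 6-vector of effects
``u_i = (a_DM, b_DM, w_DM, a_TE, b_TE, w_TE)`` drawn from a zero-mean
multivariate Gaussian whose covariance is specific to the individual's
developmental group (predator-exposed vs predator-naive); each pool carries a
4-vector ``q_p = (m_DM, m_TE, d_DM, d_TE)`` with a covariance shared across
groups.  Cross-trait dependence enters only through ``u`` and ``q``; there is
no residual cross-trait correlation at the observation level (the two assays
are separated in time).

Priors: fixed effects N(0, 1); random-effect SDs half-Student-t(3, 0, 2.8);
correlation matrices LKJ(2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.special import gammaln, log_ndtr

from . import _corr

#: fixed-effect design columns of the mean submodel, per trait
MEAN_TERMS = (
    "intercept",
    "predator",
    "trial",
    "predator_x_trial",
    "size",
    "batch2",
    "batch3",
    "batch4",
    "batch5",
    "density",
)
#: fixed-effect terms of the dispersion submodel, per trait
DISP_TERMS = ("intercept", "predator")

#: individual-effect components, trait-major
U_COMPONENTS = (
    "intercept_dm",
    "slope_dm",
    "logsd_dm",
    "intercept_te",
    "slope_te",
    "logsd_te",
)
#: pool-effect components
Q_COMPONENTS = ("mean_dm", "mean_te", "disp_dm", "disp_te")

N_MEAN_TERMS = len(MEAN_TERMS)
U_DIM = len(U_COMPONENTS)
Q_DIM = len(Q_COMPONENTS)


def u_slice(trait: int) -> tuple[int, int, int]:
    """(intercept, slope, log-SD) component indices of ``u`` for a trait."""
    return 3 * trait, 3 * trait + 1, 3 * trait + 2


@dataclass
class ModelSpec:
    """Structural switches of the DHGLM.

    The full model keeps every switch on.  Reduced variants (used for sanity
    checks against closed forms) may drop the random-effect levels or pin the
    dispersion submodel at known values.
    """

    traits: tuple[str, str] = ("distance_moved", "time_to_emerge")
    include_individual: bool = True
    include_pool: bool = True
    #: if given, (n_traits, 2) array of known dispersion fixed effects; the
    #: dispersion submodel is then not sampled
    fixed_dispersion: np.ndarray | None = None

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def to_json(self) -> str:
        d = asdict(self)
        if self.fixed_dispersion is not None:
            d["fixed_dispersion"] = np.asarray(self.fixed_dispersion).tolist()
        d["traits"] = list(self.traits)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        if d.get("fixed_dispersion") is not None:
            d["fixed_dispersion"] = np.asarray(d["fixed_dispersion"], dtype=float)
        d["traits"] = tuple(d["traits"])
        return cls(**d)


@dataclass
class PriorSpec:
    """Hyperparameters of the weakly-informative priors."""

    fixed_effect_sd: float = 1.0
    sd_df: float = 3.0
    sd_scale: float = 2.8
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("fixed_effect_sd", "sd_df", "sd_scale", "lkj_eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "PriorSpec":
        return cls(**json.loads(s))

    def sd_logpdf(self, s) -> np.ndarray:
        """log-density of the half-Student-t prior on an SD (s >= 0)."""
        s = np.asarray(s, dtype=float)
        df, sc = self.sd_df, self.sd_scale
        const = (
            np.log(2.0)
            + gammaln((df + 1.0) / 2.0)
            - gammaln(df / 2.0)
            - 0.5 * np.log(df * np.pi)
            - np.log(sc)
        )
        val = const - (df + 1.0) / 2.0 * np.log1p((s / sc) ** 2 / df)
        return np.where(s < 0, -np.inf, val)


@dataclass
class ParameterState:
    """One complete set of model parameters (constrained scale).

    beta      : (2, 10) mean fixed effects, columns ordered as MEAN_TERMS
    delta     : (2, 2) dispersion fixed effects (intercept, predator)
    u         : (n_ind, 6) individual effects, ordered as U_COMPONENTS
    q         : (n_pool, 4) pool effects, ordered as Q_COMPONENTS
    sd_g      : (2, 6) individual-effect SDs per group (0 naive, 1 exposed)
    corr_g    : (2, 6, 6) individual-effect correlation matrices per group
    sd_pool   : (4,) pool-effect SDs
    corr_pool : (4, 4) pool-effect correlation matrix
    """

    beta: np.ndarray
    delta: np.ndarray
    u: np.ndarray
    q: np.ndarray
    sd_g: np.ndarray
    corr_g: np.ndarray
    sd_pool: np.ndarray
    corr_pool: np.ndarray

    @classmethod
    def zeros(cls, n_ind: int = 0, n_pool: int = 0) -> "ParameterState":
        return cls(
            beta=np.zeros((2, N_MEAN_TERMS)),
            delta=np.zeros((2, 2)),
            u=np.zeros((n_ind, U_DIM)),
            q=np.zeros((n_pool, Q_DIM)),
            sd_g=np.ones((2, U_DIM)),
            corr_g=np.stack([np.eye(U_DIM)] * 2),
            sd_pool=np.ones(Q_DIM),
            corr_pool=np.eye(Q_DIM),
        )

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.beta.copy(),
            self.delta.copy(),
            self.u.copy(),
            self.q.copy(),
            self.sd_g.copy(),
            self.corr_g.copy(),
            self.sd_pool.copy(),
            self.corr_pool.copy(),
        )

    def group_cov(self, g: int) -> np.ndarray:
        s = self.sd_g[g]
        return self.corr_g[g] * np.outer(s, s)

    def pool_cov(self) -> np.ndarray:
        s = self.sd_pool
        return self.corr_pool * np.outer(s, s)


def mean_predictor(state: ParameterState, prepared, i: int | None = None):
    """Standardized mean of observation ``i`` (or all observations if None)."""
    k = prepared.trait
    mu = np.einsum("nj,nj->n", prepared.X, state.beta[k])
    if state.u.shape[0]:
        a = state.u[prepared.ind_idx, 3 * k]
        b = state.u[prepared.ind_idx, 3 * k + 1]
        mu = mu + a + b * prepared.trial
    if state.q.shape[0]:
        mu = mu + state.q[prepared.pool_idx, k]
    if i is None:
        return mu
    return float(mu[i])


def dispersion_predictor(state: ParameterState, prepared, i: int | None = None):
    """Log residual SD of observation ``i`` (or all observations if None)."""
    k = prepared.trait
    logsig = state.delta[k, 0] + state.delta[k, 1] * prepared.group_obs
    if state.u.shape[0]:
        logsig = logsig + state.u[prepared.ind_idx, 3 * k + 2]
    if state.q.shape[0]:
        logsig = logsig + state.q[prepared.pool_idx, 2 + k]
    if i is None:
        return logsig
    return float(logsig[i])


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def censored_normal_loglik(y, mu, sigma, bounds, censor):
    """Log-likelihood of (possibly censored) Gaussian observations.

    censor codes: 0 uncensored, 1 right-censored at the upper bound,
    -1 left-censored at the lower bound.  ``bounds = (lower, upper)`` may be
    scalars or arrays broadcastable with y.  Tail probabilities are evaluated
    through the log-CDF, so far-tail censored contributions do not underflow.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    censor = np.asarray(censor)
    lower, upper = bounds
    z = (y - mu) / sigma
    ll = -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z
    if np.any(censor == 1):
        # log P(Y >= upper) = log Phi((mu - upper) / sigma)
        tail = log_ndtr((mu - np.asarray(upper, dtype=float)) / sigma)
        ll = np.where(censor == 1, tail, ll)
    if np.any(censor == -1):
        tail = log_ndtr((np.asarray(lower, dtype=float) - mu) / sigma)
        ll = np.where(censor == -1, tail, ll)
    return ll


def observation_loglik(state: ParameterState, prepared) -> np.ndarray:
    """Per-observation censored-Gaussian log-likelihood."""
    mu = mean_predictor(state, prepared)
    sigma = np.exp(dispersion_predictor(state, prepared))
    lower = prepared.bounds[prepared.trait, 0]
    upper = prepared.bounds[prepared.trait, 1]
    return censored_normal_loglik(prepared.y, mu, sigma, (lower, upper), prepared.censor)


def _mvn_logpdf_many(x: np.ndarray, cov: np.ndarray) -> float:
    """Sum of zero-mean MVN log-densities of the rows of x."""
    if x.shape[0] == 0:
        return 0.0
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("random-effect covariance is not positive definite") from exc
    d = cov.shape[0]
    sol = np.linalg.solve(L, x.T)
    quad = np.sum(sol * sol)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    n = x.shape[0]
    return float(-0.5 * quad - 0.5 * n * (logdet + d * np.log(2.0 * np.pi)))


def joint_log_density(
    state: ParameterState,
    prepared,
    spec: ModelSpec,
    priors: PriorSpec,
) -> float:
    """Observation likelihood + random-effect densities + prior densities.

    The LKJ terms are evaluated up to their (parameter-independent)
    normalizing constants; all other terms are fully normalized.  Raises on a
    non-positive-definite covariance rather than returning -inf.
    """
    total = 0.0
    if prepared.n_obs:
        total += float(np.sum(observation_loglik(state, prepared)))

    if spec.include_individual and state.u.shape[0]:
        for g in (0, 1):
            rows = state.u[prepared.ind_group == g]
            total += _mvn_logpdf_many(rows, state.group_cov(g))
    if spec.include_pool and state.q.shape[0]:
        total += _mvn_logpdf_many(state.q, state.pool_cov())

    # fixed-effect priors
    v = priors.fixed_effect_sd
    total += float(np.sum(stats.norm.logpdf(state.beta, scale=v)))
    if spec.fixed_dispersion is None:
        total += float(np.sum(stats.norm.logpdf(state.delta, scale=v)))

    # variance-component priors
    if spec.include_individual:
        total += float(np.sum(priors.sd_logpdf(state.sd_g)))
        for g in (0, 1):
            total += _corr.lkj_corr_logpdf(state.corr_g[g], priors.lkj_eta)
    if spec.include_pool:
        total += float(np.sum(priors.sd_logpdf(state.sd_pool)))
        total += _corr.lkj_corr_logpdf(state.corr_pool, priors.lkj_eta)
    return total
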