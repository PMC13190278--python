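"""Likelihood, linear predictors and the joint log-density."""

import numpy as np
import pytest
from scipy import integrate, stats

import behavar as bv
from behavar.model import (
    ModelSpec,
    ParameterState,
    PriorSpec,
    censored_normal_loglik,
    dispersion_predictor,
    joint_log_density,
    mean_predictor,
    observation_loglik,
)

from conftest import small_params


def _random_state(rng, n_ind, n_pool):
    from behavar import _corr

    st = ParameterState.zeros(n_ind, n_pool)
    st.beta = rng.normal(0, 0.5, (2, 10))
    st.delta = rng.normal(0, 0.3, (2, 2))
    st.u = rng.normal(0, 0.4, (n_ind, 6))
    st.q = rng.normal(0, 0.2, (n_pool, 4))
    st.sd_g = np.abs(rng.normal(0.5, 0.2, (2, 6))) + 0.05
    st.corr_g = np.stack([_corr.sample_lkj(6, 2.0, rng) for _ in range(2)])
    st.sd_pool = np.abs(rng.normal(0.2, 0.1, 4)) + 0.05
    st.corr_pool = _corr.sample_lkj(4, 2.0, rng)
    return st


def test_mean_predictor_trivial_cases(paper_prepared):
    prep = paper_prepared
    st = ParameterState.zeros(prep.n_ind, prep.n_pool)
    assert mean_predictor(st, prep, 0) == 0.0
    # intercept 1 plus individual slope 0.5 at trial 2 gives 2.0
    i = int(np.where((prep.trait == 0) & (prep.trial == 2))[0][0])
    st.beta[0, 0] = 1.0
    st.u[prep.ind_idx[i], 1] = 0.5
    assert np.isclose(mean_predictor(st, prep, i), 2.0)


def test_predictors_match_independent_reimplementation(paper_prepared):
    prep = paper_prepared
    rng = np.random.default_rng(7)
    st = _random_state(rng, prep.n_ind, prep.n_pool)
    mu = mean_predictor(st, prep)
    logsig = dispersion_predictor(st, prep)
    for i in rng.choice(prep.n_obs, size=40, replace=False):
        k = prep.trait[i]
        ind = prep.ind_idx[i]
        pool = prep.pool_idx[i]
        t = prep.trial[i]
        ref_mu = float(prep.X[i] @ st.beta[k])
        ref_mu += st.u[ind, 3 * k] + st.u[ind, 3 * k + 1] * t + st.q[pool, k]
        ref_ls = (
            st.delta[k, 0]
            + st.delta[k, 1] * prep.group_obs[i]
            + st.u[ind, 3 * k + 2]
            + st.q[pool, 2 + k]
        )
        assert abs(mu[i] - ref_mu) < 1e-12
        assert abs(logsig[i] - ref_ls) < 1e-12


def test_dispersion_predictor_paper_value(paper_prepared):
    # a log-residual-SD intercept of -0.91 implies sigma = exp(-0.91) = 0.403
    st = ParameterState.zeros(paper_prepared.n_ind, paper_prepared.n_pool)
    st.delta[0, 0] = -0.91
    i = int(np.where(paper_prepared.trait == 0)[0][0])
    sigma = np.exp(dispersion_predictor(st, paper_prepared, i))
    assert np.isclose(sigma, 0.4025, atol=5e-4)
    assert np.all(np.exp(dispersion_predictor(st, paper_prepared)) > 0)


def test_censored_loglik_trivial_values():
    # density at the mean of a standard normal
    ll = censored_normal_loglik(0.0, 0.0, 1.0, (-np.inf, np.inf), 0)
    assert np.isclose(ll, -0.5 * np.log(2 * np.pi))
    # right-censored at the mean: log(1/2)
    ll = censored_normal_loglik(2.0, 2.0, 1.0, (-np.inf, 2.0), 1)
    assert np.isclose(ll, np.log(0.5))
    with pytest.raises(ValueError, match="sigma"):
        censored_normal_loglik(0.0, 0.0, -1.0, (-np.inf, np.inf), 0)


def _log_upper_tail_quadrature(z0: float) -> float:
    """log P(Z > z0) by quadrature of the factorized Gaussian tail:
    P(Z > z0) = phi(z0) * int_0^inf exp(-z0 t - t^2 / 2) dt, which stays
    representable arbitrarily far into the tail."""
    if z0 < 0:
        return float(np.log1p(-np.exp(_log_upper_tail_quadrature(-z0))))
    val, _ = integrate.quad(lambda t: np.exp(-z0 * t - 0.5 * t * t), 0, np.inf)
    return float(-0.5 * np.log(2 * np.pi) - 0.5 * z0 * z0 + np.log(val))


def test_censored_loglik_matches_quadrature_far_tails():
    for z0 in (-8.0, -3.0, -1.0, 0.0, 0.5, 2.0, 5.0, 10.0, 25.0, 37.0):
        for mu, sigma in ((0.0, 1.0), (1.3, 0.4), (-2.0, 3.5)):
            upper = mu + z0 * sigma
            ll = censored_normal_loglik(upper, mu, sigma, (-np.inf, upper), 1)
            assert abs(ll - _log_upper_tail_quadrature(z0)) < 1e-8


def test_censored_converges_to_uncensored_at_distant_bound():
    mu, sigma = 0.3, 0.8
    y = 0.5
    ll_unc = censored_normal_loglik(y, mu, sigma, (-np.inf, np.inf), 0)
    ll_bounded = censored_normal_loglik(
        y, mu, sigma, (mu - 40 * sigma, mu + 40 * sigma), 0
    )
    assert abs(ll_unc - ll_bounded) < 1e-10


def test_joint_density_empty_data_equals_prior(paper_prepared):
    import pandas as pd
    from behavar.records import COLUMNS

    prep = bv.prepare(pd.DataFrame([], columns=COLUMNS))
    spec, priors = ModelSpec(), PriorSpec()
    st = ParameterState.zeros(0, 0)
    lp = joint_log_density(st, prep, spec, priors)
    expected = (
        np.sum(stats.norm.logpdf(st.beta))
        + np.sum(stats.norm.logpdf(st.delta))
        + np.sum(priors.sd_logpdf(st.sd_g))
        + np.sum(priors.sd_logpdf(st.sd_pool))
    )  # LKJ terms vanish at identity correlation
    assert np.isclose(lp, expected)


def test_joint_density_single_observation_closed_form():
    import pandas as pd
    from behavar.records import COLUMNS

    rec = pd.DataFrame(
        [("i1", "p1", "naive", 1, 0, 10.0, 5.0, "time_to_emerge", 300.0, "none"),
         ("i1", "p1", "naive", 1, 1, 10.0, 5.0, "time_to_emerge", 400.0, "none")],
        columns=COLUMNS,
    )
    prep = bv.prepare(rec)
    spec = ModelSpec(include_individual=False, include_pool=False)
    priors = PriorSpec()
    st = ParameterState.zeros(0, 0)
    st.beta[1, 0] = 0.4
    lp = joint_log_density(st, prep, spec, priors)
    manual_obs = np.sum(stats.norm.logpdf(prep.y, loc=0.4, scale=1.0))
    manual_prior = np.sum(stats.norm.logpdf(st.beta)) + np.sum(
        stats.norm.logpdf(st.delta)
    )
    assert np.isclose(lp, manual_obs + manual_prior)


def test_joint_density_invariant_to_relabeling():
    sim = bv.simulate_dataset(small_params(seed=19))
    rec = sim.records
    prep = bv.prepare(rec)
    rng = np.random.default_rng(3)
    st = _random_state(rng, prep.n_ind, prep.n_pool)
    spec, priors = ModelSpec(), PriorSpec()
    lp1 = joint_log_density(st, prep, spec, priors)

    # rename ids so that the sorted order changes, permuting state to match
    mapping = {v: f"z{i:03d}" for i, v in enumerate(reversed(prep.individuals))}
    pool_map = {v: f"y{i:02d}" for i, v in enumerate(reversed(prep.pools))}
    rec2 = rec.assign(
        individual=rec["individual"].map(mapping), pool=rec["pool"].map(pool_map)
    )
    prep2 = bv.prepare(rec2)
    st2 = st.copy()
    reorder = [prep.individuals.index(v) for v in
               [{v2: k for k, v2 in mapping.items()}[nv] for nv in prep2.individuals]]
    st2.u = st.u[reorder]
    pool_reorder = [prep.pools.index({v2: k for k, v2 in pool_map.items()}[nv])
                    for nv in prep2.pools]
    st2.q = st.q[pool_reorder]
    lp2 = joint_log_density(st2, prep2, spec, priors)
    assert abs(lp1 - lp2) < 1e-8


def test_joint_density_group_label_symmetry():
    """With equal group covariances and no predator effects, swapping group
    labels between individuals with identical covariates leaves the density
    unchanged."""
    import pandas as pd
    from behavar.records import COLUMNS

    rows = []
    for ind, grp in (("i1", "naive"), ("i2", "exposed")):
        for t in range(2):
            rows.append((ind, "p1", grp, 1, t, 10.0, 5.0, "distance_moved",
                         100.0 * (t + 1), "none"))
            rows.append((ind, "p1", grp, 1, t, 10.0, 5.0, "time_to_emerge",
                         200.0 + 10 * t, "none"))
    rec = pd.DataFrame(rows, columns=COLUMNS)
    prep = bv.prepare(rec)
    rng = np.random.default_rng(11)
    st = _random_state(rng, 2, 1)
    st.beta[:, 1] = 0.0
    st.beta[:, 3] = 0.0
    st.delta[:, 1] = 0.0
    st.sd_g[1] = st.sd_g[0]
    st.corr_g[1] = st.corr_g[0]
    spec, priors = ModelSpec(), PriorSpec()
    lp1 = joint_log_density(st, prep, spec, priors)

    rec2 = rec.assign(group=rec["group"].map({"naive": "exposed", "exposed": "naive"}))
    prep2 = bv.prepare(rec2)
    lp2 = joint_log_density(st, prep2, spec, priors)
    assert abs(lp1 - lp2) < 1e-9


def test_joint_density_rejects_non_psd_covariance(paper_prepared):
    rng = np.random.default_rng(1)
    st = _random_state(rng, paper_prepared.n_ind, paper_prepared.n_pool)
    st.corr_g[0] = np.eye(6)
    st.corr_g[0][0, 1] = st.corr_g[0][1, 0] = 1.5
    with pytest.raises(ValueError, match="positive definite"):
        joint_log_density(st, paper_prepared, ModelSpec(), PriorSpec())


def test_likelihood_dominance_near_generating_parameters(paper_sim, paper_prepared):
    """The joint density at (a neighborhood of) the generating parameters
    beats states perturbed far from the truth."""
    prep = paper_prepared
    truth = bv.true_params_on_prepared_scale(paper_sim, prep)
    st = ParameterState.zeros(prep.n_ind, prep.n_pool)
    st.beta = truth["beta"]
    st.delta = truth["delta"]
    st.sd_g = truth["sd_g"]
    st.corr_g = truth["corr_g"]
    st.sd_pool = truth["sd_pool"]
    st.corr_pool = truth["corr_pool"]
    st.u = paper_sim.u.copy()
    st.q = paper_sim.q.copy()
    # map generator-scale random effects to the prepared scale
    for k in (0, 1):
        c = truth["sd_g"][0, 3 * k] / paper_sim.params.sd_g[0, 3 * k]
        st.u[:, 3 * k] *= c
        st.u[:, 3 * k + 1] *= c
        st.q[:, k] *= c
    spec, priors = ModelSpec(), PriorSpec()
    lp_truth = joint_log_density(st, prep, spec, priors)
    assert np.isfinite(lp_truth)
    rng = np.random.default_rng(0)
    worse = 0
    for _ in range(100):
        alt = st.copy()
        alt.beta = alt.beta + rng.normal(0, 2.0, alt.beta.shape)
        alt.delta = alt.delta + rng.normal(0, 2.0, alt.delta.shape)
        if joint_log_density(alt, prep, spec, priors) < lp_truth:
            worse += 1
    assert worse == 100


def test_spec_serialization_round_trip():
    spec = ModelSpec(fixed_dispersion=np.array([[0.1, 0.0], [0.2, 0.3]]))
    spec2 = ModelSpec.from_json(spec.to_json())
    assert np.allclose(spec2.fixed_dispersion, spec.fixed_dispersion)
    assert spec2.traits == spec.traits
    priors = PriorSpec(sd_scale=2.8)
    assert PriorSpec.from_json(priors.to_json()) == priors
    with pytest.raises(ValueError, match="strictly positive"):
        PriorSpec(lkj_eta=-1.0)
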