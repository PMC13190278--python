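"""Synthetic-data generator: structure, determinism, moment matching."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import behavar as bv
from behavar.records import TE_BOUNDS
from behavar.simulate import default_params, simulate_dataset

from conftest import small_params


def test_paper_like_preset_matches_study_conditions():
    p = default_params("paper_like")
    assert p.n_exposed == 48 and p.n_naive == 169
    assert p.n_pools_naive == 4 and p.n_pools_exposed == 8
    assert p.n_trials == 4 and p.te_bound == 600.0
    # among-individual intercept variance for distance moved, naive group
    assert np.isclose(p.sd_g[0, 0] ** 2, 0.08)


def test_null_preset_removes_group_differences():
    p = default_params("null")
    assert np.all(p.beta[:, 1] == 0) and np.all(p.beta[:, 3] == 0)
    assert np.all(p.delta[:, 1] == 0)
    assert np.array_equal(p.sd_g[0], p.sd_g[1])
    assert np.array_equal(p.corr_g[0], p.corr_g[1])


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        default_params("bogus")


def test_invalid_params_rejected():
    p = default_params("paper_like")
    p.n_trials = 1
    with pytest.raises(ValueError, match="n_trials"):
        p.validate()
    p = default_params("paper_like")
    p.corr_g[0, 0, 1] = 0.99  # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        p.validate()


def test_params_json_round_trip():
    p = default_params("paper_like", seed=9)
    q = bv.SimulationParams.from_json(p.to_json())
    assert q.n_naive == p.n_naive and q.seed == 9
    assert np.allclose(q.corr_g, p.corr_g)
    assert np.allclose(q.beta, p.beta)


def test_fixed_seed_reproduces_byte_identical_records(tmp_path):
    p = small_params(seed=11)
    a = simulate_dataset(p)
    b = simulate_dataset(small_params(seed=11))
    bv.write_records(a.records, tmp_path / "a.csv")
    bv.write_records(b.records, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    c = simulate_dataset(small_params(seed=12))
    assert not a.records.equals(c.records)


def test_record_structure_invariants(paper_sim):
    r = paper_sim.records
    # each (individual, trial, trait) at most once
    assert not r.duplicated(["individual", "trial", "trait"]).any()
    dm = r[r.trait == "distance_moved"]
    te = r[r.trait == "time_to_emerge"]
    assert (dm.value_raw > 0).all()
    assert te.value_raw.between(*TE_BOUNDS).all()
    # right-censored exactly when at the 600 s cap
    assert ((te.value_raw == TE_BOUNDS[1]) == (te.censored == "right")).all()
    assert r.trial.between(0, 3).all()
    assert set(r.group) == {"naive", "exposed"}
    # individuals nested in one pool and one group
    per = r.groupby("individual")[["pool", "group"]].nunique()
    assert (per == 1).all().all()


def test_missingness_bookkeeping_matches_validate():
    p = small_params(seed=21)
    p.n_naive, p.n_exposed = 150, 50
    p.missingness = 0.1
    sim = simulate_dataset(p)
    report = bv.validate(sim.records)
    assert sorted(report.incomplete_individuals) == sorted(sim.incomplete_ids)
    assert report.ok


def test_degenerate_variances_give_deterministic_trajectories():
    p = small_params(seed=5)
    p.sd_g[:] = 0.0
    p.sd_pool[:] = 0.0
    p.delta[:, 0] = -8.0  # residual SD ~ 3e-4
    p.delta[:, 1] = 0.0
    sim = simulate_dataset(p)
    prepared = bv.prepare(sim.records)
    # independent fixed-effect prediction on the generator scale
    r = sim.records.reset_index(drop=True)
    ind = sim.individuals.set_index("individual")
    size_z = (ind["size"] - ind["size"].mean()) / ind["size"].std(ddof=0)
    dens_z = (ind["density"] - ind["density"].mean()) / ind["density"].std(ddof=0)
    for i in range(0, len(r), 97):
        row = r.iloc[i]
        k = 0 if row.trait == "distance_moved" else 1
        g = 1.0 if row.group == "exposed" else 0.0
        b = p.beta[k]
        pred = (
            b[0] + b[1] * g + b[2] * row.trial + b[3] * g * row.trial
            + b[4] * size_z[row.individual]
            + (b[4 + row.batch - 1] if row.batch > 1 else 0.0)
            + b[9] * dens_z[row.individual]
        )
        assert abs(sim.latent_y[i] - pred) < 5e-3


def test_individual_effect_moments_match_specification():
    """Moment-matching at large n: the empirical variance of intercept
    deviations and the sample correlation matrix approach their targets."""
    p = small_params(seed=13)
    p.n_naive, p.n_exposed = 5000, 10
    p.n_pools_naive = 4
    sim = simulate_dataset(p)
    u = sim.u[:5000]
    target_var = p.sd_g[0] ** 2
    emp_var = u.var(axis=0, ddof=1)
    # 3 SEs of a variance estimate: var * sqrt(2 / (n - 1)) * 3
    tol = 3 * target_var * np.sqrt(2.0 / 4999)
    assert np.all(np.abs(emp_var - target_var) < tol + 1e-12)
    emp_corr = np.corrcoef(u.T)
    assert np.max(np.abs(emp_corr - p.corr_g[0])) < 0.05


def test_right_censoring_fraction_matches_gaussian_tail():
    """With all random effects off, the right-censoring probability has the
    closed form 1 - Phi((U_std - mu) / sigma)."""
    p = small_params(seed=17)
    p.n_naive, p.n_exposed = 2000, 1
    p.n_pools_naive, p.n_pools_exposed = 2, 1
    p.sd_g[:] = 0.0
    p.sd_pool[:] = 0.0
    p.beta[:] = 0.0
    p.beta[1, 0] = 0.6
    p.delta[:] = 0.0  # sigma = 1 on the standardized scale
    sim = simulate_dataset(p)
    te = sim.records[sim.records.trait == "time_to_emerge"]
    te_naive = te[te.group == "naive"]
    z = (p.te_bound - p.te_mean) / p.te_sd - 0.6
    expect = stats.norm.sf(z)
    frac = (te_naive.censored == "right").mean()
    n = len(te_naive)
    assert abs(frac - expect) < 4 * np.sqrt(expect * (1 - expect) / n)


def test_null_scenario_group_variances_equal_at_nominal_rate():
    """Two-sample variance-equality checks on per-individual means reject at
    roughly the nominal 5% rate under the null scenario."""
    rejections = 0
    n_reps = 30
    for rep in range(n_reps):
        p = small_params(seed=1000 + rep, scenario="null")
        p.n_naive = p.n_exposed = 50
        p.n_pools_naive = p.n_pools_exposed = 3
        sim = simulate_dataset(p)
        dm = sim.records[sim.records.trait == "distance_moved"]
        logd = np.log(dm.value_raw)
        means = logd.groupby(dm.individual).mean()
        grp = dm.groupby("individual")["group"].first()
        a = means[grp == "naive"]
        b = means[grp == "exposed"]
        if stats.levene(a, b).pvalue < 0.05:
            rejections += 1
    # P(X > 8 | Binomial(30, 0.05)) < 1e-4
    assert rejections <= 8


def test_write_dataset_round_trips(tmp_path):
    sim = simulate_dataset(small_params(seed=2))
    paths = bv.write_dataset(sim, tmp_path)
    records = bv.read_records(paths["records"])
    pd.testing.assert_frame_equal(
        records.reset_index(drop=True), sim.records.reset_index(drop=True)
    )
    params = bv.SimulationParams.from_json(paths["params"].read_text())
    assert params.seed == 2
    truth = json.loads(paths["truth"].read_text())
    assert np.asarray(truth["u"]).shape == sim.u.shape
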