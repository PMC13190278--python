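"""Derived quantities: variances, repeatability, HPDIs, contrasts, BLUPs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import behavar as bv
from behavar.derived import (
    CORRELATION_LABELS,
    blups,
    expected_residual_variance,
    group_difference,
    hpdi,
    posterior_mode,
    repeatability,
    significance_flag,
    summarize,
)


def brute_force_hpdi(x, mass=0.95):
    x = np.sort(np.asarray(x))
    n = len(x)
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[i + m - 1]))
    return best[1]


class TestExpectedResidualVariance:
    def test_trivial_and_formula(self):
        assert expected_residual_variance(0.0, 0.0) == 1.0
        # with no among-individual variance this is the plain log-normal
        # back-transform exp(2 m)
        assert np.isclose(expected_residual_variance(-0.5, 0.0), np.exp(-1.0))
        with pytest.raises(ValueError, match="non-negative"):
            expected_residual_variance(0.0, -0.1)

    def test_printed_study_values_are_consistent(self):
        # dispersion intercept -0.91 and among-individual log-SD variance
        # 0.43 give a within-individual variance of ~0.25, and with an
        # among-individual variance of 0.08 a repeatability of ~0.24
        v_within = expected_residual_variance(-0.91, 0.43)
        assert round(float(v_within), 2) == 0.25
        assert round(float(repeatability(0.08, 0.25)), 2) == 0.24

    def test_matches_monte_carlo_of_squared_mean_sd(self):
        """The quantity is (E[sigma])^2 — deliberately not E[sigma^2]."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            m = rng.uniform(-1.5, 0.5)
            v = rng.uniform(0.0, 0.8)
            draws = np.exp(rng.normal(m, np.sqrt(v), 10**6))
            est = draws.mean() ** 2
            se = 2 * draws.mean() * draws.std() / np.sqrt(len(draws))
            assert abs(expected_residual_variance(m, v) - est) < 3 * se


class TestRepeatability:
    def test_trivial_values(self):
        assert repeatability(0.0, 1.0) == 0.0
        assert repeatability(0.3, 0.3) == 0.5
        with pytest.raises(ValueError):
            repeatability(0.0, 0.0)
        with pytest.raises(ValueError):
            repeatability(-0.1, 1.0)

    def test_drawwise_range(self):
        rng = np.random.default_rng(0)
        va = rng.gamma(2, 1, 1000)
        vr = rng.gamma(2, 1, 1000)
        r = repeatability(va, vr)
        assert np.all((r >= 0) & (r <= 1))


class TestHpdi:
    def test_degenerate_and_normal(self):
        lo, hi = hpdi(np.full(100, 3.2))
        assert lo == hi == 3.2
        rng = np.random.default_rng(1)
        lo, hi = hpdi(rng.standard_normal(100_000), 0.95)
        assert abs(lo + 1.96) < 0.05 and abs(hi - 1.96) < 0.05
        with pytest.raises(ValueError, match="at least 20"):
            hpdi(np.arange(10))

    def test_matches_brute_force_on_skewed_samples(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = np.exp(rng.standard_normal(500))
            assert hpdi(x, 0.95) == brute_force_hpdi(x, 0.95)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_interval_contains_required_mass(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(1.5, 2.0, 200)
        lo, hi = hpdi(x, 0.9)
        assert np.mean((x >= lo) & (x <= hi)) >= 0.9


class TestGroupDifference:
    def test_sign_convention_and_linearity(self):
        naive = np.array([1.0, 2.0, 3.0])
        assert np.all(group_difference(naive, naive) == 0.0)
        # naive draws shifted +c above exposed: delta mean is -c
        delta = group_difference(naive + 0.7, naive)
        assert np.allclose(delta, -0.7)

    def test_matches_independent_recomputation(self, small_fit):
        summ = summarize(small_fit)
        sd_g = small_fit.stacked("sd_g")
        manual = sd_g[:, 1, 0] ** 2 - sd_g[:, 0, 0] ** 2
        assert np.max(np.abs(
            summ.quantities["v_among_distance_moved_delta"] - manual)) < 1e-12


class TestSignificanceFlag:
    def test_published_examples(self):
        # Delta Exposure for initial distance moved: (-0.79, -0.03) -> significant
        assert significance_flag(-0.41, (-0.79, -0.03), "signed")
        # Delta Exposure plasticity, distance moved: (-0.14, 0.12) crosses 0
        assert not significance_flag(-0.01, (-0.14, 0.12), "signed")
        # variance rule: lower bound must exceed 0.01
        assert not significance_flag(0.02, (0.005, 0.08), "variance")
        assert significance_flag(0.08, (0.04, 0.13), "variance")
        with pytest.raises(ValueError):
            significance_flag(0.0, (1.0, -1.0), "signed")


class TestSummarize:
    def test_table_schemas_are_frozen(self, small_fit):
        summ = summarize(small_fit)
        # table 1: 3 sections x 2 traits x (naive, exposed, delta)
        assert len(summ.table1) == 18
        assert set(summ.table1.columns) == {
            "section", "trait", "group", "mean", "lower", "upper", "significant"}
        assert list(summ.table1["section"].unique()) == [
            "initial_behavior", "plasticity", "predictability"]
        # table 2: 5 sections x 2 traits x 3 rows
        assert len(summ.table2) == 30
        # table 3: 15 correlations x 3 rows
        assert len(summ.table3) == 45
        assert set(summ.table3["correlation"]) == set(CORRELATION_LABELS)
        # table 4: (6 fixed terms + 2 pool rows) x 2 traits
        assert len(summ.table4) == 16
        assert summ.metadata["v_residual_includes_pool_dispersion"] is False

    def test_drawwise_identities(self, small_fit):
        summ = summarize(small_fit)
        q = summ.quantities
        for trait in ("distance_moved", "time_to_emerge"):
            r = q[f"repeatability_{trait}_naive"]
            assert np.all((r >= 0) & (r <= 1))
            # delta-repeatability equals the draw-wise difference
            assert np.allclose(
                q[f"repeatability_{trait}_delta"],
                q[f"repeatability_{trait}_exposed"] - q[f"repeatability_{trait}_naive"],
            )
            # summarized mean lies inside its own HPDI
            row = summ.table2[(summ.table2.section == "repeatability")
                              & (summ.table2.trait == trait)
                              & (summ.table2.group == "naive")].iloc[0]
            assert row.lower <= row["mean"] <= row.upper
            # V_residual is positive and consistent with the formula
            m = q[f"predictability_{trait}_naive"]
            v = q[f"v_predictability_{trait}_naive"]
            assert np.allclose(q[f"v_within_{trait}_naive"], np.exp(2 * m + v))

    def test_correlation_quantities_match_draws(self, small_fit):
        summ = summarize(small_fit)
        corr = small_fit.stacked("corr_g")
        assert np.allclose(
            summ.quantities["corr_behavioral_syndrome_naive"], corr[:, 0, 0, 3])
        assert np.allclose(
            summ.quantities["corr_te_personality_dm_predictability_exposed"],
            corr[:, 1, 3, 2])


class TestBlups:
    def test_degenerate_draws(self):
        x = np.full(500, 1.7)
        assert posterior_mode(x) == 1.7

    def test_symmetric_mode_near_mean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 0.5, 4000)
        assert abs(posterior_mode(x) - x.mean()) < 0.15 * x.std()

    def test_lognormal_mode_below_mean(self):
        rng = np.random.default_rng(6)
        mu, sig = 0.0, 0.8
        x = np.exp(rng.normal(mu, sig, 20_000))
        mode = posterior_mode(x)
        analytic = np.exp(mu - sig**2)
        assert mode < x.mean()
        assert abs(mode - analytic) < 0.15

    def test_blup_table_structure(self, small_fit):
        table = blups(small_fit)
        assert len(table) == len(small_fit.individuals)
        assert "intercept_dm_mean" in table.columns
        assert "logsd_te_mode" in table.columns
        assert set(table["group"]) == {"naive", "exposed"}
        u = small_fit.stacked("u")
        i = 3
        assert np.isclose(table["intercept_dm_mean"].iloc[i], u[:, i, 0].mean())
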