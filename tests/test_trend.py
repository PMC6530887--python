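"""Bayesian trend model: transforms, samplers, diagnostics, projections."""

import numpy as np
import pandas as pd
import pytest

from uhcmon import trend as T


def _delta_draws(alpha=0.0, beta=0.0, n=200, t0=1995.0):
    """Degenerate posterior concentrated at a single (alpha, beta)."""
    coef = pd.DataFrame({"alpha": np.full(n, alpha), "beta": np.full(n, beta)})
    return T.PosteriorDraws(coef=coef, sigma2=np.full(n, 1e-6),
                            chain=np.zeros(n, dtype=int), t0=t0)


class TestLogit:
    def test_symmetry_and_values(self):
        assert T.logit(0.5) == pytest.approx(0.0)
        assert T.logit(0.8) == pytest.approx(np.log(4))

    def test_round_trip(self):
        assert T.inv_logit(T.logit(0.849)) == pytest.approx(0.849, abs=1e-12)

    def test_boundary_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.3):
            with pytest.raises(ValueError):
                T.logit(bad)

    def test_adjust_boundary_pulls_inside(self):
        assert 0 < T.adjust_boundary(0.0, 100) < 0.01
        assert 0.99 < T.adjust_boundary(1.0, 100) < 1
        assert T.adjust_boundary(0.37, 100) == 0.37


class TestConjugate:
    def test_exact_line_recovers_slope_and_intercept(self):
        y = np.array([-1.0, -0.5, 0.0, 0.5])
        td = T.TrendData(years=[0, 1, 2, 3], p=T.inv_logit(y))
        d = T.fit_trend_conjugate(td, n_draws=4000, seed=0)
        assert d.coef["beta"].mean() == pytest.approx(0.5, abs=1e-3)
        assert d.coef["alpha"].mean() == pytest.approx(-1.0, abs=1e-3)

    def test_constant_series_flat_slope(self):
        td = T.TrendData(years=[0, 1, 2, 3, 4], p=[0.4] * 5)
        d = T.fit_trend_conjugate(td, n_draws=4000, seed=0)
        assert d.coef["beta"].mean() == pytest.approx(0.0, abs=1e-4)

    def test_posterior_mean_equals_least_squares(self, rng):
        years = np.arange(5) * 5.0
        y = 0.2 + 0.05 * years + rng.normal(0, 0.1, 5)
        td = T.TrendData(years=years, p=T.inv_logit(y))
        d = T.fit_trend_conjugate(td, n_draws=40_000, seed=1)
        X = np.column_stack([np.ones(5), years])
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        se = d.coef.std() / np.sqrt(len(d.coef))
        assert abs(d.coef["alpha"].mean() - bhat[0]) < 4 * se["alpha"]
        assert abs(d.coef["beta"].mean() - bhat[1]) < 4 * se["beta"]

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            T.TrendData(years=[0, 1], p=[0.3, 0.4])


class TestMcmc:
    TD = T.TrendData(years=[1993, 1998, 2003, 2008, 2014],
                     p=[0.55, 0.62, 0.70, 0.76, 0.83])

    def test_matches_conjugate_oracle(self):
        dm = T.fit_trend_mcmc(self.TD, retained=4000, seed=0)
        dc = T.fit_trend_conjugate(self.TD, n_draws=4000, seed=1)
        for name in ("alpha", "beta"):
            a, b = dm.coef[name], dc.coef[name]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 3 * se

    def test_same_seed_identical_draws(self):
        d1 = T.fit_trend_mcmc(self.TD, seed=7)
        d2 = T.fit_trend_mcmc(self.TD, seed=7)
        pd.testing.assert_frame_equal(d1.coef, d2.coef)
        assert np.array_equal(d1.sigma2, d2.sigma2)

    def test_overdispersed_starts_converge(self):
        d = T.fit_trend_mcmc(self.TD, seed=3)
        assert d.converged
        assert max(d.psrf.values()) <= 1.02

    def test_retained_count_and_chains(self):
        d = T.fit_trend_mcmc(self.TD, chains=2, retained=1000, seed=0)
        assert d.n_draws == 1000
        assert set(np.unique(d.chain)) == {0, 1}


class TestPsrf:
    def test_identical_chains(self):
        x = np.random.default_rng(0).standard_normal(1000)
        val = T.psrf(np.stack([x, x]))
        assert val == pytest.approx(np.sqrt(999 / 1000))
        assert val < 1.02

    def test_offset_chain_flags_nonconvergence(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert T.psrf(np.stack([x, x + 100])) > 1.02

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((2, 5000))
        assert 0.99 < T.psrf(chains) < 1.02

    def test_degenerate_chains_defined_as_one(self):
        assert T.psrf(np.ones((2, 10))) == 1.0


class TestDic:
    def test_effective_parameters_near_three_at_large_n(self, rng):
        years = np.linspace(1990, 2015, 200)
        y = -1 + 0.05 * (years - 1990) + rng.normal(0, 0.2, 200)
        td = T.TrendData(years=years, p=T.inv_logit(y))
        d = T.fit_trend_conjugate(td, n_draws=20_000, seed=2)
        _, p_d, _ = T.dic(td, d)
        assert p_d == pytest.approx(3.0, abs=0.5)

    def test_duplicated_data_doubles_deviance(self, rng):
        years = np.array([1990.0, 1995, 2000, 2005, 2010])
        y = -0.5 + 0.04 * (years - 1990) + rng.normal(0, 0.1, 5)
        td = T.TrendData(years=years, p=T.inv_logit(y))
        d = T.fit_trend_conjugate(td, n_draws=2000, seed=3)
        td2 = T.TrendData(years=np.tile(years, 2), p=T.inv_logit(np.tile(y, 2)))
        dbar1, _, _ = T.dic(td, d)
        dbar2, _, _ = T.dic(td2, d)  # same draws, duplicated likelihood
        assert dbar2 == pytest.approx(2 * dbar1, rel=1e-12)


class TestProjection:
    def test_delta_posterior_gives_half(self):
        d = _delta_draws(0.0, 0.0)
        proj = T.project(d, [2000, 2030])
        assert np.allclose(proj.mean, 50.0)
        assert np.allclose(proj.ci_hi - proj.ci_lo, 0.0)

    def test_positive_slope_monotone_projection(self):
        d = _delta_draws(-1.0, 0.05)
        proj = T.project(d, [2000, 2010, 2020, 2030])
        assert np.all(np.diff(proj.mean) > 0)
        assert np.all((proj.mean > 0) & (proj.mean < 100))

    def test_intervals_widen_with_extrapolation(self):
        # a mid-range trajectory, away from the saturating ends of the
        # inverse logit where the percent scale would compress intervals
        td = T.TrendData(years=[1993, 1998, 2003, 2008, 2014],
                         p=[0.48, 0.51, 0.49, 0.52, 0.50])
        d = T.fit_trend_mcmc(td, seed=0)
        proj = T.project(d, [2014, 2020, 2025, 2030])
        widths = proj.ci_hi - proj.ci_lo
        assert np.all(np.diff(widths) > 0)
        # and on the logit scale the widening holds regardless of level
        eta = np.column_stack([d.linear_predictor(y) for y in (2014, 2020, 2025, 2030)])
        eta_w = np.percentile(eta, 97.5, axis=0) - np.percentile(eta, 2.5, axis=0)
        assert np.all(np.diff(eta_w) > 0)


class TestTargetProbabilities:
    def test_all_above(self):
        assert T.prob_target_coverage(_delta_draws(3.0, 0.0)) == 1.0

    def test_split_half(self):
        coef = pd.DataFrame({
            "alpha": np.concatenate([np.full(50, T.logit(0.9)),
                                     np.full(50, T.logit(0.7))]),
            "beta": np.zeros(100)})
        d = T.PosteriorDraws(coef=coef, sigma2=np.ones(100),
                             chain=np.zeros(100, dtype=int), t0=1995.0)
        assert T.prob_target_coverage(d, target=0.80) == pytest.approx(0.5)

    def test_vacuous_target(self):
        assert T.prob_target_coverage(_delta_draws(-5.0, 0.0), target=0.0) == 1.0

    def test_financial_protection(self):
        assert T.prob_financial_protection(_delta_draws(T.logit(0.002), 0.0)) == 1.0
        assert T.prob_financial_protection(_delta_draws(T.logit(0.05), 0.0)) == 0.0
        assert T.prob_financial_protection(
            _delta_draws(T.logit(0.05), 0.0), epsilon=1.0) == 1.0


class TestAnnualRate:
    def test_flat_trend_zero_rate(self):
        mean, lo, hi = T.annual_rate_of_change(_delta_draws(0.3, 0.0), 1995, 2030)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_published_endpoint_example(self):
        """84.9% in 1995 rising to 99.2% in 2030 is ~0.45%/yr geometric."""
        alpha = T.logit(0.849)
        beta = (T.logit(0.992) - alpha) / 35.0
        d = _delta_draws(alpha, beta, t0=1995.0)
        mean, _, _ = T.annual_rate_of_change(d, 1995, 2030)
        assert mean == pytest.approx(0.45, abs=0.01)

    def test_rate_sign_follows_slope(self, rng):
        betas = rng.normal(0, 0.05, 100)
        coef = pd.DataFrame({"alpha": np.zeros(100), "beta": betas})
        d = T.PosteriorDraws(coef=coef, sigma2=np.ones(100),
                             chain=np.zeros(100, dtype=int), t0=1995.0)
        c0 = T.inv_logit(d.linear_predictor(1995))
        c1 = T.inv_logit(d.linear_predictor(2030))
        rates = (c1 / c0) ** (1 / 35) - 1
        assert np.all(np.sign(rates) == np.sign(betas))

    def test_bad_period_rejected(self):
        with pytest.raises(ValueError):
            T.annual_rate_of_change(_delta_draws(), 2030, 1995)


def _grouped_data(rng, slopes, n_groups=2, years=(1995, 2000, 2005, 2010, 2015),
                  noise=0.1, base=-0.5, offset=0.3):
    years = np.asarray(years, dtype=float)
    labels = [f"G{i}" for i in range(n_groups)]
    ys, ps, gs = [], [], []
    for i, g in enumerate(labels):
        eta = base + i * offset + slopes[i] * (years - years[0])
        eta = eta + rng.normal(0, noise, len(years))
        ys.append(years)
        ps.append(T.inv_logit(eta))
        gs.append([g] * len(years))
    return T.TrendData(years=np.concatenate(ys), p=np.concatenate(ps),
                       groups=np.concatenate(gs))


class TestGroupedTrend:
    def test_null_offsets_recovered(self, rng):
        td = _grouped_data(rng, slopes=[0.05, 0.05], offset=0.0)
        d = T.fit_grouped_trend(td, seed=0)
        u = d.coef["u[G1]"]
        assert abs(u.mean()) < 2 * u.std()

    def test_single_group_reduces_to_plain_fit(self):
        years = [1995, 2000, 2005, 2010, 2015]
        p = [0.5, 0.55, 0.6, 0.66, 0.7]
        td_g = T.TrendData(years=years, p=p, groups=["A"] * 5)
        td = T.TrendData(years=years, p=p)
        d1 = T.fit_grouped_trend(td_g, seed=4)
        d2 = T.fit_trend_mcmc(td, seed=4)
        pd.testing.assert_frame_equal(d1.coef, d2.coef)

    def test_singleton_group_error_names_group(self):
        td = T.TrendData(years=[1995, 2000, 2005, 2010, 2015, 2015],
                         p=[0.5, 0.55, 0.6, 0.65, 0.7, 0.4],
                         groups=["A", "A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            T.fit_grouped_trend(td, seed=0)

    def test_interaction_power_at_distinct_slopes(self):
        """With clearly distinct slopes the interaction term should exclude
        zero at the 95% level in most replicates."""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            td = _grouped_data(rng, slopes=[0.02, 0.10])
            d = T.fit_grouped_trend(td, interaction=True, method="conjugate",
                                    seed=seed, n_draws=1000)
            lo, hi = np.percentile(d.coef["v[G1]"], [2.5, 97.5])
            hits += not (lo <= 0 <= hi)
        assert hits >= 20

    def test_chain_relabel_invariance(self):
        td = TestMcmc.TD
        d = T.fit_trend_mcmc(td, seed=0)
        p1 = T.prob_target_coverage(d)
        perm = np.random.default_rng(0).permutation(d.n_draws)
        d.coef = d.coef.iloc[perm].reset_index(drop=True)
        assert T.prob_target_coverage(d) == pytest.approx(p1)


class TestModelSelection:
    def test_reports_both_candidates(self, rng):
        td = _grouped_data(rng, slopes=[0.05, 0.05])
        _, diags = T.select_model_by_dic(td, method="conjugate", seed=0)
        assert {"no_interaction", "interaction", "choice"} <= set(diags)
        assert diags["choice"] in ("no_interaction", "interaction")

    def test_strong_interaction_truth_selected(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            td = _grouped_data(rng, slopes=[0.0, 0.12], noise=0.05)
            _, diags = T.select_model_by_dic(td, method="conjugate", seed=seed)
            wins += diags["choice"] == "interaction"
        assert wins >= 15
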