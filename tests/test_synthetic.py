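"""Generator contracts: determinism, marginal structure, ground truth."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from uhcmon.config import (IndicatorParams, SyntheticConfig,
                           WaveExpenditureParams)
from uhcmon.synthetic import (generate_coverage_microdata,
                              generate_expenditure_microdata, true_parameters)

from conftest import small_config


class TestCoverageGenerator:
    def test_null_indicator_has_half_prevalence(self):
        cfg = small_config(
            indicator_params={"flat": IndicatorParams(a0=0.0, b=0.0, g=0.0)},
            region_effects=[0.0, 0.0, 0.0, 0.0],
            n_clusters=50,
            households_per_cluster=20,
        )
        df = generate_coverage_microdata(cfg)
        p = df["outcome_flat"].mean()
        n = len(df)
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_positive_slope_raises_last_year_coverage(self):
        hits = 0
        for seed in range(100):
            cfg = small_config(
                seed=seed,
                n_clusters=8,
                households_per_cluster=8,
                indicator_params={"up": IndicatorParams(a0=-0.5, b=0.08, g=0.3)},
            )
            df = generate_coverage_microdata(cfg)
            by_year = df.groupby("year").apply(
                lambda g: np.average(g["outcome_up"], weights=g["weight"]),
                include_groups=False,
            )
            hits += by_year.loc[2015] > by_year.loc[1995]
        assert hits >= 95

    def test_same_seed_reproduces_bytes(self, cfg_small, coverage_small):
        again = generate_coverage_microdata(small_config())
        assert coverage_small.to_csv(index=False) == again.to_csv(index=False)

    def test_different_seed_differs(self, coverage_small):
        other = generate_coverage_microdata(small_config(seed=1))
        with pytest.raises(AssertionError):
            assert_frame_equal(coverage_small, other)

    def test_weights_positive_and_sum_to_sample_size(self, coverage_small):
        assert (coverage_small["weight"] > 0).all()
        for _, g in coverage_small.groupby("year"):
            assert g["weight"].sum() == pytest.approx(len(g))

    def test_every_cluster_populated(self, coverage_small, cfg_small):
        counts = coverage_small.groupby(["year", "cluster_id"]).size()
        assert (counts >= 1).all()
        assert len(counts) == len(cfg_small.survey_years) * cfg_small.n_clusters

    def test_outcomes_binary_or_missing(self, coverage_small):
        vals = coverage_small["outcome_alpha_ind"].dropna().unique()
        assert set(vals) <= {0.0, 1.0}

    def test_missingness_rate_honoured(self):
        cfg = small_config(missing_rate=0.3)
        df = generate_coverage_microdata(cfg)
        frac = df["outcome_alpha_ind"].isna().mean()
        assert 0.25 < frac < 0.35

    def test_weighted_coverage_converges_to_generating_model(self):
        """At n = 10,000 the weighted mean matches the marginal implied by
        the linear predictor within 2 Monte-Carlo SEs (wealth and region
        integrate out by simulation of the generator's own formula)."""
        par = IndicatorParams(a0=0.3, b=0.05, g=0.6)
        cfg = small_config(
            n_clusters=100, households_per_cluster=100,
            survey_years=[2000, 2001, 2002],
            indicator_params={"ind": par},
            region_effects=[0.0, 0.0, 0.0, 0.0],
        )
        df = generate_coverage_microdata(cfg)
        sub = df[df["year"] == 2000]
        obs = np.average(sub["outcome_ind"], weights=sub["weight"])
        z = np.random.default_rng(1).standard_normal(200_000)
        expected = (1 / (1 + np.exp(-(par.a0 + par.g * z)))).mean()
        mc_se = np.sqrt(expected * (1 - expected) / len(sub))
        assert abs(obs - expected) < 2 * mc_se * 1.5  # weights inflate variance


class TestExpenditureGenerator:
    def test_accounting_identity(self, expenditure_small):
        df = expenditure_small
        assert np.allclose(df["exp_food"] + df["exp_nonfood"], df["exp_total"])
        assert (df["oop_health"] <= df["exp_nonfood"] + 1e-9).all()
        assert (df["hh_size"] >= 1).all()
        assert (df["exp_total"] > 0).all()

    def test_no_oop_means_no_che(self):
        cfg = small_config(expenditure_params={
            1995: WaveExpenditureParams(6.0, 0.6, 0.5, 18.0, 0.0, 3.0, 1.2),
            2005: WaveExpenditureParams(6.0, 0.6, 0.5, 18.0, 0.0, 3.0, 1.2),
            2015: WaveExpenditureParams(6.0, 0.6, 0.5, 18.0, 0.0, 3.0, 1.2),
        })
        df = generate_expenditure_microdata(cfg)
        assert (df["oop_health"] == 0).all()

    def test_mean_food_share_recovered(self):
        cfg = small_config(
            n_households_expenditure=10_000,
            expenditure_params={
                1995: WaveExpenditureParams(6.0, 0.6, 0.60, 18.0, 0.7, 3.0, 1.2)},
            expenditure_years=[1995],
        )
        df = generate_expenditure_microdata(cfg)
        share = df["exp_food"] / df["exp_total"]
        mean_share = np.average(share, weights=df["weight"])
        assert 0.59 < mean_share < 0.61

    def test_che_declines_across_default_waves(self):
        from uhcmon.config import default_config
        from uhcmon.hardship import compute_hardship_flags, estimate_poverty_line

        cfg = default_config(3)
        cfg.n_households_expenditure = 2000
        df = generate_expenditure_microdata(cfg)
        pls = {y: estimate_poverty_line(df, y) for y in cfg.expenditure_years}
        flags = compute_hardship_flags(df, pls)
        che = flags.groupby("year")["che"].mean()
        assert che.iloc[-1] < che.iloc[0]

    def test_same_seed_identical_table(self, expenditure_small):
        again = generate_expenditure_microdata(small_config())
        assert_frame_equal(expenditure_small, again)


class TestTrueParameters:
    def test_echoes_generating_values(self, cfg_small):
        tp = true_parameters(cfg_small)
        assert tp["indicator_params"]["alpha_ind"]["b"] == 0.06
        assert tp["region_effects"] == cfg_small.region_effects

    def test_yaml_roundtrip(self, tmp_path, cfg_small):
        path = tmp_path / "cfg.yaml"
        cfg_small.to_yaml(path)
        restored = SyntheticConfig.from_yaml(path)
        assert true_parameters(restored) == true_parameters(cfg_small)

    def test_perturbed_config_differs(self, cfg_small):
        other = small_config()
        other.indicator_params = dict(other.indicator_params)
        other.indicator_params["alpha_ind"] = IndicatorParams(a0=-0.5, b=0.07, g=0.8)
        assert true_parameters(other) != true_parameters(cfg_small)


class TestConfigValidation:
    def test_non_increasing_years_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            small_config(survey_years=[2000, 2000, 2005])

    def test_bad_food_share_rejected(self):
        with pytest.raises(ValueError, match="food_share_mean"):
            WaveExpenditureParams(6.0, 0.6, 1.2, 18.0, 0.7, 3.0, 1.2)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            small_config(n_clusters=0)

    def test_region_effect_length_checked(self):
        with pytest.raises(ValueError, match="region"):
            small_config(region_effects=[0.0])
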