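"""Seeded generators for DHS-like coverage and GLSS-like expenditure microdata.

Both generators emulate two-stage cluster samples with sampling weights.
Every random draw flows from a single :class:`numpy.random.Generator`
seeded from the configuration, so identical configurations yield
byte-identical tables.

The coverage table additionally emits the latent wealth variable used to
generate assets and outcomes.  Real surveys of course never observe it; it
is carried only so that downstream estimators (wealth index, inequality)
can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import SyntheticConfig

__all__ = [
    "generate_coverage_microdata",
    "generate_expenditure_microdata",
    "true_parameters",
    "COVERAGE_COLUMNS",
    "EXPENDITURE_COLUMNS",
]

COVERAGE_COLUMNS = ("year", "cluster_id", "region_id", "weight", "latent_wealth")
EXPENDITURE_COLUMNS = (
    "year", "region_id", "weight", "hh_size",
    "exp_total", "exp_food", "exp_nonfood", "oop_health",
)


def _inv_logit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _weights(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Inverse-inclusion-probability style weights with mild variation,
    normalised to sum to the sample size."""
    sigma = np.sqrt(np.log1p(cv**2))
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w * (n / w.sum())


def generate_coverage_microdata(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the DHS-like coverage table.

    For each survey year, ``n_clusters`` clusters of
    ``households_per_cluster`` households are drawn.  Latent wealth is a
    cluster random effect plus household noise (standard normal
    marginally, intra-cluster correlation ``cluster_wealth_icc``).  Asset
    ``k`` is Bernoulli with a probability monotone increasing in latent
    wealth; outcome ``j`` is Bernoulli of the inverse logit of
    ``a0 + b * (year - year0) + g * wealth + region offset``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    year0 = config.survey_years[0]
    icc = config.cluster_wealth_icc
    n_hh = config.households_per_cluster
    # asset cut points spread over wealth so asset prevalence varies
    asset_cuts = np.linspace(-1.2, 1.2, config.n_assets)
    asset_load = 1.2

    frames = []
    for year in config.survey_years:
        n = config.n_clusters * n_hh
        cluster_id = np.repeat(np.arange(config.n_clusters), n_hh)
        # clusters assigned to regions in blocks of (nearly) equal size
        region_id = cluster_id * config.n_regions // config.n_clusters
        cl_eff = rng.normal(0.0, np.sqrt(icc), size=config.n_clusters)
        wealth = cl_eff[cluster_id] + rng.normal(0.0, np.sqrt(1.0 - icc), size=n)
        weight = _weights(rng, n, config.weight_cv)

        cols = {
            "year": np.full(n, year, dtype=int),
            "cluster_id": cluster_id,
            "region_id": region_id.astype(int),
            "weight": weight,
            "latent_wealth": wealth,
        }
        for k in range(config.n_assets):
            p = _inv_logit(asset_load * (wealth - asset_cuts[k]))
            cols[f"asset_{k + 1}"] = (rng.random(n) < p).astype(int)

        region_off = np.asarray(config.region_effects)[region_id]
        for name, par in config.indicator_params.items():
            eta = par.a0 + par.b * (year - year0) + par.g * wealth + region_off
            y = (rng.random(n) < _inv_logit(eta)).astype(float)
            if config.missing_rate > 0:
                y[rng.random(n) < config.missing_rate] = np.nan
            cols[f"outcome_{name}"] = y
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def generate_expenditure_microdata(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the GLSS-like expenditure table.

    Per-capita total consumption is log-normal, the food share Beta, and
    OOP health spending zero-inflated log-normal capped at the household's
    non-food spending (OOP being a non-food item).  All monetary columns
    are household totals in nominal currency units of the wave.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    n = config.n_households_expenditure
    oop_region = np.asarray(config.oop_region_effects)

    frames = []
    for year in config.expenditure_years:
        par = config.expenditure_params[year]
        region_id = rng.integers(0, config.n_regions, size=n)
        weight = _weights(rng, n, config.weight_cv)
        hh_size = 1 + rng.poisson(3.0, size=n)
        pc_total = rng.lognormal(par.mu_total, par.sd_total, size=n)
        a = par.food_share_mean * par.food_share_conc
        b = (1.0 - par.food_share_mean) * par.food_share_conc
        share = rng.beta(a, b, size=n)
        exp_total = pc_total * hh_size
        exp_food = share * exp_total
        exp_nonfood = exp_total - exp_food

        any_oop = rng.random(n) < par.p_oop
        oop = np.zeros(n)
        mu = (par.mu_oop + oop_region[region_id]
              + config.oop_consumption_elasticity
              * (np.log(pc_total) - par.mu_total))
        oop[any_oop] = rng.lognormal(mu[any_oop], par.sd_oop) * hh_size[any_oop]
        oop = np.minimum(oop, exp_nonfood)

        frames.append(pd.DataFrame({
            "year": np.full(n, year, dtype=int),
            "region_id": region_id.astype(int),
            "weight": weight,
            "hh_size": hh_size.astype(int),
            "exp_total": exp_total,
            "exp_food": exp_food,
            "exp_nonfood": exp_nonfood,
            "oop_health": oop,
        }))
    return pd.concat(frames, ignore_index=True)


def true_parameters(config: SyntheticConfig) -> dict:
    """Echo the generating parameters, keyed as in the configuration."""
    return {
        "indicator_params": {k: asdict(v) for k, v in config.indicator_params.items()},
        "region_effects": list(config.region_effects),
        "expenditure_params": {int(k): asdict(v) for k, v in config.expenditure_params.items()},
    }
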