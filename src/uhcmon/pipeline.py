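"""End-to-end orchestration: synthesis -> wealth -> estimation -> trends.

Produces five report tables mirroring the standard presentation of a UHC
monitoring study:

1. national coverage per indicator with 2030 projections, target
   probabilities and annual rates of change (plus composite rows);
2. slope index of inequality (SII) per indicator over time;
3. national catastrophic-expenditure / impoverishment / hardship trends;
4. inequality in catastrophic expenditure across consumption quintiles;
5. subnational (regional) catastrophic-expenditure trends.

Every stage is seeded from a single master seed, so a run is
reproducible byte-for-byte; a JSON manifest records the configuration
hash, seed, package versions and runtime.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SyntheticConfig, demo_config
from .coverage import (CCI_COMPONENTS, default_registry, estimate_proportion,
                       IndicatorDefinition)
from .composite import composite_coverage_index, pool_random_effects
from .hardship import (add_consumption_quintiles, estimate_hardship_incidence,
                       estimate_poverty_line)
from .inequality import inequality_from_draws
from .synthetic import generate_coverage_microdata, generate_expenditure_microdata
from .trend import (TrendData, adjust_boundary, annual_rate_of_change,
                    fit_trend_mcmc, prob_financial_protection,
                    prob_target_coverage, project, select_model_by_dic)
from .wealth import add_wealth_columns

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "run_national_analysis", "run_equity_analysis",
    "run_subnational_analysis", "write_report_tables", "run_demo",
]

QUINTILE_RANKS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


@dataclass
class RunConfig:
    """Settings of one full pipeline run."""

    synthetic: SyntheticConfig | None = None
    coverage_csv: str | None = None
    expenditure_csv: str | None = None
    projection_years: list[int] = field(default_factory=lambda: [1995, 2005, 2015, 2030])
    rate_period: tuple[int, int] = (1995, 2030)
    target: float = 0.80
    frp_epsilon: float = 0.01
    che_threshold: float = 0.25
    chains: int = 2
    burn_in: int = 5000
    retained: int = 1000
    seed: int = 0
    strict: bool = False

    def __post_init__(self):
        has_files = self.coverage_csv is not None or self.expenditure_csv is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError("provide exactly one of a synthetic config or input CSV paths")


def load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.synthetic is not None:
        return (generate_coverage_microdata(config.synthetic),
                generate_expenditure_microdata(config.synthetic))
    return (pd.read_csv(config.coverage_csv), pd.read_csv(config.expenditure_csv))


def _fit_seed(config: RunConfig, tag: str):
    """Stable per-fit seed derived from the master seed and a text tag."""
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return np.random.SeedSequence([config.seed, h])


def _series_trend_data(est_by_year: dict[int, tuple[float, float]]) -> TrendData | None:
    """TrendData from {year: (p_hat, n_eff)}; None when under 3 usable years."""
    years, ps = [], []
    for y, (p, n_eff) in sorted(est_by_year.items()):
        if p is None or not np.isfinite(p):
            continue
        years.append(y)
        ps.append(adjust_boundary(p, n_eff))
    if len(set(years)) < 3:
        return None
    return TrendData(years=np.array(years), p=np.array(ps))


def _mcmc_kwargs(config: RunConfig, tag: str) -> dict:
    return dict(chains=config.chains, burn_in=config.burn_in,
                retained=config.retained, seed=_fit_seed(config, tag))


def _trend_row(config: RunConfig, draws) -> dict:
    row = {}
    proj = project(draws, config.projection_years)
    for i, y in enumerate(config.projection_years):
        row[f"cov_{y}"] = proj.mean[i]
        row[f"cov_{y}_lo"] = proj.ci_lo[i]
        row[f"cov_{y}_hi"] = proj.ci_hi[i]
    row["prob_target"] = prob_target_coverage(draws, target=config.target)
    rate = annual_rate_of_change(draws, *config.rate_period)
    row["annual_change_mean"], row["annual_change_lo"], row["annual_change_hi"] = rate
    row["psrf_max"] = max(draws.psrf.values()) if draws.psrf else np.nan
    row["converged"] = draws.converged
    return row


# ---------------------------------------------------------------------------
# Table 1 + Table 3: national analysis
# ---------------------------------------------------------------------------

def run_national_analysis(
    config: RunConfig,
    coverage_df: pd.DataFrame | None = None,
    expenditure_df: pd.DataFrame | None = None,
    registry: list[IndicatorDefinition] | None = None,
) -> dict[str, pd.DataFrame]:
    """National coverage trends per indicator plus composite indices
    (table 1) and national financial-hardship trends (table 3)."""
    registry = registry or default_registry()
    if coverage_df is None or expenditure_df is None:
        cov, exp = load_inputs(config)
        coverage_df = coverage_df if coverage_df is not None else cov
        expenditure_df = expenditure_df if expenditure_df is not None else exp

    years = sorted(coverage_df["year"].unique())
    rows = []
    est_cache: dict[str, dict[int, tuple]] = {}
    for d in registry:
        ests = {}
        for y in years:
            e = estimate_proportion(coverage_df, d.name, int(y))
            ests[int(y)] = (e.p_hat, e.n_eff, e.se)
        est_cache[d.name] = ests
        td = _series_trend_data({y: (p, n) for y, (p, n, _) in ests.items()})
        row = {"indicator": d.name, "class": d.klass}
        if td is None:
            msg = f"indicator {d.name}: fewer than 3 usable survey years"
            if config.strict:
                raise ValueError(msg)
            logger.warning(msg)
            row["flagged"] = True
        else:
            draws = fit_trend_mcmc(td, **_mcmc_kwargs(config, f"national:{d.name}"))
            row.update(_trend_row(config, draws))
            row["flagged"] = False
        rows.append(row)

    # composite prevention / treatment: DerSimonian-Laird pool per year
    for klass in ("prevention", "treatment"):
        names = [d.name for d in registry if d.klass == klass and d.in_composite]
        pooled = {}
        for y in years:
            vals = [
                (100 * est_cache[n][int(y)][0], 100 * est_cache[n][int(y)][2])
                for n in names
                if est_cache[n][int(y)][0] is not None and est_cache[n][int(y)][2] > 0
            ]
            if vals:
                ci = pool_random_effects(vals, label=klass)
                pooled[int(y)] = (np.clip(ci.value, 0.05, 99.95) / 100.0, 1e9)
        td = _series_trend_data(pooled)
        row = {"indicator": f"composite_{klass}", "class": klass, "flagged": td is None}
        if td is not None:
            draws = fit_trend_mcmc(td, **_mcmc_kwargs(config, f"national:composite_{klass}"))
            row.update(_trend_row(config, draws))
        rows.append(row)

    # composite coverage index from the eight RMNCH interventions
    cci_by_year = {}
    have_components = all(n in est_cache for n in CCI_COMPONENTS)
    for y in years if have_components else []:
        comp = [est_cache[n][int(y)][0] for n in CCI_COMPONENTS]
        if all(p is not None for p in comp):
            cci = composite_coverage_index(*[100 * p for p in comp])
            cci_by_year[int(y)] = (np.clip(cci, 0.05, 99.95) / 100.0, 1e9)
    td = _series_trend_data(cci_by_year)
    row = {"indicator": "cci", "class": "composite", "flagged": td is None}
    if td is not None:
        draws = fit_trend_mcmc(td, **_mcmc_kwargs(config, "national:cci"))
        row.update(_trend_row(config, draws))
    rows.append(row)
    table1 = pd.DataFrame(rows)

    # table 3: national hardship trends
    table3 = _hardship_trend_table(config, expenditure_df)
    return {"table1_national_coverage": table1, "table3_national_hardship": table3}


def _hardship_trend_table(config: RunConfig, expenditure_df: pd.DataFrame) -> pd.DataFrame:
    pls = {int(y): estimate_poverty_line(expenditure_df, int(y))
           for y in sorted(expenditure_df["year"].unique())}
    inc = estimate_hardship_incidence(expenditure_df, pls, config.che_threshold)
    rows = []
    for metric in ("che", "imp", "hardship"):
        ests = {i.year: (getattr(i, f"{metric}_pct") / 100.0, i.n) for i in inc}
        td = _series_trend_data({y: (adjust_boundary(p, n), n) for y, (p, n) in ests.items()})
        row = {"metric": metric}
        if td is None:
            row["flagged"] = True
        else:
            draws = fit_trend_mcmc(td, **_mcmc_kwargs(config, f"hardship:{metric}"))
            proj = project(draws, config.projection_years)
            for i, y in enumerate(config.projection_years):
                row[f"pct_{y}"] = proj.mean[i]
                row[f"pct_{y}_lo"] = proj.ci_lo[i]
                row[f"pct_{y}_hi"] = proj.ci_hi[i]
            rate = annual_rate_of_change(draws, *config.rate_period)
            row["annual_change_mean"], row["annual_change_lo"], row["annual_change_hi"] = rate
            row["prob_protection"] = prob_financial_protection(
                draws, epsilon=config.frp_epsilon)
            row["psrf_max"] = max(draws.psrf.values()) if draws.psrf else np.nan
            row["flagged"] = False
        # observed incidences for reference
        for i in inc:
            row[f"observed_{i.year}"] = getattr(i, f"{metric}_pct")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table 2 + Table 4: equity analysis
# ---------------------------------------------------------------------------

def _grouped_trend_data(est: dict, min_years: int = 3) -> TrendData | None:
    """TrendData with quintile labels from {(year, group): (p, n_eff)}."""
    years, ps, groups = [], [], []
    for (y, g), (p, n_eff) in sorted(est.items()):
        if p is None or not np.isfinite(p):
            continue
        years.append(y)
        ps.append(adjust_boundary(p, n_eff))
        groups.append(g)
    if len(set(years)) < min_years:
        return None
    return TrendData(years=np.array(years), p=np.array(ps), groups=np.array(groups))


def _quintile_inequality_rows(config, draws, label: str, years) -> list[dict]:
    rows = []
    qlabels = [f"Q{q}" for q in range(1, 6)]
    for y in years:
        D = np.column_stack([
            100.0 * (1.0 / (1.0 + np.exp(-draws.linear_predictor(y, g))))
            for g in qlabels
        ])
        res = inequality_from_draws(D, QUINTILE_RANKS)
        rows.append({
            "indicator": label, "year": y,
            "sii": res.sii, "sii_lo": res.sii_lo, "sii_hi": res.sii_hi,
            "rii": res.rii, "rii_lo": res.rii_lo, "rii_hi": res.rii_hi,
            "q1": D[:, 0].mean(), "q5": D[:, 4].mean(),
        })
    return rows


def run_equity_analysis(
    config: RunConfig,
    coverage_df: pd.DataFrame | None = None,
    expenditure_df: pd.DataFrame | None = None,
    registry: list[IndicatorDefinition] | None = None,
) -> dict[str, pd.DataFrame]:
    """Wealth-quintile trends: SII/RII per indicator (table 2) and
    inequality in catastrophic expenditure (table 4).  Quintile-adjusted
    models with and without a quintile x year interaction are compared by
    DIC and the winner drives the reported draws."""
    registry = registry or default_registry()
    if coverage_df is None or expenditure_df is None:
        cov, exp = load_inputs(config)
        coverage_df = coverage_df if coverage_df is not None else cov
        expenditure_df = expenditure_df if expenditure_df is not None else exp
    if "quintile" not in coverage_df.columns:
        coverage_df = add_wealth_columns(coverage_df)

    years = sorted(int(y) for y in coverage_df["year"].unique())
    t2_rows, model_rows = [], []
    for d in registry:
        est = {}
        for y in years:
            for q in range(1, 6):
                e = estimate_proportion(coverage_df, d.name, y, "quintile", q)
                est[(y, f"Q{q}")] = (e.p_hat, e.n_eff)
        td = _grouped_trend_data(est)
        if td is None:
            logger.warning("equity: indicator %s lacks usable data", d.name)
            continue
        draws, diags = select_model_by_dic(
            td, method="mcmc", **_mcmc_kwargs(config, f"equity:{d.name}"))
        if draws is None:
            logger.warning("equity: %s not converged; skipped", d.name)
            continue
        model_rows.append({
            "indicator": d.name,
            "dic_no_interaction": diags["no_interaction"].dic,
            "dic_interaction": diags["interaction"].dic,
            "model_choice": diags["choice"],
        })
        t2_rows.extend(
            _quintile_inequality_rows(config, draws, d.name, config.projection_years))
    table2 = pd.DataFrame(t2_rows)

    # table 4: CHE across consumption quintiles
    exp_q = add_consumption_quintiles(expenditure_df)
    pls = {int(y): estimate_poverty_line(exp_q, int(y))
           for y in sorted(exp_q["year"].unique())}
    inc = estimate_hardship_incidence(exp_q, pls, config.che_threshold, group="quintile")
    est = {(i.year, i.group): (adjust_boundary(i.che_pct / 100.0, i.n), i.n) for i in inc}
    td = _grouped_trend_data(est)
    t4_rows = []
    if td is not None:
        draws, diags = select_model_by_dic(
            td, method="mcmc", **_mcmc_kwargs(config, "equity:che"))
        if draws is not None:
            for r in _quintile_inequality_rows(config, draws, "che", config.projection_years):
                r["prob_protection_q1"] = prob_financial_protection(
                    draws, epsilon=config.frp_epsilon, group="Q1")
                r["prob_protection_q5"] = prob_financial_protection(
                    draws, epsilon=config.frp_epsilon, group="Q5")
                t4_rows.append(r)
    table4 = pd.DataFrame(t4_rows)
    return {"table2_sii_coverage": table2, "table4_che_inequality": table4,
            "equity_model_selection": pd.DataFrame(model_rows)}


# ---------------------------------------------------------------------------
# Table 5: subnational analysis
# ---------------------------------------------------------------------------

def run_subnational_analysis(
    config: RunConfig,
    expenditure_df: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Regional catastrophic-expenditure trends with financial-protection
    probabilities (table 5).  Regions observed in fewer than 2 waves are
    excluded with a warning."""
    if expenditure_df is None:
        _, expenditure_df = load_inputs(config)
    pls = {int(y): estimate_poverty_line(expenditure_df, int(y))
           for y in sorted(expenditure_df["year"].unique())}
    inc = estimate_hardship_incidence(expenditure_df, pls, config.che_threshold,
                                      group="region")
    waves_per_region = {}
    for i in inc:
        waves_per_region.setdefault(i.group, set()).add(i.year)
    keep = {g for g, w in waves_per_region.items() if len(w) >= 2}
    for g in sorted(set(waves_per_region) - keep):
        logger.warning("region %s has fewer than 2 survey waves; excluded", g)

    est = {(i.year, i.group): (adjust_boundary(i.che_pct / 100.0, i.n), i.n)
           for i in inc if i.group in keep}
    td = _grouped_trend_data(est)
    rows = []
    if td is not None:
        draws, diags = select_model_by_dic(
            td, method="mcmc", **_mcmc_kwargs(config, "subnational:che"))
        if draws is not None:
            for g in sorted(keep):
                proj = project(draws, config.projection_years, group=g)
                row = {"region": g, "model_choice": diags["choice"]}
                for i, y in enumerate(config.projection_years):
                    row[f"che_{y}"] = proj.mean[i]
                    row[f"che_{y}_lo"] = proj.ci_lo[i]
                    row[f"che_{y}_hi"] = proj.ci_hi[i]
                row["prob_protection"] = prob_financial_protection(
                    draws, epsilon=config.frp_epsilon, group=g)
                rows.append(row)
    return {"table5_subnational_che": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# report writing and demo
# ---------------------------------------------------------------------------

def write_report_tables(results: dict[str, pd.DataFrame], outdir: str | Path,
                        config: RunConfig, runtime_s: float | None = None) -> list[Path]:
    """One CSV per table plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(df))
    cfg_dict = {
        "seed": config.seed,
        "target": config.target,
        "frp_epsilon": config.frp_epsilon,
        "che_threshold": config.che_threshold,
        "chains": config.chains,
        "burn_in": config.burn_in,
        "retained": config.retained,
        "synthetic": config.synthetic.to_dict() if config.synthetic else None,
        "coverage_csv": config.coverage_csv,
        "expenditure_csv": config.expenditure_csv,
    }
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "uhcmon_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "tables": {p.name: sum(1 for _ in open(p)) - 1 for p in written},
        "runtime_s": runtime_s,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(mpath)
    return written


def run_demo(seed: int = 0, outdir: str | Path = "demo_out",
             synthetic: SyntheticConfig | None = None,
             registry: list[IndicatorDefinition] | None = None) -> dict[str, pd.DataFrame]:
    """Full pipeline on a small synthetic scenario; writes all five report
    tables plus the manifest and returns the tables in memory."""
    t_start = time.monotonic()
    cfg = RunConfig(synthetic=synthetic or demo_config(seed), seed=seed)
    cov, exp = load_inputs(cfg)
    cov = add_wealth_columns(cov)
    results = {}
    results.update(run_national_analysis(cfg, cov, exp, registry))
    results.update(run_equity_analysis(cfg, cov, exp, registry))
    results.update(run_subnational_analysis(cfg, exp))
    write_report_tables(results, outdir, cfg, runtime_s=time.monotonic() - t_start)
    return results
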