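"""Configuration objects for the synthetic survey generators.

A :class:`SyntheticConfig` fully determines a pair of synthetic surveys:

* DHS-like *coverage* microdata — a two-stage clustered sample per survey
  year carrying sampling weights, region labels, binary household asset
  indicators, and one binary service-use outcome column per health
  indicator.  Each indicator's prevalence follows a linear trend on the
  logit scale with a wealth gradient and additive region offsets.
* GLSS-like *expenditure* microdata — household consumption records
  (food / non-food split) with zero-inflated log-normal out-of-pocket
  (OOP) health spending, parametrised per survey wave so that the
  incidence of catastrophic spending can decline across waves.

Configurations round-trip through YAML so a run is reproducible from a
single text file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "IndicatorParams",
    "WaveExpenditureParams",
    "SyntheticConfig",
    "default_config",
    "demo_config",
]


@dataclass(frozen=True)
class IndicatorParams:
    """Generating parameters of one binary service-use indicator.

    Attributes
    ----------
    a0:
        Intercept on the logit scale at the first survey year.
    b:
        Linear year trend, logit units per calendar year.
    g:
        Wealth gradient, logit units per unit of latent wealth
        (latent wealth is standard normal marginally).
    """

    a0: float
    b: float
    g: float


@dataclass(frozen=True)
class WaveExpenditureParams:
    """Generating parameters of one expenditure survey wave.

    ``mu_total``/``sd_total`` are the log-scale mean and sd of per-capita
    total consumption; ``food_share_mean``/``food_share_conc`` parametrise
    a Beta distribution for the household food share; ``p_oop`` is the
    probability of any OOP health spending and ``mu_oop``/``sd_oop`` the
    log-scale parameters of OOP given any (capped at non-food spending).
    """

    mu_total: float
    sd_total: float
    food_share_mean: float
    food_share_conc: float
    p_oop: float
    mu_oop: float
    sd_oop: float

    def __post_init__(self) -> None:
        if not 0.0 < self.food_share_mean < 1.0:
            raise ValueError("food_share_mean must lie in (0, 1)")
        if self.sd_total <= 0 or self.sd_oop <= 0:
            raise ValueError("sd parameters must be positive")
        if self.food_share_conc <= 0:
            raise ValueError("food_share_conc must be positive")
        if not 0.0 <= self.p_oop <= 1.0:
            raise ValueError("p_oop must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    """Full specification of the synthetic coverage and expenditure surveys."""

    survey_years: list[int]
    n_clusters: int
    households_per_cluster: int
    n_regions: int
    n_assets: int
    indicator_params: dict[str, IndicatorParams]
    region_effects: list[float]
    expenditure_params: dict[int, WaveExpenditureParams]
    n_households_expenditure: int = 1000
    expenditure_years: list[int] | None = None
    cluster_wealth_icc: float = 0.3
    weight_cv: float = 0.25
    missing_rate: float = 0.0
    oop_region_effects: list[float] | None = None
    # elasticity of OOP health spending w.r.t. per-capita consumption;
    # below 1 so the OOP *share* of non-food spending falls with wealth,
    # giving the documented mild pro-poor concentration of catastrophic
    # spending rather than an extreme one
    oop_consumption_elasticity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in (self.n_clusters, self.households_per_cluster,
                                self.n_regions, self.n_assets,
                                self.n_households_expenditure)):
            raise ValueError("all counts must be positive")
        years = list(self.survey_years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("survey_years must be strictly increasing")
        if len(self.region_effects) != self.n_regions:
            raise ValueError("region_effects must have one entry per region")
        if not 0.0 <= self.cluster_wealth_icc < 1.0:
            raise ValueError("cluster_wealth_icc must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.expenditure_years is None:
            self.expenditure_years = list(self.survey_years)
        eyears = list(self.expenditure_years)
        if any(b <= a for a, b in zip(eyears, eyears[1:])):
            raise ValueError("expenditure_years must be strictly increasing")
        for y in eyears:
            if y not in self.expenditure_params:
                raise ValueError(f"no expenditure parameters for wave {y}")
        if self.oop_region_effects is None:
            self.oop_region_effects = [0.0] * self.n_regions
        if len(self.oop_region_effects) != self.n_regions:
            raise ValueError("oop_region_effects must have one entry per region")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["indicator_params"] = {k: asdict(v) for k, v in self.indicator_params.items()}
        d["expenditure_params"] = {int(k): asdict(v) for k, v in self.expenditure_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["indicator_params"] = {
            k: IndicatorParams(**v) for k, v in d["indicator_params"].items()
        }
        d["expenditure_params"] = {
            int(k): WaveExpenditureParams(**v) for k, v in d["expenditure_params"].items()
        }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

# Logit-scale trend parameters per indicator.  Intercepts and slopes are
# anchored to published national coverage levels for Ghana circa 1995 and
# 2015 (logit-interpolated); wealth gradients are graded so that services
# with well-documented socioeconomic gaps (institutional delivery, skilled
# birth attendance, sanitation) carry the steepest gradients while
# immunisations are nearly equitable.
_DEFAULT_INDICATOR_PARAMS: dict[str, IndicatorParams] = {
    # prevention
    "family_planning": IndicatorParams(a0=-0.549, b=0.0200, g=0.30),
    "anc4": IndicatorParams(a0=0.319, b=0.0704, g=0.70),
    "pnc_mothers": IndicatorParams(a0=-5.644, b=0.3512, g=1.00),
    "exclusive_breastfeeding": IndicatorParams(a0=-1.614, b=0.1233, g=0.10),
    "itn_children": IndicatorParams(a0=-4.805, b=0.2662, g=0.15),
    "itn_mothers": IndicatorParams(a0=-5.538, b=0.2904, g=0.15),
    "bcg": IndicatorParams(a0=1.727, b=0.0911, g=0.25),
    "dpt3": IndicatorParams(a0=0.726, b=0.0788, g=0.25),
    "polio3": IndicatorParams(a0=0.749, b=0.0604, g=0.20),
    "measles": IndicatorParams(a0=0.824, b=0.0809, g=0.25),
    "improved_water": IndicatorParams(a0=0.443, b=0.0757, g=0.80),
    "sanitation": IndicatorParams(a0=-1.121, b=0.0850, g=1.80),
    "no_tobacco": IndicatorParams(a0=2.426, b=-0.0050, g=0.30),
    # treatment
    "institutional_delivery": IndicatorParams(a0=-0.393, b=0.0656, g=1.80),
    "sba": IndicatorParams(a0=-0.352, b=0.0651, g=1.60),
    "ort": IndicatorParams(a0=-0.426, b=0.0649, g=0.30),
    "care_seeking_pneumonia": IndicatorParams(a0=-0.580, b=0.0288, g=0.50),
}

# Additive logit offsets per region (10 regions); the spread emulates the
# documented gap between the best- and worst-served regions.
_DEFAULT_REGION_EFFECTS = [0.5, 0.2, 0.1, 0.1, 0.0, 0.0, -0.1, -0.2, -0.2, -0.6]

# Expenditure waves: nominal per-capita consumption grows while the OOP
# level stays flat, so the share of non-food spending going to health — and
# with it the catastrophic-spending rate — declines across waves.
_DEFAULT_EXPENDITURE_PARAMS: dict[int, WaveExpenditureParams] = {
    1992: WaveExpenditureParams(6.2, 0.6, 0.55, 18.0, 0.70, 2.94, 1.2),
    1998: WaveExpenditureParams(6.6, 0.6, 0.53, 18.0, 0.70, 2.93, 1.2),
    2006: WaveExpenditureParams(7.2, 0.6, 0.50, 18.0, 0.70, 2.99, 1.2),
    2013: WaveExpenditureParams(7.8, 0.6, 0.47, 18.0, 0.70, 3.21, 1.2),
}

_DEFAULT_OOP_REGION_EFFECTS = [0.15, 0.05, 0.2, 0.05, -0.4, -0.1, -0.4, -0.5, 0.15, 0.0]


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default synthetic scenario: 5 DHS-like rounds, 4 GLSS-like waves,
    10 regions, 12 binary assets, 17 indicators."""
    return SyntheticConfig(
        survey_years=[1993, 1998, 2003, 2008, 2014],
        n_clusters=100,
        households_per_cluster=25,
        n_regions=10,
        n_assets=12,
        indicator_params=dict(_DEFAULT_INDICATOR_PARAMS),
        region_effects=list(_DEFAULT_REGION_EFFECTS),
        expenditure_params=dict(_DEFAULT_EXPENDITURE_PARAMS),
        expenditure_years=[1992, 1998, 2006, 2013],
        n_households_expenditure=3000,
        oop_region_effects=list(_DEFAULT_OOP_REGION_EFFECTS),
        seed=seed,
    )


def demo_config(seed: int = 0) -> SyntheticConfig:
    """A scaled-down scenario for the end-to-end demo (minutes, one CPU)."""
    cfg = default_config(seed)
    cfg.n_clusters = 40
    cfg.households_per_cluster = 15
    cfg.n_households_expenditure = 1200
    return cfg
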