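"""Survey-weighted coverage estimation with design-based uncertainty.

Point estimates are Hajek ratio means ``sum(w*y) / sum(w)`` over eligible
rows.  Variance uses Taylor linearisation with clusters as primary
sampling units within a survey year; confidence intervals are Wald
intervals on the logit scale, back-transformed, so they always stay
inside [0, 1].  Boundary estimates (0 or 1) keep their exact point value
but receive a half-success continuity adjustment before the logit so the
interval — and any downstream logit transform — stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndicatorDefinition",
    "CoverageEstimate",
    "default_registry",
    "CCI_COMPONENTS",
    "estimate_proportion",
    "estimate_all",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class IndicatorDefinition:
    """One health-service indicator: name, prevention/treatment class,
    whether it enters the composite index for its class, and the coverage
    target (0.80 by default, the service-coverage goal for 2030)."""

    name: str
    klass: str  # "prevention" | "treatment"
    in_composite: bool
    target: float = 0.80

    def __post_init__(self):
        if self.klass not in ("prevention", "treatment"):
            raise ValueError(f"unknown indicator class {self.klass!r}")


def default_registry() -> list[IndicatorDefinition]:
    """The 17 default indicators: 13 prevention (9 of which enter the
    composite prevention index) and 4 treatment (all in the composite)."""
    prevention_in = {
        "anc4", "exclusive_breastfeeding", "family_planning", "improved_water",
        "sanitation", "bcg", "measles", "dpt3", "polio3",
    }
    prevention = [
        "family_planning", "anc4", "pnc_mothers", "exclusive_breastfeeding",
        "itn_children", "itn_mothers", "bcg", "dpt3", "polio3", "measles",
        "improved_water", "sanitation", "no_tobacco",
    ]
    treatment = ["institutional_delivery", "sba", "ort", "care_seeking_pneumonia"]
    defs = [IndicatorDefinition(n, "prevention", n in prevention_in) for n in prevention]
    defs += [IndicatorDefinition(n, "treatment", True) for n in treatment]
    return defs


#: The eight interventions of the composite coverage index, in the order
#: expected by :func:`uhcmon.composite.composite_coverage_index`.
CCI_COMPONENTS = (
    "family_planning", "anc4", "sba", "bcg",
    "dpt3", "measles", "ort", "care_seeking_pneumonia",
)


@dataclass
class CoverageEstimate:
    indicator: str
    year: int
    group_type: str  # "national" | "quintile" | "region"
    group: str
    p_hat: float | None
    se: float | None
    ci_lo: float | None
    ci_hi: float | None
    n_eff: float
    missing: bool = False


def _linearized_variance(
    y: np.ndarray, w: np.ndarray, cluster: np.ndarray, p_hat: float
) -> float:
    """Taylor-linearised variance of the weighted ratio mean, clusters as
    PSUs.  Falls back to the weighted SRS formula when there is a single
    cluster."""
    z = w * (y - p_hat) / w.sum()
    clusters = pd.Series(z).groupby(cluster).sum().to_numpy()
    nc = len(clusters)
    if nc < 2:
        n = len(y)
        if n < 2:
            return float("nan")
        return float(np.sum(z**2) * n / (n - 1))
    return float(nc / (nc - 1) * np.sum((clusters - clusters.mean()) ** 2))


def estimate_proportion(
    microdata: pd.DataFrame,
    indicator: str,
    year: int,
    group_type: str = "national",
    group=None,
    alpha: float = 0.05,
) -> CoverageEstimate:
    """Design-based proportion for one indicator x year x group cell.

    An empty denominator (no eligible rows with a non-missing outcome)
    yields a flagged estimate with missing values, never a silent zero.
    """
    col = f"outcome_{indicator}"
    if col not in microdata.columns:
        raise KeyError(f"unknown indicator {indicator!r}")
    sub = microdata.loc[microdata["year"] == year]
    label = "national"
    if group_type == "quintile":
        sub = sub.loc[sub["quintile"] == group]
        label = f"Q{group}"
    elif group_type == "region":
        sub = sub.loc[sub["region_id"] == group]
        label = f"region_{group}"
    elif group_type != "national":
        raise ValueError(f"unknown group_type {group_type!r}")
    sub = sub.loc[sub[col].notna()]
    if len(sub) == 0:
        return CoverageEstimate(indicator, year, group_type, label,
                                None, None, None, None, 0.0, missing=True)

    y = sub[col].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    cluster = sub["cluster_id"].to_numpy() if "cluster_id" in sub else np.zeros(len(sub))
    p_hat = float(w @ y / w.sum())
    var = _linearized_variance(y, w, cluster, p_hat)
    se = float(np.sqrt(var)) if np.isfinite(var) else float("nan")
    n_eff = float(w.sum() ** 2 / np.sum(w**2))

    # half-success continuity adjustment keeps the logit finite at 0/1
    p_ci = p_hat
    if p_hat <= 0.0 or p_hat >= 1.0:
        p_ci = (p_hat * n_eff + 0.5) / (n_eff + 1.0)
    z = stats.norm.ppf(1 - alpha / 2)
    if se > 0 and np.isfinite(se):
        se_logit = se / (p_ci * (1 - p_ci))
        lo = float(1 / (1 + np.exp(-(np.log(p_ci / (1 - p_ci)) - z * se_logit))))
        hi = float(1 / (1 + np.exp(-(np.log(p_ci / (1 - p_ci)) + z * se_logit))))
    else:
        lo = hi = p_hat
    return CoverageEstimate(indicator, year, group_type, label,
                            p_hat, se, lo, hi, n_eff)


def estimate_all(
    microdata: pd.DataFrame,
    registry: list[IndicatorDefinition],
    groupings: list[str] = ("national",),
) -> list[CoverageEstimate]:
    """Estimate every indicator x year x group cell in the cross product.

    Indicator-years with no observed data are emitted as flagged missing
    cells; a name absent from the table entirely raises."""
    out: list[CoverageEstimate] = []
    years = sorted(microdata["year"].unique())
    for d in registry:
        if f"outcome_{d.name}" not in microdata.columns:
            raise KeyError(f"indicator {d.name!r} not present in microdata")
        for year in years:
            for g in groupings:
                if g == "national":
                    out.append(estimate_proportion(microdata, d.name, year))
                elif g == "quintile":
                    for q in range(1, 6):
                        out.append(estimate_proportion(microdata, d.name, year, "quintile", q))
                elif g == "region":
                    for r in sorted(microdata["region_id"].unique()):
                        out.append(estimate_proportion(microdata, d.name, year, "region", r))
                else:
                    raise ValueError(f"unknown grouping {g!r}")
    return out


def estimates_to_frame(
    estimates: list[CoverageEstimate],
    registry: list[IndicatorDefinition] | None = None,
) -> pd.DataFrame:
    """Tabulate estimates with the documented output schema."""
    klass = {d.name: d.klass for d in registry} if registry else {}
    return pd.DataFrame(
        {
            "indicator": [e.indicator for e in estimates],
            "class": [klass.get(e.indicator, "") for e in estimates],
            "year": [e.year for e in estimates],
            "group_type": [e.group_type for e in estimates],
            "group": [e.group for e in estimates],
            "p_hat": [e.p_hat for e in estimates],
            "se": [e.se for e in estimates],
            "ci_lo": [e.ci_lo for e in estimates],
            "ci_hi": [e.ci_hi for e in estimates],
            "n_eff": [e.n_eff for e in estimates],
        }
    )
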