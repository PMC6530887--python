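"""Financial-hardship indicators from household expenditure microdata.

Three household-level flags are derived from out-of-pocket (OOP) health
spending:

* **Catastrophic health expenditure (CHE)** — OOP strictly exceeding a
  threshold share (default 25%) of non-food consumption.
* **Impoverishment** — a household not already below the poverty line
  whose per-capita spending net of OOP falls below it.  The poverty line
  is the food-share method: the weighted mean per-capita food spending of
  households whose food share sits in the 45th–55th percentile band.
* **Financial hardship** — the union of the two.

Incidences are survey-weighted proportions with linearised confidence
intervals, reported per year and optionally per group (consumption
quintile or region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PovertyLine",
    "HardshipIncidence",
    "compute_oop_share",
    "flag_catastrophic",
    "estimate_poverty_line",
    "flag_impoverished",
    "compute_hardship_flags",
    "estimate_hardship_incidence",
    "add_consumption_quintiles",
]


@dataclass
class PovertyLine:
    value: float  # currency per capita
    band: tuple[float, float]  # food-share bounds actually used
    n_band: int  # households inside the band
    year: int


@dataclass
class HardshipIncidence:
    year: int
    group_type: str
    group: str
    che_pct: float
    che_lo: float
    che_hi: float
    imp_pct: float
    imp_lo: float
    imp_hi: float
    hardship_pct: float
    hardship_lo: float
    hardship_hi: float
    poverty_line: float
    n: int


def compute_oop_share(oop_health: float, exp_nonfood: float) -> float:
    """OOP health spending as a share of non-food consumption.

    A household with no non-food spending but positive OOP is assigned the
    maximal share 1 (and logged); no non-food and no OOP gives share 0.
    """
    if exp_nonfood <= 0:
        if oop_health > 0:
            logger.warning("household with OOP > 0 but no non-food spending; share set to 1")
            return 1.0
        return 0.0
    return float(min(oop_health / exp_nonfood, 1.0))


def flag_catastrophic(share: float, threshold: float = 0.25) -> int:
    """1 iff the OOP share strictly exceeds the threshold."""
    return int(share > threshold)


def _weighted_quantile_lower(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Lower-inclusive weighted quantile: the smallest value whose
    cumulative weight fraction reaches q."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, len(v) - 1)])


def estimate_poverty_line(microdata: pd.DataFrame, year: int) -> PovertyLine:
    """Food-share poverty line for one survey wave.

    Selects households whose food share (food / total) lies within the
    weighted 45th–55th percentile band of food shares and returns their
    weighted mean per-capita food spending.  An empty band is widened
    symmetrically by one percentile at a time until nonempty.
    """
    sub = microdata.loc[microdata["year"] == year]
    if len(sub) < 3:
        raise ValueError(f"need at least 3 households in year {year}")
    share = (sub["exp_food"] / sub["exp_total"]).to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    pc_food = (sub["exp_food"] / sub["hh_size"]).to_numpy(dtype=float)

    lo_q, hi_q = 0.45, 0.55
    while True:
        lo = _weighted_quantile_lower(share, w, lo_q)
        hi = _weighted_quantile_lower(share, w, hi_q)
        in_band = (share >= lo) & (share <= hi)
        if in_band.any():
            break
        lo_q, hi_q = max(0.0, lo_q - 0.01), min(1.0, hi_q + 0.01)
        logger.warning("empty food-share band in %s; widened to (%.2f, %.2f)", year, lo_q, hi_q)
    value = float(w[in_band] @ pc_food[in_band] / w[in_band].sum())
    return PovertyLine(value=value, band=(lo, hi), n_band=int(in_band.sum()), year=year)


def flag_impoverished(
    exp_total: float, oop_health: float, hh_size: float, pl: PovertyLine
) -> tuple[int, int]:
    """(pre_poor, impoverished) for one household.

    A household already below the poverty line before paying (pre_poor)
    cannot be newly impoverished; impoverishment requires crossing the
    line because of the OOP payment.
    """
    pc_total = exp_total / hh_size
    pre_poor = int(pc_total < pl.value)
    impoverished = int(pre_poor == 0 and (exp_total - oop_health) / hh_size < pl.value)
    return pre_poor, impoverished


def compute_hardship_flags(
    microdata: pd.DataFrame,
    pl_by_year: dict[int, PovertyLine],
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Vectorised household flags: oop_share, che, pre_poor, impoverished,
    hardship."""
    out = microdata.copy()
    nonfood = out["exp_nonfood"].to_numpy(dtype=float)
    oop = out["oop_health"].to_numpy(dtype=float)
    share = np.zeros(len(out))
    pos = nonfood > 0
    share[pos] = np.minimum(oop[pos] / nonfood[pos], 1.0)
    share[~pos & (oop > 0)] = 1.0
    if np.any(~pos & (oop > 0)):
        logger.warning("%d households with OOP > 0 but no non-food spending",
                       int(np.sum(~pos & (oop > 0))))
    out["oop_share"] = share
    out["che"] = (share > threshold).astype(int)

    pl = out["year"].map({y: p.value for y, p in pl_by_year.items()}).to_numpy(dtype=float)
    pc_total = (out["exp_total"] / out["hh_size"]).to_numpy(dtype=float)
    pc_post = ((out["exp_total"] - out["oop_health"]) / out["hh_size"]).to_numpy(dtype=float)
    out["pre_poor"] = (pc_total < pl).astype(int)
    out["impoverished"] = ((pc_total >= pl) & (pc_post < pl)).astype(int)
    out["hardship"] = ((out["che"] == 1) | (out["impoverished"] == 1)).astype(int)
    out["poverty_line"] = pl
    return out


def _weighted_prop_ci(y: np.ndarray, w: np.ndarray, alpha: float = 0.05):
    p = float(w @ y / w.sum())
    z = w * (y - p) / w.sum()
    n = len(y)
    var = float(np.sum(z**2) * n / (n - 1)) if n > 1 else float("nan")
    se = np.sqrt(var)
    if se > 0 and 0 < p < 1:
        zc = stats.norm.ppf(1 - alpha / 2)
        se_logit = se / (p * (1 - p))
        eta = np.log(p / (1 - p))
        lo = 1 / (1 + np.exp(-(eta - zc * se_logit)))
        hi = 1 / (1 + np.exp(-(eta + zc * se_logit)))
    else:
        lo = hi = p
    return p, float(lo), float(hi)


def estimate_hardship_incidence(
    microdata: pd.DataFrame,
    pl_by_year: dict[int, PovertyLine] | None = None,
    threshold: float = 0.25,
    group: str = "national",
) -> list[HardshipIncidence]:
    """Weighted CHE / impoverishment / hardship incidence per year x group.

    ``group`` is "national", "quintile" (requires a ``quintile`` column,
    see :func:`add_consumption_quintiles`) or "region".
    """
    if pl_by_year is None:
        pl_by_year = {
            int(y): estimate_poverty_line(microdata, int(y))
            for y in sorted(microdata["year"].unique())
        }
    flagged = compute_hardship_flags(microdata, pl_by_year, threshold)
    out: list[HardshipIncidence] = []
    for year in sorted(flagged["year"].unique()):
        ysub = flagged.loc[flagged["year"] == year]
        if group == "national":
            cells = [("national", "national", ysub)]
        elif group == "quintile":
            cells = [("quintile", f"Q{q}", ysub.loc[ysub["quintile"] == q]) for q in range(1, 6)]
        elif group == "region":
            cells = [("region", f"region_{r}", ysub.loc[ysub["region_id"] == r])
                     for r in sorted(flagged["region_id"].unique())]
        else:
            raise ValueError(f"unknown group {group!r}")
        for gtype, label, sub in cells:
            if len(sub) == 0:
                logger.warning("empty group %s in %s", label, year)
                continue
            w = sub["weight"].to_numpy(dtype=float)
            che = _weighted_prop_ci(sub["che"].to_numpy(dtype=float), w)
            imp = _weighted_prop_ci(sub["impoverished"].to_numpy(dtype=float), w)
            hs = _weighted_prop_ci(sub["hardship"].to_numpy(dtype=float), w)
            out.append(HardshipIncidence(
                year=int(year), group_type=gtype, group=label,
                che_pct=100 * che[0], che_lo=100 * che[1], che_hi=100 * che[2],
                imp_pct=100 * imp[0], imp_lo=100 * imp[1], imp_hi=100 * imp[2],
                hardship_pct=100 * hs[0], hardship_lo=100 * hs[1], hardship_hi=100 * hs[2],
                poverty_line=pl_by_year[int(year)].value, n=len(sub),
            ))
    return out


def add_consumption_quintiles(microdata: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted consumption quintiles per wave, ranked by
    per-capita total expenditure (the economic-status measure available in
    expenditure surveys).  Q1 is the poorest."""
    from .wealth import _midpoint_ranks

    out = microdata.copy()
    out["quintile"] = 0
    for year in sorted(out["year"].unique()):
        mask = (out["year"] == year).to_numpy()
        pc = (out.loc[mask, "exp_total"] / out.loc[mask, "hh_size"]).to_numpy(dtype=float)
        w = out.loc[mask, "weight"].to_numpy(dtype=float)
        ranks = _midpoint_ranks(pc, w)
        out.loc[mask, "quintile"] = np.minimum((ranks * 5).astype(int), 4) + 1
    return out


def incidence_to_frame(incidences: list[HardshipIncidence]) -> pd.DataFrame:
    """Tabulate with the documented output schema."""
    return pd.DataFrame([vars(i) for i in incidences])
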