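"""Slope and relative indices of inequality across wealth quintiles.

Both indices come from a weighted least-squares regression of the
quintile-level outcome (percent) on the quintiles' relative-rank
midpoints, weighted by the quintile population shares:

* **SII** — the fitted slope: the modelled outcome difference between the
  extremes of the wealth distribution (rank 1, richest, minus rank 0,
  poorest), in percentage points.
* **RII** — the ratio of fitted values at the extremes,
  ``fitted(1) / fitted(0)`` (richest over poorest), so an outcome that
  rises with wealth gives RII > 1 and one that falls (such as
  catastrophic health spending) gives RII < 1.

Credible intervals come from applying the same closed form to each joint
posterior draw of the five quintile values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InequalityResult", "slope_and_relative_index", "inequality_from_draws"]


@dataclass
class InequalityResult:
    sii: float
    rii: float | None  # None when fitted(0) <= 0 (ratio undefined)
    sii_lo: float | None = None
    sii_hi: float | None = None
    rii_lo: float | None = None
    rii_hi: float | None = None


def _wls_extremes(values: np.ndarray, ranks: np.ndarray, shares: np.ndarray):
    """Closed-form WLS of value on rank; returns (fitted(0), fitted(1))."""
    w = shares / shares.sum()
    rbar = w @ ranks
    vbar = w @ values
    slope = (w @ ((ranks - rbar) * (values - vbar))) / (w @ (ranks - rbar) ** 2)
    intercept = vbar - slope * rbar
    return intercept, intercept + slope


def slope_and_relative_index(
    values_by_quintile, ranks, shares=None
) -> InequalityResult:
    """SII and RII from five quintile values (percent), their rank
    midpoints, and population shares (default: equal fifths)."""
    values = np.asarray(values_by_quintile, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if shares is None:
        shares = np.full(len(values), 1.0 / len(values))
    shares = np.asarray(shares, dtype=float)
    if not (len(values) == len(ranks) == len(shares)):
        raise ValueError("values, ranks and shares must have equal length")
    f0, f1 = _wls_extremes(values, ranks, shares)
    sii = f1 - f0
    rii = float(f1 / f0) if f0 > 0 else None
    return InequalityResult(sii=float(sii), rii=rii)


def inequality_from_draws(
    draws_by_quintile: np.ndarray, ranks, shares=None
) -> InequalityResult:
    """SII / RII posterior summaries from joint quintile draws.

    ``draws_by_quintile`` has shape (n_draws, 5); each row is one joint
    posterior draw of the five quintile values, so rows must index the
    same underlying posterior draw in every column (permuting draws within
    one quintile breaks the joint dependence and is a caller error).
    Reports posterior means and central 95% intervals.
    """
    D = np.asarray(draws_by_quintile, dtype=float)
    if D.ndim != 2:
        raise ValueError("draws must be a 2-D array (n_draws, n_quintiles)")
    ranks = np.asarray(ranks, dtype=float)
    if shares is None:
        shares = np.full(D.shape[1], 1.0 / D.shape[1])
    shares = np.asarray(shares, dtype=float)

    w = shares / shares.sum()
    rbar = w @ ranks
    denom = w @ (ranks - rbar) ** 2
    vbar = D @ w
    slope = (D - vbar[:, None]) @ (w * (ranks - rbar)) / denom
    f0 = vbar - slope * rbar
    f1 = f0 + slope

    sii = f1 - f0
    valid = f0 > 0
    rii = np.where(valid, f1 / np.where(valid, f0, 1.0), np.nan)
    res = InequalityResult(
        sii=float(np.mean(sii)),
        rii=float(np.nanmean(rii)) if valid.any() else None,
        sii_lo=float(np.percentile(sii, 2.5)),
        sii_hi=float(np.percentile(sii, 97.5)),
    )
    if valid.all():
        res.rii_lo = float(np.percentile(rii, 2.5))
        res.rii_hi = float(np.percentile(rii, 97.5))
    return res
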