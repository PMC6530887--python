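"""Composite coverage summaries.

Two kinds of composite are provided:

* Random-effects pooling (DerSimonian–Laird) of indicator-level estimates
  into the composite prevention and composite treatment indices.  With
  equal standard errors this reduces to the arithmetic mean of the
  inputs.  Pooling is done on the percent scale by default; a logit-scale
  option exists for sensitivity analysis.
* The composite coverage index (CCI) of reproductive, maternal, newborn
  and child health: a fixed weighting of eight interventions across four
  specialties — family planning 1/4; maternal & newborn care 1/4 split
  between skilled birth attendance and antenatal care; immunisation 1/4
  with DPT3 double-weighted against measles and BCG; case management 1/4
  split between oral rehydration therapy and care-seeking for pneumonia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompositeIndex", "pool_random_effects", "composite_coverage_index"]


@dataclass
class CompositeIndex:
    label: str
    value: float  # pooled value, percent scale
    se: float
    tau2: float  # between-indicator variance
    ci_lo: float
    ci_hi: float
    k: int  # number of pooled estimates


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _inv_logit(y: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-y))


def pool_random_effects(
    estimates: list[tuple[float, float]],
    label: str = "composite",
    scale: str = "percent",
) -> CompositeIndex:
    """DerSimonian–Laird random-effects pool of ``(value, SE)`` pairs.

    ``Q = sum w_i (y_i - ybar_w)^2`` with fixed weights ``w_i = 1/SE_i^2``;
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``; the pooled
    mean and SE use weights ``1/(SE_i^2 + tau2)``.

    With ``scale="logit"`` values (percents) are logit-transformed with
    delta-method SEs before pooling and the pool is back-transformed.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    y = np.array([v for v, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se < 0) or (len(estimates) > 1 and np.any(se == 0)):
        raise ValueError("standard errors must be positive")

    if scale == "logit":
        p = np.clip(y / 100.0, 1e-6, 1 - 1e-6)
        se_t = (se / 100.0) / (p * (1 - p))
        y_t = _logit(p)
    elif scale == "percent":
        y_t, se_t = y, se
    else:
        raise ValueError(f"unknown scale {scale!r}")

    k = len(y_t)
    if k == 1:
        lo, hi = y_t[0] - 1.959964 * se_t[0], y_t[0] + 1.959964 * se_t[0]
        pooled, pooled_se, tau2 = y_t[0], se_t[0], 0.0
    else:
        w = 1.0 / se_t**2
        ybar = w @ y_t / w.sum()
        Q = float(w @ (y_t - ybar) ** 2)
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom)
        w_re = 1.0 / (se_t**2 + tau2)
        pooled = float(w_re @ y_t / w_re.sum())
        pooled_se = float(np.sqrt(1.0 / w_re.sum()))
        lo, hi = pooled - 1.959964 * pooled_se, pooled + 1.959964 * pooled_se

    if scale == "logit":
        p = _inv_logit(np.array([pooled, lo, hi]))
        pooled_pct, lo, hi = 100 * p[0], 100 * p[1], 100 * p[2]
        pooled_se = pooled_se * 100.0 * p[0] * (1 - p[0])  # delta method
        return CompositeIndex(label, float(pooled_pct), float(pooled_se),
                              float(tau2), float(lo), float(hi), k)
    return CompositeIndex(label, float(pooled), float(pooled_se),
                          float(tau2), float(lo), float(hi), k)


def composite_coverage_index(
    fps: float, anc: float, sba: float, bcg: float,
    dpt3: float, msl: float, ort: float, carep: float,
) -> float:
    """Composite coverage index (percent) from eight intervention coverages
    (percent):

    ``CCI = 1/4 [ fps + (sba + anc)/2 + (2 dpt3 + msl + bcg)/4 + (ort + carep)/2 ]``
    """
    vals = np.array([fps, anc, sba, bcg, dpt3, msl, ort, carep], dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValueError("all CCI inputs must lie in [0, 100]")
    return float(
        0.25 * (fps + (sba + anc) / 2 + (2 * dpt3 + msl + bcg) / 4 + (ort + carep) / 2)
    )
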