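"""Asset-based wealth index, quintile assignment, and relative ranks.

The wealth score is the first principal component of the household asset
matrix, computed separately for each survey year (each survey carries its
own index).  Assets are standardised to weighted mean 0 / variance 1; the
principal axis itself is the leading eigenvector of the unweighted
correlation of the standardised assets, which keeps the score's weighted
mean at zero.  The sign is fixed so that the score correlates positively
with the plain asset count.

Quintiles are population-weighted: each household's relative rank is the
midpoint of its interval in the cumulative weight distribution of the
score, and the household falls in the fifth of [0, 1) containing that
midpoint.  Q1 is the poorest fifth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WealthScores",
    "QuintileAssignment",
    "compute_wealth_index",
    "assign_quintiles",
    "quintile_relative_ranks",
    "add_wealth_columns",
]


@dataclass
class WealthScores:
    """First-principal-component wealth score per household of one year."""

    score: np.ndarray
    weight: np.ndarray
    year: int
    loadings: pd.Series  # PC1 loadings per retained asset
    explained_ratio: float  # share of standardised variance on PC1


@dataclass
class QuintileAssignment:
    """Quintile label (1..5, Q1 poorest), realised weighted shares, and
    the relative-rank midpoint of each household."""

    quintile: np.ndarray  # int in 1..5 per household
    shares: np.ndarray  # realised weighted share of each quintile
    household_rank: np.ndarray  # midpoint rank in (0,1) per household


def compute_wealth_index(
    microdata: pd.DataFrame, year: int, asset_prefix: str = "asset_"
) -> WealthScores:
    """PCA wealth score for the households of one survey year.

    Zero-variance assets are dropped with a warning; if every asset is
    degenerate no index exists and a ``ValueError`` is raised.
    """
    sub = microdata.loc[microdata["year"] == year]
    asset_cols = [c for c in sub.columns if c.startswith(asset_prefix)]
    if len(asset_cols) < 2:
        raise ValueError("need at least 2 asset columns")
    X = sub[asset_cols].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    wn = w / w.sum()

    mu = wn @ X
    var = wn @ (X - mu) ** 2
    keep = var > 1e-12  # tolerance absorbs float noise in constant columns
    dropped = [c for c, k in zip(asset_cols, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance assets in %s: %s", year, dropped)
    if keep.sum() == 0:
        raise ValueError(f"all assets have zero variance in year {year}")
    Z = (X[:, keep] - mu[keep]) / np.sqrt(var[keep])

    C = (Z.T @ Z) / len(Z)
    evals, evecs = np.linalg.eigh(C)
    v = evecs[:, -1]
    if v @ np.ones(len(v)) < 0:  # orient toward higher asset counts
        v = -v
    score = Z @ v
    kept_cols = [c for c, k in zip(asset_cols, keep) if k]
    return WealthScores(
        score=score,
        weight=w,
        year=year,
        loadings=pd.Series(v, index=kept_cols),
        explained_ratio=float(evals[-1] / evals.sum()),
    )


def _midpoint_ranks(score: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Relative rank of each household: midpoint of its weight interval in
    the cumulative distribution of the score (ties kept in input order)."""
    order = np.argsort(score, kind="stable")
    w = weight[order]
    cum = np.cumsum(w)
    total = cum[-1]
    mid = (cum - w / 2.0) / total
    ranks = np.empty_like(mid)
    ranks[order] = mid
    return ranks


def assign_quintiles(scores: WealthScores) -> QuintileAssignment:
    """Assign population-weighted quintiles from wealth scores."""
    if len(scores.score) == 0:
        raise ValueError("empty scores")
    if np.any(scores.weight <= 0):
        raise ValueError("weights must be strictly positive")
    if len(np.unique(scores.score)) < 5:
        raise ValueError(
            "fewer than 5 distinct wealth scores; quintiles are degenerate"
        )
    ranks = _midpoint_ranks(scores.score, scores.weight)
    quintile = np.minimum((ranks * 5).astype(int), 4) + 1
    total = scores.weight.sum()
    shares = np.array(
        [scores.weight[quintile == q].sum() / total for q in range(1, 6)]
    )
    return QuintileAssignment(quintile=quintile, shares=shares, household_rank=ranks)


def quintile_relative_ranks(assignment: QuintileAssignment) -> np.ndarray:
    """Rank midpoint of each quintile: for quintile q covering the
    cumulative-share interval [c_{q-1}, c_q], the midpoint (c_{q-1}+c_q)/2."""
    cum = np.concatenate([[0.0], np.cumsum(assignment.shares)])
    return (cum[:-1] + cum[1:]) / 2.0


def add_wealth_columns(microdata: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the coverage microdata with ``wealth_score``,
    ``quintile`` and ``rel_rank`` columns, computed per survey year."""
    out = microdata.copy()
    out["wealth_score"] = np.nan
    out["quintile"] = 0
    out["rel_rank"] = np.nan
    for year in sorted(out["year"].unique()):
        mask = (out["year"] == year).to_numpy()
        ws = compute_wealth_index(out, year)
        qa = assign_quintiles(ws)
        out.loc[mask, "wealth_score"] = ws.score
        out.loc[mask, "quintile"] = qa.quintile
        out.loc[mask, "rel_rank"] = qa.household_rank
    return out
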