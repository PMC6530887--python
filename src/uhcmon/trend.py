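"""Bayesian logit-linear trend fitting, diagnostics, and projection.

The model regresses logit-transformed coverage (or hardship-incidence)
proportions on calendar year with a Gaussian likelihood and the standard
non-informative prior ``p(alpha, beta, sigma^2) ∝ 1/sigma^2``:

    y_i = logit(p_i),    y_i ~ Normal(alpha + beta * (t_i - t0), sigma^2)

Under that prior the posterior is normal–inverse-gamma and available in
closed form (:func:`fit_trend_conjugate`), which serves as the exact
oracle for the MCMC sampler (:func:`fit_trend_mcmc`), a two-block Gibbs
sampler run as two chains with 5000 burn-in iterations each and 1000
retained draws in total by default.  Convergence is monitored with the
Gelman–Rubin potential scale reduction factor (PSRF, threshold 1.02) and
model variants (group offsets, group-specific slopes) are compared by the
deviance information criterion (DIC).

Projections push posterior draws of the mean trend through the inverse
logit to the percent scale; from these come 2030 coverage summaries,
probabilities of meeting the 80% service-coverage target (or of reaching
full financial-risk protection, operationalised as incidence below a
small epsilon), and annual rates of change between two years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrendData",
    "PosteriorDraws",
    "ProjectionResult",
    "ModelFitDiagnostics",
    "logit",
    "inv_logit",
    "fit_trend_conjugate",
    "fit_trend_mcmc",
    "fit_grouped_trend",
    "psrf",
    "dic",
    "project",
    "prob_target_coverage",
    "prob_financial_protection",
    "annual_rate_of_change",
    "select_model_by_dic",
]

SIGMA2_FLOOR = 1e-8  # residual-variance floor for exact-line data
PSRF_THRESHOLD = 1.02
MAX_ITER = 200_000


def logit(p):
    """Log-odds transform; defined only strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires p strictly inside (0, 1)")
    return np.log(p / (1.0 - p))


def inv_logit(y):
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-y[pos]))
    ey = np.exp(y[~pos])
    out[~pos] = ey / (1.0 + ey)
    return out if out.ndim else float(out)


@dataclass
class TrendData:
    """Observed (year, proportion) pairs for one indicator x group series,
    optionally with group labels for the quintile/region-adjusted model."""

    years: np.ndarray
    p: np.ndarray
    groups: np.ndarray | None = None
    y: np.ndarray = field(init=False)
    t0: float = field(init=False)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.years) != len(self.p):
            raise ValueError("years and p must have equal length")
        if len(np.unique(self.years)) < 3:
            raise ValueError("need at least 3 distinct years")
        self.y = logit(self.p)
        self.t0 = float(self.years.min())  # centering for conditioning
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != len(self.p):
                raise ValueError("groups must match observations")


@dataclass
class PosteriorDraws:
    """Joint posterior draws of the trend model.

    ``coef`` columns are ``alpha``, ``beta`` and, for grouped fits,
    ``u[<group>]`` intercept offsets and ``v[<group>]`` slope offsets
    relative to the (alphabetically first) reference group."""

    coef: pd.DataFrame
    sigma2: np.ndarray
    chain: np.ndarray
    t0: float
    groups: list | None = None
    interaction: bool = False
    converged: bool = True
    psrf: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)

    def linear_predictor(self, year: float, group=None) -> np.ndarray:
        """Posterior draws of alpha_g + beta_g * (year - t0)."""
        a = self.coef["alpha"].to_numpy()
        b = self.coef["beta"].to_numpy()
        if group is not None and self.groups is not None:
            ucol, vcol = f"u[{group}]", f"v[{group}]"
            if ucol in self.coef:
                a = a + self.coef[ucol].to_numpy()
            if vcol in self.coef:
                b = b + self.coef[vcol].to_numpy()
        return a + b * (year - self.t0)


@dataclass
class ProjectionResult:
    years: np.ndarray
    mean: np.ndarray  # percent scale
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    draws: np.ndarray  # (n_draws, n_years), percent scale


@dataclass
class ModelFitDiagnostics:
    psrf: dict
    converged: bool
    dbar: float
    p_d: float
    dic: float


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _design(data: TrendData, interaction: bool = False):
    """Design matrix, response, column names, and group list."""
    t = data.years - data.t0
    if data.groups is None:
        X = np.column_stack([np.ones_like(t), t])
        return X, data.y, ["alpha", "beta"], None
    labels = sorted(np.unique(data.groups).tolist())
    if len(labels) < 2:
        X = np.column_stack([np.ones_like(t), t])
        return X, data.y, ["alpha", "beta"], None
    for g in labels:
        if np.sum(data.groups == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    cols = [np.ones_like(t), t]
    names = ["alpha", "beta"]
    for g in labels[1:]:
        cols.append((data.groups == g).astype(float))
        names.append(f"u[{g}]")
    if interaction:
        for g in labels[1:]:
            cols.append(t * (data.groups == g))
            names.append(f"v[{g}]")
    return np.column_stack(cols), data.y, names, labels


def _ols(X: np.ndarray, y: np.ndarray):
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    bhat = XtX_inv @ X.T @ y
    resid = y - X @ bhat
    rss = float(resid @ resid)
    return bhat, XtX_inv, rss


# ---------------------------------------------------------------------------
# conjugate (exact) posterior
# ---------------------------------------------------------------------------

def fit_trend_conjugate(
    data: TrendData,
    n_draws: int = 1000,
    seed: int | None = 0,
    interaction: bool = False,
) -> PosteriorDraws:
    """Exact draws from the normal–inverse-gamma posterior.

    With prior ∝ 1/sigma^2, sigma^2 | y is scaled inverse chi-square with
    ``n - k`` degrees of freedom and scale ``s^2``, and the coefficients
    given sigma^2 are normal around the least-squares solution.
    """
    X, y, names, labels = _design(data, interaction)
    n, k = X.shape
    if n < k + 1:
        raise ValueError("too few observations for a proper posterior")
    bhat, XtX_inv, rss = _ols(X, y)
    nu = n - k
    if rss / max(nu, 1) < SIGMA2_FLOOR:
        import logging
        logging.getLogger(__name__).warning(
            "residual variance below floor; flooring at %.1e", SIGMA2_FLOOR)
        rss = SIGMA2_FLOOR * nu
    rng = np.random.default_rng(seed)
    sigma2 = rss / rng.chisquare(nu, size=n_draws)
    L = np.linalg.cholesky(XtX_inv)
    z = rng.standard_normal((n_draws, k))
    coef = bhat[None, :] + np.sqrt(sigma2)[:, None] * (z @ L.T)
    return PosteriorDraws(
        coef=pd.DataFrame(coef, columns=names),
        sigma2=sigma2,
        chain=np.zeros(n_draws, dtype=int),
        t0=data.t0,
        groups=labels,
        interaction=interaction,
    )


# ---------------------------------------------------------------------------
# Gibbs MCMC
# ---------------------------------------------------------------------------

def psrf(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor for one parameter.

    ``chains`` has shape (m, n).  PSRF = sqrt(((n-1)/n * W + B/n) / W)
    with W the mean within-chain variance and B/n the variance of the
    chain means.  Degenerate chains (W = 0) give PSRF 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    B_over_n = chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def _gibbs_chain(X, y, bhat, XtX_inv, rss_min, n_keep, burn_in, rng,
                 init_factor: float = 1.0):
    """One Gibbs chain for the flat-prior Gaussian linear model.

    Alternates beta | sigma^2 ~ N(bhat, sigma^2 (X'X)^-1) and
    sigma^2 | beta ~ InvGamma(n/2, RSS(beta)/2), where
    RSS(beta) = RSS_min + sigma^2 * ||z||^2 for beta drawn via the
    Cholesky factor of (X'X)^-1 (an exact identity, not an approximation).
    ``init_factor`` scales the starting variance so chains can be started
    overdispersed.
    """
    n, k = X.shape
    L = np.linalg.cholesky(XtX_inv)
    sigma2 = max(init_factor * rss_min / max(n - k, 1), SIGMA2_FLOOR)
    keep_coef = np.empty((n_keep, k))
    keep_sig = np.empty(n_keep)
    j = 0
    for it in range(burn_in + n_keep):
        z = rng.standard_normal(k)
        beta = bhat + np.sqrt(sigma2) * (L @ z)
        rss_beta = rss_min + sigma2 * float(z @ z)
        sigma2 = max(rss_beta / rng.chisquare(n), SIGMA2_FLOOR)
        if it >= burn_in:
            keep_coef[j] = beta
            keep_sig[j] = sigma2
            j += 1
    return keep_coef, keep_sig


def fit_trend_mcmc(
    data: TrendData,
    chains: int = 2,
    burn_in: int = 5000,
    retained: int = 1000,
    seed: int | None = 0,
    interaction: bool = False,
    max_iter: int = MAX_ITER,
) -> PosteriorDraws:
    """Gibbs-sampled posterior of the logit-linear trend model.

    Runs ``chains`` chains, discarding ``burn_in`` iterations each and
    retaining ``retained`` draws in total.  If any parameter's PSRF
    exceeds 1.02 the burn-in doubles, up to ``max_iter`` iterations per
    chain; a fit that never reaches the threshold is returned with
    ``converged=False``.
    """
    X, y, names, labels = _design(data, interaction)
    n, k = X.shape
    if n < k + 1:
        raise ValueError("too few observations for a proper posterior")
    bhat, XtX_inv, rss = _ols(X, y)
    nu = n - k
    if rss / max(nu, 1) < SIGMA2_FLOOR:
        import logging
        logging.getLogger(__name__).warning(
            "residual variance below floor; flooring at %.1e", SIGMA2_FLOOR)
        rss = SIGMA2_FLOOR * nu

    per_chain = int(np.ceil(retained / chains))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    current_burn = burn_in
    while True:
        rngs = [np.random.default_rng(s) for s in ss.spawn(chains)]
        coef_chains, sig_chains = [], []
        # overdispersed starts: alternate small/large initial variances
        init_factors = [0.1 if c % 2 == 0 else 10.0 for c in range(chains)]
        for c in range(chains):
            coefs, sigs = _gibbs_chain(X, y, bhat, XtX_inv, rss,
                                       per_chain, current_burn, rngs[c],
                                       init_factor=init_factors[c])
            coef_chains.append(coefs)
            sig_chains.append(sigs)
        psrfs = {}
        for i, nm in enumerate(names):
            psrfs[nm] = psrf(np.stack([cc[:, i] for cc in coef_chains]))
        psrfs["sigma2"] = psrf(np.log(np.stack(sig_chains)))
        converged = all(v <= PSRF_THRESHOLD for v in psrfs.values())
        if converged or current_burn + per_chain >= max_iter:
            break
        current_burn *= 2

    coef = np.concatenate(coef_chains)[: retained]
    sigma2 = np.concatenate(sig_chains)[: retained]
    chain_id = np.repeat(np.arange(chains), per_chain)[: retained]
    return PosteriorDraws(
        coef=pd.DataFrame(coef, columns=names),
        sigma2=sigma2,
        chain=chain_id,
        t0=data.t0,
        groups=labels,
        interaction=interaction,
        converged=converged,
        psrf=psrfs,
    )


def fit_grouped_trend(
    data: TrendData,
    interaction: bool = False,
    method: str = "mcmc",
    **kwargs,
) -> PosteriorDraws:
    """Quintile/region-adjusted trend: adds group intercept offsets and,
    with ``interaction=True``, group-specific slopes.  The reference group
    is the alphabetically first label.  With a single group this reduces
    to the plain trend fit."""
    if data.groups is None:
        raise ValueError("grouped fit requires group labels")
    fit = fit_trend_mcmc if method == "mcmc" else fit_trend_conjugate
    return fit(data, interaction=interaction, **kwargs)


# ---------------------------------------------------------------------------
# deviance information criterion
# ---------------------------------------------------------------------------

def dic(data: TrendData, draws: PosteriorDraws) -> tuple[float, float, float]:
    """(Dbar, pD, DIC) for the Gaussian logit-scale likelihood.

    Deviance D(theta) = -2 log L; Dbar averages over draws; pD is
    Dbar - D(posterior mean); DIC = Dbar + pD.
    """
    X, y, names, _ = _design(data, draws.interaction)
    coef = draws.coef[names].to_numpy()
    resid = y[None, :] - coef @ X.T
    rss = np.sum(resid**2, axis=1)
    n = len(y)
    D = n * np.log(2 * np.pi * draws.sigma2) + rss / draws.sigma2
    dbar = float(D.mean())
    coef_bar = coef.mean(axis=0)
    sig_bar = float(draws.sigma2.mean())
    rss_bar = float(np.sum((y - X @ coef_bar) ** 2))
    d_at_mean = n * np.log(2 * np.pi * sig_bar) + rss_bar / sig_bar
    p_d = dbar - d_at_mean
    return dbar, float(p_d), float(dbar + p_d)


def select_model_by_dic(
    data: TrendData, method: str = "mcmc", seed: int | None = 0, **kwargs
):
    """Fit the grouped trend with and without a group x year interaction
    and keep the model with the smaller DIC.

    Returns ``(chosen_draws, diagnostics)`` where ``diagnostics`` maps
    "no_interaction"/"interaction" to :class:`ModelFitDiagnostics` plus a
    "choice" key.  If either fit fails to converge the selection is
    aborted (choice None) and the diagnostics are still returned.
    """
    fits = {}
    diags = {}
    for label, inter in (("no_interaction", False), ("interaction", True)):
        d = fit_grouped_trend(data, interaction=inter, method=method, seed=seed, **kwargs)
        dbar, p_d, dic_val = dic(data, d)
        fits[label] = d
        diags[label] = ModelFitDiagnostics(
            psrf=d.psrf, converged=d.converged, dbar=dbar, p_d=p_d, dic=dic_val
        )
    if not all(diag.converged for diag in diags.values()) and method == "mcmc":
        diags["choice"] = None
        return None, diags
    choice = min(("no_interaction", "interaction"), key=lambda m: diags[m].dic)
    diags["choice"] = choice
    return fits[choice], diags


# ---------------------------------------------------------------------------
# projection and derived quantities
# ---------------------------------------------------------------------------

def project(draws: PosteriorDraws, years, group=None) -> ProjectionResult:
    """Posterior mean-trend coverage (percent) at the requested years.

    Projects the systematic trend inv_logit(alpha + beta t) per draw; no
    new-observation residual noise is added."""
    years = np.atleast_1d(np.asarray(years, dtype=float))
    mat = np.column_stack([
        100.0 * inv_logit(draws.linear_predictor(yr, group)) for yr in years
    ])
    return ProjectionResult(
        years=years,
        mean=mat.mean(axis=0),
        ci_lo=np.percentile(mat, 2.5, axis=0),
        ci_hi=np.percentile(mat, 97.5, axis=0),
        draws=mat,
    )


def prob_target_coverage(
    draws: PosteriorDraws, year: float = 2030, target: float = 0.80, group=None
) -> float:
    """Fraction of posterior draws with projected coverage >= target."""
    p = inv_logit(draws.linear_predictor(year, group))
    return float(np.mean(p >= target))


def prob_financial_protection(
    draws: PosteriorDraws, year: float = 2030, epsilon: float = 0.01, group=None
) -> float:
    """Probability of (near-)complete financial-risk protection: the
    fraction of draws whose projected hardship incidence falls below
    ``epsilon`` (default one percentage point).  Exact 0% incidence has
    probability zero under any continuous posterior, hence the epsilon."""
    p = inv_logit(draws.linear_predictor(year, group))
    return float(np.mean(p < epsilon))


def annual_rate_of_change(
    draws: PosteriorDraws, start_year: float, end_year: float, group=None
) -> tuple[float, float, float]:
    """Endpoint geometric annual rate of change, percent per year.

    Per draw: ``100 * ((c_end / c_start)^(1/(end-start)) - 1)`` on the
    coverage scale.  Returns (mean, 2.5th, 97.5th percentile).
    """
    if start_year >= end_year:
        raise ValueError("start_year must precede end_year")
    c0 = inv_logit(draws.linear_predictor(start_year, group))
    c1 = inv_logit(draws.linear_predictor(end_year, group))
    rate = 100.0 * ((c1 / c0) ** (1.0 / (end_year - start_year)) - 1.0)
    return (
        float(rate.mean()),
        float(np.percentile(rate, 2.5)),
        float(np.percentile(rate, 97.5)),
    )


def adjust_boundary(p: float, n_eff: float) -> float:
    """Half-success continuity adjustment pulling boundary proportions
    strictly inside (0, 1) before the logit transform."""
    if 0.0 < p < 1.0:
        return p
    return (p * n_eff + 0.5) / (n_eff + 1.0)
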