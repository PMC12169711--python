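"""Random-intercept linear mixed models for repeated exposure-outcome data.

The working model is y_ij = x_ij' beta + b_i + e_ij with participant
random intercepts b_i ~ N(0, sigma_b^2) and residuals e_ij ~ N(0,
sigma^2 / w_ij).  Unweighted fits go through statsmodels MixedLM (REML);
weighted fits use an internal profiled-REML solver, since MixedLM does not
support per-observation residual weights.  Fixed-effect intervals are Wald
95 % CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

Z95 = 1.959963984540054


@dataclass
class FitResult:
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    sigma_b2: float
    n_obs: int
    n_participants: int
    converged: bool
    singular: bool = False
    method: str = "statsmodels"

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + Z95 * self.se

    @property
    def pvalues(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def coef(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "ci": (float(self.ci_low[i]), float(self.ci_high[i])),
            "p": float(self.pvalues[i]),
        }


def _design(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...],
    group: str,
    weights: str | None,
):
    cols = [outcome, exposure, *covariates, group]
    if weights is not None:
        cols.append(weights)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[cols].dropna()
    if sub.empty:
        raise ValueError("no complete rows after missing-data exclusion")
    y = sub[outcome].to_numpy(dtype=float)
    terms = ("intercept", exposure, *covariates)
    x = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in (exposure, *covariates)]
    )
    groups = sub[group].to_numpy()
    w = sub[weights].to_numpy(dtype=float) if weights is not None else None
    # rank check, naming the aliased columns
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        aliased = [terms[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return y, x, terms, groups, w, sub


def _reml_random_intercept(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    w: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Profiled REML for the random-intercept model with residual weights.

    Profiles beta and sigma^2 out of the restricted likelihood and
    optimizes the single ratio theta = sigma_b^2 / sigma^2.  Group-level
    inverses use the Sherman-Morrison identity, so cost is linear in n.
    """
    n, p = x.shape
    if w is None:
        w = np.ones(n)
    order = np.argsort(groups, kind="stable")
    y, x, w, groups = y[order], x[order], w[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    starts = np.sort(starts)

    # sufficient statistics; group reductions via reduceat (Sherman-Morrison
    # per group: Sigma^-1 = W - theta W 1 1' W / (1 + theta * sum(w)))
    wx = w[:, None] * x
    wy = w * y
    xtwx = x.T @ wx
    xtwy = x.T @ wy
    logw_sum = float(np.log(w).sum())
    s_g = np.add.reduceat(w, starts)
    xtw1_g = np.add.reduceat(wx, starts, axis=0)  # (G, p)
    ytw1_g = np.add.reduceat(wy, starts)

    def profile(theta: float):
        shrink = theta / (1.0 + theta * s_g)
        a = xtwx - (shrink[:, None] * xtw1_g).T @ xtw1_g
        c = xtwy - xtw1_g.T @ (shrink * ytw1_g)
        beta = np.linalg.solve(a, c)
        resid = y - x @ beta
        wr_g = np.add.reduceat(w * resid, starts)
        rss = float(resid @ (w * resid) - shrink @ wr_g**2)
        sigma2 = rss / (n - p)
        logdet = -logw_sum + float(np.log1p(theta * s_g).sum())
        _, logdet_a = np.linalg.slogdet(a)
        nll = 0.5 * ((n - p) * np.log(sigma2) + logdet + logdet_a + (n - p))
        return nll, beta, sigma2, a

    def objective(log_theta: float) -> float:
        return profile(np.exp(log_theta))[0]

    res = optimize.minimize_scalar(objective, bounds=(-12.0, 8.0), method="bounded")
    theta = float(np.exp(res.x))
    nll_opt = res.fun
    nll_zero = profile(0.0)[0]
    singular = False
    if nll_zero <= nll_opt + 1e-9 or theta < 1e-5:
        theta = 0.0
        singular = True
    _, beta, sigma2, a = profile(theta)
    cov_beta = sigma2 * np.linalg.inv(a)
    se = np.sqrt(np.diag(cov_beta))
    return beta, se, sigma2, theta * sigma2, bool(res.success), singular


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...] | list[str] = (),
    group: str = "participant",
    weights: str | None = None,
    engine: str | None = None,
) -> FitResult:
    """Fit the random-intercept model by REML.

    ``engine`` may force "statsmodels" or "internal"; by default
    statsmodels is used unless observation weights are supplied.  A
    boundary (singular) random-intercept variance is reported as
    sigma_b^2 = 0 with the ``singular`` flag, not as a failure.
    """
    covariates = tuple(covariates)
    y, x, terms, groups, w, _ = _design(data, outcome, exposure, covariates, group, weights)
    n_participants = len(np.unique(groups))
    if n_participants < 2:
        raise ValueError("need at least two participants")
    if engine is None:
        engine = "internal" if weights is not None else "statsmodels"
    if engine == "statsmodels" and weights is not None:
        raise ValueError("statsmodels engine does not support observation weights")

    if engine == "statsmodels":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, x, groups=groups)
            try:
                fit = model.fit(reml=True, method=["lbfgs", "powell"])
                beta = np.asarray(fit.fe_params, dtype=float)
                se = np.asarray(fit.bse_fe, dtype=float)
                if not (np.isfinite(beta).all() and np.isfinite(se).all()):
                    raise ValueError("non-finite fixed-effect estimates")
                sigma2 = float(fit.scale)
                sigma_b2 = float(np.asarray(fit.cov_re)[0, 0])
                converged = bool(fit.converged)
                singular = sigma_b2 < 1e-8 * max(sigma2, 1e-12)
                return FitResult(
                    terms, beta, se, sigma2, max(sigma_b2, 0.0),
                    len(y), n_participants, converged, singular, "statsmodels",
                )
            except (np.linalg.LinAlgError, ValueError):
                engine = "internal"  # fall back on numerically awkward fits

    beta, se, sigma2, sigma_b2, converged, singular = _reml_random_intercept(y, x, groups, w)
    return FitResult(
        terms, beta, se, sigma2, sigma_b2, len(y), n_participants, converged, singular, "internal"
    )
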