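"""Association inference: imputation, pooling, weighting, multiplicity.

Simplified but interface-complete stand-ins accompany the mixed models:
stochastic-regression multiple imputation (in place of chained equations)
and logistic-regression stabilized inverse-probability weights (in place
of covariate-balancing propensity scores).  Pooling across imputations
follows Rubin's rules with Barnard-Rubin small-sample degrees of freedom,
and multiplicity over the five dwell-time outcomes uses the eigenvalue
based effective number of tests m_eff = (sum sqrt(lambda))^2 / sum lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exposure import DEFAULT_INCREMENTS, scale_to_increment
from .lmm import FitResult, fit_lmm

MAX_MISSING_FRACTION = 0.35  # covariate-selection rule: < 35 % missing


def impute_simple(
    table: pd.DataFrame,
    m: int,
    seed: int = 0,
    columns: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Stochastic-regression multiple imputation of missing covariates.

    Each incomplete column is regressed on the complete columns; missing
    entries get fitted mean + resampled Gaussian residual (Bernoulli draws
    from fitted probabilities for binary columns).  Returns ``m`` completed
    copies, deterministic given ``seed``.  Columns missing >= 35 % are
    rejected, mirroring the covariate-selection rule.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    numeric = table.select_dtypes(include=[np.number])
    if columns is None:
        columns = [c for c in numeric.columns if table[c].isna().any()]
    for c in columns:
        frac = table[c].isna().mean()
        if frac >= MAX_MISSING_FRACTION:
            raise ValueError(
                f"covariate {c!r} is {frac:.0%} missing (limit {MAX_MISSING_FRACTION:.0%})"
            )
    predictors = [c for c in numeric.columns if c not in columns and not table[c].isna().any()]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        completed = table.copy()
        for c in columns:
            obs = table[c].notna()
            if obs.all():
                continue
            yc = table.loc[obs, c].to_numpy(dtype=float)
            if predictors:
                x_obs = np.column_stack(
                    [np.ones(obs.sum())] + [table.loc[obs, p].to_numpy(dtype=float) for p in predictors]
                )
                x_mis = np.column_stack(
                    [np.ones((~obs).sum())] + [table.loc[~obs, p].to_numpy(dtype=float) for p in predictors]
                )
            else:
                x_obs = np.ones((obs.sum(), 1))
                x_mis = np.ones(((~obs).sum(), 1))
            vals = np.unique(yc)
            binary = vals.size <= 2 and np.isin(vals, [0.0, 1.0]).all()
            if binary:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        fitted = sm.Logit(yc, x_obs).fit(disp=0)
                        p_mis = np.clip(fitted.predict(x_mis), 1e-6, 1 - 1e-6)
                    except Exception:
                        p_mis = np.full(x_mis.shape[0], yc.mean())
                draws = (rng.random(x_mis.shape[0]) < p_mis).astype(float)
            else:
                coef, _, _, _ = np.linalg.lstsq(x_obs, yc, rcond=None)
                resid = yc - x_obs @ coef
                dof = max(len(yc) - x_obs.shape[1], 1)
                sd = float(np.sqrt(resid @ resid / dof))
                draws = x_mis @ coef + rng.normal(0.0, sd, size=x_mis.shape[0])
            completed.loc[~obs, c] = draws
        out.append(completed)
    return out


@dataclass
class PooledResult:
    beta: float
    se: float
    within: float  # mean squared SE across imputations
    between: float  # sample variance of the betas
    total: float  # within + (1 + 1/M) * between
    df: float
    ci: tuple[float, float]
    p: float
    m: int


def pool_scalar(
    betas: np.ndarray,
    ses: np.ndarray,
    df_com: float | None = None,
) -> PooledResult:
    """Rubin's rules for one coefficient across M imputations.

    Degrees of freedom follow Barnard-Rubin when the complete-data df is
    supplied, otherwise the classic large-sample formula.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = betas.size
    if m < 2:
        raise ValueError("pooling needs at least 2 imputations")
    qbar = float(betas.mean())
    wbar = float((ses**2).mean())
    b = float(betas.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * b
    if b <= 0:
        df = float("inf")
    else:
        r = (1.0 + 1.0 / m) * b / wbar
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2
        if df_com is None:
            df = df_old
        else:
            gamma = (1.0 + 1.0 / m) * b / total
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - gamma)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = float(np.sqrt(total))
    t = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    ci = (qbar - t * se, qbar + t * se)
    if np.isfinite(df):
        p = float(2 * stats.t.sf(abs(qbar / se), df))
    else:
        p = float(2 * stats.norm.sf(abs(qbar / se)))
    return PooledResult(qbar, se, wbar, b, total, float(df), ci, p, m)


def pool_rubin(fits: list[FitResult], term: str) -> PooledResult:
    """Pool one fixed-effect coefficient across imputation fits."""
    if len(fits) < 2:
        raise ValueError("pooling needs at least 2 fits")
    terms0 = fits[0].terms
    if any(f.terms != terms0 for f in fits):
        raise ValueError("fits have heterogeneous model specifications")
    i = terms0.index(term)
    betas = np.array([f.beta[i] for f in fits])
    ses = np.array([f.se[i] for f in fits])
    df_com = float(fits[0].n_obs - len(terms0))
    return pool_scalar(betas, ses, df_com)


def ipw_weights(
    covariates: pd.DataFrame,
    included: np.ndarray,
    truncate: tuple[float, float] = (0.01, 0.99),
) -> np.ndarray:
    """Stabilized inverse-probability-of-inclusion weights.

    Fits a logistic model of inclusion on the covariates and returns
    P(inclusion) / P(inclusion | covariates) per participant, truncated at
    the given quantiles.  Perfect separation is handled by capping fitted
    probabilities rather than failing.
    """
    included = np.asarray(included).astype(float)
    if included.min() == included.max():
        raise ValueError("inclusion indicator is constant")
    x = covariates.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("covariates must be complete (impute first)")
    design = np.column_stack([np.ones(len(x)), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(included, design).fit(disp=0, maxiter=200)
            p = fit.predict(design)
        except Exception:  # perfect separation and friends
            fit = sm.Logit(included, design).fit_regularized(disp=0, alpha=1e-4)
            p = fit.predict(design)
    p = np.clip(p, 1e-3, 1 - 1e-3)
    w = included.mean() / p
    lo, hi = np.quantile(w, truncate)
    return np.clip(w, lo, hi)


@dataclass
class MultiplicityResult:
    eigenvalues: np.ndarray
    m_eff: float
    alpha: float  # 0.05 / m_eff


def effective_tests(outcomes: pd.DataFrame | np.ndarray) -> MultiplicityResult:
    """Effective number of tests among correlated outcomes.

    Uses the pairwise-complete Pearson correlation matrix of the outcome
    columns; eigenvalues are clipped at 0 and
    m_eff = (sum sqrt(lambda))^2 / sum lambda, so independence gives the
    outcome count and rank one gives 1.
    """
    df = pd.DataFrame(outcomes)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 outcomes")
    if df.notna().sum().min() < 10:
        raise ValueError("need at least 10 observations per outcome")
    if (df.std(ddof=0) == 0).any():
        const = list(df.columns[df.std(ddof=0) == 0])
        raise ValueError(f"constant outcome column(s): {const}")
    corr = df.corr(method="pearson").to_numpy()
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    m_eff = float(np.sqrt(lam).sum() ** 2 / lam.sum())
    return MultiplicityResult(lam[::-1], m_eff, 0.05 / m_eff)


def vif_check(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per covariate; pass iff all VIF < 10.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j (with intercept) on
    the remaining covariates; exact collinearity reports infinity.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than covariates")
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    rows = []
    for j, name in enumerate(names):
        yj = x[:, j]
        others = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        if tss == 0:
            vif = float("inf")
        else:
            r2 = 1.0 - rss / tss
            vif = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": name, "vif": vif})
    out = pd.DataFrame(rows)
    out["pass"] = out["vif"] < 10.0
    return out


def run_association_grid(
    dwell: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    adjustment_sets: dict[str, list[str]],
    outcome: str = "dwell_transformed",
    imputed_covariates: list[pd.DataFrame] | None = None,
    weights: str | None = None,
    increments: dict[str, float] | None = None,
    alpha_adjusted: float | None = None,
    visit_subset: int | None = None,
) -> pd.DataFrame:
    """One mixed-model fit per (pollutant, setting, state, adjustment) cell.

    ``dwell`` is long (participant, visit, state, <outcome>); ``exposures``
    long (participant, visit, setting, pollutant, weekly_mean and optional
    longterm_mean); ``covariates`` keyed by (participant, visit).  An
    adjustment-set entry equal to ``"@longterm"`` expands to the
    pollutant-specific ``longterm_mean`` column carried by the exposure
    rows.  When ``imputed_covariates`` is given, each cell is
    fitted per completed table and pooled by Rubin's rules.  Coefficients
    are reported per the pollutant's increment, flagged at 0.05 and at the
    m_eff-adjusted threshold.
    """
    increments = DEFAULT_INCREMENTS if increments is None else increments
    states_ = sorted(dwell["state"].unique())
    rows = []
    for setting in sorted(exposures["setting"].unique()):
        exp_s = exposures[exposures["setting"] == setting]
        for pollutant in sorted(exp_s["pollutant"].unique()):
            exp_sp = exp_s[exp_s["pollutant"] == pollutant]
            for state in states_:
                dw = dwell[dwell["state"] == state]
                carry = ["participant", "visit", "weekly_mean"]
                if "longterm_mean" in exp_sp.columns:
                    carry.append("longterm_mean")
                base = dw.merge(exp_sp[carry], on=["participant", "visit"])
                if visit_subset is not None:
                    base = base[base["visit"] == visit_subset]
                for adj_name, adj_cols in adjustment_sets.items():
                    covs = ["longterm_mean" if c == "@longterm" else c for c in adj_cols]
                    tables = (
                        imputed_covariates if imputed_covariates is not None else [covariates]
                    )
                    fits = []
                    for tab in tables:
                        cell = base.merge(tab, on=["participant", "visit"], how="left")
                        if cell[[outcome, "weekly_mean"]].dropna().empty:
                            raise ValueError(
                                f"empty cell: {pollutant}/{setting}/state {state}/{adj_name}"
                            )
                        fits.append(
                            fit_lmm(
                                cell,
                                outcome=outcome,
                                exposure="weekly_mean",
                                covariates=[c for c in covs if c in cell.columns],
                                weights=weights,
                            )
                        )
                    if len(fits) > 1:
                        pooled = pool_rubin(fits, "weekly_mean")
                        beta, ci, p = pooled.beta, pooled.ci, pooled.p
                    else:
                        c0 = fits[0].coef("weekly_mean")
                        beta, ci, p = c0["beta"], c0["ci"], c0["p"]
                    beta_s, ci_s = scale_to_increment(beta, ci, pollutant, increments)
                    rows.append(
                        {
                            "exposure": pollutant,
                            "setting": setting,
                            "state": state,
                            "adjustment": adj_name,
                            "beta": beta_s,
                            "ci_low": ci_s[0],
                            "ci_high": ci_s[1],
                            "p": p,
                            "n_obs": fits[0].n_obs,
                            "n_participants": fits[0].n_participants,
                            "significant_raw": p < 0.05,
                            "significant_meff": (
                                p < alpha_adjusted if alpha_adjusted is not None else None
                            ),
                        }
                    )
    return pd.DataFrame(rows)
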