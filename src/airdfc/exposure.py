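"""Ratio-method exposure assessment.

Annual land-use-regression (LUR) means at each address are extrapolated to
single days by multiplying them with the cross-site mean of daily-to-annual
concentration ratios from routine monitoring sites, where the annual
denominator is the site mean over the reference measurement period.  Weekly
pre-scan averages, surrogate-pollutant substitution for days with no
monitoring data (NOx for PM2.5 absorbance, PM10 for PM2.5), and
residence-time-weighted long-term averages complete the exposure records.

Concentration units are μg/m³ throughout, except PM2.5 absorbance
(1e-5 m^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: reporting increments: coefficients are presented per this much exposure
DEFAULT_INCREMENTS = {
    "NO2": 10.0,
    "NOX": 20.0,
    "PM25": 5.0,
    "PM10": 10.0,
    "PMCOARSE": 5.0,
    "PM25ABS": 1.0,
}

#: pollutant -> surrogate used when the target has no monitoring data
DEFAULT_SUBSTITUTION = {"PM25ABS": "NOX", "PM25": "PM10"}

PANEL_COLUMNS = ("site", "date", "pollutant", "concentration")


class CoverageError(ValueError):
    """Raised when too few days are available for an average."""

    def __init__(self, message: str, coverage: float):
        super().__init__(message)
        self.coverage = coverage


def check_substitution_rule(rule: dict[str, str]) -> None:
    for target, surrogate in rule.items():
        if surrogate == target:
            raise ValueError(f"surrogate for {target!r} is itself")
        # follow the chain to detect cycles
        seen = {target}
        cur = surrogate
        while cur in rule:
            if cur in seen:
                raise ValueError(f"substitution cycle at {cur!r}")
            seen.add(cur)
            cur = rule[cur]


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"monitoring panel missing columns {missing}")
    if (panel["concentration"] <= 0).any():
        raise ValueError("monitoring concentrations must be positive")
    return panel


def reference_period_mean(
    panel: pd.DataFrame,
    site: str,
    pollutant: str,
    period: tuple,
    min_coverage: float = 0.75,
) -> float:
    """Arithmetic mean of daily values over the reference period.

    Requires at least ``min_coverage`` of the period's days to be present.
    """
    _validate_panel(panel)
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    n_days = (end - start).days + 1
    sel = panel[
        (panel["site"] == site)
        & (panel["pollutant"] == pollutant)
        & (panel["date"] >= start)
        & (panel["date"] <= end)
    ]
    coverage = sel["date"].nunique() / n_days
    if coverage < min_coverage:
        raise CoverageError(
            f"{site}/{pollutant}: only {coverage:.0%} of reference-period days present "
            f"(need {min_coverage:.0%})",
            coverage,
        )
    return float(sel["concentration"].mean())


def annual_site_means(
    panel: pd.DataFrame,
    period: tuple,
    min_coverage: float = 0.75,
) -> pd.DataFrame:
    """Reference-period means for every (site, pollutant) with coverage.

    Under-covered combinations are silently dropped; they simply contribute
    no ratios downstream.
    """
    _validate_panel(panel)
    rows = []
    for (site, pollutant), _ in panel.groupby(["site", "pollutant"]):
        try:
            m = reference_period_mean(panel, site, pollutant, period, min_coverage)
        except CoverageError:
            continue
        rows.append({"site": site, "pollutant": pollutant, "annual": m})
    return pd.DataFrame(rows)


def daily_ratio(
    panel: pd.DataFrame,
    annual_means: pd.DataFrame,
    date,
    pollutant: str,
    rule: dict[str, str] | None = None,
) -> tuple[float, bool]:
    """Cross-site mean of daily/annual ratios for one date.

    Falls back to the surrogate pollutant's ratio (flag True) when the
    target has no data at any site that day.
    """
    rule = DEFAULT_SUBSTITUTION if rule is None else rule
    check_substitution_rule(rule)
    date = pd.Timestamp(date)

    def _ratio(p: str) -> float | None:
        day = panel[(panel["date"] == date) & (panel["pollutant"] == p)]
        ann = annual_means[annual_means["pollutant"] == p]
        merged = day.merge(ann, on="site")
        if merged.empty:
            return None
        return float((merged["concentration"] / merged["annual"]).mean())

    r = _ratio(pollutant)
    if r is not None:
        return r, False
    surrogate = rule.get(pollutant)
    if surrogate is not None:
        r = _ratio(surrogate)
        if r is not None:
            return r, True
    raise ValueError(f"no monitoring data for {pollutant} or its surrogate on {date.date()}")


def daily_ratio_series(
    panel: pd.DataFrame,
    annual_means: pd.DataFrame,
    rule: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`daily_ratio` over every (date, pollutant).

    Returns a long frame (date, pollutant, ratio, substituted); dates with
    neither target nor surrogate data are absent.
    """
    rule = DEFAULT_SUBSTITUTION if rule is None else rule
    check_substitution_rule(rule)
    _validate_panel(panel)
    merged = panel.merge(annual_means, on=["site", "pollutant"])
    merged["r"] = merged["concentration"] / merged["annual"]
    base = merged.groupby(["date", "pollutant"], as_index=False)["r"].mean()
    wide = base.pivot(index="date", columns="pollutant", values="r")
    frames = []
    pollutants = set(panel["pollutant"]) | set(rule)
    for p in pollutants:
        target = wide[p] if p in wide.columns else pd.Series(np.nan, index=wide.index)
        substituted = target.isna()
        filled = target.copy()
        surrogate = rule.get(p)
        if surrogate is not None and surrogate in wide.columns:
            filled = filled.fillna(wide[surrogate])
        out = pd.DataFrame(
            {
                "date": wide.index,
                "pollutant": p,
                "ratio": filled.to_numpy(),
                "substituted": (substituted & filled.notna()).to_numpy(),
            }
        )
        frames.append(out.dropna(subset=["ratio"]))
    return pd.concat(frames, ignore_index=True)


def extrapolate_daily(address_annual: float, ratio: float) -> float:
    """Daily address concentration = annual LUR mean x cross-site ratio."""
    if address_annual <= 0 or ratio <= 0:
        raise ValueError("annual mean and ratio must be positive")
    return address_annual * ratio


@dataclass(frozen=True)
class WeeklyExposure:
    mean: float
    n_days_used: int
    substituted: bool


def weekly_exposure(
    address_annual: float,
    ratios: pd.DataFrame,
    scan_date,
    pollutant: str,
    include_scan_day: bool = False,
    min_days: int = 5,
) -> WeeklyExposure:
    """Mean extrapolated daily concentration over the pre-scan week.

    The window is the 7 calendar days strictly before ``scan_date``;
    ``include_scan_day`` extends it to the scan day itself (8 days).  At
    least ``min_days`` window days must be resolvable.  ``ratios`` is the
    output of :func:`daily_ratio_series`.
    """
    scan_date = pd.Timestamp(scan_date)
    last = scan_date if include_scan_day else scan_date - pd.Timedelta(days=1)
    days = pd.date_range(scan_date - pd.Timedelta(days=7), last, freq="D")
    sel = ratios[(ratios["pollutant"] == pollutant) & (ratios["date"].isin(days))]
    if len(sel) < min_days:
        raise CoverageError(
            f"only {len(sel)} of {len(days)} pre-scan days resolvable for {pollutant} "
            f"before {scan_date.date()} (need {min_days})",
            len(sel) / len(days),
        )
    dailies = [extrapolate_daily(address_annual, r) for r in sel["ratio"]]
    return WeeklyExposure(float(np.mean(dailies)), len(sel), bool(sel["substituted"].any()))


def weekly_exposure_table(
    surface: pd.DataFrame,
    ratios: pd.DataFrame,
    sessions: pd.DataFrame,
    pollutants: tuple[str, ...] | list[str],
    include_scan_day: bool = False,
    min_days: int = 5,
) -> pd.DataFrame:
    """Vectorized :func:`weekly_exposure` for many sessions at once.

    ``sessions`` needs columns participant, visit, address, scan_date.
    Returns a long frame (participant, visit, pollutant, weekly_mean,
    n_days_used, substituted); sessions whose pre-scan window has fewer
    than ``min_days`` resolvable days get NaN weekly_mean.  Agrees exactly
    with per-session :func:`weekly_exposure` calls.
    """
    window = 8 if include_scan_day else 7
    wide = ratios.pivot(index="date", columns="pollutant", values="ratio")
    sub = ratios.pivot(index="date", columns="pollutant", values="substituted")
    full_idx = pd.date_range(wide.index.min(), wide.index.max(), freq="D")
    wide = wide.reindex(full_idx)
    sub = sub.reindex(full_idx)
    # stats over the window ending the day before (or on) the scan date
    roll_mean = wide.rolling(window, min_periods=1).mean()
    roll_n = wide.notna().rolling(window, min_periods=1).sum()
    roll_sub = sub.fillna(False).rolling(window, min_periods=1).max()
    frames = []
    offset = pd.Timedelta(days=0 if include_scan_day else 1)
    lookup = pd.DatetimeIndex(pd.to_datetime(sessions["scan_date"])) - offset
    for p in pollutants:
        if p not in roll_mean.columns:
            raise KeyError(f"no ratios available for pollutant {p!r}")
        n_used = np.nan_to_num(roll_n[p].reindex(lookup).to_numpy())
        mean_ratio = roll_mean[p].reindex(lookup).to_numpy()
        annual = surface.loc[sessions["address"], p].to_numpy(dtype=float)
        weekly = annual * mean_ratio
        ok = n_used >= min_days
        frames.append(
            pd.DataFrame(
                {
                    "participant": sessions["participant"].to_numpy(),
                    "visit": sessions["visit"].to_numpy(),
                    "pollutant": p,
                    "weekly_mean": np.where(ok, weekly, np.nan),
                    "n_days_used": n_used.astype(int),
                    "substituted": roll_sub[p].reindex(lookup).fillna(False).to_numpy().astype(bool),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def longterm_exposure(
    residence_history: list[tuple],
    surface: pd.DataFrame,
    period: tuple,
    pollutant: str,
    min_coverage: float = 0.9,
) -> float:
    """Residence-time-weighted mean annual concentration over a period.

    ``residence_history`` is a list of (address, start, end) with inclusive,
    non-overlapping date ranges; ``surface`` an address x pollutant frame of
    annual means.  The history must cover at least ``min_coverage`` of the
    period; exposure is Σ(days_i × annual_i) / Σ days_i.
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    total_days = (end - start).days + 1
    intervals = []
    for address, a, b in residence_history:
        a, b = pd.Timestamp(a), pd.Timestamp(b)
        a, b = max(a, start), min(b, end)
        if a > b:
            continue
        intervals.append((address, a, b))
    intervals.sort(key=lambda t: t[1])
    for (_, _, b1), (_, a2, _) in zip(intervals, intervals[1:]):
        if a2 <= b1:
            raise ValueError("overlapping residence intervals")
    covered = sum((b - a).days + 1 for _, a, b in intervals)
    if covered / total_days < min_coverage:
        raise CoverageError(
            f"residence history covers only {covered / total_days:.0%} of the period",
            covered / total_days,
        )
    weights, values = [], []
    for address, a, b in intervals:
        weights.append((b - a).days + 1)
        values.append(float(surface.loc[address, pollutant]))
    return float(np.average(values, weights=weights))


def scale_to_increment(
    beta_per_unit: float,
    ci_per_unit: tuple[float, float],
    pollutant: str,
    table: dict[str, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Rescale a per-unit coefficient and CI to the reporting increment."""
    table = DEFAULT_INCREMENTS if table is None else table
    if pollutant not in table:
        raise KeyError(f"no increment for pollutant {pollutant!r}")
    d = table[pollutant]
    if d <= 0:
        raise ValueError("increment must be positive")
    return beta_per_unit * d, (ci_per_unit[0] * d, ci_per_unit[1] * d)
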