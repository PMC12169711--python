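"""Synthetic cohort bundles: every input the analysis pipeline consumes.

One call to :func:`simulate_cohort` produces, per participant and visit,
a component time series, a framewise-displacement trace, scan metadata,
weekly and long-term pollutant exposures derived from the monitoring world
by the same ratio-method machinery the pipeline uses, a covariate row with
injected missingness, and an inclusion indicator from a covariate-dependent
selection model.  The planted exposure effect routes through the latent
state chain: weekly exposure to the target pollutant (and a shared
socioeconomic factor, the confounding path) shift the log-odds of the
target state's self-transition.

All randomness descends from one seed; the manifest records every planted
parameter, and regenerating from the manifest reproduces the bundle
byte-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import exposure as expo
from .simulate import StateSequenceModel, simulate_session_batch, simulate_state_sequences
from .templates import DEFAULT_ARCHETYPES, NetworkLayout, StateTemplateSet, build_state_templates
from .world import POLLUTANTS, MonitoringWorld, simulate_annual_surface

SCHOOL_POLLUTANTS = tuple(p for p in POLLUTANTS if p != "PM25ABS")  # absorbance: home only


@dataclass
class CohortSpec:
    """Planted parameters of the synthetic cohort."""

    n_participants: int = 300
    visits: int = 2
    seed: int = 0
    # latent state dynamics
    n_states: int = 5
    self_transition: float = 0.9
    target_state: int = 3  # 0-based: the non-modularized "state 4"
    effect_size: float = 0.15  # logit shift of target self-transition per exposure_scale
    ses_link: float = 0.10  # confounding: logit shift per SD of SES
    target_pollutant: str = "NOX"
    exposure_ref: float = 40.0  # μg/m³ centering of the planted link
    exposure_scale: float = 10.0  # μg/m³ per unit logit shift
    # imaging
    n_windows: int = 60
    epoch_len: int = 25  # TR per state epoch; align window width to this
    observation_noise_sd: float = 0.2
    # exposure surfaces / confounding
    ses_gradient: float = -0.08  # annual-surface tilt per SD SES
    mover_fraction: float = 0.3
    # motion model
    fd_median: float = 0.09  # mm
    fd_between_sd: float = 0.40  # log-scale sd of per-session mean FD
    fd_within_sd: float = 0.60  # log-scale sd of per-volume FD
    # missingness (MCAR rates on stable covariates) and selection
    missing_rates: dict = field(
        default_factory=lambda: {"maternal_iq": 0.10, "income": 0.15, "bmi": 0.08}
    )
    selection_intercept: float = 1.8
    selection_ses: float = 0.3
    include_school: bool = True
    include_longterm: bool = True

    def validate(self) -> None:
        if not 0 <= self.target_state < self.n_states:
            raise ValueError(
                f"effect size planted on unknown state {self.target_state} (k={self.n_states})"
            )
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0,1]")
        if not 0.0 <= self.mover_fraction <= 1.0:
            raise ValueError("mover_fraction outside [0,1]")


@dataclass
class CohortBundle:
    spec: CohortSpec
    participants: pd.DataFrame
    sessions: pd.DataFrame
    covariates: pd.DataFrame  # per (participant, visit), with injected missingness
    exposures: pd.DataFrame  # long: participant, visit, setting, pollutant, weekly_mean, ...
    fd_traces: dict
    timeseries: dict  # (participant, visit) -> (TR x component) array; may be empty
    true_sequences: dict  # (participant, visit) -> planted label sequence
    templates: StateTemplateSet
    manifest: dict
    residence: pd.DataFrame | None = None
    surface: pd.DataFrame | None = None


def state_sequence_model(spec: CohortSpec) -> StateSequenceModel:
    """The planted chain; the per-session 'exposure' fed to it is the
    combined logit shift (exposure term + SES term)."""
    return StateSequenceModel.symmetric(
        spec.n_states, spec.self_transition, exposure_link={spec.target_state: 1.0}
    )


def _seasonal_weather(dates: pd.Series, rng: np.random.Generator):
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    phase = np.cos(2 * np.pi * (doy - 196) / 365.25)  # warm mid-July
    temperature = 10.0 + 8.0 * phase + rng.normal(0, 3, size=len(dates))
    humidity = 80.0 - 6.0 * phase + rng.normal(0, 5, size=len(dates))
    season_sin = np.sin(2 * np.pi * doy / 365.25)
    season_cos = np.cos(2 * np.pi * doy / 365.25)
    return temperature, humidity, season_sin, season_cos


def simulate_cohort(
    spec: CohortSpec,
    world: MonitoringWorld,
    templates: StateTemplateSet | None = None,
    include_imaging: bool = True,
    ratios: pd.DataFrame | None = None,
) -> CohortBundle:
    """Generate the full synthetic dataset bundle.

    ``include_imaging=False`` skips component time series and FD traces
    (the true label sequences are still produced), which makes very large
    sequence-level oracle cohorts cheap.  ``ratios`` may carry a
    precomputed :func:`airdfc.exposure.daily_ratio_series` for the world.
    """
    spec.validate()
    if templates is None:
        layout = NetworkLayout.small()
        templates = build_state_templates(layout, DEFAULT_ARCHETYPES[: spec.n_states], seed=spec.seed)
    if templates.n_states != spec.n_states:
        raise ValueError("template count does not match n_states")
    root = np.random.SeedSequence(spec.seed)
    keys = root.spawn(8)
    rng_pop = np.random.default_rng(keys[0])
    rng_dates = np.random.default_rng(keys[1])
    rng_weather = np.random.default_rng(keys[2])
    rng_seq = np.random.default_rng(keys[3])
    rng_img = np.random.default_rng(keys[4])
    rng_fd = np.random.default_rng(keys[5])
    rng_miss = np.random.default_rng(keys[6])
    rng_surface_seed = int(np.random.default_rng(keys[7]).integers(2**31 - 1))

    n = spec.n_participants
    pids = np.array([f"p{i+1:04d}" for i in range(n)])
    ses = rng_pop.standard_normal(n)

    # --- participant-level covariates (SES proxies) --------------------
    maternal_iq = 100.0 + 8.0 * ses + rng_pop.normal(0, 8, n)
    income = 2.0 + 0.5 * ses + rng_pop.normal(0, 0.7, n)
    maternal_age = 31.0 + 1.5 * ses + rng_pop.normal(0, 4.5, n)
    bmi = 23.6 - 0.8 * ses + rng_pop.normal(0, 4, n)
    incl_logit = spec.selection_intercept + spec.selection_ses * ses
    included = rng_pop.random(n) < 1.0 / (1.0 + np.exp(-incl_logit))

    # --- addresses, movers, schools ------------------------------------
    home1 = np.array([f"home_{p}" for p in pids])
    movers = rng_pop.random(n) < spec.mover_fraction
    home0 = np.where(movers, [f"prev_{p}" for p in pids], home1)
    n_schools = max(1, n // 40)
    school_names = np.array([f"school_{j+1}" for j in range(n_schools)])
    school_of = school_names[rng_pop.integers(0, n_schools, n)]

    addresses = list(home1) + list(home0[movers]) + list(school_names)
    addr_ses = np.concatenate([ses, ses[movers], np.zeros(n_schools)])
    surface = simulate_annual_surface(
        addresses,
        POLLUTANTS,
        ses=addr_ses,
        ses_gradient=spec.ses_gradient,
        seed=rng_surface_seed,
    )

    # --- scan dates and session table ----------------------------------
    d0 = world.dates[0]
    last_ok = len(world.dates) - 1
    v1_offset = rng_dates.integers(400, 731, n)
    gap = np.round(rng_dates.normal(1388, 45, n)).astype(int)
    age1 = 10.2 + rng_dates.normal(0, 0.5, n)
    visits = np.arange(spec.visits)
    offsets = np.minimum(v1_offset[:, None] + visits[None, :] * gap[:, None], last_ok)
    n_sess = n * spec.visits
    sessions = pd.DataFrame(
        {
            "participant": np.repeat(pids, spec.visits),
            "visit": np.tile(visits + 1, n),
            "scan_date": d0 + pd.to_timedelta(offsets.ravel(), unit="D"),
            "address": np.repeat(home1, spec.visits),
            "school": np.repeat(school_of, spec.visits),
            "age": (age1[:, None] + visits[None, :] * gap[:, None] / 365.25).ravel(),
            "scan_hour": rng_dates.uniform(8, 18, n_sess),
            "weekday": rng_dates.integers(0, 6, n_sess),
        }
    )
    temp, hum, s_sin, s_cos = _seasonal_weather(sessions["scan_date"], rng_weather)
    sessions["temperature"] = temp
    sessions["humidity"] = hum
    sessions["season_sin"] = s_sin
    sessions["season_cos"] = s_cos

    # --- exposures via the ratio method --------------------------------
    if ratios is None:
        annual = expo.annual_site_means(world.panel, world.reference_period)
        ratios = expo.daily_ratio_series(world.panel, annual)
    home_exp = expo.weekly_exposure_table(surface, ratios, sessions, POLLUTANTS)
    home_exp.insert(2, "setting", "home")
    frames = [home_exp]
    if spec.include_school:
        school_sessions = sessions.copy()
        school_sessions["address"] = school_sessions["school"]
        school_exp = expo.weekly_exposure_table(surface, ratios, school_sessions, SCHOOL_POLLUTANTS)
        school_exp.insert(2, "setting", "school")
        frames.append(school_exp)
    exposures = pd.concat(frames, ignore_index=True)

    # --- residence history and long-term averages -----------------------
    childhood = int(10.2 * 365.25)
    v1_dates = d0 + pd.to_timedelta(offsets[:, 0], unit="D")
    birth_dates = v1_dates - pd.Timedelta(days=childhood)
    move_days = rng_pop.uniform(365, 3000, n).astype(int)
    res_rows = []
    for i in range(n):
        if movers[i]:
            move = birth_dates[i] + pd.Timedelta(days=int(move_days[i]))
            res_rows.append((pids[i], home0[i], birth_dates[i], move))
            res_rows.append((pids[i], home1[i], move + pd.Timedelta(days=1), v1_dates[i]))
        else:
            res_rows.append((pids[i], home1[i], birth_dates[i], v1_dates[i]))
    residence = pd.DataFrame(res_rows, columns=["participant", "address", "start", "end"])

    if spec.include_longterm:
        lt_rows = []
        for pid, hist_df in residence.groupby("participant", sort=False):
            hist = list(hist_df[["address", "start", "end"]].itertuples(index=False, name=None))
            period = (hist[0][1], hist[-1][2])
            for p in POLLUTANTS:
                lt_rows.append(
                    {
                        "participant": pid,
                        "pollutant": p,
                        "longterm_mean": expo.longterm_exposure(hist, surface, period, p),
                    }
                )
        exposures = exposures.merge(pd.DataFrame(lt_rows), on=["participant", "pollutant"], how="left")

    # --- planted outcome: exposure-linked state chain -------------------
    target = exposures[
        (exposures["setting"] == "home") & (exposures["pollutant"] == spec.target_pollutant)
    ].set_index(["participant", "visit"])["weekly_mean"]
    sess_keys = list(zip(sessions["participant"], sessions["visit"]))
    x_true = target.loc[sess_keys].to_numpy()
    ses_by_pid = dict(zip(pids, ses))
    ses_sess = np.array([ses_by_pid[p] for p in sessions["participant"]])
    shifts = (
        spec.effect_size * (x_true - spec.exposure_ref) / spec.exposure_scale
        + spec.ses_link * ses_sess
    )
    model = state_sequence_model(spec)
    labels = simulate_state_sequences(model, spec.n_windows, shifts, rng_seq)
    true_sequences = {k: labels[i] for i, k in enumerate(sess_keys)}

    # --- imaging and motion ---------------------------------------------
    timeseries: dict = {}
    fd_traces: dict = {}
    if include_imaging:
        data = simulate_session_batch(
            templates, labels, spec.epoch_len, spec.observation_noise_sd, rng_img
        )
        n_volumes = spec.n_windows * spec.epoch_len
        session_fd = spec.fd_median * np.exp(rng_fd.normal(0, spec.fd_between_sd, len(sess_keys)))
        for i, k in enumerate(sess_keys):
            timeseries[k] = data[i]
            fd_traces[k] = session_fd[i] * np.exp(
                rng_fd.normal(0, spec.fd_within_sd, n_volumes) - 0.5 * spec.fd_within_sd**2
            )

    # --- covariate table with injected missingness ----------------------
    participants = pd.DataFrame(
        {
            "participant": pids,
            "ses": ses,
            "maternal_iq": maternal_iq,
            "income": income,
            "maternal_age": maternal_age,
            "bmi": bmi,
            "included": included,
        }
    )
    covariates = sessions[
        ["participant", "visit", "age", "temperature", "humidity",
         "season_sin", "season_cos", "weekday", "scan_hour"]
    ].merge(participants.drop(columns=["included"]), on="participant")
    for col, rate in spec.missing_rates.items():
        if rate > 0 and col in covariates.columns:
            mask = rng_miss.random(len(covariates)) < rate
            covariates.loc[mask, col] = np.nan

    manifest = {
        "spec": {k: (dict(v) if isinstance(v, dict) else v) for k, v in asdict(spec).items()},
        "world_params": world.params,
        "template_seed": templates.seed,
        "n_sessions": len(sess_keys),
        "target_pollutant": spec.target_pollutant,
    }
    return CohortBundle(
        spec=spec,
        participants=participants,
        sessions=sessions,
        covariates=covariates,
        exposures=exposures,
        fd_traces=fd_traces,
        timeseries=timeseries,
        true_sequences=true_sequences,
        templates=templates,
        manifest=manifest,
        residence=residence,
        surface=surface,
    )
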