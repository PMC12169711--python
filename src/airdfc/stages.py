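"""File-based pipeline stages.

Each stage reads the previous stage's documented CSV / delimited-text
outputs from a working directory, writes its own, and records a JSON
manifest (stage, parameters, seed, input/output counts, exclusions with
reasons).  Stages are idempotent: identical config and inputs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as expo
from .cohort import CohortSpec, simulate_cohort
from .config import RunConfig
from .pipeline import (
    compute_stacks,
    default_adjustment_sets,
    dwell_outcomes,
    fit_and_assign,
    qc_sessions,
    template_reference,
)
from .inference import impute_simple
from .templates import DEFAULT_ARCHETYPES, NetworkLayout, build_state_templates
from .windows import QCSpec, WindowSpec
from .world import POLLUTANTS, simulate_monitoring_world

log = logging.getLogger("airdfc")

STAGES = ("simulate", "dfc", "states", "exposure", "associate")

SESSION_COLUMNS = ("participant", "visit", "scan_date", "address", "school")
PANEL_COLUMNS = ("site", "date", "pollutant", "concentration")


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: RunConfig, info: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        **info,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def _require_columns(df: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _read_csv(path: Path, needed, parse_dates=()) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream output {path}")
    df = pd.read_csv(path, parse_dates=list(parse_dates))
    _require_columns(df, needed, path)
    return df


def _session_key(row) -> str:
    return f"{row['participant']}_v{row['visit']}"


def _window_spec(config: RunConfig) -> WindowSpec:
    return WindowSpec(config.width, config.step, config.taper_sigma)


def _qc_spec(config: RunConfig) -> QCSpec:
    return QCSpec(config.mean_fd_max, config.fd_spike_threshold, config.spike_fraction_max)


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    layout = NetworkLayout.small() if config.layout == "small" else NetworkLayout.default()
    templates = build_state_templates(layout, DEFAULT_ARCHETYPES[: config.k], seed=config.seed)
    world = simulate_monitoring_world(n_sites=config.n_sites, n_days=config.n_days, seed=config.seed)
    spec = CohortSpec(
        n_participants=config.n_participants,
        visits=config.visits,
        seed=config.seed,
        n_states=config.k,
        target_state=config.target_state,
        effect_size=config.effect_size,
        target_pollutant=config.target_pollutant,
        n_windows=config.n_windows,
        epoch_len=config.epoch_len,
        observation_noise_sd=config.observation_noise_sd,
        include_school=config.include_school,
        include_longterm=config.include_longterm,
    )
    bundle = simulate_cohort(spec, world, templates)

    world.panel.assign(date=world.panel["date"].dt.date).to_csv(outdir / "monitoring_panel.csv", index=False)
    bundle.surface.to_csv(outdir / "annual_surface.csv")
    bundle.sessions.assign(scan_date=bundle.sessions["scan_date"].dt.date).to_csv(
        outdir / "sessions.csv", index=False
    )
    bundle.covariates.to_csv(outdir / "covariates.csv", index=False)
    bundle.participants.to_csv(outdir / "participants.csv", index=False)
    res = bundle.residence.copy()
    res["start"] = res["start"].dt.date
    res["end"] = res["end"].dt.date
    res.to_csv(outdir / "residence.csv", index=False)
    bundle.exposures.to_csv(outdir / "exposures_true.csv", index=False)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(exist_ok=True)
    for (pid, visit), ts in bundle.timeseries.items():
        np.savetxt(tsdir / f"ts_{pid}_v{visit}.tsv", ts, fmt="%.6f", delimiter="\t")
        np.savetxt(tsdir / f"fd_{pid}_v{visit}.txt", bundle.fd_traces[(pid, visit)], fmt="%.6f")
    info = {
        "world": world.params,
        "reference_period": [str(d.date()) for d in world.reference_period],
        "n_sessions": len(bundle.sessions),
        "planted": bundle.manifest["spec"],
    }
    _write_manifest(outdir, "simulate", config, info)
    return info


def stage_dfc(config: RunConfig, outdir: Path) -> dict:
    sessions = _read_csv(outdir / "sessions.csv", SESSION_COLUMNS, parse_dates=("scan_date",))
    tsdir = outdir / "timeseries"
    fd_traces, timeseries = {}, {}
    for _, row in sessions.iterrows():
        key = (row["participant"], int(row["visit"]))
        fd_traces[key] = np.loadtxt(tsdir / f"fd_{key[0]}_v{key[1]}.txt")
        timeseries[key] = np.loadtxt(tsdir / f"ts_{key[0]}_v{key[1]}.tsv", delimiter="\t")
    kept, exclusions = qc_sessions(fd_traces, _qc_spec(config))
    exclusions.to_csv(outdir / "qc_exclusions.csv", index=False)
    stacks = compute_stacks(timeseries, kept, _window_spec(config))
    stackdir = outdir / "stacks"
    stackdir.mkdir(exist_ok=True)
    for (pid, visit), stack in stacks.items():
        np.savetxt(stackdir / f"stack_{pid}_v{visit}.tsv", stack.vectors, fmt="%.6f", delimiter="\t")
    sidecar = {
        "window_spec": {"width": config.width, "step": config.step, "taper_sigma": config.taper_sigma},
        "sessions": [f"{p}_v{v}" for p, v in kept],
    }
    (outdir / "stacks.json").write_text(json.dumps(sidecar, indent=2))
    for _, row in exclusions.iterrows():
        log.info("QC excluded %s visit %s: %s", row["participant"], row["visit"], row["reasons"])
    info = {"n_input": len(fd_traces), "n_kept": len(kept), "n_excluded": len(exclusions)}
    _write_manifest(outdir, "dfc", config, info)
    return info


def _load_stacks(outdir: Path) -> dict:
    sidecar_path = outdir / "stacks.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing upstream output {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    stacks = {}
    for name in sidecar["sessions"]:
        pid, v = name.rsplit("_v", 1)
        stacks[(pid, int(v))] = np.loadtxt(outdir / "stacks" / f"stack_{name}.tsv", delimiter="\t")
    return stacks


def stage_states(config: RunConfig, outdir: Path) -> dict:
    stacks = _load_stacks(outdir)
    layout = NetworkLayout.small() if config.layout == "small" else NetworkLayout.default()
    templates = build_state_templates(layout, DEFAULT_ARCHETYPES[: config.k], seed=config.seed)
    model, assignments, match = fit_and_assign(
        stacks, k=config.k, seed=config.seed, n_restarts=config.n_restarts,
        reference=template_reference(templates),
    )
    np.savetxt(outdir / "centroids.tsv", model.centroids, fmt="%.6f", delimiter="\t")
    (outdir / "state_model.json").write_text(
        json.dumps(
            {
                "k": model.k,
                "seed": model.seed,
                "n_restarts": model.n_restarts,
                "inertia": model.inertia,
                "match_correlations": [float(c) for c in match.correlations],
            },
            indent=2,
        )
    )
    dwell, transforms = dwell_outcomes(assignments, config.k, unvisited=config.unvisited)
    dwell.to_csv(outdir / "dwell.csv", index=False)
    info = {
        "n_sessions": len(stacks),
        "inertia": model.inertia,
        "boxcox_lambda": {s: t.lambda_ for s, t in transforms.items()},
    }
    _write_manifest(outdir, "states", config, info)
    return info


def stage_exposure(config: RunConfig, outdir: Path) -> dict:
    panel = _read_csv(outdir / "monitoring_panel.csv", PANEL_COLUMNS, parse_dates=("date",))
    surface = pd.read_csv(outdir / "annual_surface.csv", index_col="address")
    sessions = _read_csv(outdir / "sessions.csv", SESSION_COLUMNS, parse_dates=("scan_date",))
    period = (panel["date"].min(), panel["date"].min() + pd.Timedelta(days=364))
    annual = expo.annual_site_means(panel, period, config.reference_coverage)
    ratios = expo.daily_ratio_series(panel, annual)
    home = expo.weekly_exposure_table(
        surface, ratios, sessions, POLLUTANTS,
        include_scan_day=config.include_scan_day, min_days=config.min_week_days,
    )
    home.insert(2, "setting", "home")
    frames = [home]
    if config.include_school:
        school_sessions = sessions.copy()
        school_sessions["address"] = school_sessions["school"]
        school = expo.weekly_exposure_table(
            surface, ratios, school_sessions,
            [p for p in POLLUTANTS if p != "PM25ABS"],
            include_scan_day=config.include_scan_day, min_days=config.min_week_days,
        )
        school.insert(2, "setting", "school")
        frames.append(school)
    records = pd.concat(frames, ignore_index=True)
    if config.include_longterm:
        residence = _read_csv(
            outdir / "residence.csv", ("participant", "address", "start", "end"),
            parse_dates=("start", "end"),
        )
        lt_rows = []
        for pid, hist_df in residence.groupby("participant"):
            hist = [(r["address"], r["start"], r["end"]) for _, r in hist_df.iterrows()]
            period_lt = (min(h[1] for h in hist), max(h[2] for h in hist))
            for p in POLLUTANTS:
                lt_rows.append(
                    {
                        "participant": pid,
                        "pollutant": p,
                        "longterm_mean": expo.longterm_exposure(
                            hist, surface, period_lt, p, config.longterm_coverage
                        ),
                    }
                )
        records = records.merge(pd.DataFrame(lt_rows), on=["participant", "pollutant"], how="left")
    records.to_csv(outdir / "exposure_records.csv", index=False)
    info = {"n_records": len(records), "pollutants": sorted(records["pollutant"].unique())}
    _write_manifest(outdir, "exposure", config, info)
    return info


def stage_associate(config: RunConfig, outdir: Path) -> dict:
    from .inference import effective_tests, run_association_grid

    dwell = _read_csv(outdir / "dwell.csv", ("participant", "visit", "state", "dwell", "dwell_transformed"))
    exposures = _read_csv(
        outdir / "exposure_records.csv",
        ("participant", "visit", "setting", "pollutant", "weekly_mean"),
    )
    covariates = _read_csv(outdir / "covariates.csv", ("participant", "visit"))
    sets = default_adjustment_sets()
    if config.adjustment != "all":
        sets = {config.adjustment: sets[config.adjustment]}
    if not config.include_longterm:
        sets.pop("main_longterm", None)
    imputed = None
    if covariates.isna().any().any() and config.m_imputations >= 2:
        imputed = impute_simple(covariates, config.m_imputations, seed=config.seed)
    outcome_wide = dwell.pivot_table(
        index=["participant", "visit"], columns="state", values="dwell_transformed"
    )
    meff = effective_tests(outcome_wide)
    grid = run_association_grid(
        dwell, exposures, covariates, sets,
        imputed_covariates=imputed, alpha_adjusted=meff.alpha,
    )
    grid.to_csv(outdir / "results.csv", index=False)
    (outdir / "multiplicity.json").write_text(
        json.dumps(
            {
                "eigenvalues": [float(v) for v in meff.eigenvalues],
                "m_eff": meff.m_eff,
                "alpha_adjusted": meff.alpha,
            },
            indent=2,
        )
    )
    info = {"n_cells": len(grid), "m_eff": meff.m_eff, "alpha_adjusted": meff.alpha}
    _write_manifest(outdir, "associate", config, info)
    return info


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dfc": stage_dfc,
    "states": stage_states,
    "exposure": stage_exposure,
    "associate": stage_associate,
}


def run_stage(name: str, config: RunConfig, outdir) -> dict:
    """Run one named stage (or "run-all" for the full chain)."""
    outdir = Path(outdir)
    if name == "run-all":
        info = {}
        for stage in STAGES:
            log.info("running stage %s", stage)
            info[stage] = _STAGE_FUNCS[stage](config, outdir)
        return info
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES + ('run-all',)}")
    return _STAGE_FUNCS[name](config, outdir)
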