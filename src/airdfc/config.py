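"""Run configuration: a single YAML/JSON document with strict validation.

Unknown keys are rejected with a nearest-key suggestion; cross-field
constraints (e.g. step <= width) are enforced at load time.  Every seed
that enters a run is recorded in the stage manifests.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    # synthetic cohort
    n_participants: int = 60
    visits: int = 2
    layout: str = "small"  # "small" (12 comps / 4 networks) or "default" (51 / 7)
    n_windows: int = 60
    epoch_len: int = 25
    observation_noise_sd: float = 0.3
    effect_size: float = 0.15
    target_state: int = 3
    target_pollutant: str = "NOX"
    include_school: bool = False
    include_longterm: bool = True
    # monitoring world
    n_sites: int = 7
    n_days: int = 2190
    # windows
    width: int = 25
    step: int = 25
    taper_sigma: float = 3.0
    # QC
    mean_fd_max: float = 0.25
    fd_spike_threshold: float = 0.2
    spike_fraction_max: float = 0.20
    # states / outcomes
    k: int = 5
    n_restarts: int = 5
    unvisited: str = "missing"
    # exposures
    include_scan_day: bool = False
    min_week_days: int = 5
    reference_coverage: float = 0.75
    longterm_coverage: float = 0.90
    # inference
    m_imputations: int = 25
    adjustment: str = "main"  # minimal | main | main_longterm | all

    def validate(self) -> "RunConfig":
        if self.width < 3:
            raise ValueError("window width must be >= 3")
        if self.step < 1 or self.step > self.width:
            raise ValueError("window step must satisfy 1 <= step <= width")
        if self.taper_sigma < 0:
            raise ValueError("taper_sigma must be >= 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if self.layout not in ("small", "default"):
            raise ValueError("layout must be 'small' or 'default'")
        if self.unvisited not in ("missing", "zero"):
            raise ValueError("unvisited must be 'missing' or 'zero'")
        if self.adjustment not in ("minimal", "main", "main_longterm", "all"):
            raise ValueError("unknown adjustment set")
        if not 0 < self.reference_coverage <= 1 or not 0 < self.longterm_coverage <= 1:
            raise ValueError("coverage thresholds must be in (0, 1]")
        if self.n_days < 365:
            raise ValueError("monitoring world needs at least 365 days")
        if not 0 <= self.target_state < self.k:
            raise ValueError("target_state outside [0, k)")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and validate a config document; fill defaults.

    An empty document yields all defaults (window width 25, k 5, 25
    imputations).  Unknown keys raise with a did-you-mean suggestion.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a key-value document")
    kwargs = {}
    for key, value in data.items():
        if key not in _FIELDS:
            hint = difflib.get_close_matches(key, _FIELDS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion}")
        f = _FIELDS[key]
        try:
            if f.type in ("int", int):
                value = int(value)
            elif f.type in ("float", float):
                value = float(value)
            elif f.type in ("bool", bool):
                if isinstance(value, str):
                    value = value.lower() in ("1", "true", "yes", "on")
                value = bool(value)
            elif f.type in ("str", str):
                value = str(value)
        except (TypeError, ValueError) as err:
            raise ValueError(f"config key {key!r}: cannot coerce {value!r}") from err
        kwargs[key] = value
    return RunConfig(**kwargs).validate()
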