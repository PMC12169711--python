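"""Latent state sequences and component time series.

The latent connectivity process is modeled as a first-order Markov chain
over window-length epochs: one state label per epoch, each epoch spanning a
fixed number of repetition times (TR).  Exposure enters as a logistic shift
of the self-transition probability of target states, which monotonically
lengthens (or shortens) dwell times in those states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .templates import StateTemplateSet


@dataclass
class StateSequenceModel:
    """Markov chain over states with an exposure-linked self-transition.

    ``exposure_link[s]`` is the additive shift, per unit exposure, applied to
    the log-odds of state ``s``'s self-transition probability.  Off-diagonal
    probabilities in the shifted row are rescaled proportionally.
    """

    transition: np.ndarray
    initial: np.ndarray | None = None
    exposure_link: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.transition.shape[0]
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix must be square")
        if (self.transition < 0).any() or not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix must be row-stochastic")
        if self.initial is None:
            self.initial = np.full(k, 1.0 / k)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (k,) or (self.initial < 0).any() or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution invalid")
        if self.exposure_link is None:
            self.exposure_link = np.zeros(k)
        self.exposure_link = np.asarray(self.exposure_link, dtype=float)
        if self.exposure_link.shape != (k,):
            raise ValueError("exposure_link must have one entry per state")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @classmethod
    def symmetric(
        cls,
        n_states: int = 5,
        self_transition: float = 0.9,
        exposure_link: dict[int, float] | None = None,
    ) -> "StateSequenceModel":
        """Equal self-transitions, uniform off-diagonal switching."""
        if not 0.0 <= self_transition <= 1.0:
            raise ValueError("self_transition must be a probability")
        off = (1.0 - self_transition) / (n_states - 1) if n_states > 1 else 0.0
        trans = np.full((n_states, n_states), off)
        np.fill_diagonal(trans, self_transition)
        link = np.zeros(n_states)
        for s, v in (exposure_link or {}).items():
            if not 0 <= s < n_states:
                raise ValueError(f"exposure link on unknown state {s}")
            link[s] = v
        return cls(trans, exposure_link=link)

    def effective_transition(self, exposure: float) -> np.ndarray:
        """Transition matrix after the exposure-linked logistic shift."""
        trans = self.transition.copy()
        for s in np.flatnonzero(self.exposure_link):
            p = trans[s, s]
            if p <= 0.0 or p >= 1.0:
                continue  # degenerate rows are left untouched
            p_new = float(expit(logit(p) + self.exposure_link[s] * exposure))
            scale = (1.0 - p_new) / (1.0 - p)
            trans[s] = trans[s] * scale
            trans[s, s] = p_new
        return trans


def simulate_state_sequence(
    model: StateSequenceModel,
    n_windows: int,
    exposure: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one label sequence of length ``n_windows``."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return simulate_state_sequences(model, n_windows, np.array([exposure]), seed)[0]


def simulate_state_sequences(
    model: StateSequenceModel,
    n_windows: int,
    exposures: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Vectorized simulation of one sequence per exposure value.

    Returns an ``(n_sequences, n_windows)`` integer array.  With all
    exposure links zero the chain is homogeneous and a state with
    self-transition p has geometric run lengths with mean 1/(1-p).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exposures = np.asarray(exposures, dtype=float)
    n = exposures.size
    k = model.n_states

    base_cum = np.cumsum(model.transition, axis=1)
    linked = np.flatnonzero(model.exposure_link)
    # per-individual cumulative rows only for exposure-linked states
    cum_linked: dict[int, np.ndarray] = {}
    for s in linked:
        rows = np.empty((n, k))
        for i, x in enumerate(exposures):
            rows[i] = model.effective_transition(float(x))[s]
        cum_linked[s] = np.cumsum(rows, axis=1)

    out = np.empty((n, n_windows), dtype=np.int64)
    state = np.searchsorted(np.cumsum(model.initial), rng.random(n), side="right")
    state = np.minimum(state, k - 1)
    out[:, 0] = state
    for t in range(1, n_windows):
        u = rng.random(n)
        cum = base_cum[state]
        for s, rows in cum_linked.items():
            mask = state == s
            if mask.any():
                cum[mask] = rows[mask]
        state = (u[:, None] > cum).sum(axis=1)
        state = np.minimum(state, k - 1)
        out[:, t] = state
    return out


def _state_choleskys(templates: StateTemplateSet) -> list[np.ndarray]:
    chols = []
    for t in templates.templates:
        c = t.shape[0]
        chols.append(np.linalg.cholesky(t + 1e-9 * np.eye(c)))
    return chols


def simulate_component_timeseries(
    templates: StateTemplateSet,
    sequence: np.ndarray,
    n_timepoints_per_window_step: int = 25,
    observation_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a (TR x component) series whose epochs follow the label sequence.

    Each label governs ``n_timepoints_per_window_step`` consecutive rows,
    drawn i.i.d. from a zero-mean Gaussian with the active state's template
    as correlation, plus isotropic observation noise.
    """
    sequence = np.asarray(sequence)
    if sequence.size == 0:
        raise ValueError("sequence must be nonempty")
    out = simulate_session_batch(
        templates,
        sequence[None, :],
        n_timepoints_per_window_step,
        observation_noise_sd,
        seed,
    )
    return out[0]


def simulate_session_batch(
    templates: StateTemplateSet,
    label_matrix: np.ndarray,
    epoch_len: int,
    observation_noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Batch version: (sessions, labels) -> (sessions, labels*epoch_len, C)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    label_matrix = np.asarray(label_matrix)
    n_sessions, n_labels = label_matrix.shape
    c = templates.layout.n_components
    if label_matrix.min() < 0 or label_matrix.max() >= templates.n_states:
        raise ValueError("label outside template range")
    chols = _state_choleskys(templates)
    tp_labels = np.repeat(label_matrix, epoch_len, axis=1).ravel()
    total = tp_labels.size
    data = np.empty((total, c))
    for s in range(templates.n_states):
        idx = np.flatnonzero(tp_labels == s)
        if idx.size:
            data[idx] = rng.standard_normal((idx.size, c)) @ chols[s].T
    if observation_noise_sd > 0:
        data += observation_noise_sd * rng.standard_normal((total, c))
    return data.reshape(n_sessions, n_labels * epoch_len, c)


def simulate_window_vectors(
    templates: StateTemplateSet,
    labels: np.ndarray,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Fisher-z window vectors drawn directly around template z-vectors.

    Bypasses the time-series route: vector = template z-vector + isotropic
    Gaussian noise.  Useful for planted-partition clustering checks where
    the signal-to-noise ratio must be controlled exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.asarray(labels)
    z = templates.zvectors()
    return z[labels] + noise_sd * rng.standard_normal((labels.size, z.shape[1]))


def mean_run_length(sequence: np.ndarray, state: int) -> float:
    """Mean length of maximal runs of *state*; NaN if never visited."""
    sequence = np.asarray(sequence)
    mask = np.concatenate(([False], sequence == state, [False]))
    starts = np.flatnonzero(~mask[:-1] & mask[1:])
    ends = np.flatnonzero(mask[:-1] & ~mask[1:])
    if starts.size == 0:
        return float("nan")
    return float(np.mean(ends - starts))
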