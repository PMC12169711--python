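"""Connectivity states: pooled k-means, label matching, dwell times.

Window vectors from all sessions and visits are pooled and clustered with
multi-restart k-means (Euclidean distance on Fisher-z vectors, default
k = 5).  Centroids are returned in canonical order (descending occupancy)
and replicate runs are aligned by an exact optimal assignment maximizing
summed centroid correlation.  The per-session outcome is the mean dwell
time in each state: the average length, in windows, of maximal runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .windows import WindowStack


@dataclass
class StateModel:
    centroids: np.ndarray  # (k, n_edges)
    seed: int = 0
    n_restarts: int = 1
    inertia: float = float("nan")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_edges(self) -> int:
        return self.centroids.shape[1]


def _pool(stacks) -> np.ndarray:
    if isinstance(stacks, np.ndarray):
        return stacks
    if isinstance(stacks, WindowStack):
        return stacks.vectors
    return np.vstack([s.vectors if isinstance(s, WindowStack) else np.asarray(s) for s in stacks])


def fit_states(
    stacks,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> StateModel:
    """Multi-restart k-means over pooled window vectors.

    Deterministic given ``seed``; best restart by inertia.  Centroids are
    ordered by descending occupancy so labels are stable across runs on the
    same data.
    """
    x = _pool(stacks)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] < 10 * k:
        raise ValueError(f"need at least {10 * k} windows to fit {k} states")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("fewer distinct window vectors than states")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    return StateModel(km.cluster_centers_[order], seed=seed, n_restarts=n_restarts, inertia=float(km.inertia_))


@dataclass
class StateMatch:
    """Label alignment between two state models.

    ``permutation[i]`` is the reference label matched to model label ``i``;
    ``correlations[i]`` the Pearson correlation of the matched centroids.
    """

    permutation: np.ndarray
    correlations: np.ndarray

    def relabel(self, labels: np.ndarray) -> np.ndarray:
        """Map model labels onto the reference labeling."""
        return self.permutation[np.asarray(labels)]


def match_states(model: StateModel, reference: StateModel) -> StateMatch:
    """Exact optimal one-to-one label assignment (Hungarian algorithm)
    maximizing summed centroid Pearson correlation."""
    if model.k != reference.k or model.n_edges != reference.n_edges:
        raise ValueError("model and reference dimensions differ")
    k = model.k
    corr = np.corrcoef(model.centroids, reference.centroids)[:k, k:]
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return StateMatch(perm, corr[rows, cols])


def assign_states(stack, model: StateModel) -> np.ndarray:
    """Nearest-centroid (Euclidean) labels; ties go to the lowest label."""
    x = _pool(stack)
    if x.shape[1] != model.n_edges:
        raise ValueError("edge dimension mismatch")
    return np.argmin(cdist(x, model.centroids), axis=1)


@dataclass
class DwellResult:
    dwell: np.ndarray  # mean run length per state; NaN where unvisited
    fraction: np.ndarray  # occupancy fraction per state


def mean_dwell_time(sequence: np.ndarray, k: int) -> DwellResult:
    """Mean dwell time (average maximal-run length, in windows) per state.

    Unvisited states get NaN dwell and fraction 0; fractions sum to 1.
    """
    seq = np.asarray(sequence)
    if seq.size == 0:
        raise ValueError("empty sequence")
    if seq.min() < 0 or seq.max() >= k:
        raise ValueError("labels outside [0, k)")
    boundaries = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [seq.size]))
    run_states = seq[starts]
    run_lens = ends - starts
    dwell = np.full(k, np.nan)
    fraction = np.zeros(k)
    for s in range(k):
        mask = run_states == s
        if mask.any():
            dwell[s] = float(run_lens[mask].mean())
            fraction[s] = float(run_lens[mask].sum()) / seq.size
    return DwellResult(dwell, fraction)


def dwell_table(assignments: dict, k: int) -> pd.DataFrame:
    """Long-form dwell table from per-session label sequences.

    ``assignments`` maps (participant, visit) -> label sequence.  Columns:
    participant, visit, state (1-based, matching the field's convention),
    dwell, fraction.
    """
    rows = []
    for (participant, visit), labels in assignments.items():
        res = mean_dwell_time(labels, k)
        for s in range(k):
            rows.append(
                {
                    "participant": participant,
                    "visit": visit,
                    "state": s + 1,
                    "dwell": res.dwell[s],
                    "fraction": res.fraction[s],
                }
            )
    return pd.DataFrame(rows)
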