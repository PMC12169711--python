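"""Motion QC and tapered sliding-window connectivity.

Sessions are screened on framewise displacement (FD): a scan is excluded
when mean FD exceeds 0.25 mm or when more than 20 % of volumes exceed
0.2 mm.  Surviving component time series are cut into tapered sliding
windows (default width 25 TR, step 1 TR; taper = rectangle convolved with a
Gaussian of sd 3 TR) and each window yields a weighted Pearson correlation
matrix, Fisher-z transformed and vectorized over the upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

FISHER_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class QCSpec:
    """Motion-exclusion thresholds (all in mm / proportions)."""

    mean_fd_max: float = 0.25
    fd_spike_threshold: float = 0.2
    spike_fraction_max: float = 0.20

    def __post_init__(self) -> None:
        if self.mean_fd_max <= 0 or self.fd_spike_threshold <= 0:
            raise ValueError("FD thresholds must be positive")
        if not 0.0 < self.spike_fraction_max < 1.0:
            raise ValueError("spike_fraction_max must be in (0,1)")


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reasons: tuple[str, ...]
    mean_fd: float
    spike_fraction: float


def qc_filter(fd_trace: np.ndarray, spec: QCSpec = QCSpec()) -> QCDecision:
    """Keep/exclude decision for one session's FD trace.

    Both reasons are reported when both rules fire.  The mean rule is
    invariant to trace ordering; the spike rule to permutation.
    """
    fd = np.asarray(fd_trace, dtype=float)
    if fd.size == 0:
        raise ValueError("FD trace is empty")
    if (fd < 0).any():
        raise ValueError("negative FD values")
    mean_fd = float(fd.mean())
    spike_fraction = float((fd > spec.fd_spike_threshold).mean())
    reasons = []
    if mean_fd > spec.mean_fd_max:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {spec.mean_fd_max} mm")
    if spike_fraction > spec.spike_fraction_max:
        reasons.append(
            f"{spike_fraction:.1%} of volumes with FD > {spec.fd_spike_threshold} mm "
            f"(limit {spec.spike_fraction_max:.0%})"
        )
    return QCDecision(not reasons, tuple(reasons), mean_fd, spike_fraction)


@dataclass(frozen=True)
class WindowSpec:
    """Tapered sliding-window geometry, in TR units.

    Windows are indexed 0-based by starting row and cover the half-open
    range [start, start+width).
    """

    width: int = 25
    step: int = 1
    taper_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.width < 3:
            raise ValueError("width must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.taper_sigma < 0:
            raise ValueError("taper_sigma must be >= 0")


def make_taper(spec: WindowSpec) -> np.ndarray:
    """Rectangle-convolved-with-Gaussian taper, length ``width``, sum 1.

    With ``taper_sigma == 0`` the kernel degenerates to a delta and the
    taper is uniform.  Weights are symmetric and maximal at the center.
    """
    w = spec.width
    if spec.taper_sigma < 1e-8:  # delta kernel; avoids overflow at tiny sd
        return np.full(w, 1.0 / w)
    half = int(np.ceil(4 * spec.taper_sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / spec.taper_sigma) ** 2)
    kernel /= kernel.sum()
    # central `width` values of the full convolution (truncation)
    full = np.convolve(np.ones(w), kernel, mode="full")
    taper = full[half : half + w]
    taper = taper / taper.sum()
    # convolution of symmetric inputs: enforce exact symmetry numerically
    taper = (taper + taper[::-1]) / 2.0
    return taper / taper.sum()


def sliding_windows(n_timepoints: int, spec: WindowSpec) -> np.ndarray:
    """Window start indices 0, step, 2*step, ... <= n_timepoints - width."""
    if n_timepoints < spec.width:
        raise ValueError(
            f"series length {n_timepoints} shorter than window width {spec.width}"
        )
    return np.arange(0, n_timepoints - spec.width + 1, spec.step)


@dataclass
class WindowStack:
    """Fisher-z window vectors for one session.

    ``vectors`` is (n_windows, n_edges) with row-major upper-triangle
    vectorization (diagonal excluded), so n_edges = C(C-1)/2.
    """

    vectors: np.ndarray
    session_id: str = ""
    window_starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_edges(self) -> int:
        return self.vectors.shape[1]


def _weighted_corr_batch(wins: np.ndarray, taper: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation for a (n_win, width, C) stack."""
    mean = np.einsum("wtc,t->wc", wins, taper)
    xc = wins - mean[:, None, :]
    cov = np.einsum("wtc,wtd,t->wcd", xc, xc, taper)
    var = np.einsum("wcc->wc", cov)
    if (var <= 0).any():
        w_idx, c_idx = np.argwhere(var <= 0)[0]
        raise ValueError(
            f"zero weighted variance in window {int(w_idx)}, component {int(c_idx)}"
        )
    sd = np.sqrt(var)
    return cov / (sd[:, :, None] * sd[:, None, :])


def windowed_correlation(
    timeseries: np.ndarray,
    spec: WindowSpec = WindowSpec(),
    session_id: str = "",
) -> WindowStack:
    """Tapered weighted correlations per sliding window, Fisher-z vectorized.

    Correlations are clipped to |r| <= 1 - 1e-6 before z = atanh(r), so
    degenerate (perfectly correlated) windows stay finite.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2:
        raise ValueError("timeseries must be 2-D (TR x components)")
    if np.isnan(x).any():
        raise ValueError("timeseries contains missing values")
    starts = sliding_windows(x.shape[0], spec)
    taper = make_taper(spec)
    wins = sliding_window_view(x, spec.width, axis=0)[starts]  # (n_win, C, width)
    wins = np.swapaxes(wins, 1, 2)  # (n_win, width, C)
    corr = _weighted_corr_batch(wins, taper)
    c = x.shape[1]
    iu = np.triu_indices(c, k=1)
    r = np.clip(corr[:, iu[0], iu[1]], -FISHER_CLIP, FISHER_CLIP)
    return WindowStack(np.arctanh(r), session_id=session_id, window_starts=starts)
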