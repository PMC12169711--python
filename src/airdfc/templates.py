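"""Connectivity-state templates over ICA components grouped into networks.

A dynamic-connectivity "state" is summarized by a correlation matrix over
component time courses.  Templates come in five archetypes that mirror the
qualitative taxonomy of resting-state dynamic-connectivity studies:

* ``drowsy`` — subcortical and sensorimotor networks positively connected
  within themselves and negatively with everything else;
* ``modular_sm_dmn`` — sensorimotor and default-mode networks modularized;
* ``modular_dmn`` — default-mode network modularized;
* ``non_modular`` — no block organization at all;
* ``partial_modular`` — sub-modules within networks, with opposite-sign
  couplings between the halves of a network and another network.

Each template is a valid correlation matrix (symmetric, unit diagonal,
positive semi-definite); the block construction is projected to the nearest
correlation matrix when indefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

ARCHETYPES = (
    "drowsy",
    "modular_sm_dmn",
    "modular_dmn",
    "non_modular",
    "partial_modular",
)

#: networks an archetype modularizes, matched by name against the layout
_PREFERRED_NETWORKS = {
    "drowsy": ("subcortical", "sensorimotor"),
    "modular_sm_dmn": ("sensorimotor", "default-mode"),
    "modular_dmn": ("default-mode",),
    "partial_modular": ("subcortical", "visual"),
    "non_modular": (),
}

DEFAULT_ARCHETYPES = ARCHETYPES


@dataclass(frozen=True)
class NetworkLayout:
    """Assignment of ICA components to named networks.

    ``network_of[i]`` is the network label of component ``i``;
    ``network_labels`` fixes the network order.
    """

    network_of: tuple[str, ...]
    network_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.network_of:
            raise ValueError("layout needs at least one component")
        for lab in self.network_of:
            if lab not in self.network_labels:
                raise ValueError(f"component assigned to unknown network {lab!r}")
        for lab in self.network_labels:
            if lab not in self.network_of:
                raise ValueError(f"network {lab!r} has no components")

    @property
    def n_components(self) -> int:
        return len(self.network_of)

    def components_in(self, label: str) -> np.ndarray:
        if label not in self.network_labels:
            raise KeyError(label)
        return np.array([i for i, lab in enumerate(self.network_of) if lab == label])

    @classmethod
    def from_sizes(cls, sizes: dict[str, int]) -> "NetworkLayout":
        network_of: list[str] = []
        for lab, n in sizes.items():
            if n < 1:
                raise ValueError(f"network {lab!r} has no components")
            network_of.extend([lab] * n)
        return cls(tuple(network_of), tuple(sizes))

    @classmethod
    def default(cls) -> "NetworkLayout":
        """51 components in the seven canonical resting-state networks."""
        return cls.from_sizes(
            {
                "subcortical": 5,
                "auditory": 4,
                "sensorimotor": 8,
                "visual": 10,
                "default-mode": 9,
                "cognitive-control": 11,
                "cerebellar": 4,
            }
        )

    @classmethod
    def small(cls) -> "NetworkLayout":
        """12 components in 4 networks; desk-scale configuration."""
        return cls.from_sizes(
            {
                "subcortical": 3,
                "sensorimotor": 3,
                "default-mode": 3,
                "visual": 3,
            }
        )


@dataclass(frozen=True)
class StateTemplateSet:
    """One correlation-matrix template per archetype, over a shared layout."""

    templates: tuple[np.ndarray, ...]
    archetypes: tuple[str, ...]
    layout: NetworkLayout
    seed: int | None = field(default=None)

    @property
    def n_states(self) -> int:
        return len(self.templates)

    @property
    def n_edges(self) -> int:
        c = self.layout.n_components
        return c * (c - 1) // 2

    def zvectors(self) -> np.ndarray:
        """(n_states, n_edges) Fisher-z upper-triangle vectorization."""
        return np.stack([template_zvector(t) for t in self.templates])


def designated_networks(layout: NetworkLayout, archetype: str) -> tuple[str, ...]:
    """Networks an archetype modularizes, falling back positionally when the
    preferred network names are absent from the layout."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    preferred = _PREFERRED_NETWORKS[archetype]
    chosen = [lab for lab in preferred if lab in layout.network_labels]
    missing = len(preferred) - len(chosen)
    if missing:
        offset = ARCHETYPES.index(archetype)
        pool = [lab for lab in layout.network_labels if lab not in chosen]
        for j in range(missing):
            chosen.append(pool[(offset + j) % len(pool)])
    return tuple(chosen)


def template_vector(template: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (diagonal excluded) vectorization."""
    iu = np.triu_indices(template.shape[0], k=1)
    return template[iu]


def template_zvector(template: np.ndarray, clip: float = 1.0 - 1e-6) -> np.ndarray:
    r = np.clip(template_vector(template), -clip, clip)
    return np.arctanh(r)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration-limit noise; result is checked below
        out = corr_nearest(mat, threshold=1e-7, n_fact=200)
    out = np.asarray(out)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _base(layout: NetworkLayout, rng: np.random.Generator, bg_sd: float) -> np.ndarray:
    c = layout.n_components
    noise = rng.normal(0.0, bg_sd, size=(c, c))
    mat = (noise + noise.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return mat


def _set_block(mat: np.ndarray, rows: np.ndarray, cols: np.ndarray, value: float) -> None:
    mat[np.ix_(rows, cols)] += value
    mat[np.ix_(cols, rows)] += value


def _modular(
    layout: NetworkLayout,
    archetype: str,
    designated: tuple[str, ...],
    rng: np.random.Generator,
    within: float,
    between: float,
    bg_sd: float,
) -> np.ndarray:
    """Modular archetypes share the within+/between- motif but differ in
    their cross-network sign structure, which keeps the planted states
    mutually distinguishable (as the observed states are)."""
    mat = _base(layout, rng, bg_sd)
    desig_idx = np.concatenate([layout.components_in(n) for n in designated])
    outside_nets = [n for n in layout.network_labels if n not in designated]
    outside = np.setdiff1d(np.arange(layout.n_components), desig_idx)
    for j, net in enumerate(designated):
        idx = layout.components_in(net)
        # secondary designated network carries a weaker block, so archetypes
        # sharing a network remain distinguishable
        mat[np.ix_(idx, idx)] += within if j == 0 else 0.7 * within

    if archetype == "drowsy":
        # designated networks negative with everything else and each other
        if outside.size:
            _set_block(mat, desig_idx, outside, between)
        if len(designated) == 2:
            a = layout.components_in(designated[0])
            b = layout.components_in(designated[1])
            _set_block(mat, a, b, between)
    elif archetype == "modular_sm_dmn" and len(designated) == 2 and len(outside_nets) >= 2:
        # the two designated networks anticorrelate; remaining networks
        # split into a half coupled +B/-A and a half coupled -B/+A
        a = layout.components_in(designated[0])
        b = layout.components_in(designated[1])
        _set_block(mat, a, b, between * 1.5)
        cut = (len(outside_nets) + 1) // 2
        plus_b = np.concatenate([layout.components_in(n) for n in outside_nets[:cut]])
        minus_b = np.concatenate([layout.components_in(n) for n in outside_nets[cut:]])
        _set_block(mat, plus_b, b, 0.30)
        _set_block(mat, plus_b, a, -0.30)
        _set_block(mat, minus_b, b, -0.35)
        _set_block(mat, minus_b, a, 0.25)
    else:
        # single modularized network, negative with all others except a
        # weakly positive partner network (frontal-control-like)
        if outside.size:
            _set_block(mat, desig_idx, outside, between)
        if archetype == "modular_dmn" and outside_nets:
            partner = layout.components_in(outside_nets[min(1, len(outside_nets) - 1)])
            _set_block(mat, desig_idx, partner, 0.20 - between)
    np.fill_diagonal(mat, 1.0)
    return mat


def _partial_modular(
    layout: NetworkLayout,
    designated: tuple[str, ...],
    rng: np.random.Generator,
    within: float,
    bg_sd: float,
) -> np.ndarray:
    # sub-modules: split the first designated network into halves, each half
    # coupled with opposite sign to the second designated network
    mat = _base(layout, rng, bg_sd)
    net_a, net_b = designated[0], designated[-1]
    a = layout.components_in(net_a)
    b = layout.components_in(net_b)
    half = max(1, a.size // 2)
    a1, a2 = a[:half], a[half:]
    for sub in (a1, a2):
        if sub.size:
            mat[np.ix_(sub, sub)] += within
    mat[np.ix_(b, b)] += within
    if a1.size and a2.size:
        mat[np.ix_(a1, a2)] -= within / 2.0
        mat[np.ix_(a2, a1)] -= within / 2.0
    mat[np.ix_(a1, b)] += within * 0.7
    mat[np.ix_(b, a1)] += within * 0.7
    if a2.size:
        mat[np.ix_(a2, b)] -= within * 0.7
        mat[np.ix_(b, a2)] -= within * 0.7
    np.fill_diagonal(mat, 1.0)
    return mat


def build_state_templates(
    layout: NetworkLayout,
    archetypes: tuple[str, ...] | list[str] = DEFAULT_ARCHETYPES,
    seed: int = 0,
    within: float = 0.65,
    between: float = -0.28,
    bg_sd: float = 0.04,
) -> StateTemplateSet:
    """Build one planted correlation template per archetype.

    Deterministic given ``seed``.  Indefinite block constructions are
    projected to the nearest correlation matrix, so every template is a
    valid correlation matrix.
    """
    if not archetypes:
        raise ValueError("need at least one archetype")
    rng = np.random.default_rng(seed)
    templates = []
    for arch in archetypes:
        if arch not in ARCHETYPES:
            raise ValueError(f"unknown archetype {arch!r}")
        designated = designated_networks(layout, arch)
        if arch == "non_modular":
            mat = _base(layout, rng, bg_sd=0.05)
        elif arch == "partial_modular":
            mat = _partial_modular(layout, designated, rng, within, bg_sd)
        else:
            mat = _modular(layout, arch, designated, rng, within, between, bg_sd)
        mat = np.clip(mat, -0.97, 0.97)
        np.fill_diagonal(mat, 1.0)
        mat = _nearest_correlation(mat)
        mat = np.clip(mat, -0.97, 0.97)
        np.fill_diagonal(mat, 1.0)
        templates.append(mat)
    return StateTemplateSet(tuple(templates), tuple(archetypes), layout, seed)


def block_means(template: np.ndarray, layout: NetworkLayout, networks: tuple[str, ...]):
    """Mean within-network and between-network (designated vs. rest)
    off-diagonal entries for a set of designated networks."""
    within_vals = []
    for net in networks:
        idx = layout.components_in(net)
        block = template[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        if iu[0].size:
            within_vals.append(block[iu])
    desig = np.concatenate([layout.components_in(n) for n in networks]) if networks else np.array([], dtype=int)
    rest = np.setdiff1d(np.arange(layout.n_components), desig)
    between_vals = template[np.ix_(desig, rest)].ravel() if desig.size and rest.size else np.array([])
    within = float(np.mean(np.concatenate(within_vals))) if within_vals else float("nan")
    between = float(np.mean(between_vals)) if between_vals.size else float("nan")
    return within, between


def overall_block_contrast(template: np.ndarray, layout: NetworkLayout) -> float:
    """|mean within-network entry − mean between-network entry| over all networks."""
    c = layout.n_components
    same = np.array([[layout.network_of[i] == layout.network_of[j] for j in range(c)] for i in range(c)])
    iu = np.triu_indices(c, k=1)
    vals = template[iu]
    mask = same[iu]
    return abs(float(vals[mask].mean()) - float(vals[~mask].mean()))


def check_valid_correlation(mat: np.ndarray, tol: float = 1e-6) -> None:
    """Raise if *mat* is not symmetric / unit-diagonal / PSD within *tol*."""
    if not np.allclose(mat, mat.T, atol=tol):
        raise ValueError("matrix not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=tol):
        raise ValueError("diagonal not 1")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol:
        raise ValueError(f"matrix not PSD (min eigenvalue {w.min():.2e})")
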