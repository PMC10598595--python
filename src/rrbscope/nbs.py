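"""Network-based statistic (NBS): edge-level t tests, suprathreshold
connected components, and permutation FWER control.

Component extent is measured in edges.  Directional contrasts are handled by
keeping only suprathreshold edges whose t sign matches the requested
direction; the permutation null applies the same one-sided rule.  Group
labels are permuted for two-sample designs; per-subject condition differences
are sign-flipped for paired designs (the exchangeability-correct null).
When the permutation space is smaller than ``n_perm`` it is enumerated
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np
from scipy import stats as sps

from .spectral import ConnectivityMatrix

__all__ = [
    "EdgeStats",
    "NBSResult",
    "edge_vector",
    "stack_matrices",
    "edge_ttests",
    "threshold_and_components",
    "nbs_test",
    "node_degrees",
]

logger = logging.getLogger(__name__)

T_CAP = 1e6  # zero-variance paired contrasts are capped here, not at infinity


@dataclass
class EdgeStats:
    """Per-edge t statistic and two-tailed p over the upper-triangle edge set."""

    channels: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # upper-triangle channel pairs, in order
    t: np.ndarray
    p: np.ndarray
    design: str  # "two_sample" | "paired"
    direction: int = 0  # +1: first group/condition larger; -1: smaller; 0: two-sided
    df: float = np.nan
    flagged: np.ndarray = field(default=None)  # zero-variance edges

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.edges), dtype=bool)


@dataclass
class NBSResult:
    components: list[list[tuple[str, str]]]  # edge lists, largest first
    component_p: np.ndarray  # FWER-corrected p per component
    observed_max_size: int
    null_max_sizes: np.ndarray
    stats: EdgeStats
    edge_alpha: float
    comp_alpha: float
    n_perm: int
    seed: int | None
    exact: bool = False

    @property
    def significant(self) -> list[list[tuple[str, str]]]:
        return [c for c, p in zip(self.components, self.component_p) if p <= self.comp_alpha]


# ---------------------------------------------------------------------------
# matrix stacking
# ---------------------------------------------------------------------------

def edge_vector(matrix: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle entries in row-major order."""
    n = len(matrix.channels)
    iu = np.triu_indices(n, k=1)
    return matrix.values[iu]


def stack_matrices(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, tuple, tuple]:
    """Stack a collection into (n_subjects, n_edges); returns (X, channels, edges)."""
    channels = matrices[0].channels
    for m in matrices:
        if m.channels != channels:
            raise ValueError("all connectivity matrices must share one channel set")
    X = np.stack([edge_vector(m) for m in matrices])
    edges = tuple(
        (channels[i], channels[j]) for i, j in zip(*np.triu_indices(len(channels), k=1))
    )
    return X, channels, edges


# ---------------------------------------------------------------------------
# edge-level t statistics (vectorized over edges)
# ---------------------------------------------------------------------------

def _two_sample_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Pooled-variance two-sample t per column; returns (t, df, flat_flag).

    Zero pooled variance with equal means (identical data) gives t = 0 and is
    flagged; zero variance with *different* means is perfect separation and
    is capped at +/-T_CAP rather than zeroed.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss = ((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    sp2 = ss / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    t = np.zeros_like(m1)
    np.divide(m1 - m2, denom, out=t, where=~zero)
    separated = zero & (m1 != m2)
    t[separated] = np.sign((m1 - m2)[separated]) * T_CAP
    return t, float(df), zero & (m1 == m2)

def _welch_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1) / n1
    v2 = x2.var(axis=0, ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    zero = denom == 0
    t = np.zeros_like(m1)
    np.divide(m1 - m2, denom, out=t, where=~zero)
    df = np.where(zero, 1.0, (v1 + v2) ** 2 /
                  np.where(zero, 1.0, v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1)))
    return t, df, zero


def _paired_t(d: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """One-sample t on per-subject differences; constant nonzero d is capped."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    df = n - 1
    zero = sd == 0
    t = np.zeros_like(m)
    np.divide(m, sd / np.sqrt(n), out=t, where=~zero)
    degenerate = zero & (m != 0)
    t[degenerate] = np.sign(m[degenerate]) * T_CAP
    return t, float(df), zero & (m == 0)


def edge_ttests(
    matrices: list[ConnectivityMatrix],
    design: str,
    groups: list[str] | None = None,
    direction: int = 0,
    welch: bool = False,
) -> EdgeStats:
    """Per-edge t statistics.

    two_sample: ``groups`` gives one label per matrix; the contrast is
    (first-named group) - (second).  paired: matrices must come in
    per-subject (condition A, condition B) order and the contrast is A - B;
    use :func:`paired_differences` to build that ordering from a collection.
    """
    X, channels, edges = stack_matrices(matrices)
    if design == "two_sample":
        if groups is None:
            raise ValueError("two_sample design requires group labels")
        labels = np.asarray(groups)
        names = list(dict.fromkeys(labels))
        if len(names) != 2:
            raise ValueError(f"expected exactly 2 groups, got {names}")
        x1, x2 = X[labels == names[0]], X[labels == names[1]]
        if min(x1.shape[0], x2.shape[0]) < 2:
            raise ValueError("need >= 2 subjects per group")
        if welch:
            t, df, flagged = _welch_t(x1, x2)
            p = 2.0 * sps.t.sf(np.abs(t), df)
        else:
            t, df, flagged = _two_sample_t(x1, x2)
            p = 2.0 * sps.t.sf(np.abs(t), df)
    elif design == "paired":
        if X.shape[0] % 2:
            raise ValueError("paired design expects (A, B) matrix pairs per subject")
        d = X[0::2] - X[1::2]
        t, df, flagged = _paired_t(d)
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown design {design!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[flagged] = 1.0
    return EdgeStats(channels=channels, edges=edges, t=t, p=p,
                     design=design, direction=direction,
                     df=float(np.mean(df)), flagged=flagged)


def paired_differences(
    matrices: list[ConnectivityMatrix], cond_a: str = "HRIS", cond_b: str = "LRIS"
) -> list[ConnectivityMatrix]:
    """Order a mixed collection as (cond_a, cond_b) pairs per subject."""
    by_subject: dict[str, dict[str, ConnectivityMatrix]] = {}
    for m in matrices:
        by_subject.setdefault(m.subject_id, {})[m.condition] = m
    ordered = []
    for sid, conds in by_subject.items():
        if cond_a not in conds or cond_b not in conds:
            raise ValueError(f"subject {sid} is missing a condition for the paired design")
        ordered += [conds[cond_a], conds[cond_b]]
    return ordered


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def _suprathreshold_mask(t: np.ndarray, p: np.ndarray, edge_alpha: float, direction: int) -> np.ndarray:
    mask = p < edge_alpha
    if direction > 0:
        mask &= t > 0
    elif direction < 0:
        mask &= t < 0
    return mask


def threshold_and_components(stats: EdgeStats, edge_alpha: float = 0.005) -> list[list[tuple[str, str]]]:
    """Connected components (edge lists) of the suprathreshold graph, largest first."""
    mask = _suprathreshold_mask(stats.t, stats.p, edge_alpha, stats.direction)
    g = nx.Graph()
    for (a, b), keep in zip(stats.edges, mask):
        if keep:
            g.add_edge(a, b)
    comps = []
    for nodes in nx.connected_components(g):
        comps.append(sorted(g.subgraph(nodes).edges()))
    comps.sort(key=len, reverse=True)
    return comps


def _max_component_size(edge_idx: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray) -> int:
    """Largest component extent (edges) via union-find on an edge-index list."""
    k = edge_idx.size
    if k <= 1:
        return int(k)
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in edge_idx:
        i, j = int(pair_i[e]), int(pair_j[e])
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    counts: dict[int, int] = {}
    for e in edge_idx:
        r = find(int(pair_i[e]))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def node_degrees(component: list[tuple[str, str]]) -> dict[str, int]:
    """Edge-incidence degree per channel; degrees sum to 2 x edge count."""
    deg: dict[str, int] = {}
    for a, b in component:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _null_max_sizes_two_sample(
    X: np.ndarray, labels: np.ndarray, name1, t_crit: float, direction: int,
    pair_i: np.ndarray, pair_j: np.ndarray, n_perm: int, rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    n = X.shape[0]
    n1 = int((labels == name1).sum())
    exact = False
    from math import comb
    if comb(n, n1) <= n_perm:
        exact = True
        assignments = list(combinations(range(n), n1))
    else:
        assignments = None
    sizes = []
    iterator = assignments if exact else range(n_perm)
    for item in iterator:
        if exact:
            idx1 = np.fromiter(item, int)
            mask = np.zeros(n, dtype=bool)
            mask[idx1] = True
        else:
            mask = np.zeros(n, dtype=bool)
            mask[rng.permutation(n)[:n1]] = True
        t, _, _ = _two_sample_t(X[mask], X[~mask])
        supra = np.abs(t) > t_crit
        if direction > 0:
            supra &= t > 0
        elif direction < 0:
            supra &= t < 0
        sizes.append(_max_component_size(np.flatnonzero(supra), pair_i, pair_j))
    return np.asarray(sizes), exact


def _null_max_sizes_paired(
    D: np.ndarray, t_crit: float, direction: int,
    pair_i: np.ndarray, pair_j: np.ndarray, n_perm: int, rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    n = D.shape[0]
    exact = 2 ** n <= n_perm
    sizes = []
    flips_iter = product([1.0, -1.0], repeat=n) if exact else range(n_perm)
    for item in flips_iter:
        signs = np.asarray(item) if exact else rng.choice([1.0, -1.0], size=n)
        t, _, _ = _paired_t(D * signs[:, None])
        supra = np.abs(t) > t_crit
        if direction > 0:
            supra &= t > 0
        elif direction < 0:
            supra &= t < 0
        sizes.append(_max_component_size(np.flatnonzero(supra), pair_i, pair_j))
    return np.asarray(sizes), exact


def nbs_test(
    matrices: list[ConnectivityMatrix],
    design: str,
    groups: list[str] | None = None,
    direction: int = 0,
    edge_alpha: float = 0.005,
    comp_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> NBSResult:
    """NBS permutation test with FWER control over components.

    Per-component p = (1 + #{null max extent >= component extent}) /
    (n_perm + 1) for the sampled null (plain proportion under exact
    enumeration).  Suprathreshold edges are those with two-tailed p below
    ``edge_alpha`` and, for directional contrasts, a matching t sign.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    stats = edge_ttests(matrices, design, groups=groups, direction=direction)
    components = threshold_and_components(stats, edge_alpha)
    observed_max = len(components[0]) if components else 0
    X, channels, edges = stack_matrices(matrices)
    n_ch = len(channels)
    pair_i, pair_j = np.triu_indices(n_ch, k=1)
    t_crit = sps.t.ppf(1.0 - edge_alpha / 2.0, stats.df)
    rng = np.random.default_rng(seed)
    if design == "two_sample":
        labels = np.asarray(groups)
        name1 = list(dict.fromkeys(labels))[0]
        null_sizes, exact = _null_max_sizes_two_sample(
            X, labels, name1, t_crit, direction, pair_i, pair_j, n_perm, rng)
    else:
        D = X[0::2] - X[1::2]
        null_sizes, exact = _null_max_sizes_paired(
            D, t_crit, direction, pair_i, pair_j, n_perm, rng)
    comp_sizes = np.array([len(c) for c in components], dtype=int)
    if exact:
        comp_p = np.array([
            (null_sizes >= s).sum() / null_sizes.size for s in comp_sizes])
    else:
        comp_p = np.array([
            (1.0 + (null_sizes >= s).sum()) / (null_sizes.size + 1.0) for s in comp_sizes])
    return NBSResult(
        components=components,
        component_p=comp_p,
        observed_max_size=int(observed_max),
        null_max_sizes=null_sizes,
        stats=stats,
        edge_alpha=edge_alpha,
        comp_alpha=comp_alpha,
        n_perm=int(null_sizes.size),
        seed=seed,
        exact=exact,
    )
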