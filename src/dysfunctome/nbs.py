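"""Network-based statistic (NBS) for severity-predictive components.

Mass-univariate simple linear regression of every edge weight on a
per-subject severity score yields a symmetric matrix of t-values. A primary
threshold tau keeps edges with ``t > tau`` (one-sided, positive direction by
default: components whose connectivity *increases* with the score); the
connected components of the suprathreshold graph are the candidate
networks. Family-wise inference compares each component's edge count with
the permutation null distribution of the *largest* component size obtained
by re-running the regression on score-shuffled data.

The sweep repeats this across a grid of primary thresholds; the component
retained per condition is the significant one at the highest threshold
whose size still meets a minimum fraction of all possible edges, and the
final "target dysfunctome" across conditions is the component whose mean
within-component connectivity correlates most strongly with the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _cc

from .connectivity import ConnectivityMatrix

__all__ = [
    "StatisticMatrix",
    "NetworkComponent",
    "NbsConfig",
    "SweepResult",
    "edge_regression",
    "threshold_matrix",
    "components",
    "permutation_null",
    "component_p",
    "threshold_sweep",
    "min_component_size",
    "select_component",
    "component_severity_correlation",
    "choose_dysfunctome",
]

T_CAP = 1e6  # finite stand-in for a perfect linear fit


class DegenerateDesignError(ValueError):
    """Raised when the regression design is degenerate (constant scores)."""


@dataclass
class StatisticMatrix:
    labels: tuple[str, ...]
    T: np.ndarray  # symmetric per-edge t-values, zero diagonal
    df: int
    capped_edges: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class NetworkComponent:
    """A connected set of suprathreshold edges."""

    edges: tuple[tuple[str, str], ...]
    tau: float | None = None
    p_value: float | None = None
    condition: str = ""
    r: float | None = None  # component-mean-connectivity vs score correlation

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class NbsConfig:
    tau_grid: tuple[float, ...] = tuple(np.round(np.arange(2.0, 4.01, 0.2), 10))
    n_perm: int = 10_000
    alpha: float = 0.05
    min_edge_frac: float = 0.03
    direction: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.tau_grid) != sorted(self.tau_grid):
            raise ValueError("tau_grid must be ascending")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _stack_edges(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, tuple, np.ndarray, np.ndarray]:
    """Per-subject upper-triangle edge weights as an (n_subjects, n_edges) array."""
    labels = matrices[0].labels
    for m in matrices:
        if m.labels != labels:
            raise ValueError("matrices do not share channel labels")
    n = len(labels)
    iu, ju = np.triu_indices(n, 1)
    X = np.stack([m.W[iu, ju] for m in matrices])
    return X, labels, iu, ju


def _edge_r(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of each edge (column of X) with the scores."""
    s = np.asarray(scores, dtype=float)
    if s.std() == 0:
        raise DegenerateDesignError("severity scores are constant")
    zs = (s - s.mean()) / s.std()
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = np.where(sd > 0, Xc / sd, 0.0)
    r = zs @ Xz / len(s)
    return np.clip(r, -1.0, 1.0)


def _r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    return np.where(np.isfinite(t), np.clip(t, -T_CAP, T_CAP), np.sign(r) * T_CAP)


def edge_regression(
    matrices: list[ConnectivityMatrix], scores: np.ndarray
) -> StatisticMatrix:
    """Per-edge t-value of the simple regression of edge weight on score.

    For simple linear regression, slope/SE equals ``r * sqrt(df / (1 - r^2))``
    with ``df = n - 2``; edges constant across subjects get t = 0; perfect
    fits are capped at a large finite value and flagged.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 subjects")
    X, labels, iu, ju = _stack_edges(matrices)
    df = len(matrices) - 2
    r = _edge_r(X, np.asarray(scores, dtype=float))
    t = _r_to_t(r, df)
    n = len(labels)
    T = np.zeros((n, n))
    T[iu, ju] = t
    T = T + T.T
    capped = [
        (labels[iu[e]], labels[ju[e]]) for e in np.flatnonzero(np.abs(t) >= T_CAP)
    ]
    return StatisticMatrix(labels=labels, T=T, df=df, capped_edges=capped)


def threshold_matrix(stat: StatisticMatrix, tau: float, direction: str = "positive") -> np.ndarray:
    """Binary adjacency of edges strictly exceeding the primary threshold."""
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    T = stat.T if direction == "positive" else -stat.T
    adj = T > tau
    np.fill_diagonal(adj, False)
    return adj


def components(adj: np.ndarray, labels: tuple[str, ...]) -> list[NetworkComponent]:
    """Connected components of a binary adjacency, largest (by edges) first."""
    G = nx.from_numpy_array(np.asarray(adj, dtype=bool))
    out = []
    for nodes in nx.connected_components(G):
        sub = G.subgraph(nodes)
        if sub.number_of_edges() == 0:
            continue  # isolated node
        edges = tuple(
            sorted(tuple(sorted((labels[a], labels[b]))) for a, b in sub.edges())
        )
        out.append(NetworkComponent(edges=edges))
    out.sort(key=lambda c: (-c.size, c.edges))
    return out


def _max_component_sizes_batched(
    mask: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Largest component size (in edges) per row of a (P, E) edge mask.

    All P suprathreshold graphs are stacked into one block-diagonal sparse
    graph so a single connected-components pass labels everything.
    """
    P = mask.shape[0]
    p_idx, e_idx = np.nonzero(mask)
    if len(p_idx) == 0:
        return np.zeros(P, dtype=int)
    rows = p_idx * n_nodes + iu[e_idx]
    cols = p_idx * n_nodes + ju[e_idx]
    g = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(P * n_nodes, P * n_nodes),
    )
    _, node_comp = _cc(g, directed=False)
    edge_comp = node_comp[rows]  # both endpoints share the component label
    edges_per_comp = np.bincount(edge_comp)
    comp_perm = node_comp[rows]  # component -> permutation via any member edge
    out = np.zeros(P, dtype=int)
    np.maximum.at(out, p_idx, edges_per_comp[comp_perm])
    return out


def _null_r(
    X: np.ndarray, scores: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """(n_perm, n_edges) per-edge correlations under score shuffling."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    zs = (s - s.mean()) / s.std()
    perms = np.stack([rng.permutation(zs) for _ in range(n_perm)])
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = np.where(sd > 0, Xc / sd, 0.0)
    return np.clip(perms @ Xz / len(s), -1.0, 1.0)


def _tau_to_r(tau: float, df: int) -> float:
    """Threshold on t translated to the equivalent threshold on r."""
    return tau / math.sqrt(df + tau**2)


def permutation_null(
    matrices: list[ConnectivityMatrix],
    scores: np.ndarray,
    tau: float,
    n_perm: int,
    seed: int,
    direction: str = "positive",
) -> np.ndarray:
    """Null distribution of the largest component size under label shuffling.

    Permutations are uniform random shuffles (duplicates across iterations
    allowed), seeded and reproducible.
    """
    X, labels, iu, ju = _stack_edges(matrices)
    df = len(matrices) - 2
    null_r = _null_r(X, np.asarray(scores, dtype=float), n_perm, seed)
    if direction == "negative":
        null_r = -null_r
    mask = null_r > _tau_to_r(tau, df)
    return _max_component_sizes_batched(mask, iu, ju, len(labels))


def component_p(observed_size: int, null: np.ndarray) -> float:
    """Permutation p-value with the (1 + count) / (1 + K) convention."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed_size)) / (1 + null.size))


@dataclass
class TauResult:
    tau: float
    components: list[NetworkComponent]
    null_max: np.ndarray

    @property
    def max_size(self) -> int:
        return self.components[0].size if self.components else 0


@dataclass
class SweepResult:
    stat: StatisticMatrix
    results: list[TauResult]
    config: NbsConfig
    condition: str = ""

    def significant_components(self) -> list[NetworkComponent]:
        return [
            c
            for res in self.results
            for c in res.components
            if c.p_value is not None and c.p_value < self.config.alpha
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            if not res.components:
                rows.append(
                    {"tau": res.tau, "component_rank": None, "size": 0, "p_value": None}
                )
            for k, c in enumerate(res.components):
                rows.append(
                    {"tau": res.tau, "component_rank": k, "size": c.size, "p_value": c.p_value}
                )
        return pd.DataFrame(rows)


def threshold_sweep(
    matrices: list[ConnectivityMatrix],
    scores: np.ndarray,
    config: NbsConfig | None = None,
    condition: str = "",
) -> SweepResult:
    """Run NBS over the primary-threshold grid.

    The statistic matrix is computed once; one shared set of seeded
    permutations provides the null maximal-component distribution at every
    threshold. Every component (not only the largest) is assigned a p-value
    against that threshold's null-max distribution.
    """
    config = config or NbsConfig()
    stat = edge_regression(matrices, scores)
    X, labels, iu, ju = _stack_edges(matrices)
    null_r = _null_r(X, np.asarray(scores, dtype=float), config.n_perm, config.seed)
    if config.direction == "negative":
        null_r = -null_r
    results = []
    for tau in config.tau_grid:
        mask = null_r > _tau_to_r(tau, stat.df)
        null_max = _max_component_sizes_batched(mask, iu, ju, len(labels))
        comps = components(threshold_matrix(stat, tau, config.direction), labels)
        for c in comps:
            c.tau = float(tau)
            c.p_value = component_p(c.size, null_max)
            c.condition = condition
        results.append(TauResult(tau=float(tau), components=comps, null_max=null_max))
    return SweepResult(stat=stat, results=results, config=config, condition=condition)


def min_component_size(n_channels: int, min_edge_frac: float = 0.03) -> int:
    """Smallest qualifying component size: ceil(frac * possible edges)."""
    total_edges = n_channels * (n_channels - 1) // 2
    return math.ceil(min_edge_frac * total_edges)


def select_component(
    sweep: SweepResult,
    n_channels: int | None = None,
    min_edge_frac: float | None = None,
    alpha: float | None = None,
) -> NetworkComponent | None:
    """Significant component at the highest threshold still meeting the size floor."""
    if n_channels is None:
        n_channels = len(sweep.stat.labels)
    if min_edge_frac is None:
        min_edge_frac = sweep.config.min_edge_frac
    if alpha is None:
        alpha = sweep.config.alpha
    floor = min_component_size(n_channels, min_edge_frac)
    best: NetworkComponent | None = None
    for res in sweep.results:  # ascending tau; later hits overwrite earlier
        qualifying = [
            c for c in res.components if c.p_value < alpha and c.size >= floor
        ]
        if qualifying:
            best = max(qualifying, key=lambda c: c.size)
    return best


def component_severity_correlation(
    matrices: list[ConnectivityMatrix],
    component: NetworkComponent,
    scores: np.ndarray,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of mean within-component connectivity vs score."""
    if component.size == 0:
        raise ValueError("empty component")
    labels = matrices[0].labels
    idx = {l: i for i, l in enumerate(labels)}
    pairs = [(idx[a], idx[b]) for a, b in component.edges]
    means = np.array([np.mean([m.W[i, j] for i, j in pairs]) for m in matrices])
    if means.std() == 0:
        raise DegenerateDesignError("component means are constant across subjects")
    r, p = stats.pearsonr(means, np.asarray(scores, dtype=float))
    return float(r), float(p)


def choose_dysfunctome(candidates: list[NetworkComponent]) -> NetworkComponent:
    """Component with the highest severity correlation (ties: higher tau, then condition)."""
    if not candidates:
        raise ValueError("no candidate components")
    for c in candidates:
        if c.r is None:
            raise ValueError(f"candidate {c.condition} has no correlation recorded")
    ranked = sorted(
        candidates,
        key=lambda c: (-c.r, -(c.tau if c.tau is not None else -np.inf), c.condition),
    )
    return ranked[0]
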