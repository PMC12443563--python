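"""Pre/post outcome measures on connectivity matrices.

Weighted outcomes (target edge weight, node strength, mean dysfunctome
connectivity) are read from the raw PLI matrix, each with a within-subject
z-normalized variant. Global topology metrics (mean clustering coefficient,
global efficiency, small-worldness, modularity) are computed on an
unweighted graph obtained by keeping the strongest edges up to a proportional
density threshold (default 35% of all possible edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .nbs import NetworkComponent

__all__ = [
    "MetricReport",
    "binarize_density",
    "clustering_coefficient",
    "global_efficiency",
    "small_worldness",
    "modularity",
    "node_strength",
    "target_node_strength",
    "within_subject_z",
    "metric_report",
    "density_sweep",
]


def binarize_density(cm: ConnectivityMatrix, density: float) -> np.ndarray:
    """Keep the ``floor(density * M)`` strongest edges (M = possible edges).

    Ties at the cutoff weight are resolved by lexicographic edge label so
    the result is deterministic even on weight-tied synthetic matrices.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = len(cm.labels)
    iu, ju = np.triu_indices(n, 1)
    m_total = len(iu)
    k = int(np.floor(density * m_total))
    order = sorted(
        range(m_total),
        key=lambda e: (-cm.W[iu[e], ju[e]], (cm.labels[iu[e]], cm.labels[ju[e]])),
    )
    adj = np.zeros((n, n), dtype=bool)
    keep = order[:k]
    adj[iu[keep], ju[keep]] = True
    return adj | adj.T


def _graph(adj: np.ndarray) -> nx.Graph:
    G = nx.from_numpy_array(np.asarray(adj, dtype=bool))
    return G


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean per-node triangle ratio; degree < 2 nodes contribute 0."""
    return float(nx.average_clustering(_graph(adj)))


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest path length; disconnected pairs contribute 0."""
    return float(nx.global_efficiency(_graph(adj)))


def _char_path_length(G: nx.Graph) -> float:
    """Average shortest path length on the largest connected component."""
    giant = G.subgraph(max(nx.connected_components(G), key=len))
    return nx.average_shortest_path_length(giant)


def small_worldness(
    adj: np.ndarray,
    n_null: int = 100,
    seed: int | None = None,
    n_swap_per_edge: int = 10,
) -> float:
    """Small-world index sigma = (C / C_null) / (L / L_null).

    Null graphs are degree-preserving rewirings (``n_swap_per_edge`` swap
    attempts per edge); C is the mean clustering coefficient and L the
    characteristic path length on the largest connected component. A
    warning is emitted if the giant component covers < 90% of nodes.
    """
    G = _graph(adj)
    m = G.number_of_edges()
    if m < 2:
        raise ValueError("graph too sparse to rewire")
    giant = max(nx.connected_components(G), key=len)
    if len(giant) < 0.9 * G.number_of_nodes():
        warnings.warn(
            f"giant component covers only {len(giant)}/{G.number_of_nodes()} nodes",
            stacklevel=2,
        )
    C = nx.average_clustering(G)
    L = _char_path_length(G)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        H = G.copy()
        nx.double_edge_swap(
            H, nswap=n_swap_per_edge * m, max_tries=100 * n_swap_per_edge * m,
            seed=int(rng.integers(2**31 - 1)),
        )
        c_null.append(nx.average_clustering(H))
        l_null.append(_char_path_length(H))
    c_bar, l_bar = float(np.mean(c_null)), float(np.mean(l_null))
    if c_bar == 0:
        raise ValueError("null clustering is zero; sigma undefined")
    return float((C / c_bar) / (L / l_bar))


def modularity(
    adj: np.ndarray, seed: int | None = None, n_restarts: int = 100
) -> float:
    """Newman modularity Q of the best seeded Louvain partition.

    Best-of ``n_restarts`` runs, so Q never decreases with more restarts.
    """
    G = _graph(adj)
    if G.number_of_edges() == 0:
        raise ValueError("empty graph has no modularity")
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, seed=int(rng.integers(2**31 - 1))
        )
        q = nx.community.modularity(G, comms)
        best = max(best, q)
    return float(best)


def node_strength(cm: ConnectivityMatrix) -> pd.Series:
    """Row sums of the weighted matrix, indexed by channel label."""
    return pd.Series(cm.W.sum(axis=1), index=list(cm.labels))


def target_node_strength(cm: ConnectivityMatrix, edge: tuple[str, str]) -> float:
    """Mean strength of the two nodes joined by the target edge."""
    s = node_strength(cm)
    for node in edge:
        if node not in s.index:
            raise KeyError(f"unknown endpoint label: {node!r}")
    return float((s[edge[0]] + s[edge[1]]) / 2.0)


def within_subject_z(
    values: np.ndarray, query: float | np.ndarray | None = None, ddof: int = 1
) -> float | np.ndarray:
    """z-score of ``query`` against the subject's own distribution.

    Sample standard deviation (``ddof=1``) by default. With ``query=None``
    the whole array is z-scored.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mu, sd = values.mean(), values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero spread; z-score undefined")
    if query is None:
        return (values - mu) / sd
    return (np.asarray(query, dtype=float) - mu) / sd


def _edge_weights(cm: ConnectivityMatrix) -> np.ndarray:
    iu, ju = np.triu_indices(len(cm.labels), 1)
    return cm.W[iu, ju]


def _dysfunctome_values(cm: ConnectivityMatrix, component: NetworkComponent) -> np.ndarray:
    return np.array([cm[e] for e in component.edges])


@dataclass
class MetricReport:
    """Table-row-style outcome set for one subject x session."""

    subject_id: str
    session: str
    target_edge_weight: float
    normalized_target_edge: float
    target_node_strength: float
    normalized_target_node_strength: float
    dysfunctome_mean: float
    normalized_dysfunctome_mean: float
    clustering: float
    global_efficiency: float
    small_worldness: float
    modularity: float
    density: float
    divergent_naming_rate: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _single_report(
    cm: ConnectivityMatrix,
    component: NetworkComponent,
    target_edge: tuple[str, str],
    density: float,
    n_null: int,
    n_restarts: int,
    seed: int | None,
    session: str,
    behavioral: float | None,
) -> MetricReport:
    adj = binarize_density(cm, density)
    all_weights = _edge_weights(cm)
    strengths = node_strength(cm).to_numpy()
    tns = target_node_strength(cm, target_edge)
    dys = _dysfunctome_values(cm, component)
    return MetricReport(
        subject_id=str(cm.meta.get("subject_id", "")),
        session=session,
        target_edge_weight=cm[target_edge],
        normalized_target_edge=float(within_subject_z(all_weights, cm[target_edge])),
        target_node_strength=tns,
        normalized_target_node_strength=float(within_subject_z(strengths, tns)),
        dysfunctome_mean=float(dys.mean()),
        normalized_dysfunctome_mean=float(
            np.mean(within_subject_z(all_weights, dys))
        ),
        clustering=clustering_coefficient(adj),
        global_efficiency=global_efficiency(adj),
        small_worldness=small_worldness(adj, n_null=n_null, seed=seed),
        modularity=modularity(adj, seed=seed, n_restarts=n_restarts),
        density=density,
        divergent_naming_rate=behavioral,
    )


def metric_report(
    pre: ConnectivityMatrix,
    post: ConnectivityMatrix,
    component: NetworkComponent,
    target_edge: tuple[str, str],
    density: float = 0.35,
    n_null: int = 100,
    n_restarts: int = 100,
    seed: int | None = None,
    behavioral_pre: float | None = None,
    behavioral_post: float | None = None,
) -> tuple[MetricReport, MetricReport]:
    """Full outcome set for a pre/post matrix pair."""
    if pre.labels != post.labels:
        raise ValueError("pre and post matrices do not share labels")
    if tuple(sorted(target_edge)) not in {tuple(sorted(e)) for e in component.edges}:
        raise ValueError(f"target edge {target_edge} not in component")
    rep_pre = _single_report(
        pre, component, target_edge, density, n_null, n_restarts, seed, "pre", behavioral_pre
    )
    rep_post = _single_report(
        post, component, target_edge, density, n_null, n_restarts, seed, "post", behavioral_post
    )
    return rep_pre, rep_post


def density_sweep(
    cm: ConnectivityMatrix,
    densities: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 10)),
    n_null: int = 100,
    n_restarts: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Global metrics across proportional density thresholds (default 5-50%).

    Densities at which the graph is too sparse or fragmented for a defined
    small-world index (or modularity) are reported as NaN rather than
    aborting the sweep.
    """
    rows = []
    for d in densities:
        adj = binarize_density(cm, d)
        try:
            sigma = small_worldness(adj, n_null=n_null, seed=seed)
        except ValueError:
            sigma = float("nan")
        try:
            q = modularity(adj, seed=seed, n_restarts=n_restarts)
        except ValueError:
            q = float("nan")
        rows.append(
            {
                "density": d,
                "clustering": clustering_coefficient(adj),
                "global_efficiency": global_efficiency(adj),
                "small_worldness": sigma,
                "modularity": q,
            }
        )
    return pd.DataFrame(rows)
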