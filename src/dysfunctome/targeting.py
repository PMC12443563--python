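"""Individualized dual-site stimulation targets from a dysfunctome profile.

Given the group-level target dysfunctome (a connected edge set) and one
subject's weighted profile over those edges, every edge receives:

* a *centrality ranking* — normalized rank of its unweighted shortest-path
  edge betweenness centrality within the dysfunctome (higher is better);
* a *connectivity ranking* — normalized rank of the subject's PLI on that
  edge; *restoration* targeting prefers weakly connected edges (lower is
  better), *enhancement* targeting prefers strongly connected ones;
* a *priority index* — the plain average of the two rankings.

The stimulation target is the highest-priority edge whose endpoints are far
enough apart on the cap to host two independent 3x1 HD units; inadmissible
edges are skipped in priority order (the fallback depth is recorded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .connectivity import ConnectivityMatrix
from .montage import Montage, edge_admissible
from .nbs import NetworkComponent

__all__ = [
    "DysfunctomeProfile",
    "TargetSelection",
    "NoAdmissibleEdgeError",
    "edge_betweenness",
    "normalized_ranking",
    "priority_table",
    "select_target",
    "select_both_targets",
]

Edge = tuple[str, str]


class NoAdmissibleEdgeError(RuntimeError):
    """Every candidate edge violated the admissibility rule."""


def _canon(edge) -> Edge:
    a, b = edge
    return (a, b) if a <= b else (b, a)


@dataclass
class DysfunctomeProfile:
    """One subject's weighted view of the group dysfunctome."""

    subject_id: str
    component: NetworkComponent
    weights: dict[Edge, float]

    def __post_init__(self) -> None:
        self.weights = {_canon(e): float(w) for e, w in self.weights.items()}
        missing = [e for e in self.component.edges if _canon(e) not in self.weights]
        if missing:
            raise ValueError(f"profile missing weights for edges: {missing[:5]}")

    @classmethod
    def from_matrix(
        cls, component: NetworkComponent, matrix: ConnectivityMatrix, subject_id: str = ""
    ) -> "DysfunctomeProfile":
        weights = {_canon(e): matrix[e] for e in component.edges}
        return cls(
            subject_id=subject_id or str(matrix.meta.get("subject_id", "")),
            component=component,
            weights=weights,
        )


@dataclass
class TargetSelection:
    subject_id: str
    principle: str
    target_edge: Edge
    table: pd.DataFrame  # per-edge ebc, rankings, priority, admissibility
    fallback_depth: int


def edge_betweenness(component: NetworkComponent) -> dict[Edge, float]:
    """Unweighted shortest-path edge betweenness on the component subgraph.

    Raw pair counts (not normalized); equally short paths split fractionally.
    """
    if component.size == 0:
        raise ValueError("empty component")
    G = nx.Graph()
    G.add_edges_from(component.edges)
    ebc = nx.edge_betweenness_centrality(G, normalized=False)
    return {_canon(e): float(v) for e, v in ebc.items()}


def normalized_ranking(
    values: dict[Edge, float], direction: str = "higher_is_better"
) -> dict[Edge, float]:
    """Average-rank normalization to [0, 1]; the best edge scores 1.

    With m edges the ranking is ``(rank - 1) / (m - 1)``; a single edge maps
    to 1.0; ties receive the average rank.
    """
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    edges = list(values)
    vals = np.array([values[e] for e in edges], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN in ranking values")
    m = len(vals)
    if m == 1:
        return {edges[0]: 1.0}
    ranks = rankdata(vals if direction == "higher_is_better" else -vals)
    return {e: float((rk - 1.0) / (m - 1.0)) for e, rk in zip(edges, ranks)}


def priority_table(
    profile: DysfunctomeProfile,
    principle: str,
    ebc: dict[Edge, float] | None = None,
) -> pd.DataFrame:
    """Per-edge priority indices for one subject under one principle."""
    if principle not in ("restoration", "enhancement"):
        raise ValueError(f"principle must be restoration or enhancement, got {principle!r}")
    if ebc is None:
        ebc = edge_betweenness(profile.component)
    edges = [_canon(e) for e in profile.component.edges]
    cent = normalized_ranking({e: ebc[e] for e in edges}, "higher_is_better")
    conn_dir = "lower_is_better" if principle == "restoration" else "higher_is_better"
    conn = normalized_ranking({e: profile.weights[e] for e in edges}, conn_dir)
    df = pd.DataFrame(
        {
            "edge": edges,
            "ebc": [ebc[e] for e in edges],
            "weight": [profile.weights[e] for e in edges],
            "centrality_ranking": [cent[e] for e in edges],
            "connectivity_ranking": [conn[e] for e in edges],
        }
    )
    df["priority_index"] = (df["centrality_ranking"] + df["connectivity_ranking"]) / 2.0
    return df.sort_values(
        ["priority_index", "ebc", "edge"], ascending=[False, False, True]
    ).reset_index(drop=True)


def select_target(
    profile: DysfunctomeProfile,
    principle: str,
    montage: Montage,
    ring_size: int | None = None,
    ebc: dict[Edge, float] | None = None,
    admissibility_rule: str = "ring_overlap",
    min_distance: float | None = None,
) -> TargetSelection:
    """Highest-priority admissible edge; skips inadmissible ones in order.

    Ties are broken by higher edge betweenness, then lexicographic edge
    label, so the selection is deterministic and input-order invariant.
    """
    table = priority_table(profile, principle, ebc=ebc)
    admissible_flags = []
    reasons = []
    for e in table["edge"]:
        ok, reason = edge_admissible(
            montage, e, ring_size=ring_size, rule=admissibility_rule, min_distance=min_distance
        )
        admissible_flags.append(ok)
        reasons.append(reason)
    table = table.assign(admissible=admissible_flags, inadmissible_reason=reasons)
    for depth, row in table.iterrows():
        if row["admissible"]:
            return TargetSelection(
                subject_id=profile.subject_id,
                principle=principle,
                target_edge=_canon(row["edge"]),
                table=table,
                fallback_depth=int(depth),
            )
    violations = {tuple(e): r for e, r in zip(table["edge"], table["inadmissible_reason"])}
    raise NoAdmissibleEdgeError(
        f"no admissible edge for {profile.subject_id} ({principle}): {violations}"
    )


def select_both_targets(
    profile: DysfunctomeProfile,
    montage: Montage,
    ring_size: int | None = None,
    admissibility_rule: str = "ring_overlap",
    min_distance: float | None = None,
) -> tuple[TargetSelection, TargetSelection]:
    """Restoration and enhancement selections sharing one centrality computation.

    The two principles usually pick different edges, but an edge that
    dominates the centrality ranking while sitting at the subject's median
    connectivity can win under both; that case is allowed with a warning.
    """
    ebc = edge_betweenness(profile.component)
    restoration = select_target(
        profile, "restoration", montage, ring_size=ring_size, ebc=ebc,
        admissibility_rule=admissibility_rule, min_distance=min_distance,
    )
    enhancement = select_target(
        profile, "enhancement", montage, ring_size=ring_size, ebc=ebc,
        admissibility_rule=admissibility_rule, min_distance=min_distance,
    )
    if restoration.target_edge == enhancement.target_edge:
        warnings.warn(
            f"restoration and enhancement selected the same edge "
            f"{restoration.target_edge} for {profile.subject_id}",
            stacklevel=2,
        )
    return restoration, enhancement
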