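import networkx as nx
import numpy as np
import pytest

from dysfunctome.montage import Montage, standard_61_montage


@pytest.fixture(scope="session")
def std61() -> Montage:
    return standard_61_montage()


@pytest.fixture(scope="session")
def grid_montage() -> Montage:
    """6x6 unit grid in the z=0 plane; labels g00..g35 row-major."""
    labels = []
    coords = []
    for i in range(6):
        for j in range(6):
            labels.append(f"g{i}{j}")
            coords.append((float(i), float(j), 0.0))
    return Montage(labels=tuple(labels), coords=np.array(coords), ring_size=3)


def brute_force_ring(montage: Montage, center: str, k: int) -> tuple[str, ...]:
    """Independent nearest-neighbour oracle: full sort of labelled distances."""
    ci = montage.index(center)
    pairs = [
        (float(np.linalg.norm(montage.coords[i] - montage.coords[ci])), montage.labels[i])
        for i in range(len(montage))
        if i != ci
    ]
    pairs.sort()
    return tuple(label for _, label in pairs[:k])


def brute_force_ebc(G: nx.Graph) -> dict[tuple[str, str], float]:
    """Edge betweenness by exhaustive shortest-path enumeration."""
    vals = {tuple(sorted(e)): 0.0 for e in G.edges}
    nodes = sorted(G.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if not nx.has_path(G, s, t):
                continue
            paths = list(nx.all_shortest_paths(G, s, t))
            w = 1.0 / len(paths)
            for p in paths:
                for a, b in zip(p[:-1], p[1:]):
                    vals[tuple(sorted((a, b)))] += w
    return vals


def naive_pli(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Sign-mean PLI as an explicit per-sample loop."""
    total = 0.0
    for a, b in zip(phase_i, phase_j):
        total += np.sign(np.sin(a - b))
    return abs(total / len(phase_i))
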