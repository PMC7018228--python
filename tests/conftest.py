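"""Shared fixtures and the independent brute-force routing oracle.

The oracle deliberately shares no code with the package: plain dicts and
``math`` only, so it can certify the vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from navmaps import Connectome, EuclideanMetric


# ---------------------------------------------------------------------------
# brute-force greedy-routing simulator (independent oracle)
# ---------------------------------------------------------------------------

def brute_force_greedy(
    nodes: dict[str, tuple[float, ...]],
    edges: set[tuple[str, str]],
    source: str,
    target: str,
) -> tuple[bool, list[str]]:
    """Simulate the greedy protocol literally: forward to the neighbor
    closest to the target (smallest id on ties); fail on the first revisit
    or when out of moves."""

    def dist(a: str, b: str) -> float:
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(nodes[a], nodes[b])))

    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    if source == target:
        return True, [source]
    path = [source]
    seen = {source}
    here = source
    for _ in range(len(nodes)):
        options = sorted(adjacency[here])
        if not options:
            return False, path
        best, best_d = None, math.inf
        for cand in options:
            d = dist(cand, target)
            if d < best_d:
                best, best_d = cand, d
        path.append(best)
        if best == target:
            return True, path
        if best in seen:
            return False, path
        seen.add(best)
        here = best
    return False, path


def random_instance(seed: int, n_max: int = 10, p_edge: float = 0.4):
    """A random spatial graph: N <= n_max nodes, uniform 3D positions."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    names = [f"v{i}" for i in range(n)]
    coords = {name: tuple(rng.uniform(0, 1, 3)) for name in names}
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.add((names[i], names[j]))
    return names, coords, edges


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def instance_w():
    """The hand-enumerated 4-node instance: a chain s-m-f-t with a detour.

    Exhaustive enumeration over its 12 ordered pairs gives SR = 10/12,
    incoming rate 1/3 at t and outgoing rate 2/3 at s.
    """
    positions = {
        "t": np.array([0.0, 0.0, 0.0]),
        "m": np.array([1.0, 0.0, 0.0]),
        "s": np.array([2.0, 0.0, 0.0]),
        "f": np.array([1.0, 5.0, 0.0]),
    }
    connectome = Connectome(
        node_ids=["t", "m", "s", "f"],
        edges={("m", "s"), ("f", "m"), ("f", "t")},
        positions=positions,
    )
    return connectome, EuclideanMetric(positions)
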