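"""Greedy routing and its navigability statistics.

In greedy routing a source node forwards a signal to its neighbor closest
to the target in the underlying geometry; each node repeats the rule until
the signal reaches the target (success) or revisits a node (failure — with
a deterministic next-hop rule a revisit guarantees an infinite loop).

Navigability of a (graph, metric) pair is summarized by

* the success rate — fraction of successful ordered source/target pairs
  within connected components;
* the topological stretch — greedy hops divided by shortest-path hops
  (>= 1 by construction);
* the geometric stretch — greedy metric length divided by the metric length
  of the hop-minimal path (the hop-minimal path of minimal metric length is
  used when several exist); it can fall below 1;
* locally outgoing/incoming success rates per node.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .io import Connectome, connected_components

__all__ = [
    "RoutingOutcome",
    "NavigabilityReport",
    "greedy_route",
    "navigability",
]


@dataclasses.dataclass
class RoutingOutcome:
    """One greedy-routing attempt.

    On success the path ends at the target and ``hops == len(path) - 1``;
    on failure it ends at the first revisited node.
    """

    source: str
    target: str
    success: bool
    path: list[str]
    hops: int
    geometric_length: float


def _summary(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"mean": float("nan"), "p10": float("nan"), "p90": float("nan")}
    return {
        "mean": float(values.mean()),
        "p10": float(np.percentile(values, 10)),
        "p90": float(np.percentile(values, 90)),
    }


@dataclasses.dataclass
class NavigabilityReport:
    """Navigability of one (graph, metric) pair."""

    success_rate: float
    pair_count: int
    topological_stretch_values: np.ndarray
    geometric_stretch_values: np.ndarray
    outgoing_sr: dict[str, float]
    incoming_sr: dict[str, float]

    @property
    def topological_stretch(self) -> dict[str, float]:
        return _summary(self.topological_stretch_values)

    @property
    def geometric_stretch(self) -> dict[str, float]:
        return _summary(self.geometric_stretch_values)

    def to_dict(self) -> dict:
        return {
            "success_rate": self.success_rate,
            "pair_count": self.pair_count,
            "topological_stretch": self.topological_stretch,
            "geometric_stretch": self.geometric_stretch,
            "outgoing_sr": self.outgoing_sr,
            "incoming_sr": self.incoming_sr,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# single-pair protocol
# ---------------------------------------------------------------------------

def greedy_route(
    connectome: Connectome,
    metric: Callable[[str, str], float],
    source: str,
    target: str,
    directed: bool = False,
) -> RoutingOutcome:
    """Route one signal from ``source`` to ``target`` under the greedy rule.

    Ties in neighbor distance are broken by the lexicographically smallest
    node id, making runs reproducible bit for bit.  The current node always
    forwards, even if it is itself closer to the target than every neighbor;
    the revisit rule then detects the failure.  A hop cap of N is kept as a
    backstop only.
    """
    nodes = set(connectome.node_ids)
    if source not in nodes or target not in nodes:
        raise KeyError(f"unknown node in pair ({source!r}, {target!r})")
    if source == target:
        return RoutingOutcome(source, target, True, [source], 0, 0.0)
    adj = connectome.out_neighbors() if directed else connectome.neighbors()
    path = [source]
    visited = {source}
    length = 0.0
    current = source
    for _ in range(connectome.N):
        neigh = adj[current]
        if not neigh:
            return RoutingOutcome(source, target, False, path, len(path) - 1, length)
        # neighbor lists are sorted, so min() keeps the lexicographic tie-break
        best = min(neigh, key=lambda n: metric(n, target))
        length += metric(current, best)
        path.append(best)
        if best == target:
            return RoutingOutcome(source, target, True, path, len(path) - 1, length)
        if best in visited:
            return RoutingOutcome(source, target, False, path, len(path) - 1, length)
        visited.add(best)
        current = best
    return RoutingOutcome(source, target, False, path, len(path) - 1, length)


# ---------------------------------------------------------------------------
# full navigability sweep
# ---------------------------------------------------------------------------

def _distance_matrix(metric, node_ids: Sequence[str]) -> np.ndarray:
    if hasattr(metric, "matrix"):
        return np.asarray(metric.matrix(node_ids), dtype=float)
    n = len(node_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = metric(node_ids[i], node_ids[j])
    return D


def _bfs_with_min_geo(
    source: int,
    adj: list[np.ndarray],
    D: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hop distances from ``source`` and, per node, the minimal metric length
    over all hop-minimal paths (layered relaxation over the BFS level graph)."""
    n = len(adj)
    hops = np.full(n, -1, dtype=np.int64)
    geo = np.full(n, np.inf)
    hops[source] = 0
    geo[source] = 0.0
    frontier = [source]
    while frontier:
        nxt: list[int] = []
        for u in frontier:
            du = geo[u]
            for v in adj[u]:
                if hops[v] == -1:
                    hops[v] = hops[u] + 1
                    nxt.append(v)
                if hops[v] == hops[u] + 1:
                    cand = du + D[u, v]
                    if cand < geo[v]:
                        geo[v] = cand
        frontier = nxt
    return hops, geo


def navigability(
    connectome: Connectome,
    metric: Callable[[str, str], float],
    directed: bool = False,
    pair_log: Optional[list] = None,
) -> NavigabilityReport:
    """Run greedy routing over every ordered intra-component pair.

    Pairs spanning different undirected components are excluded from both
    numerator and denominator (they cannot succeed by definition), and
    source == target pairs are not evaluated.  ``pair_log``, when given,
    receives one (source, target, success, hops, topo_stretch, geo_stretch)
    tuple per evaluated pair.
    """
    ids = sorted(connectome.node_ids)  # index order == lexicographic order
    index = {n: i for i, n in enumerate(ids)}
    n = len(ids)
    D = _distance_matrix(metric, ids)

    adj_map = connectome.out_neighbors() if directed else connectome.neighbors()
    adj = [np.array([index[v] for v in adj_map[ids[i]]], dtype=np.int64) for i in range(n)]

    comps = connected_components(connectome)
    comp_of = np.full(n, -1, dtype=np.int64)
    for c, comp in enumerate(comps):
        for node in comp:
            comp_of[index[node]] = c

    successes = 0
    pairs = 0
    topo: list[float] = []
    geo: list[float] = []
    out_succ = np.zeros(n, dtype=np.int64)
    out_tot = np.zeros(n, dtype=np.int64)
    in_succ = np.zeros(n, dtype=np.int64)
    in_tot = np.zeros(n, dtype=np.int64)
    max_hops = n

    for s in range(n):
        targets = np.flatnonzero(comp_of == comp_of[s])
        targets = targets[targets != s]
        if targets.size == 0:
            continue
        hops_sp, geo_sp = _bfs_with_min_geo(s, adj, D)
        for t in targets:
            # --- greedy walk from s toward t over the index arrays -------
            current = s
            visited = {s}
            glen = 0.0
            ghops = 0
            success = False
            while ghops < max_hops:
                neigh = adj[current]
                if neigh.size == 0:
                    break
                nxt = neigh[int(np.argmin(D[neigh, t]))]
                glen += D[current, nxt]
                ghops += 1
                if nxt == t:
                    success = True
                    break
                if nxt in visited:
                    break
                visited.add(nxt)
                current = nxt
            pairs += 1
            out_tot[s] += 1
            in_tot[t] += 1
            ts = gs = float("nan")
            if success:
                successes += 1
                out_succ[s] += 1
                in_succ[t] += 1
                ts = ghops / hops_sp[t]
                denom = geo_sp[t]
                gs = glen / denom if denom > 0 else 1.0
                topo.append(ts)
                geo.append(gs)
            if pair_log is not None:
                pair_log.append((ids[s], ids[t], success, ghops, ts, gs))

    return NavigabilityReport(
        success_rate=successes / pairs if pairs else float("nan"),
        pair_count=pairs,
        topological_stretch_values=np.asarray(topo),
        geometric_stretch_values=np.asarray(geo),
        outgoing_sr={ids[i]: float(out_succ[i] / out_tot[i]) for i in range(n) if out_tot[i]},
        incoming_sr={ids[i]: float(in_succ[i] / in_tot[i]) for i in range(n) if in_tot[i]},
    )
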