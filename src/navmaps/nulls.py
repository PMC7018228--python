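"""Randomization baselines for navigability comparisons.

Three null models put a network's navigability in perspective:

1. position swap — permute the node -> position assignment, leaving the
   topology untouched (destroys the coupling between geometry and
   structure);
2. degree-preserving rewiring — repeated double-edge swaps, the
   configuration-model surrogate, run until 100 L successful swaps;
3. cost-preserving rewiring — as (2), but a swap of links A–B, C–D into
   A–C, B–D is additionally accepted only if

       |(d_AB + d_CD) - (d_AC + d_BD)| < eps * D,

   where D is the total metric length over the *original* edge set (each
   undirected edge counted once) and eps defaults to 1/60.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Optional

import numpy as np

from .io import Connectome
from .model import HyperbolicMap

logger = logging.getLogger(__name__)

__all__ = [
    "RewireConfig",
    "shuffle_positions",
    "shuffle_map",
    "rewire_degree_preserving",
    "rewire_cost_preserving",
    "total_cost",
]


@dataclasses.dataclass
class RewireConfig:
    """Knobs of the rewiring null models.

    ``swap_multiplier`` successful swaps are requested per link;
    ``max_attempt_factor`` bounds the attempts allowed per requested swap so
    swap-poor graphs (triangles, cliques) terminate with a warning instead
    of hanging.
    """

    epsilon: float = 1.0 / 60.0
    swap_multiplier: int = 100
    max_attempt_factor: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.swap_multiplier <= 0 or self.max_attempt_factor <= 0:
            raise ValueError("multipliers must be positive")


def shuffle_positions(connectome: Connectome, seed: int) -> Connectome:
    """Null model 1: uniformly permute the node -> position assignment."""
    if connectome.positions is None:
        raise ValueError("connectome has no positions to shuffle")
    rng = np.random.default_rng(seed)
    ids = list(connectome.node_ids)
    perm = rng.permutation(len(ids))
    new_positions = {ids[i]: connectome.positions[ids[perm[i]]] for i in range(len(ids))}
    return dataclasses.replace(connectome, positions=new_positions)


def shuffle_map(hmap: HyperbolicMap, seed: int) -> HyperbolicMap:
    """Null model 1 for hyperbolic maps: permute the (r, theta) assignment."""
    rng = np.random.default_rng(seed)
    ids = sorted(hmap.coordinates)
    perm = rng.permutation(len(ids))
    coords = {ids[i]: hmap.coordinates[ids[perm[i]]] for i in range(len(ids))}
    return HyperbolicMap(coordinates=coords, R=hmap.R, beta=hmap.beta)


def total_cost(connectome: Connectome, metric: Callable[[str, str], float]) -> float:
    """Total metric length over the edge set, each undirected edge once."""
    return float(sum(metric(u, v) for u, v in connectome.edges))


def _rewire(
    connectome: Connectome,
    config: RewireConfig,
    accept: Optional[Callable[[str, str, str, str], bool]],
    provenance: Optional[dict],
    model_name: str,
) -> Connectome:
    """Double-edge-swap engine shared by null models 2 and 3.

    ``accept(a, b, c, d)`` vets the candidate swap (a–b, c–d) -> (a–c, b–d)
    after the structural checks (4 distinct nodes, no duplicate edges).
    """
    if connectome.L < 2:
        raise ValueError("rewiring needs at least 2 links")
    rng = np.random.default_rng(config.seed)
    edges = sorted(connectome.edges)
    edge_set = set(edges)
    L = len(edges)
    target_swaps = config.swap_multiplier * L
    attempt_budget = config.max_attempt_factor * target_swaps
    accepted = 0
    attempts = 0
    swap_log: list[tuple[str, str, str, str]] = []
    while accepted < target_swaps and attempts < attempt_budget:
        attempts += 1
        i, j = rng.integers(0, L, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # orientation of the re-pairing
            c, d = d, c
        # candidate: (a-b, c-d) -> (a-c, b-d)
        if len({a, b, c, d}) < 4:
            continue
        e1 = (a, c) if a <= c else (c, a)
        e2 = (b, d) if b <= d else (d, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        if accept is not None and not accept(a, b, c, d):
            continue
        edge_set.discard((a, b) if a <= b else (b, a))
        edge_set.discard((c, d) if c <= d else (d, c))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        accepted += 1
        if provenance is not None:
            swap_log.append((a, b, c, d))
    if accepted < target_swaps:
        logger.warning(
            "%s: attempt budget exhausted after %d attempts (%d/%d swaps accepted)",
            model_name, attempts, accepted, target_swaps,
        )
    if provenance is not None:
        provenance.update(
            model=model_name,
            seed=config.seed,
            swaps_attempted=attempts,
            swaps_accepted=accepted,
            swaps_requested=target_swaps,
            swap_log=swap_log,
        )
    return connectome.with_edges(edge_set)


def rewire_degree_preserving(
    connectome: Connectome,
    config: RewireConfig,
    provenance: Optional[dict] = None,
) -> Connectome:
    """Null model 2: double-edge swaps preserving the degree sequence exactly."""
    return _rewire(connectome, config, None, provenance, "degree_preserving")


def rewire_cost_preserving(
    connectome: Connectome,
    metric: Callable[[str, str], float],
    config: RewireConfig,
    provenance: Optional[dict] = None,
) -> Connectome:
    """Null model 3: degree-preserving swaps that also preserve wiring cost.

    Each individual swap must keep the edge-length change below
    ``config.epsilon`` times the total cost D of the *input* network; D is
    computed once and never updated.
    """
    D = total_cost(connectome, metric)
    eps_D = config.epsilon * D

    def accept(a: str, b: str, c: str, d: str) -> bool:
        delta = (metric(a, b) + metric(c, d)) - (metric(a, c) + metric(b, d))
        return abs(delta) < eps_D

    out = _rewire(connectome, config, accept, provenance, "cost_preserving")
    if provenance is not None:
        provenance.update(
            epsilon=config.epsilon,
            total_cost_initial=D,
            total_cost_final=total_cost(out, metric),
        )
    return out
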