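"""Geometric interpretation statistics for hyperbolic maps.

Once a network is embedded, the angular (similarity) coordinate can be
read like a map: contiguous arcs of nodes form communities, annotated node
groups (anatomical regions, functional clusters) may or may not be
angularly localized, and the empirical connection probability as a
function of distance characterizes how geometry shapes the topology.

The critical gap method cuts the circular ordering of nodes wherever the
angular gap between consecutive nodes exceeds the largest gap expected for
uniformly placed nodes, (2*pi/N) * ln N by default.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np

from .geometry import TWO_PI, angular_separation
from .io import Connectome
from .model import HyperbolicMap

__all__ = [
    "Partition",
    "LocalizationReport",
    "critical_gap_communities",
    "nmi",
    "angular_localization",
    "region_angular_span",
    "empirical_connection_probability",
    "BinnedCurve",
]


@dataclasses.dataclass
class Partition:
    """A hard partition: every node carries exactly one community label."""

    assignment: dict[str, str]

    @property
    def labels(self) -> set[str]:
        return set(self.assignment.values())

    def communities(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, set()).add(n)
        return out

    @classmethod
    def from_annotations(cls, connectome: Connectome, label_set: str) -> "Partition":
        if not connectome.annotations:
            raise ValueError("connectome has no annotations")
        assignment = {}
        for n in connectome.node_ids:
            try:
                assignment[n] = connectome.annotations[n][label_set]
            except KeyError:
                raise ValueError(f"node {n!r} lacks label set {label_set!r}") from None
        return cls(assignment)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id\tcommunity\n")
            for n in sorted(self.assignment):
                fh.write(f"{n}\t{self.assignment[n]}\n")


@dataclasses.dataclass
class LocalizationReport:
    """Observed vs null mean angular separation of a node subset."""

    cluster_name: str
    n_nodes: int
    mean_sep_observed: float
    mean_sep_null: float
    ratio: float
    p_value: float
    n_samples: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# critical gap communities
# ---------------------------------------------------------------------------

def critical_gap_communities(
    hmap: HyperbolicMap,
    critical_gap: Optional[float] = None,
) -> Partition:
    """Split the angular ordering at gaps larger than the critical gap.

    Nodes are sorted by angle; every consecutive gap (including the
    wraparound) strictly greater than ``critical_gap`` separates two
    communities.  The default threshold (2*pi/N) * ln N is the asymptotic
    expected maximal gap of N uniform angles, so uniformly spread nodes
    typically form one community.  The output is rotation invariant up to
    community labels.
    """
    ids = sorted(hmap.coordinates)
    if not ids:
        raise ValueError("empty map")
    N = len(ids)
    if critical_gap is None:
        critical_gap = (TWO_PI / N) * math.log(N)
    thetas = np.array([hmap.coordinates[n].theta for n in ids])
    order = np.argsort(thetas, kind="stable")
    sorted_thetas = thetas[order]
    gaps = np.diff(sorted_thetas, append=sorted_thetas[0] + TWO_PI)
    # gaps[k] separates sorted node k from k+1 (gaps[-1] wraps around)
    cut_after = np.flatnonzero(gaps > critical_gap)
    assignment: dict[str, str] = {}
    if cut_after.size == 0:
        for n in ids:
            assignment[n] = "c0"
        return Partition(assignment)
    # start each community right after a cut; wrap the circular ordering
    cut_set = set(cut_after.tolist())
    start = (int(cut_after[-1]) + 1) % N
    community = 0
    for k in range(N):
        pos = (start + k) % N
        assignment[ids[order[pos]]] = f"c{community}"
        if pos in cut_set and k < N - 1:
            community += 1
    return Partition(assignment)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def nmi(p1: Partition, p2: Partition, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions of one node set.

    Computed from the joint contingency table with natural logarithms and
    normalized by the arithmetic mean of the entropies (``max`` and
    ``sqrt`` variants selectable).  Two identical single-cluster partitions
    score 1; if exactly one side is a single cluster the score is 0.
    """
    if set(p1.assignment) != set(p2.assignment):
        raise ValueError("partitions must cover the identical node set")
    if normalization not in ("arithmetic", "max", "sqrt"):
        raise ValueError(f"unknown normalization {normalization!r}")
    nodes = sorted(p1.assignment)
    n = len(nodes)
    counts: dict[tuple[str, str], int] = {}
    c1: dict[str, int] = {}
    c2: dict[str, int] = {}
    for node in nodes:
        a, b = p1.assignment[node], p2.assignment[node]
        counts[(a, b)] = counts.get((a, b), 0) + 1
        c1[a] = c1.get(a, 0) + 1
        c2[b] = c2.get(b, 0) + 1
    h1 = -sum((c / n) * math.log(c / n) for c in c1.values())
    h2 = -sum((c / n) * math.log(c / n) for c in c2.values())
    if h1 == 0.0 and h2 == 0.0:
        return 1.0  # both single-cluster over the same nodes: identical
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    mi = 0.0
    for (a, b), c in counts.items():
        mi += (c / n) * math.log(c * n / (c1[a] * c2[b]))
    if normalization == "arithmetic":
        denom = 0.5 * (h1 + h2)
    elif normalization == "max":
        denom = max(h1, h2)
    else:
        denom = math.sqrt(h1 * h2)
    return max(0.0, min(1.0, mi / denom))


# ---------------------------------------------------------------------------
# angular localization
# ---------------------------------------------------------------------------

def _mean_pairwise_separation(thetas: np.ndarray) -> float:
    d = np.abs(thetas[:, None] - thetas[None, :]) % TWO_PI
    d = np.pi - np.abs(np.pi - d)
    m = thetas.size
    iu = np.triu_indices(m, k=1)
    return float(d[iu].mean())


def angular_localization(
    hmap: HyperbolicMap,
    cluster: Iterable[str],
    cluster_name: str = "cluster",
    n_samples: int = 10_000,
    seed: int = 0,
) -> LocalizationReport:
    """Permutation test for the angular concentration of a node subset.

    The observed statistic is the mean angular separation over all
    within-cluster pairs; the null draws ``n_samples`` equally sized subsets
    uniformly without replacement from all map nodes (cluster members
    included).  The p-value is the plain fraction of null samples with a
    mean separation less than or equal to the observed one.
    """
    cluster = sorted(set(cluster))
    m = len(cluster)
    if m < 2:
        raise ValueError("cluster must contain at least 2 nodes")
    missing = [c for c in cluster if c not in hmap.coordinates]
    if missing:
        raise ValueError(f"cluster node(s) missing from map: {missing[:5]}")
    ids = sorted(hmap.coordinates)
    all_thetas = np.array([hmap.coordinates[n].theta for n in ids])
    observed = _mean_pairwise_separation(
        np.array([hmap.coordinates[n].theta for n in cluster])
    )
    rng = np.random.default_rng(seed)
    N = len(ids)
    # m smallest of N uniforms per row = a uniform m-subset
    keys = rng.random((n_samples, N))
    subsets = np.argpartition(keys, m - 1, axis=1)[:, :m]
    samples = all_thetas[subsets]  # (n_samples, m)
    d = np.abs(samples[:, :, None] - samples[:, None, :]) % TWO_PI
    d = np.pi - np.abs(np.pi - d)
    iu = np.triu_indices(m, k=1)
    null_means = d[:, iu[0], iu[1]].mean(axis=1)
    mean_null = float(null_means.mean())
    # tolerance so exact ties (e.g. the full node set) survive round-off
    p_value = float((null_means <= observed + 1e-9).sum() / n_samples)
    return LocalizationReport(
        cluster_name=cluster_name,
        n_nodes=m,
        mean_sep_observed=observed,
        mean_sep_null=mean_null,
        ratio=observed / mean_null if mean_null > 0 else float("inf"),
        p_value=p_value,
        n_samples=n_samples,
    )


def region_angular_span(hmap: HyperbolicMap, cluster: Iterable[str]) -> float:
    """Fraction of the circle covered by the smallest arc containing a cluster.

    The span is 2*pi minus the largest gap between consecutive sorted
    cluster angles (wraparound included), normalized by 2*pi.
    """
    cluster = sorted(set(cluster))
    if not cluster:
        raise ValueError("empty cluster")
    thetas = np.sort(np.array([hmap.coordinates[n].theta for n in cluster]))
    if thetas.size == 1:
        return 0.0
    gaps = np.diff(thetas, append=thetas[0] + TWO_PI)
    return float((TWO_PI - gaps.max()) / TWO_PI)


# ---------------------------------------------------------------------------
# empirical connection probability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BinnedCurve:
    """Connection frequency vs distance in equal-width bins.

    ``fractions`` is NaN for empty bins (their ``counts`` entry is 0).
    """

    centers: np.ndarray
    fractions: np.ndarray
    counts: np.ndarray

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("bin_center\tfraction_connected\tpair_count\n")
            for c, f, k in zip(self.centers, self.fractions, self.counts):
                fh.write(f"{float(c)!r}\t{float(f)!r}\t{int(k)}\n")


def empirical_connection_probability(
    connectome: Connectome,
    metric: Callable[[str, str], float],
    n_bins: int,
) -> BinnedCurve:
    """Fraction of node pairs that are connected, binned by pair distance.

    All unordered pairs are placed into ``n_bins`` equal-width bins spanning
    the observed distance range.
    """
    if connectome.N < 2:
        raise ValueError("need at least 2 nodes")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ids = sorted(connectome.node_ids)
    index = {n: i for i, n in enumerate(ids)}
    if hasattr(metric, "matrix"):
        D = np.asarray(metric.matrix(ids), dtype=float)
    else:
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = metric(ids[i], ids[j])
    iu = np.triu_indices(len(ids), k=1)
    dist = D[iu]
    A = np.zeros((len(ids), len(ids)), dtype=bool)
    for u, v in connectome.edges:
        A[index[u], index[v]] = True
        A[index[v], index[u]] = True
    connected = A[iu]
    lo, hi = float(dist.min()), float(dist.max())
    if hi == lo:
        hi = lo + 1.0  # all pairs equidistant: single occupied bin
    edges_ = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(dist, edges_) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    hits = np.bincount(which, weights=connected.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        fractions = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges_[:-1] + edges_[1:])
    return BinnedCurve(centers=centers, fractions=fractions, counts=counts)
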