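"""Reading, validating and writing connectomes and their side data.

The on-disk formats are deliberately plain text:

* edge list — two whitespace-separated node ids per line, ``#`` comments;
* positions — four columns: id, x, y, z;
* annotations — TSV with a header row: id, then one column per label set;
* analysis reports — JSON.

Node ids are opaque strings.  Any dense integer indexing used internally by
the algorithms never leaks into files or returned objects.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "read_edge_list",
    "write_edge_list",
    "read_positions",
    "write_positions",
    "read_annotations",
    "write_annotations",
    "connected_components",
    "giant_component",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) representation of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclasses.dataclass
class Connectome:
    """An unweighted network with optional spatial and categorical side data.

    Parameters
    ----------
    node_ids
        Ordered unique string identifiers.
    edges
        Undirected edges as canonical (min, max) id pairs; no self-loops.
    directed_edges
        Optional ordered pairs; when present, ``edges`` must equal their
        symmetrized projection.
    positions
        Optional map id -> 3D coordinate (uniform but arbitrary length unit).
    annotations
        Optional map id -> {label-set name -> category}.
    """

    node_ids: list[str]
    edges: set[tuple[str, str]]
    directed_edges: Optional[set[tuple[str, str]]] = None
    positions: Optional[dict[str, np.ndarray]] = None
    annotations: Optional[dict[str, dict[str, str]]] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        nodes = set(self.node_ids)
        if len(nodes) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        canonical = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge {(u, v)} references undeclared node")
            canonical.add(canonical_edge(u, v))
        self.edges = canonical
        if self.directed_edges is not None:
            for u, v in self.directed_edges:
                if u == v:
                    raise ValueError(f"directed self-loop on node {u!r}")
                if u not in nodes or v not in nodes:
                    raise ValueError(f"directed edge {(u, v)} references undeclared node")
            sym = {canonical_edge(u, v) for u, v in self.directed_edges}
            if sym != self.edges:
                raise ValueError("edges must equal the symmetrized projection of directed_edges")
        if self.positions is not None:
            missing = nodes - set(self.positions)
            if missing:
                raise ValueError(f"positions missing for nodes: {sorted(missing)[:5]}")
            for n, p in self.positions.items():
                arr = np.asarray(p, dtype=float)
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"non-finite coordinate for node {n!r}")
                self.positions[n] = arr

    # -- basic accessors ------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def L(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.node_ids}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbors(self) -> dict[str, list[str]]:
        """Undirected adjacency, neighbor lists sorted lexicographically."""
        adj: dict[str, list[str]] = {n: [] for n in self.node_ids}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for n in adj:
            adj[n].sort()
        return adj

    def out_neighbors(self) -> dict[str, list[str]]:
        """Directed adjacency (falls back to undirected when absent)."""
        if self.directed_edges is None:
            return self.neighbors()
        adj: dict[str, list[str]] = {n: [] for n in self.node_ids}
        for u, v in self.directed_edges:
            adj[u].append(v)
        for n in adj:
            adj[n].sort()
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def subgraph(self, nodes: Iterable[str]) -> "Connectome":
        """Induced subgraph on a node subset (side data restricted too)."""
        keep = set(nodes)
        unknown = keep - set(self.node_ids)
        if unknown:
            raise ValueError(f"unknown node(s): {sorted(unknown)[:5]}")
        return Connectome(
            node_ids=[n for n in self.node_ids if n in keep],
            edges={e for e in self.edges if e[0] in keep and e[1] in keep},
            directed_edges=None if self.directed_edges is None else {
                e for e in self.directed_edges if e[0] in keep and e[1] in keep
            },
            positions=None if self.positions is None else {n: self.positions[n] for n in keep},
            annotations=None if self.annotations is None else {
                n: dict(self.annotations[n]) for n in keep if n in self.annotations
            },
        )

    def with_edges(self, edges: Iterable[tuple[str, str]]) -> "Connectome":
        """Copy of this connectome with a replaced undirected edge set."""
        new_edges = {canonical_edge(u, v) for u, v in edges}
        return Connectome(
            node_ids=list(self.node_ids),
            edges=new_edges,
            directed_edges=None,
            positions=None if self.positions is None else dict(self.positions),
            annotations=None if self.annotations is None else {n: dict(d) for n, d in self.annotations.items()},
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, directed: bool = False) -> Connectome:
    """Read a two-column edge list.

    Lines starting with ``#`` are ignored.  Duplicate edges are collapsed and
    self-loop lines dropped; both are counted in a single warning.  A line
    with a token count other than two is a hard error reported with its line
    number.
    """
    path = Path(path)
    node_ids: list[str] = []
    seen_nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    directed_edges: set[tuple[str, str]] = set()
    n_selfloops = 0
    n_duplicates = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}")
            u, v = tokens
            for n in (u, v):
                if n not in seen_nodes:
                    seen_nodes.add(n)
                    node_ids.append(n)
            if u == v:
                n_selfloops += 1
                continue
            if directed:
                if (u, v) in directed_edges:
                    n_duplicates += 1
                    continue
                directed_edges.add((u, v))
                edges.add(canonical_edge(u, v))
            else:
                e = canonical_edge(u, v)
                if e in edges:
                    n_duplicates += 1
                    continue
                edges.add(e)
    if n_selfloops or n_duplicates:
        logger.warning(
            "%s: dropped %d self-loop line(s) and %d duplicate edge line(s)",
            path, n_selfloops, n_duplicates,
        )
    return Connectome(
        node_ids=node_ids,
        edges=edges,
        directed_edges=directed_edges if directed else None,
    )


def write_edge_list(connectome: Connectome, path: str | Path) -> None:
    """Write the undirected edge set (directed set when present) as TSV."""
    path = Path(path)
    pairs = sorted(connectome.directed_edges) if connectome.directed_edges is not None else sorted(connectome.edges)
    with path.open("w") as fh:
        for u, v in pairs:
            fh.write(f"{u}\t{v}\n")


def read_positions(path: str | Path, connectome: Connectome) -> Connectome:
    """Attach 3D positions from a four-column table (id, x, y, z).

    Rows for unknown nodes are skipped with a warning; a connectome node
    without a row is a hard error (positions are all-or-none).
    """
    path = Path(path)
    nodes = set(connectome.node_ids)
    positions: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tokens (id x y z), got {len(tokens)}")
            n = tokens[0]
            if n not in nodes:
                skipped.append(n)
                continue
            positions[n] = np.array([float(t) for t in tokens[1:]], dtype=float)
    if skipped:
        logger.warning("%s: skipped %d position row(s) for unknown node(s): %s",
                       path, len(skipped), skipped[:5])
    missing = nodes - set(positions)
    if missing:
        raise ValueError(f"no position for node(s): {sorted(missing)}")
    return dataclasses.replace(connectome, positions=positions)


def write_positions(connectome: Connectome, path: str | Path) -> None:
    if connectome.positions is None:
        raise ValueError("connectome has no positions")
    with Path(path).open("w") as fh:
        for n in connectome.node_ids:
            x, y, z = (float(c) for c in connectome.positions[n])
            fh.write(f"{n}\t{x!r}\t{y!r}\t{z!r}\n")


def read_annotations(path: str | Path, connectome: Connectome) -> Connectome:
    """Attach categorical annotations from a headered TSV (id + label sets)."""
    path = Path(path)
    nodes = set(connectome.node_ids)
    annotations: dict[str, dict[str, str]] = {}
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: annotation header needs id plus >= 1 label-set column")
        label_sets = header[1:]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(tokens)}")
            n = tokens[0]
            if n not in nodes:
                logger.warning("%s:%d: annotation row for unknown node %r skipped", path, lineno, n)
                continue
            annotations[n] = dict(zip(label_sets, tokens[1:]))
    return dataclasses.replace(connectome, annotations=annotations)


def write_annotations(connectome: Connectome, path: str | Path) -> None:
    if not connectome.annotations:
        raise ValueError("connectome has no annotations")
    label_sets = sorted({ls for d in connectome.annotations.values() for ls in d})
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(label_sets) + "\n")
        for n in connectome.node_ids:
            if n in connectome.annotations:
                row = [connectome.annotations[n].get(ls, "NA") for ls in label_sets]
                fh.write(n + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def connected_components(connectome: Connectome) -> list[set[str]]:
    """Maximal undirected components, largest first, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(connectome.to_networkx())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def giant_component(connectome: Connectome) -> Connectome:
    """Induced subgraph on the largest undirected component."""
    return connectome.subgraph(connected_components(connectome)[0])
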