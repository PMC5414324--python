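"""Spatial vessel graphs and the plain-text formats they travel in.

A vessel centerline is represented as an undirected spatial graph: each node
carries a position (2D or 3D, continuous image/physical units — never voxel
indices) and a positive radius, the local vessel half-width.  Trees arrive as
SWC files; general graphs (cerebral vasculature can contain cycles, which SWC
cannot encode) use a small JSON dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VesselNode",
    "VesselGraph",
    "GraphFormatError",
    "read_swc",
    "write_swc",
    "read_graph_json",
    "write_graph_json",
    "degree",
]


class GraphFormatError(ValueError):
    """A vessel-graph file violates its format or an invariant."""


@dataclass(frozen=True)
class VesselNode:
    """A centerline point: integer id, spatial position, vessel radius."""

    id: int
    position: tuple[float, ...]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"node {self.id}: radius must be > 0, got {self.radius}")
        if len(self.position) not in (2, 3):
            raise ValueError(f"node {self.id}: position must be 2D or 3D")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


class VesselGraph:
    """Undirected spatial graph of vessel centerline nodes.

    Nodes are :class:`VesselNode` keyed by id; edges are unordered id pairs.
    Self-loops, duplicate edges and dangling endpoints are rejected.
    """

    def __init__(self, nodes=(), edges=(), dim: int | None = None):
        self._nodes: dict[int, VesselNode] = {}
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)
        if dim is not None and self._nodes:
            if dim != self.dim:
                raise GraphFormatError(
                    f"declared dim {dim} != node dimensionality {self.dim}"
                )
        self._declared_dim = dim

    # -- construction -----------------------------------------------------
    def add_node(self, node: VesselNode) -> None:
        if node.id in self._nodes:
            raise GraphFormatError(f"duplicate node id {node.id}")
        if self._nodes:
            d = len(next(iter(self._nodes.values())).position)
            if len(node.position) != d:
                raise GraphFormatError(
                    f"node {node.id}: dimensionality {len(node.position)} != graph dim {d}"
                )
        self._nodes[node.id] = node
        self._g.add_node(node.id)

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise GraphFormatError(f"self-loop on node {a}")
        for v in (a, b):
            if v not in self._nodes:
                raise GraphFormatError(f"edge ({a},{b}) references unknown node {v}")
        if self._g.has_edge(a, b):
            raise GraphFormatError(f"duplicate edge ({a},{b})")
        self._g.add_edge(a, b)

    # -- queries ----------------------------------------------------------
    @property
    def dim(self) -> int:
        if not self._nodes:
            return self._declared_dim or 3
        return len(next(iter(self._nodes.values())).position)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node(self, id: int) -> VesselNode:
        try:
            return self._nodes[id]
        except KeyError:
            raise KeyError(f"unknown node id {id}") from None

    def position(self, id: int) -> np.ndarray:
        return self.node(id).pos

    def radius(self, id: int) -> float:
        return self.node(id).radius

    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self._g.edges())

    def neighbors(self, id: int) -> list[int]:
        self.node(id)
        return sorted(self._g.neighbors(id))

    def degree(self, id: int) -> int:
        self.node(id)
        return self._g.degree(id)

    @property
    def nx(self) -> nx.Graph:
        """Read-only view of the underlying networkx graph."""
        return self._g

    @property
    def extent(self) -> np.ndarray:
        """Per-axis bounding-box lengths (max - min)."""
        if not self._nodes:
            return np.zeros(self.dim)
        P = np.array([n.position for n in self._nodes.values()], dtype=float)
        return P.max(axis=0) - P.min(axis=0)

    @property
    def max_extent(self) -> float:
        e = self.extent
        return float(e.max()) if e.size else 0.0

    def copy(self) -> "VesselGraph":
        return VesselGraph(self._nodes.values(), self.edges(), dim=self._declared_dim)

    def subgraph_without(self, drop_ids) -> "VesselGraph":
        drop = set(drop_ids)
        nodes = [n for i, n in self._nodes.items() if i not in drop]
        edges = [(a, b) for a, b in self.edges() if a not in drop and b not in drop]
        return VesselGraph(nodes, edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VesselGraph):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and set(map(frozenset, self._g.edges()))
            == set(map(frozenset, other._g.edges()))
        )

    def __repr__(self) -> str:
        return f"VesselGraph(dim={self.dim}, nodes={self.n_nodes}, edges={self.n_edges})"


def degree(graph: VesselGraph, id: int) -> int:
    """Number of edges incident to node ``id``."""
    return graph.degree(id)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path) -> VesselGraph:
    """Read an SWC file (``id type x y z radius parent``, '#' comments).

    2D graphs are stored with z = 0 and auto-detected: when every z is equal,
    the z column is dropped and the graph is returned with dim = 2.
    """
    records: list[tuple[int, float, float, float, float, int]] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 7 whitespace-separated fields"
                )
            try:
                nid = int(parts[0])
                x, y, z, r = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise GraphFormatError(f"{path}:{lineno}: {exc}") from None
            if nid in seen:
                raise GraphFormatError(f"{path}:{lineno}: duplicate id {nid}")
            if r <= 0:
                raise GraphFormatError(
                    f"{path}:{lineno}: non-positive radius {r} for node {nid}"
                )
            seen.add(nid)
            records.append((nid, x, y, z, r, parent))

    flat = bool(records) and len({z for (_, _, _, z, _, _) in records}) == 1
    graph = VesselGraph()
    for nid, x, y, z, r, _ in records:
        pos = (x, y) if flat else (x, y, z)
        graph.add_node(VesselNode(nid, pos, r))
    for lineno_like, (nid, _, _, _, _, parent) in enumerate(records):
        if parent == -1:
            continue
        if parent not in seen:
            raise GraphFormatError(
                f"{path}: node {nid} references unknown parent {parent}"
            )
        graph.add_edge(nid, parent)
    return graph


def write_swc(graph: VesselGraph, path) -> None:
    """Write a tree-shaped graph as SWC (2D graphs get z = 0).

    Raises :class:`GraphFormatError` if the graph contains a cycle (SWC is a
    forest format); use the JSON dialect for general graphs.
    """
    g = graph.nx
    if nx.cycle_basis(g):
        raise GraphFormatError("graph contains cycles; SWC encodes forests only")

    parent: dict[int, int] = {}
    for comp in nx.connected_components(g):
        root = min(comp)
        parent[root] = -1
        for u, v in nx.bfs_edges(g, root):
            parent[v] = u
    lines = ["# id type x y z radius parent"]
    for nid in graph.node_ids:
        n = graph.node(nid)
        x, y = n.position[0], n.position[1]
        z = n.position[2] if len(n.position) == 3 else 0.0
        lines.append(
            f"{nid} 2 {x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {parent.get(nid, -1)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON dialect: {"dim": d, "nodes": [{"id","pos","radius"}], "edges": [[a,b]]}
# ---------------------------------------------------------------------------

def read_graph_json(path) -> VesselGraph:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"{path}: not valid JSON: {exc}") from None
    return graph_from_dict(doc, where=str(path))


def graph_from_dict(doc: dict, where: str = "<dict>") -> VesselGraph:
    if not isinstance(doc, dict):
        raise GraphFormatError(f"{where}: $: expected object")
    for key in ("dim", "nodes", "edges"):
        if key not in doc:
            raise GraphFormatError(f"{where}: $.{key}: missing")
    dim = doc["dim"]
    if dim not in (2, 3):
        raise GraphFormatError(f"{where}: $.dim: must be 2 or 3, got {dim!r}")
    graph = VesselGraph(dim=dim)
    for i, nd in enumerate(doc["nodes"]):
        jp = f"$.nodes[{i}]"
        if not isinstance(nd, dict) or not {"id", "pos", "radius"} <= set(nd):
            raise GraphFormatError(f"{where}: {jp}: expected {{id,pos,radius}}")
        pos = nd["pos"]
        if not isinstance(pos, (list, tuple)) or len(pos) != dim:
            raise GraphFormatError(f"{where}: {jp}.pos: expected {dim} coordinates")
        try:
            node = VesselNode(int(nd["id"]), tuple(float(c) for c in pos),
                              float(nd["radius"]))
        except (TypeError, ValueError) as exc:
            raise GraphFormatError(f"{where}: {jp}: {exc}") from None
        try:
            graph.add_node(node)
        except GraphFormatError as exc:
            raise GraphFormatError(f"{where}: {jp}: {exc}") from None
    for i, e in enumerate(doc["edges"]):
        jp = f"$.edges[{i}]"
        if not isinstance(e, (list, tuple)) or len(e) != 2:
            raise GraphFormatError(f"{where}: {jp}: expected [a, b]")
        try:
            graph.add_edge(int(e[0]), int(e[1]))
        except GraphFormatError as exc:
            raise GraphFormatError(f"{where}: {jp}: {exc}") from None
    return graph


def graph_to_dict(graph: VesselGraph) -> dict:
    return {
        "dim": graph.dim,
        "nodes": [
            {
                "id": nid,
                "pos": [float(c) for c in graph.node(nid).position],
                "radius": float(graph.radius(nid)),
            }
            for nid in graph.node_ids
        ],
        "edges": [[a, b] for a, b in graph.edges()],
    }


def write_graph_json(graph: VesselGraph, path) -> None:
    """Write the JSON dialect with deterministic key and element order."""
    with open(path, "w") as fh:
        json.dump(graph_to_dict(graph), fh, indent=1, sort_keys=False)
        fh.write("\n")


def drop_small_components(graph: VesselGraph, min_nodes: int = 3) -> VesselGraph:
    """Drop isolated connected components smaller than ``min_nodes``.

    Tiny disconnected fragments are likely tracing noise or trivial vessels
    and are excluded from registration.
    """
    drop: set[int] = set()
    for comp in nx.connected_components(graph.nx):
        if len(comp) < min_nodes:
            drop |= comp
    if drop:
        logger.warning(
            "dropping %d node(s) in isolated components of < %d nodes",
            len(drop), min_nodes,
        )
        return graph.subgraph_without(drop)
    return graph
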