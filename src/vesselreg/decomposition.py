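"""Decompose a vessel graph into branches anchored at matched salient points.

Two kinds of branch are extracted, in order:

* kind 1 (``salient-to-salient``): for every pair of matched salient nodes
  joined by a path containing no other salient node, the hop-shortest such
  path;
* kind 2 (``salient-to-leaf``): for every degree-1 node reachable from a
  matched salient node along a salient-free path, the shortest path from its
  nearest salient node.

Every edge belongs to at most one branch; kind-1 extraction runs first and
claimed edges are masked before the kind-2 search.  Leaves are claimed in
descending hop distance so that, where paths share a prefix (e.g. behind an
unmatched bifurcation), the long trunk vessel wins and short interference
spurs fall into the residual edge set.  Unclaimed edges are returned as the
residual set and flow to fusion as unmatched structure.

A branch's node list excludes its anchoring salient endpoints; its three
matching features are the forward direction at the starting point, the sum of
node radii (a proxy for vessel volume) and the tortuosity (arc/chord ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphio import VesselGraph

__all__ = [
    "Branch",
    "decompose",
    "forward_direction",
    "sum_radius",
    "tortuosity",
    "annotate_features",
    "branch_table_tsv",
]

KIND_SALIENT = "salient-to-salient"
KIND_LEAF = "salient-to-leaf"


@dataclass
class Branch:
    """A salient-free node path anchored at a matched salient point.

    ``nodes`` is ordered from the anchor outward and never contains a salient
    node; the anchor (and for kind-1 branches the terminal salient) is stored
    separately and is not a member.
    """

    id: int
    nodes: list[int]
    kind: str
    anchor: int
    terminal: int | None = None
    # features, filled by annotate_features
    forward_direction: float | np.ndarray | None = None
    sum_radius: float | None = None
    tortuosity: float | None = None

    @property
    def path(self) -> list[int]:
        """Full node sequence including the salient endpoint(s)."""
        p = [self.anchor, *self.nodes]
        if self.terminal is not None:
            p.append(self.terminal)
        return p

    @property
    def edge_set(self) -> set[frozenset]:
        p = self.path
        return {frozenset(e) for e in zip(p, p[1:])}


def _lex_bfs_paths(graph: VesselGraph, sources, blocked, edge_ok):
    """Deterministic BFS from ``sources`` over edges passing ``edge_ok``.

    ``blocked`` nodes are never traversed through (they may only be sources).
    Returns (dist, pred) with predecessors chosen as the smallest-id neighbor
    on a shortest path, making reconstructed paths deterministic.
    """
    dist: dict[int, int] = {s: 0 for s in sources}
    pred: dict[int, int] = {}
    frontier = sorted(sources)
    while frontier:
        nxt: dict[int, int] = {}
        for u in frontier:
            for v in graph.neighbors(u):
                if not edge_ok(u, v):
                    continue
                if v in dist:
                    continue
                if v in nxt:
                    nxt[v] = min(nxt[v], u)
                else:
                    nxt[v] = u
        for v, p in nxt.items():
            dist[v] = dist[p] + 1
            pred[v] = p
        frontier = sorted(v for v in nxt if v not in blocked)
    return dist, pred


def _reconstruct(pred, source_set, v) -> list[int]:
    path = [v]
    while path[-1] not in source_set:
        path.append(pred[path[-1]])
    path.reverse()
    return path


def decompose(
    graph: VesselGraph,
    salient_ids,
    anchor_priority: dict[int, float] | None = None,
) -> tuple[list[Branch], set[frozenset]]:
    """Split ``graph`` into branches anchored at ``salient_ids``.

    ``anchor_priority`` orients kind-1 branches: the endpoint with the higher
    priority (by convention, the reference-side NSI of its salient pair)
    becomes the anchor.  Without priorities the smaller node id anchors.

    Returns ``(branches, residual_edges)``; residual edges are those claimed
    by no branch (arms behind unmatched bifurcations, interference spurs,
    degenerate salient-salient edges).
    """
    salient = set(salient_ids)
    if not salient:
        raise ValueError("salient_ids must be nonempty")
    prio = anchor_priority or {}
    claimed: set[frozenset] = set()
    branches: list[Branch] = []
    next_id = 0

    # ---- kind 1: salient-to-salient -----------------------------------
    seen_pairs: set[frozenset] = set()
    for s in sorted(salient):
        dist, pred = _lex_bfs_paths(
            graph, [s], blocked=salient, edge_ok=lambda u, v: True
        )
        for t in sorted(salient):
            if t == s or t not in dist:
                continue
            key = frozenset((s, t))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            path = _reconstruct(pred, {s}, t)
            if len(path) < 3:
                continue  # adjacent salients: no interior, edge goes residual
            edges = {frozenset(e) for e in zip(path, path[1:])}
            if edges & claimed:
                continue
            a, b = path[0], path[-1]
            pa, pb = prio.get(a, -a), prio.get(b, -b)
            if (pb, -b) > (pa, -a):
                path = path[::-1]
            claimed |= edges
            branches.append(
                Branch(next_id, path[1:-1], KIND_SALIENT, path[0], path[-1])
            )
            next_id += 1

    # ---- kind 2: salient-to-leaf ---------------------------------------
    leaves_done: set[int] = set()
    while True:
        dist, pred = _lex_bfs_paths(
            graph,
            sorted(salient),
            blocked=salient,
            edge_ok=lambda u, v: frozenset((u, v)) not in claimed,
        )
        cand = [
            (dist[v], v)
            for v in dist
            if graph.degree(v) == 1 and v not in salient and v not in leaves_done
            and dist[v] > 0
        ]
        if not cand:
            break
        # longest first: trunk vessels claim shared prefixes before spurs
        d, leaf = max(cand, key=lambda t: (t[0], -t[1]))
        path = _reconstruct(pred, salient, leaf)
        claimed |= {frozenset(e) for e in zip(path, path[1:])}
        leaves_done.add(leaf)
        branches.append(Branch(next_id, path[1:], KIND_LEAF, path[0]))
        next_id += 1

    residual = {frozenset((a, b)) for a, b in graph.edges()} - claimed
    return branches, residual


# ---------------------------------------------------------------------------
# Branch features
# ---------------------------------------------------------------------------

def forward_direction(graph: VesselGraph, branch: Branch):
    """Advancing direction from the anchoring salient point to the first node.

    2D: counterclockwise angle in degrees from the positive x axis, in
    [0, 360).  3D: the normalized direction vector.
    """
    if not branch.nodes:
        raise ValueError(f"branch {branch.id}: empty node list")
    v = graph.position(branch.nodes[0]) - graph.position(branch.anchor)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError(
            f"branch {branch.id}: anchor and first node are coincident"
        )
    if graph.dim == 2:
        return math.degrees(math.atan2(v[1], v[0])) % 360.0
    return v / norm


def sum_radius(branch: Branch, graph: VesselGraph) -> float:
    """Sum of node radii along the branch (approximates vessel volume)."""
    return float(sum(graph.radius(n) for n in branch.nodes))


def tortuosity(branch: Branch, graph: VesselGraph) -> float:
    """Arc length over chord length of the branch node path (>= 1)."""
    if len(branch.nodes) < 2:
        raise ValueError(f"branch {branch.id}: tortuosity needs >= 2 nodes")
    P = np.array([graph.position(n) for n in branch.nodes])
    arc = float(np.sum(np.linalg.norm(np.diff(P, axis=0), axis=1)))
    chord = float(np.linalg.norm(P[-1] - P[0]))
    if chord == 0.0:
        raise ValueError(
            f"branch {branch.id}: coincident endpoints, tortuosity undefined"
        )
    return arc / chord


def annotate_features(branches: list[Branch], graph: VesselGraph) -> list[Branch]:
    """Fill the three matching features in place (single-node branches get
    tortuosity 1.0 by convention)."""
    for b in branches:
        b.forward_direction = forward_direction(graph, b)
        b.sum_radius = sum_radius(b, graph)
        b.tortuosity = tortuosity(b, graph) if len(b.nodes) >= 2 else 1.0
    return branches


def branch_table_tsv(branches: list[Branch], graph: VesselGraph) -> str:
    lines = ["branch_id\tkind\tanchor\ttortuosity\tsum_radius\tforward_direction"]
    for b in branches:
        fd = b.forward_direction
        fd_s = f"{fd:.4f}" if np.isscalar(fd) else ",".join(f"{c:.4f}" for c in fd)
        lines.append(
            f"{b.id}\t{b.kind}\t{b.anchor}\t{b.tortuosity:.4f}\t{b.sum_radius:.4f}\t{fd_s}"
        )
    return "\n".join(lines) + "\n"
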