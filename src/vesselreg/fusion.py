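"""Assemble the fused graph.

Matched sensed nodes are placed on the reference frame: a node's voltage
difference is read as the fractional deviation along the straight segment
between its leading and succeeding reference nodes, measured from the base
node.  Each placed node records a deviation vector (fused position minus the
original sensed position, expressed in the reference frame).

Sensed branches that found no reference partner still carry unique
information: any such branch (or residual edge component) that touches an
already-placed node is shifted rigidly by that anchor's deviation vector and
kept.  Unreachable pieces are carried over untransformed and flagged.  The
reference graph passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .decomposition import Branch
from .graphio import VesselGraph, graph_to_dict
from .node_matching import NodeMatch

__all__ = ["FusedNode", "FusedGraph", "interpolate_position", "fuse",
           "registration_error", "correspondence_tsv"]

MATCHED = "matched"
SHIFTED = "shifted"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class FusedNode:
    sensed_id: int
    position: np.ndarray       # fused position in the reference frame
    deviation: np.ndarray      # fused - original sensed position
    provenance: str            # matched | shifted | unplaced


@dataclass
class FusedGraph:
    reference: VesselGraph
    sensed: VesselGraph
    fused: dict[int, FusedNode]
    shifted_branch_offsets: dict[int, np.ndarray] = field(default_factory=dict)

    def provenance(self, sensed_id: int) -> str:
        return self.fused[sensed_id].provenance

    def to_dict(self) -> dict:
        return {
            "reference": graph_to_dict(self.reference),
            "sensed_edges": [[a, b] for a, b in self.sensed.edges()],
            "fused_nodes": [
                {
                    "sensed_id": i,
                    "pos": [float(c) for c in f.position],
                    "deviation": [float(c) for c in f.deviation],
                    "radius": float(self.sensed.radius(i)),
                    "provenance": f.provenance,
                }
                for i, f in sorted(self.fused.items())
            ],
        }


def interpolate_position(
    ref_branch: Branch, match: NodeMatch, graph_ref: VesselGraph
) -> np.ndarray:
    """Fused position of one matched sensed node.

    The voltage difference is the fractional offset from the base node toward
    the other bracketing node along the straight segment between them;
    clamped matches sit exactly on the base node.
    """
    nodes = ref_branch.nodes
    base = nodes[match.base]
    p_base = graph_ref.position(base)
    if match.clamped or match.delta_v == 0.0:
        return p_base.copy()
    other_idx = match.leading + 1 if match.base == match.leading else match.leading
    p_other = graph_ref.position(nodes[other_idx])
    return p_base + match.delta_v * (p_other - p_base)


def fuse(
    ref_graph: VesselGraph,
    sensed_graph: VesselGraph,
    ref_branches: list[Branch],
    sensed_branches: list[Branch],
    branch_pairs,
    node_matches: dict[int, list[NodeMatch]],
    unmatched_sensed_branches: list[int],
    salient_pairs=(),
) -> FusedGraph:
    """Build the fusion of a registered pair.

    ``node_matches`` maps a reference branch id to the per-node matches of
    its paired sensed branch.  Matched salient points are placed directly on
    their reference partners.  Every sensed node appears exactly once in the
    output, tagged matched, shifted or unplaced.
    """
    ref_by_id = {b.id: b for b in ref_branches}
    sen_by_id = {b.id: b for b in sensed_branches}
    fused: dict[int, FusedNode] = {}

    def place(sid: int, pos: np.ndarray, prov: str) -> None:
        dev = pos - sensed_graph.position(sid)
        fused[sid] = FusedNode(sid, np.asarray(pos, float), dev, prov)

    for sp in salient_pairs:
        place(sp.sensed_id, ref_graph.position(sp.ref_id), MATCHED)

    for bp in branch_pairs:
        rb = ref_by_id[bp.ref_id]
        sb = sen_by_id[bp.sensed_id]
        for m in node_matches.get(bp.ref_id, []):
            sid = sb.nodes[m.sensed_index]
            if sid in fused:
                continue
            place(sid, interpolate_position(rb, m, ref_graph), MATCHED)

    # --- shift unique sensed structure by its anchor's deviation ----------
    pending: list[set[int]] = []
    for bid in unmatched_sensed_branches:
        pending.append(set(sen_by_id[bid].nodes) - set(fused))
    placed_edges = {
        e for b in sensed_branches for e in b.edge_set
    }
    residual_edges = {
        frozenset((a, b)) for a, b in sensed_graph.edges()
    } - placed_edges
    if residual_edges:
        rg = nx.Graph(tuple(e) for e in residual_edges)
        for comp in nx.connected_components(rg):
            comp = set(comp) - set(fused)
            if comp:
                pending.append(comp)

    # anchor each component at an adjacent placed node (least motion wins);
    # iterate so pieces may chain onto freshly shifted structure
    progress = True
    while progress and pending:
        progress = False
        remaining = []
        for comp in pending:
            anchors = []
            for v in comp:
                for u in sensed_graph.neighbors(v):
                    if u in fused:
                        anchors.append(fused[u].deviation)
            if anchors:
                offset = min(anchors, key=lambda d: float(np.linalg.norm(d)))
                for v in sorted(comp):
                    if v not in fused:
                        place(v, sensed_graph.position(v) + offset, SHIFTED)
                progress = True
            else:
                remaining.append(comp)
        pending = remaining

    for comp in pending:
        for v in sorted(comp):
            if v not in fused:
                place(v, sensed_graph.position(v), UNPLACED)
    for v in sensed_graph.node_ids:  # stray nodes not on any branch
        if v not in fused:
            place(v, sensed_graph.position(v), UNPLACED)

    offsets = {}
    for bid in unmatched_sensed_branches:
        nodes = sen_by_id[bid].nodes
        if nodes and all(fused[v].provenance == SHIFTED for v in nodes):
            offsets[bid] = fused[nodes[0]].deviation
    return FusedGraph(ref_graph, sensed_graph, fused, offsets)


def registration_error(fused: FusedGraph, ground_truth: dict[int, np.ndarray],
                       tolerance: float | None = None) -> dict:
    """Per-node Euclidean error between fused and true positions.

    ``ground_truth`` maps sensed node ids to their true corresponding
    positions (available for synthetic runs).  Nodes absent from either side
    are ignored; statistics cover the overlap only.
    """
    errs = []
    for sid, true_pos in ground_truth.items():
        f = fused.fused.get(sid)
        if f is None:
            continue
        errs.append(float(np.linalg.norm(f.position - np.asarray(true_pos, float))))
    if not errs:
        raise ValueError("no overlap between fused nodes and ground truth")
    errs = np.array(errs)
    out = {
        "n": int(errs.size),
        "mean": float(errs.mean()),
        "median": float(np.median(errs)),
        "max": float(errs.max()),
    }
    if tolerance is not None:
        out["within_tolerance"] = float(np.mean(errs <= tolerance))
        out["tolerance"] = float(tolerance)
    return out


def write_vtk_polydata(fused: FusedGraph, path) -> None:
    """Write the fused graph as legacy ASCII VTK polydata for 3D viewing.

    Reference nodes come first, then fused sensed nodes; edges become line
    cells, and radius plus provenance (0 reference, 1 matched, 2 shifted,
    3 unplaced) are attached as point data.
    """
    ref, sen = fused.reference, fused.sensed
    prov_code = {MATCHED: 1, SHIFTED: 2, UNPLACED: 3}

    def lift(p):
        return (*p, 0.0) if len(p) == 2 else tuple(p)

    points, radii, prov = [], [], []
    index: dict[tuple[str, int], int] = {}
    for i in ref.node_ids:
        index[("r", i)] = len(points)
        points.append(lift(ref.position(i)))
        radii.append(ref.radius(i))
        prov.append(0)
    for i, f in sorted(fused.fused.items()):
        index[("s", i)] = len(points)
        points.append(lift(f.position))
        radii.append(sen.radius(i))
        prov.append(prov_code[f.provenance])
    lines = [(index[("r", a)], index[("r", b)]) for a, b in ref.edges()]
    lines += [(index[("s", a)], index[("s", b)]) for a, b in sen.edges()]

    out = [
        "# vtk DataFile Version 3.0",
        "fused vessel graph",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
        *(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in points),
        f"LINES {len(lines)} {3 * len(lines)}",
        *(f"2 {a} {b}" for a, b in lines),
        f"POINT_DATA {len(points)}",
        "SCALARS radius float 1",
        "LOOKUP_TABLE default",
        *(f"{r:.6f}" for r in radii),
        "SCALARS provenance int 1",
        "LOOKUP_TABLE default",
        *(str(p) for p in prov),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def correspondence_tsv(fused: FusedGraph) -> str:
    dim = fused.reference.dim
    dcols = "\t".join(f"d{c}" for c in "xyz"[:dim])
    lines = [f"sensed_id\tprovenance\t{dcols}"]
    for sid, f in sorted(fused.fused.items()):
        dev = "\t".join(f"{c:.6g}" for c in f.deviation)
        lines.append(f"{sid}\t{f.provenance}\t{dev}")
    return "\n".join(lines) + "\n"
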