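"""Ground-truthed synthetic vascular trees and deformed/corrupted copies.

The generator emulates the kind of traced centerline pair the registration
method is designed for: a bifurcating 2D (or 3D) vascular tree of roughly
90-150 nodes whose sensed copy differs from the reference by a smooth
non-linear spatial warp, per-node radius noise, a few small interference
branches attached near bifurcations, and deleted sub-branches.  Every sensed
node that survives keeps its source node's id, so the returned correspondence
map is simply identity on the surviving ids.

All randomness flows from the explicit seed in each config; there is no
hidden global state, and a fixed seed reproduces the graphs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graphio import VesselGraph, VesselNode

__all__ = ["TreeConfig", "DeformConfig", "DeformInfo", "generate_tree", "deform",
           "ground_truth_tsv"]


@dataclass(frozen=True)
class TreeConfig:
    """Geometry of one synthetic bifurcating tree.

    ``depth`` counts segment levels: a tree of depth d has 2**d - 1 segments
    (trunk, then d-1 rounds of two-way splits).  Segment length shrinks by
    ``length_decay`` per level, as in real vascular trees, while the
    centerline sampling interval stays constant (trunk length divided by
    ``nodes_per_segment``), so deeper segments carry fewer nodes.  The
    defaults produce a 2D tree of ~115-125 nodes with branches of roughly
    5-15 centerline points, the scale of traced vascular networks the
    registration method targets.  Lengths are in arbitrary image units.
    """

    dim: int = 2
    depth: int = 4                   # segment levels; 2**depth - 1 segments
    segment_length: float = 11.0     # trunk length (mean)
    segment_length_sd: float = 1.1
    length_decay: float = 0.72       # child segment length = parent level * decay
    nodes_per_segment: int = 16      # trunk nodes; sets the sampling interval
    root_radius: float = 2.5
    radius_decay: float = 0.8        # child radius = parent * decay (jittered)
    radius_jitter: float = 0.03
    curvature: float = 0.08          # transverse sine amplitude, fraction of length
    branch_angle: float = 35.0       # half-opening angle at bifurcations, degrees
    angle_jitter: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        for name in ("radius_decay", "length_decay"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("segment_length", "nodes_per_segment", "root_radius", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DeformConfig:
    """Corruptions applied to produce the sensed copy.

    Defaults state the standard test condition: warp of at most 5% of the
    image extent, 10% fractional radius noise, 1-3 interference spurs near
    bifurcations, and exactly one deleted leaf branch.  ``leaf_deletion_prob``
    offers a per-branch random alternative to the exact deletion count.
    """

    warp_amplitude: float = 0.05     # max displacement, fraction of extent
    warp_scale: float = 0.5          # bump width, fraction of extent
    n_warp_bumps: int = 3
    radius_noise_sd: float = 0.10    # fractional, per node
    min_spurs: int = 1
    max_spurs: int = 3
    spur_nodes: int = 2
    n_leaf_deletions: int = 1
    leaf_deletion_prob: float | None = None  # overrides n_leaf_deletions if set
    seed: int = 0

    def __post_init__(self):
        if self.warp_amplitude < 0 or self.radius_noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.leaf_deletion_prob is not None and not 0 <= self.leaf_deletion_prob <= 1:
            raise ValueError("leaf_deletion_prob must be in [0, 1]")


@dataclass
class DeformInfo:
    """Bookkeeping for the corruptions, so tests can reason about them."""

    deleted_nodes: set[int] = field(default_factory=set)
    affected_junctions: set[int] = field(default_factory=set)
    spur_nodes: set[int] = field(default_factory=set)
    spur_attachments: set[int] = field(default_factory=set)
    max_displacement: float = 0.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rot2(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def generate_tree(config: TreeConfig) -> VesselGraph:
    """Grow a connected bifurcating tree, radii decaying root to leaf."""
    rng = np.random.default_rng(config.seed)
    g = VesselGraph()
    next_id = [0]

    def new_node(pos, radius) -> int:
        nid = next_id[0]
        next_id[0] += 1
        g.add_node(VesselNode(nid, tuple(float(c) for c in pos), float(radius)))
        return nid

    spacing = config.segment_length / config.nodes_per_segment

    def grow_segment(start_id, start_pos, direction, radius, level):
        """One centerline segment; returns its terminal node id/pos."""
        mean_len = config.segment_length * config.length_decay**level
        sd = config.segment_length_sd * config.length_decay**level
        length = max(0.4 * mean_len, rng.normal(mean_len, sd))
        n = max(4, round(length / spacing))
        direction = _unit(np.asarray(direction, float))
        # transverse unit vector for in-plane curvature
        if config.dim == 2:
            perp = np.array([-direction[1], direction[0]])
        else:
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(ref, direction)) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            perp = _unit(np.cross(direction, ref))
        amp = config.curvature * length * rng.uniform(0.3, 1.0) * rng.choice([-1, 1])
        prev = start_id
        pos = np.asarray(start_pos, float)
        for i in range(1, n + 1):
            t = i / n
            # sine bow: zero offset at both segment endpoints
            p = pos + t * length * direction + amp * math.sin(math.pi * t) * perp
            r = radius * (1 + rng.normal(0, config.radius_jitter))
            nid = new_node(p, max(r, 0.05 * config.root_radius))
            g.add_edge(prev, nid)
            prev = nid
        return prev, g.position(prev)

    root_dir = np.zeros(config.dim)
    root_dir[-1] = 1.0
    root = new_node(np.zeros(config.dim), config.root_radius)
    frontier = [(root, np.zeros(config.dim), root_dir, config.root_radius)]
    # trunk level 0, then depth-1 rounds of bifurcation
    for level in range(config.depth):
        new_frontier = []
        for nid, pos, direction, radius in frontier:
            end_id, end_pos = grow_segment(nid, pos, direction, radius, level)
            if level == config.depth - 1:
                continue
            for sign in (-1.0, +1.0):
                ang = sign * (config.branch_angle + rng.normal(0, config.angle_jitter))
                if config.dim == 2:
                    d = _rot2(ang) @ _unit(direction)
                else:
                    # rotate in the plane spanned by direction and a random
                    # transverse axis
                    axis = rng.normal(size=3)
                    axis -= axis.dot(_unit(direction)) * _unit(direction)
                    axis = _unit(axis)
                    a = math.radians(ang)
                    d = math.cos(a) * _unit(direction) + math.sin(a) * axis
                child_r = radius * config.radius_decay * (
                    1 + rng.normal(0, config.radius_jitter)
                )
                new_frontier.append((end_id, end_pos, d, child_r))
        frontier = new_frontier

    if g.n_nodes < 3:
        raise ValueError("config produces fewer than 3 nodes")
    return g


def _leaf_branches(graph: VesselGraph) -> list[list[int]]:
    """Paths from each leaf back to (but excluding) the nearest bifurcation."""
    out = []
    for leaf in graph.node_ids:
        if graph.degree(leaf) != 1:
            continue
        path = [leaf]
        prev, cur = None, leaf
        while graph.degree(cur) <= 2:
            nbrs = [u for u in graph.neighbors(cur) if u != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            if graph.degree(cur) <= 2:
                path.append(cur)
        if graph.degree(cur) >= 3:
            out.append((path, cur))
    return out


def deform(
    graph: VesselGraph, config: DeformConfig
) -> tuple[VesselGraph, dict[int, int], DeformInfo]:
    """Produce the sensed copy of a reference tree.

    Returns ``(sensed, correspondence, info)`` where ``correspondence`` maps
    every surviving sensed node id to its source reference id.  The warp is a
    sum of smooth radial bump displacement fields rescaled so the maximum
    node displacement equals ``warp_amplitude * extent`` (diffeomorphic at
    the amplitudes used here); spurs are short, thin chains attached one to
    two nodes away from randomly chosen bifurcations.
    """
    rng = np.random.default_rng(config.seed)
    info = DeformInfo()
    extent = graph.max_extent
    dim = graph.dim
    P = {i: graph.position(i) for i in graph.node_ids}
    allpos = np.array([P[i] for i in graph.node_ids])
    lo, hi = allpos.min(axis=0), allpos.max(axis=0)

    # ---- smooth warp ----------------------------------------------------
    disp = {i: np.zeros(dim) for i in graph.node_ids}
    if config.warp_amplitude > 0 and extent > 0:
        sigma = config.warp_scale * extent
        for _ in range(config.n_warp_bumps):
            center = rng.uniform(lo, hi)
            direction = _unit(rng.normal(size=dim))
            weight = rng.uniform(0.5, 1.0)
            for i in graph.node_ids:
                w = math.exp(-float(np.sum((P[i] - center) ** 2)) / (2 * sigma**2))
                disp[i] = disp[i] + weight * w * direction
        peak = max(float(np.linalg.norm(d)) for d in disp.values())
        if peak > 0:
            scale = config.warp_amplitude * extent / peak
            disp = {i: d * scale for i, d in disp.items()}
        info.max_displacement = max(float(np.linalg.norm(d)) for d in disp.values())

    # ---- select leaf branches to delete ---------------------------------
    branches = _leaf_branches(graph)
    delete: list[tuple[list[int], int]] = []
    if config.leaf_deletion_prob is not None:
        for path, junction in branches:
            if rng.uniform() < config.leaf_deletion_prob:
                delete.append((path, junction))
    elif config.n_leaf_deletions > 0 and branches:
        k = min(config.n_leaf_deletions, len(branches))
        idx = rng.choice(len(branches), size=k, replace=False)
        delete = [branches[i] for i in sorted(idx)]
    for path, junction in delete:
        info.deleted_nodes |= set(path)
        info.affected_junctions.add(junction)

    # ---- build sensed graph ---------------------------------------------
    sensed = VesselGraph()
    corr: dict[int, int] = {}
    for i in graph.node_ids:
        if i in info.deleted_nodes:
            continue
        r = graph.radius(i) * (1 + rng.normal(0, config.radius_noise_sd))
        r = max(r, 0.02 * graph.radius(i))
        sensed.add_node(VesselNode(i, tuple(float(c) for c in (P[i] + disp[i])), r))
        corr[i] = i
    for a, b in graph.edges():
        if a in info.deleted_nodes or b in info.deleted_nodes:
            continue
        sensed.add_edge(a, b)

    # ---- interference spurs near bifurcations ----------------------------
    bifs = [i for i in sensed.node_ids if sensed.degree(i) >= 3]
    n_spurs = int(rng.integers(config.min_spurs, config.max_spurs + 1)) if bifs else 0
    next_id = max(graph.node_ids) + 1
    for _ in range(n_spurs):
        b = int(bifs[rng.integers(len(bifs))])
        # attach 1-2 nodes away from the bifurcation
        attach = b
        for _ in range(int(rng.integers(1, 3))):
            nbrs = sensed.neighbors(attach)
            attach = int(nbrs[rng.integers(len(nbrs))])
        base_pos = sensed.position(attach)
        direction = _unit(rng.normal(size=dim))
        step = 0.08 * extent / max(config.spur_nodes, 1)
        spur_r = 0.3 * sensed.radius(attach)
        prev = attach
        for s in range(1, config.spur_nodes + 1):
            nid = next_id
            next_id += 1
            pos = base_pos + s * step * direction
            sensed.add_node(VesselNode(nid, tuple(float(c) for c in pos),
                                       max(spur_r, 1e-3)))
            sensed.add_edge(prev, nid)
            info.spur_nodes.add(nid)
            prev = nid
        info.spur_attachments.add(attach)

    return sensed, corr, info


def ground_truth_tsv(corr: dict[int, int]) -> str:
    lines = ["sensed_id\tref_id"]
    for s, r in sorted(corr.items()):
        lines.append(f"{s}\t{r}")
    return "\n".join(lines) + "\n"
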