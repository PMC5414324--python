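"""End-to-end registration: the full pipeline behind the CLI.

Load graphs -> NSI -> salient-point matching -> decomposition -> sequential
branch matching -> circuit conversion -> voltage-based node matching ->
fusion.  All tunable parameters live in :class:`RunConfig`; results are
collected in a :class:`RegistrationResult` that exposes the intermediate
products (salient pairs, branches, branch pairs, node matches) alongside the
fused graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import branch_matching, circuit, decomposition, fusion, node_matching, nsi
from .graphio import VesselGraph, drop_small_components

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RegistrationResult", "NoSalientPairsError", "register"]


class NoSalientPairsError(RuntimeError):
    """No salient-point correspondences were found; registration cannot
    proceed (e.g. under a large initial rotation that pushes every
    corresponding salient point beyond the allowable distance)."""


@dataclass(frozen=True)
class RunConfig:
    neighborhood_frac: float = 0.05   # salient search radius, fraction of extent
    max_angle: float = 60.0           # max allowable forward-direction difference
    radius_tol: float = 0.30          # allowable relative sum-radius difference
    search_frac: float = 0.20         # node-matching window, fraction of branch
    nsi_h: int = 2
    nsi_lambda: float = 0.5
    topology: str = "series_loop"
    seed: int = 0

    def __post_init__(self):
        for name in ("neighborhood_frac", "radius_tol", "search_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.max_angle <= 180:
            raise ValueError("max_angle must be in (0, 180]")


@dataclass
class RegistrationResult:
    config: RunConfig
    ref: VesselGraph
    sensed: VesselGraph
    ref_scores: nsi.NsiScores
    sensed_scores: nsi.NsiScores
    salient_pairs: list
    ref_branches: list
    sensed_branches: list
    branch_pairs: list
    unmatched_ref_branches: list
    unmatched_sensed_branches: list
    node_matches: dict
    fused: fusion.FusedGraph
    voltage_sequences: dict = field(default_factory=dict)


def _branch_voltages(branches, graph, scores, topology):
    """Integrated-voltage magnitude per branch id (None when degenerate)."""
    out = {}
    for b in branches:
        try:
            circ = circuit.branch_to_circuit(b, graph, scores, topology=topology)
            out[b.id] = circuit.integrated_voltage_sequence(circ)
        except (circuit.SingularLoopError, ValueError) as exc:
            logger.warning("branch %d: circuit skipped (%s)", b.id, exc)
            out[b.id] = None
    return out


def _proportional_fallback(n_ref: int, n_sensed: int):
    """Index-proportional clamped matches when voltage matching is degenerate."""
    out = []
    for i in range(n_sensed):
        j = int(round(i * (n_ref - 1) / (n_sensed - 1))) if n_sensed > 1 else 0
        out.append(node_matching.NodeMatch(i, j, 0.0, j, clamped=True))
    return out


def register(
    ref: VesselGraph, sensed: VesselGraph, config: RunConfig = RunConfig()
) -> RegistrationResult:
    """Register ``sensed`` onto ``ref`` and build the fused graph."""
    ref = drop_small_components(ref)
    sensed = drop_small_components(sensed)

    ref_scores = nsi.compute_nsi(ref, h=config.nsi_h, lam=config.nsi_lambda)
    sen_scores = nsi.compute_nsi(sensed, h=config.nsi_h, lam=config.nsi_lambda)
    pairs = nsi.match_salient_points(
        ref, sensed, ref_scores, sen_scores, rho_frac=config.neighborhood_frac
    )
    if not pairs:
        raise NoSalientPairsError(
            "no corresponding structurally salient points found"
        )
    logger.info("%d salient pair(s)", len(pairs))

    # orient salient-to-salient branches consistently on both sides: the
    # endpoint whose pair has the larger reference-side NSI anchors the branch
    ref_prio = {p.ref_id: p.ref_nsi for p in pairs}
    sen_prio = {p.sensed_id: p.ref_nsi for p in pairs}
    ref_branches, ref_residual = decomposition.decompose(
        ref, set(ref_prio), anchor_priority=ref_prio
    )
    sen_branches, sen_residual = decomposition.decompose(
        sensed, set(sen_prio), anchor_priority=sen_prio
    )
    decomposition.annotate_features(ref_branches, ref)
    decomposition.annotate_features(sen_branches, sensed)

    branch_pairs, unmatched_ref, unmatched_sen = branch_matching.match_branches(
        ref_branches, sen_branches, pairs,
        max_angle=config.max_angle, radius_tol=config.radius_tol,
    )
    logger.info(
        "%d branch pair(s); %d reference / %d sensed unmatched",
        len(branch_pairs), len(unmatched_ref), len(unmatched_sen),
    )

    ref_v = _branch_voltages(ref_branches, ref, ref_scores, config.topology)
    sen_v = _branch_voltages(sen_branches, sensed, sen_scores, config.topology)

    ref_by_id = {b.id: b for b in ref_branches}
    sen_by_id = {b.id: b for b in sen_branches}
    matches: dict[int, list] = {}
    for bp in branch_pairs:
        va_seq, vb_seq = ref_v[bp.ref_id], sen_v[bp.sensed_id]
        n_ref = len(ref_by_id[bp.ref_id].nodes)
        n_sen = len(sen_by_id[bp.sensed_id].nodes)
        if va_seq is None or vb_seq is None or n_ref < 2 or n_sen < 2:
            matches[bp.ref_id] = _proportional_fallback(n_ref, n_sen)
            continue
        try:
            _, vb_scaled = node_matching.scale_sequence(
                vb_seq.magnitude, va_seq.magnitude
            )
            matches[bp.ref_id] = node_matching.match_nodes(
                va_seq.magnitude, vb_scaled, w_frac=config.search_frac
            )
        except ValueError as exc:
            logger.warning(
                "branch pair (%d, %d): voltage matching degenerate (%s); "
                "falling back to proportional mapping",
                bp.ref_id, bp.sensed_id, exc,
            )
            matches[bp.ref_id] = _proportional_fallback(n_ref, n_sen)

    fused = fusion.fuse(
        ref, sensed, ref_branches, sen_branches, branch_pairs, matches,
        unmatched_sen, salient_pairs=pairs,
    )
    return RegistrationResult(
        config=config, ref=ref, sensed=sensed,
        ref_scores=ref_scores, sensed_scores=sen_scores,
        salient_pairs=pairs,
        ref_branches=ref_branches, sensed_branches=sen_branches,
        branch_pairs=branch_pairs,
        unmatched_ref_branches=unmatched_ref,
        unmatched_sensed_branches=unmatched_sen,
        node_matches=matches, fused=fused,
        voltage_sequences={"ref": ref_v, "sensed": sen_v},
    )
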