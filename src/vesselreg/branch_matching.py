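"""Sequential branch matching.

Reference and sensed branches are paired group-by-group: the candidates for a
reference branch are the sensed branches anchored at the sensed partner of
its anchoring salient point.  Salient-to-salient branches whose two endpoint
pairs correspond are matched outright; everything else runs through the
sequential criteria, each consulted only when the previous one is not
discriminative enough:

1. forward direction   — keep candidates within the maximum allowable angular
   difference (60 degrees by default); a unique survivor matches;
2. sum of node radii   — a unique candidate within the allowable relative
   difference (30% by default) matches;
3. tortuosity          — otherwise the survivor with the closest tortuosity
   matches (relative comparison only, no threshold).

Unmatched branches are a normal outcome: they carry unique structure and are
routed to fusion, never force-matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decomposition import Branch, KIND_SALIENT
from .nsi import SalientPair

__all__ = ["BranchPair", "angular_difference", "match_branches", "pairing_report_tsv"]


@dataclass(frozen=True)
class BranchPair:
    ref_id: int
    sensed_id: int
    decided_by: str  # endpoint | direction | radius | tortuosity


def angular_difference(a, b) -> float:
    """Unsigned difference between two forward directions, in degrees [0, 180].

    2D directions are CCW angles in degrees (wraparound metric); 3D
    directions are unit vectors (arccos of the clamped dot product).
    """
    if np.isscalar(a) != np.isscalar(b):
        raise ValueError("cannot mix 2D angle and 3D vector directions")
    if np.isscalar(a):
        d = abs(float(a) - float(b)) % 360.0
        return min(d, 360.0 - d)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-length direction vector")
    cosang = float(np.clip(np.dot(a / na, b / nb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def match_branches(
    ref_branches: list[Branch],
    sensed_branches: list[Branch],
    salient_pairs: list[SalientPair],
    max_angle: float = 60.0,
    radius_tol: float = 0.30,
) -> tuple[list[BranchPair], list[int], list[int]]:
    """Pair branches of the two graphs by the sequential criteria.

    Returns ``(pairs, unmatched_ref_ids, unmatched_sensed_ids)``.  Matched
    sensed branches are removed from the candidate pool as soon as they are
    claimed, so the outcome is deterministic: groups are processed in
    ascending reference branch id, and exact tortuosity ties resolve to the
    smaller sensed branch id.
    """
    ref_to_sensed = {p.ref_id: p.sensed_id for p in salient_pairs}
    pairs: list[BranchPair] = []
    taken: set[int] = set()

    by_sensed_anchor: dict[int, list[Branch]] = {}
    for sb in sensed_branches:
        by_sensed_anchor.setdefault(sb.anchor, []).append(sb)

    def endpoint_key(b: Branch, mapped: bool):
        a = ref_to_sensed.get(b.anchor, b.anchor) if mapped else b.anchor
        t = b.terminal
        if t is not None and mapped:
            t = ref_to_sensed.get(t, t)
        return (a, t)

    # Stage 0: salient-to-salient branches with corresponding endpoint pairs.
    sensed_k1: dict[tuple, list[Branch]] = {}
    for sb in sensed_branches:
        if sb.kind == KIND_SALIENT:
            sensed_k1.setdefault(endpoint_key(sb, mapped=False), []).append(sb)
    for rb in sorted(ref_branches, key=lambda b: b.id):
        if rb.kind != KIND_SALIENT:
            continue
        if rb.anchor not in ref_to_sensed or rb.terminal not in ref_to_sensed:
            continue
        cands = [
            sb for sb in sensed_k1.get(endpoint_key(rb, mapped=True), [])
            if sb.id not in taken
        ]
        if len(cands) == 1:
            pairs.append(BranchPair(rb.id, cands[0].id, "endpoint"))
            taken.add(cands[0].id)
        # several sensed branches share both endpoints: fall through to the
        # sequential criteria below

    matched_ref = {p.ref_id for p in pairs}

    # Stages 1-3: sequential criteria within each anchor's candidate group.
    for rb in sorted(ref_branches, key=lambda b: b.id):
        if rb.id in matched_ref:
            continue
        s_anchor = ref_to_sensed.get(rb.anchor)
        if s_anchor is None:
            continue
        group = [
            sb for sb in by_sensed_anchor.get(s_anchor, []) if sb.id not in taken
        ]
        if rb.kind == KIND_SALIENT:
            # endpoints must still correspond for salient-to-salient branches
            group = [
                sb for sb in group
                if sb.kind == KIND_SALIENT
                and endpoint_key(sb, mapped=False) == endpoint_key(rb, mapped=True)
            ]

        survivors = [
            sb for sb in group
            if angular_difference(rb.forward_direction, sb.forward_direction)
            <= max_angle
        ]
        if not survivors:
            continue
        if len(survivors) == 1:
            pairs.append(BranchPair(rb.id, survivors[0].id, "direction"))
            taken.add(survivors[0].id)
            continue

        within_radius = [
            sb for sb in survivors
            if abs(sb.sum_radius - rb.sum_radius) / rb.sum_radius <= radius_tol
        ]
        if len(within_radius) == 1:
            pairs.append(BranchPair(rb.id, within_radius[0].id, "radius"))
            taken.add(within_radius[0].id)
            continue

        pool = within_radius if within_radius else survivors
        best = min(pool, key=lambda sb: (abs(sb.tortuosity - rb.tortuosity), sb.id))
        pairs.append(BranchPair(rb.id, best.id, "tortuosity"))
        taken.add(best.id)

    matched_ref = {p.ref_id for p in pairs}
    unmatched_ref = sorted(b.id for b in ref_branches if b.id not in matched_ref)
    unmatched_sensed = sorted(b.id for b in sensed_branches if b.id not in taken)
    return pairs, unmatched_ref, unmatched_sensed


def pairing_report_tsv(
    pairs: list[BranchPair],
    ref_branches: list[Branch],
    sensed_branches: list[Branch],
) -> str:
    ref = {b.id: b for b in ref_branches}
    sen = {b.id: b for b in sensed_branches}
    lines = [
        "ref_branch\tsensed_branch\tdecided_by\tdirection_diff\tradius_diff_frac\ttortuosity_diff"
    ]
    for p in pairs:
        rb, sb = ref[p.ref_id], sen[p.sensed_id]
        dd = angular_difference(rb.forward_direction, sb.forward_direction)
        rd = abs(sb.sum_radius - rb.sum_radius) / rb.sum_radius
        td = abs(sb.tortuosity - rb.tortuosity)
        lines.append(
            f"{p.ref_id}\t{p.sensed_id}\t{p.decided_by}\t{dd:.4f}\t{rd:.4f}\t{td:.4f}"
        )
    return "\n".join(lines) + "\n"
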