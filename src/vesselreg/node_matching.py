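"""Node matching within a pair of branches via scaled voltage sequences.

The sensed branch's integrated-voltage magnitudes V_b are first linearly
scaled so their range coincides with the reference branch's range V_a
(V_b' = k*V_b + b).  Each sensed node then searches a close region of the
reference sequence (a window of 20% of the branch's node count by default,
centered on its proportional position) for the leading node j that brackets
its scaled voltage:

    V_aj <= V_bi' < V_a(j+1)        (increasing reference sequence)
    V_aj >= V_bi' > V_a(j+1)        (decreasing reference sequence)

The fractional offsets dV1 = (V_bi' - V_aj)/(V_a(j+1) - V_aj) and
dV2 = 1 - dV1 pick the voltage-difference base node: j when dV1 <= dV2,
else j+1, with the voltage difference min(dV1, dV2) <= 0.5.  Matching acts
on magnitudes only; the argument stays a diagnostic channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingParams", "NodeMatch", "scale_sequence", "match_nodes",
           "match_table_tsv"]


@dataclass(frozen=True)
class ScalingParams:
    gain: float
    offset: float


@dataclass(frozen=True)
class NodeMatch:
    sensed_index: int
    leading: int          # reference index j
    delta_v: float        # in [0, 0.5]; fraction of the bracket interval
    base: int             # j or j+1
    clamped: bool = False # no bracket found; snapped to nearest-by-value node


def scale_sequence(Vb, Va) -> tuple[ScalingParams, np.ndarray]:
    """Affine map sending [min Vb, max Vb] onto [min Va, max Va]."""
    Vb = np.asarray(Vb, dtype=float)
    Va = np.asarray(Va, dtype=float)
    if Vb.size == 0 or Va.size == 0:
        raise ValueError("sequences must be nonempty")
    lo_b, hi_b = float(Vb.min()), float(Vb.max())
    lo_a, hi_a = float(Va.min()), float(Va.max())
    if hi_b == lo_b:
        raise ValueError("degenerate sensed sequence (zero range)")
    gain = (hi_a - lo_a) / (hi_b - lo_b)
    offset = lo_a - gain * lo_b
    return ScalingParams(gain, offset), gain * Vb + offset


def _window(center: int, half: int, n: int) -> range:
    lo = max(0, center - half)
    hi = min(n - 1, center + half)
    return range(lo, hi + 1)


def match_nodes(Va, Vb_scaled, w_frac: float = 0.20) -> list[NodeMatch]:
    """Match every sensed node into the reference voltage sequence.

    The search window is centered on the sensed node's proportional position
    ``round(i * (len(Va)-1) / (len(Vb)-1))`` with total width ``w_frac *
    len(Va)`` (minimum 3 nodes).  Sensed nodes with no bracketing reference
    pair in their window clamp to the window's nearest-by-value node with a
    zero voltage difference and a warning flag.  Monotonicity direction is
    taken from the reference sequence's first and last values.
    """
    Va = np.asarray(Va, dtype=float)
    Vb = np.asarray(Vb_scaled, dtype=float)
    na, nb = len(Va), len(Vb)
    if na == 0 or nb == 0:
        raise ValueError("sequences must be nonempty")
    decreasing = Va[-1] < Va[0]
    half = max(1, int(round(0.5 * w_frac * na)))

    out: list[NodeMatch] = []
    for i in range(nb):
        center = int(round(i * (na - 1) / (nb - 1))) if nb > 1 else 0
        win = _window(center, half, na)
        v = Vb[i]
        best = None  # (dist_to_center, j, dv1)
        for j in win:
            if j + 1 >= na:
                continue
            a0, a1 = Va[j], Va[j + 1]
            if decreasing:
                ok = a0 >= v > a1
            else:
                ok = a0 <= v < a1
            if not ok:
                continue
            dv1 = abs((v - a0) / (a1 - a0))
            cand = (abs(j - center), j, dv1)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            # exact hit on a window node (incl. the terminal value) is a
            # clean zero-difference match, not a clamp
            exact = [j for j in win if Va[j] == v]
            if exact:
                j = min(exact, key=lambda j: abs(j - center))
                out.append(NodeMatch(i, j, 0.0, j, clamped=False))
            else:
                j = min(win, key=lambda j: (abs(Va[j] - v), abs(j - center)))
                out.append(NodeMatch(i, j, 0.0, j, clamped=True))
            continue
        _, j, dv1 = best
        dv2 = 1.0 - dv1
        if dv1 <= dv2:
            out.append(NodeMatch(i, j, dv1, j))
        else:
            out.append(NodeMatch(i, j, dv2, j + 1))
    return out


def match_table_tsv(matches: list[NodeMatch]) -> str:
    lines = ["sensed_index\tleading_node\tvoltage_difference\tbase_node\tclamped"]
    for m in matches:
        lines.append(
            f"{m.sensed_index}\t{m.leading}\t{100*m.delta_v:.2f}%\t{m.base}\t{int(m.clamped)}"
        )
    return "\n".join(lines) + "\n"
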