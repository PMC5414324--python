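"""Generic complex modified nodal analysis (MNA).

An independent phasor circuit solver used to cross-check the closed-form
series-loop solution in :mod:`vesselreg.circuit`.  It knows nothing about
that closed form: it assembles the standard MNA linear system

    [ G  B ] [ v ]   [ 0 ]
    [ B' 0 ] [ i ] = [ e ]

from an explicit netlist of two-terminal impedances and ideal voltage
sources, and solves it densely with numpy.  Any connected netlist with a
ground node is accepted.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_netlist", "series_loop_probe_voltages"]


def solve_netlist(impedances, vsources, ground):
    """Solve a phasor netlist by modified nodal analysis.

    Parameters
    ----------
    impedances : iterable of (node_a, node_b, Z) with complex Z != 0.
    vsources : iterable of (node_minus, node_plus, E); ideal sources enforcing
        ``v(node_plus) - v(node_minus) = E``.
    ground : the reference node (voltage 0).

    Returns
    -------
    dict mapping every node to its complex voltage.
    """
    impedances = list(impedances)
    vsources = list(vsources)
    nodes: list = []
    seen = set()
    for a, b, _ in impedances + vsources:
        for t in (a, b):
            if t not in seen:
                seen.add(t)
                nodes.append(t)
    if ground not in seen:
        raise ValueError("ground node does not appear in the netlist")

    unknown = [t for t in nodes if t != ground]
    idx = {t: i for i, t in enumerate(unknown)}
    nv, ns = len(unknown), len(vsources)
    A = np.zeros((nv + ns, nv + ns), dtype=complex)
    rhs = np.zeros(nv + ns, dtype=complex)

    for a, b, Z in impedances:
        if Z == 0:
            raise ValueError("zero impedance element")
        y = 1.0 / Z
        if a != ground:
            A[idx[a], idx[a]] += y
        if b != ground:
            A[idx[b], idx[b]] += y
        if a != ground and b != ground:
            A[idx[a], idx[b]] -= y
            A[idx[b], idx[a]] -= y

    for s, (a, b, E) in enumerate(vsources):
        row = nv + s
        if b != ground:
            A[idx[b], row] += 1.0
            A[row, idx[b]] += 1.0
        if a != ground:
            A[idx[a], row] -= 1.0
            A[row, idx[a]] -= 1.0
        rhs[row] = E

    x = np.linalg.solve(A, rhs)
    out = {ground: 0.0 + 0.0j}
    for t, i in idx.items():
        out[t] = x[i]
    return out


def series_loop_probe_voltages(E, Z, active) -> np.ndarray:
    """Probe voltages of the series-loop netlist via generic MNA.

    The loop chains segments (source E_k, then impedance Z_k) through
    junctions J_0 .. J_n with J_n identified with the grounded J_0; the probe
    for node k sits between E_k and Z_k.  ``active`` selects which sources
    are on (an index, or an iterable of indices); inactive sources are
    short-circuited ideal sources with E = 0.
    """
    E = np.asarray(E, dtype=float)
    Z = np.asarray(Z, dtype=complex)
    n = len(E)
    if np.isscalar(active):
        active_set = {int(active)}
    else:
        active_set = {int(a) for a in active}

    def junction(k):  # J_n wraps to ground J_0
        return ("J", k % n)

    imps = [(("P", k), junction(k + 1), Z[k]) for k in range(n)]
    srcs = [
        (junction(k), ("P", k), E[k] if k in active_set else 0.0)
        for k in range(n)
    ]
    sol = solve_netlist(imps, srcs, ground=("J", 0))
    return np.array([sol[("P", k)] for k in range(n)])
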