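"""Electrical image of a vessel branch and its integrated voltage sequence.

Each node k of a branch becomes a group of circuit elements: a real voltage
source whose magnitude is the node's NSI, plus a complex impedance carrying
the node's geometry,

    Z_k = r_k * cos(theta_k) + j * r_k * sin(theta_k),        |Z_k| = r_k,

where r_k is the vessel radius and theta_k the deviation angle between the
node's local forward direction and the whole-branch direction.  The real part
is a resistance, the imaginary part an inductive reactance at the fixed
angular frequency omega = 1 rad/s (omega is a free gauge: only the product
omega*L is constrained).

The default wiring is a single series loop closed through ground: segments
(source E_k, then Z_k) are chained junction to junction, and the probe for
node k sits between E_k and Z_k.  With only source j active the loop current
is E_j / Z_tot and the probe voltage has the closed form

    v_k^(j) = E_j * ([j <= k] - S_k / Z_tot),    S_k = sum_{m<k} Z_m,

which the generic nodal-analysis solver in :mod:`vesselreg.mna` reproduces
independently.  Exciting the sources one at a time and averaging all
responses collected up to each node's own excitation gives the integrated
voltage sequence

    V~_k = mean(E_1..E_k) * (1 - S_k / Z_tot),

the branch's matching signal: its magnitude falls with cumulative vessel
thickness (a fast drop marks a fast trend toward a thinner area) and its
argument bends where the branch turns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .decomposition import Branch
from .graphio import VesselGraph
from .nsi import NsiScores

__all__ = [
    "CircuitBranch",
    "VoltageSequence",
    "SequenceDiagnostics",
    "SingularLoopError",
    "node_impedance",
    "deviation_angle",
    "branch_to_circuit",
    "solve_single_source",
    "solve_all_sources",
    "integrated_voltage_sequence",
    "sequence_diagnostics",
    "voltage_sequence_tsv",
]

#: scale-free guard for the division by the loop impedance
SINGULAR_TOL = 1e-9


class SingularLoopError(ValueError):
    """The total loop impedance is numerically zero; the loop is unsolvable."""


def node_impedance(r: float, theta: float) -> complex:
    """Impedance of one node: ``r*cos(theta) + j*r*sin(theta)``.

    ``theta`` is the unsigned deviation angle in radians, in [0, pi]; the
    imaginary (inductive) part is therefore non-negative.  Values of theta
    beyond pi/2 yield a negative resistance, which the series loop tolerates.
    """
    if r <= 0:
        raise ValueError(f"radius must be > 0, got {r}")
    return complex(r * math.cos(theta), r * math.sin(theta))


def deviation_angle(branch: Branch, graph: VesselGraph, k: int) -> float:
    """Unsigned angle in [0, pi] between node k's local forward direction and
    the whole-branch direction (first node to last node).

    The local forward vector at node k points to node k+1; the last node
    reuses the preceding segment.  Single-node branches have theta = 0.
    """
    nodes = branch.nodes
    n = len(nodes)
    if not 0 <= k < n:
        raise IndexError(f"node index {k} out of range for branch of {n} nodes")
    if n == 1:
        return 0.0
    P = [graph.position(i) for i in nodes]
    if k < n - 1:
        local = P[k + 1] - P[k]
    else:
        local = P[n - 1] - P[n - 2]
    whole = P[n - 1] - P[0]
    nl, nw = np.linalg.norm(local), np.linalg.norm(whole)
    if nl == 0.0:
        raise ValueError(
            f"branch {branch.id}: coincident consecutive nodes at index {k}"
        )
    if nw == 0.0:
        raise ValueError(f"branch {branch.id}: coincident branch endpoints")
    cosang = float(np.clip(np.dot(local / nl, whole / nw), -1.0, 1.0))
    return math.acos(cosang)


@dataclass
class CircuitBranch:
    """Per-node sources and impedances of one branch, in branch order."""

    E: np.ndarray        # real source magnitudes (NSI values), phase 0
    Z: np.ndarray        # complex impedances, |Z_k| = r_k
    theta: np.ndarray    # deviation angles, radians
    radii: np.ndarray
    branch_id: int | None = None
    topology: str = "series_loop"

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.Z = np.asarray(self.Z, dtype=complex)
        self.theta = np.asarray(self.theta, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not (len(self.E) == len(self.Z) == len(self.theta) == len(self.radii)):
            raise ValueError("E, Z, theta, radii must have equal length")
        if len(self.E) == 0:
            raise ValueError("empty circuit")

    @property
    def n(self) -> int:
        return len(self.E)

    @property
    def z_total(self) -> complex:
        return complex(np.sum(self.Z))

    def check_solvable(self) -> None:
        if abs(self.z_total) <= SINGULAR_TOL * float(np.sum(np.abs(self.Z))):
            name = "" if self.branch_id is None else f" (branch {self.branch_id})"
            raise SingularLoopError(
                f"near-singular loop impedance |Z_tot| = {abs(self.z_total):.3e}{name}"
            )


def branch_to_circuit(
    branch: Branch, graph: VesselGraph, nsi: NsiScores, topology: str = "series_loop"
) -> CircuitBranch:
    """Convert a branch into its electrical image (order follows the branch)."""
    if not branch.nodes:
        raise ValueError(f"branch {branch.id}: empty")
    radii = np.array([graph.radius(i) for i in branch.nodes])
    theta = np.array(
        [deviation_angle(branch, graph, k) for k in range(len(branch.nodes))]
    )
    Z = np.array([node_impedance(r, t) for r, t in zip(radii, theta)])
    E = np.array([nsi[i] for i in branch.nodes], dtype=float)
    circ = CircuitBranch(E, Z, theta, radii, branch_id=branch.id, topology=topology)
    circ.check_solvable()
    return circ


# ---------------------------------------------------------------------------
# Solvers (closed form; the generic MNA oracle lives in vesselreg.mna)
# ---------------------------------------------------------------------------

def _prefix_sums(Z: np.ndarray) -> np.ndarray:
    """S_k = sum of Z_m for m < k (S_0 = 0), length n."""
    return np.concatenate(([0.0 + 0.0j], np.cumsum(Z)[:-1]))


def _series_loop_single(circ: CircuitBranch, j: int) -> np.ndarray:
    S = _prefix_sums(circ.Z)
    k = np.arange(circ.n)
    return circ.E[j] * ((j <= k).astype(float) - S / circ.z_total)


_TOPOLOGIES: dict[str, Callable[[CircuitBranch, int], np.ndarray]] = {
    "series_loop": _series_loop_single,
}


def solve_single_source(circuit: CircuitBranch, j: int) -> np.ndarray:
    """Probe voltages at every node with only source ``j`` (0-based) active."""
    if not 0 <= j < circuit.n:
        raise IndexError(f"source index {j} out of range")
    circuit.check_solvable()
    try:
        fn = _TOPOLOGIES[circuit.topology]
    except KeyError:
        raise ValueError(f"unknown circuit topology {circuit.topology!r}") from None
    return fn(circuit, j)


def solve_all_sources(circuit: CircuitBranch) -> np.ndarray:
    """Probe voltages with every source active simultaneously.

    By superposition this equals the sum of the single-source responses; it
    is computed directly from the closed form so the property is testable.
    """
    circuit.check_solvable()
    S = _prefix_sums(circuit.Z)
    k = np.arange(circuit.n)
    # sum_j E_j * ([j <= k] - S_k/Z_tot)
    csum = np.cumsum(circuit.E)
    return csum - circuit.E.sum() * S / circuit.z_total


@dataclass
class VoltageSequence:
    """Complex integrated voltage per branch node, plus scalar views."""

    values: np.ndarray
    branch_id: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def argument(self) -> np.ndarray:
        """Phase per node, unwrapped along the branch."""
        return np.unwrap(np.angle(self.values))


def integrated_voltage_sequence(circuit: CircuitBranch) -> VoltageSequence:
    """The branch's matching signal.

    Node k averages the steady-state responses to excitations 1..k inclusive:
    ``V~_k = (1/k) * sum_{j<=k} v_k^(j) = mean(E_1..E_k) * (1 - S_k/Z_tot)``.
    ``V~_1 = E_1`` exactly.
    """
    circuit.check_solvable()
    S = _prefix_sums(circuit.Z)
    running_mean = np.cumsum(circuit.E) / np.arange(1, circuit.n + 1)
    return VoltageSequence(
        running_mean * (1.0 - S / circuit.z_total), branch_id=circuit.branch_id
    )


@dataclass
class SequenceDiagnostics:
    """First differences of |V~| and unwrapped arg(V~), with peak locations."""

    magnitude_gradient: np.ndarray
    argument_gradient: np.ndarray
    peak_magnitude_gradient: int
    peak_argument_gradient: int


def sequence_diagnostics(seq: VoltageSequence) -> SequenceDiagnostics:
    """Gradient views of a voltage sequence.

    A fast descent of the magnitude gradient marks a fast trend toward a
    thinner vessel area; an evident change in the argument marks a large
    turning point of the branch.
    """
    if len(seq) < 2:
        raise ValueError("diagnostics need a sequence of >= 2 nodes")
    mg = np.diff(seq.magnitude)
    ag = np.diff(seq.argument)
    return SequenceDiagnostics(
        magnitude_gradient=mg,
        argument_gradient=ag,
        peak_magnitude_gradient=int(np.argmax(np.abs(mg))),
        peak_argument_gradient=int(np.argmax(np.abs(ag))),
    )


def voltage_sequence_tsv(seq: VoltageSequence) -> str:
    lines = ["index\tre\tim\tmagnitude\targument"]
    arg = seq.argument
    for k, v in enumerate(seq.values):
        lines.append(f"{k}\t{v.real:.8g}\t{v.imag:.8g}\t{abs(v):.8g}\t{arg[k]:.8g}")
    return "\n".join(lines) + "\n"
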