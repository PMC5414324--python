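# Methods

This note records the model behind `vesselreg`, the parameters that matter,
the numerical conventions, and the design choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

Two centerline tracings of the same vasculature are given as spatial graphs:
nodes with 2D/3D positions and radii, undirected edges along vessel paths.
The method assumes

* the two graphs overlap structurally (shared main bifurcations), with
  differences limited to smooth non-linear deformation, radius measurement
  noise, small interference branches, and missing sub-branches;
* the initial misalignment is small relative to the salient-point search
  neighborhood — under a large initial rotation or translation no salient
  pairs are found and the pipeline aborts with a diagnostic rather than
  guessing;
* coordinates are continuous physical/image units.  No voxel convention
  applies because the method never touches the raster; tracing is upstream.

Isolated connected components of fewer than 3 nodes are dropped with a
warning before registration: they are indistinguishable from tracing noise.

## Network Structure Index

NSI(v) = Σ over u with hop distance d(v,u) ≤ h of r(u)·deg(u)·λ^d, including
u = v at d = 0.  Defaults h = 2, λ = 0.5.  The index uses only topology and
radii, so it is rigid-motion invariant, linear in a global radius scale, and
local: nodes beyond the h-hop ball cannot affect a score (the practical
advantage over betweenness centrality, which needs the whole network and
degrades when structure is missing).  The formula is a named strategy
(`vesselreg.nsi.NSI_STRATEGIES`) so an alternative weighting can be dropped
in without touching callers.

Salient candidates are all degree ≥ 3 nodes.  The matching neighborhood is a
Euclidean ball of radius ρ = 0.05 × the largest bounding-box edge of the
*reference* graph ("5% of image size", adjustable via
`RunConfig.neighborhood_frac`).  A reference candidate qualifies only if it
is the NSI maximum among reference candidates within ρ of itself; it pairs
with the highest-NSI sensed candidate within ρ of its own position.
Conflicts resolve greedily in descending reference NSI, giving a
deterministic one-to-one pairing.  Two consequences worth noting:

* interference junctions near a true bifurcation are suppressed on both
  sides (low NSI, not local maxima);
* a bifurcation that lost an arm in the sensed image falls to degree 2
  there, leaves its reference twin unpaired, and the structure behind it is
  handled by composite branches and fusion-time shifting (below).

Hop distance defines the NSI neighborhood; physical distance defines the
matching neighborhood.  The first is a topology index, the second a spatial
search — mixing the two conventions is intentional.

## Decomposition

Only *matched* salient nodes act as path barriers.  Salient-to-salient
branches are extracted first (hop-shortest salient-free path per matched
pair, deterministic smallest-id tie-break), then salient-to-leaf branches;
every edge belongs to at most one branch.  Where several leaves share a path
prefix (behind a bifurcation that failed to match), leaves are claimed in
descending hop distance: the long trunk vessel wins the shared prefix and
short interference spurs fall into the residual edge set.  Unclaimed edges
(spurs, arms behind unmatched bifurcations, degenerate salient-salient
edges with no interior node) are returned as the residual set and reach
fusion as unmatched structure.

A branch's node list excludes its anchoring salient endpoints.
Salient-to-salient branches are oriented so that the endpoint whose salient
pair carries the higher reference-side NSI anchors the branch — computed
from the pair table on both graphs, which keeps the two sides consistently
oriented.  Single-node branches (a leaf adjacent to a salient point) are
allowed and get tortuosity 1 by convention.

Branch features: forward direction (2D: CCW degrees from +x in [0, 360);
3D: unit vector) of the anchor-to-first-node step; sum of node radii (a
volume proxy); tortuosity = arc length / chord length ≥ 1, with equality
exactly for collinear branches.

## Sequential branch matching

Candidates for a reference branch are sensed branches anchored at the
sensed partner of its anchor.  Salient-to-salient branches whose two
endpoint pairs correspond match outright.  Otherwise: keep candidates
within 60° forward-direction difference (wraparound metric in 2D, arccos of
unit-vector dot product in 3D); a unique survivor matches.  Among several,
a unique candidate within 30% relative sum-radius difference matches.
Otherwise the candidate with the nearest tortuosity wins (relative
comparison only; exact ties go to the smaller sensed id).  Matched sensed
branches leave the pool immediately; groups are processed in ascending
reference branch id, so the outcome is order-independent.  Reference
branches with no survivor stay unmatched — they carry unique information
and are never force-matched.  Both thresholds are `RunConfig` parameters.

## Circuit model

Each branch node k becomes a segment of an electrical loop: a real voltage
source E_k equal to the node's NSI, in series with the impedance

    Z_k = r_k cos θ_k + j r_k sin θ_k,     |Z_k| = r_k,

where θ_k ∈ [0, π] is the unsigned angle between the node's local forward
direction (node k to k+1; the last node reuses the preceding segment) and
the whole-branch direction.  The real part is a resistance, the imaginary
part an inductive reactance; ω is fixed at 1 rad/s because only the product
ωL is constrained — ω is a free gauge.  θ is unsigned in both 2D and 3D for
a single cross-dimensional convention, making the inductance non-negative;
θ > π/2 yields a negative resistance, which the loop algebra tolerates.

**Topology.**  Segments (E_k then Z_k) chain through junctions
J_0 → … → J_n with J_n = J_0 grounded — a single series loop — and the
probe for node k sits between E_k and Z_k.  With source j alone active the
loop current is E_j/Z_tot and

    v_k^(j) = E_j ([j ≤ k] − S_k / Z_tot),   S_k = Σ_{m<k} Z_m.

The excitation schedule activates one source at a time; node k's integrated
voltage averages the responses to excitations 1..k inclusive:

    Ṽ_k = mean(E_1..E_k) (1 − S_k / Z_tot),

so Ṽ_1 = E_1 exactly and |Ṽ| is strictly decreasing along a straight
constant-source branch.  A ladder topology with shunt paths would damp
faults harder; the solver is a pluggable strategy
(`vesselreg.circuit._TOPOLOGIES`) so such a variant can be added, and the
series loop is the default because it admits the exact closed form and
reproduces all the qualitative signal properties (thickness → magnitude
slope, turning → argument bend, fault confinement toward the branch end).

**Numerical guards.**  The loop is rejected as singular when
|Z_tot| ≤ 10⁻⁹ Σ|Z_k| — a scale-free guard on the division by Z_tot.
The closed form is verified against `vesselreg.mna`, an independent generic
complex modified-nodal-analysis solver that assembles and densely solves
the standard MNA system from an explicit netlist; the two code paths share
nothing but numpy.

**Fault tolerance.**  On a straight constant-source branch, crushing one
interior radius leaves Ṽ_1 exactly unchanged and produces a relative
magnitude change that is non-decreasing along the branch with its maximum
at the final node, provided the fault sits in the first half of the
branch's radius mass (Σ_{m≥fault} r_m ≥ Z_tot/2) — behind the fault the
change is the constant δ/(Z_tot−δ).  The acceptance script reports this
profile for a 34-node branch with the 10th radius crushed from 2.2037 to
0.01.

## Node matching

Matching operates on |Ṽ|; the argument stays a diagnostic channel, because
the bracketing inequalities and percentage differences presuppose a scalar
ordering and magnitude/argument behave as separate scalar channels.  The
sensed magnitudes are affinely mapped so their [min, max] coincides with
the reference range (a constant sensed sequence is degenerate and rejected;
the pipeline then falls back to proportional index mapping with a warning
flag, as it does for single-node branches).

Each sensed index i searches a window centered on its proportional position
round(i·(n_a−1)/(n_b−1)) with total width 20% of the reference branch
length, minimum 3 nodes, for the leading node j with V_aj ≤ V_bi′ < V_a(j+1)
(inequalities flipped for decreasing sequences; the direction is read off
the reference sequence's endpoints).  ΔV₁ = (V_bi′−V_aj)/(V_a(j+1)−V_aj)
and ΔV₂ = 1−ΔV₁ select the base node (j if ΔV₁ ≤ ΔV₂, else j+1, ties to j)
and the reported difference min(ΔV₁, ΔV₂) ≤ 0.5.  A sensed value with no
bracket in its window — off the end of the reference range, or drifted past
the window — clamps to the window's nearest-by-value node with ΔV = 0 and a
flag; an exact hit on a window node (including the terminal value) is a
clean zero-difference match, not a clamp.

## Fusion

A matched sensed node is placed at base + ΔV·(other − base) along the
straight segment between its bracketing reference nodes; its deviation
vector (fused − original sensed position) is expressed in the reference
frame.  Matched salient nodes land exactly on their reference partners.
Unmatched sensed branches translate rigidly by their anchor's deviation;
residual components anchor on any adjacent already-placed node, least
deviation magnitude first, iterating so pieces may chain; anything still
unreachable is carried untransformed and flagged.  Every sensed node
appears exactly once, tagged matched / shifted / unplaced.  For curved
reference segments the placement is purely along the leading-to-succeeding
chord; transverse residuals are not modeled.

## Synthetic data

`generate_tree` grows a 2D (optionally 3D) bifurcating tree: a trunk and
depth−1 rounds of two-way splits at ±35° ± 6°, segment length shrinking by
0.72 per level from 11 units at the trunk (10% length jitter), constant
centerline sampling interval (11/16 units), radii decaying by 0.8 per level
from 2.5 with 3% per-node jitter, and a transverse sine bow (8% of segment
length) for curvature.  The defaults give trees of ~116–130 nodes with
branches of roughly 5–15 nodes and 7 bifurcations — the branch statistics
of the traced vascular networks the method targets, where matched branches
run from a handful of nodes to a few dozen.

`deform` produces the sensed copy: a smooth warp (sum of 3 Gaussian radial
bumps, width 0.5 × extent, rescaled so the maximum node displacement equals
5% of the extent — diffeomorphic at this amplitude), 10% fractional radius
noise, exactly one deleted leaf branch (a per-branch deletion probability is
available as an alternative), and 1–3 interference spurs: short chains of 2
thin nodes (30% of local radius) attached one to two hops from a randomly
chosen bifurcation.  Surviving nodes keep their ids, so the ground-truth
correspondence is identity on the survivors; spur nodes are excluded from
it.  All randomness flows from the explicit seed in each config.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: tracing artifacts (gaps, doubled centerlines),
cycles (the readers accept them; the generator never produces them),
anisotropic 3D sampling, radius bias correlated with vessel direction, and
deformations larger than the salient search radius.  The identity and
recovery results bound behavior under the modeled corruption classes only.

## Sensitivities and limitations

* **Excitation distortion.**  Ṽ_k carries the running mean of the NSI
  excitations, so a corrupted NSI near a branch's *start* (e.g. a spur
  attached at its first node raises that node's degree and neighborhood
  sum) biases the whole sequence and can shift node matches by one to two
  positions.  Faults further along a branch are increasingly harmless.
* **Symmetric sibling arms.**  When a bifurcation loses an arm in one
  image, the decomposition on the intact side must route the composite
  branch through one of the surviving arms; if the siblings are nearly
  symmetric in direction, radius and tortuosity, the sequential criteria
  cannot tell them apart and the suffix may be placed on the wrong arm.
  The affected nodes are confined beyond the weakened junction.
* **Initial alignment.**  Salient pairing searches a 5%-extent ball around
  each reference candidate; rotations or shifts beyond it yield no pairs
  and an explicit failure.
* Problem sizes throughout (trees of ~120 nodes, 20-seed recovery runs,
  200-branch oracle sweeps) are chosen to match the scale of the traced
  networks the method targets while keeping the full suite fast enough to
  run on every change.
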