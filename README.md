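# vesselreg

Registration of vascular centerline graphs by network saliency and circuit
simulation.

Clinicians and image-analysis pipelines often need to bring two tracings of
the same vasculature — a retinal fundus pair, two time-of-flight MRA scans of
the same brain region — into a single fused view.  Intensity- and
feature-based registration struggles here: vessels carry few stable
keypoints, tracings differ non-linearly, small interference branches sprout
near bifurcations, and whole sub-branches can be missing from one image.
`vesselreg` registers the *graphs* instead: vessel centerlines with node
positions, radii and connectivity (SWC files or a small JSON dialect; 2D and
3D alike).  Tracing raster images into centerlines is upstream of this
package.

## Method

Given a reference graph and a sensed graph, the pipeline runs five stages:

1. **Network Structure Index (NSI).**  Each node v gets a saliency score
   combining its weight (vessel radius), its degree, and the decayed
   contribution of its neighborhood,

   NSI(v) = Σ_{d(v,u) ≤ h} r(u) · deg(u) · λ^d(v,u),   (h = 2, λ = 0.5)

   with d the hop distance.  Structurally salient points are bifurcations
   (degree ≥ 3) whose NSI is the local maximum within 5% of the image
   extent; each reference local maximum pairs with the largest-NSI sensed
   candidate in range.  Low-NSI interference junctions are suppressed by the
   local-maximum rule.
2. **Decomposition.**  Each graph splits into salient-free branches:
   salient-to-salient paths, then salient-to-leaf paths, edge-disjointly.
3. **Sequential branch matching.**  Candidate branches anchored at
   corresponding salient points are filtered by forward direction (≤ 60°),
   then sum of node radii (≤ 30% relative difference), then nearest
   tortuosity (arc/chord ratio).
4. **Circuit conversion.**  Each branch node k becomes a voltage source
   E_k = NSI(k) in series with the impedance Z_k = r_k·cos θ_k + j·r_k·sin θ_k,
   where θ_k is the node's deviation from the whole-branch direction — a
   resistance plus an inductance at ω = 1 rad/s.  The elements form a series
   loop; exciting the sources one at a time and averaging the responses up
   to each node's own excitation yields the *integrated voltage sequence*
   Ṽ_k = mean(E_1..E_k) · (1 − S_k/Z_tot), the branch's matching signal.
   Its magnitude falls with cumulative vessel thickness; its argument bends
   where the vessel turns.
5. **Node matching and fusion.**  Sensed voltage magnitudes are linearly
   scaled onto the reference range; each sensed node finds the reference
   pair (V_aj, V_a(j+1)) bracketing its value inside a 20% search window and
   is placed at the fractional position ΔV between them.  Unmatched sensed
   branches shift rigidly by their anchor's deviation vector; the reference
   graph passes through unchanged.

A generic complex nodal-analysis solver (`vesselreg.mna`) provides an
independent oracle for the closed-form circuit solution, and
`vesselreg.synthetic` generates ground-truthed bifurcating trees with smooth
non-linear warps, radius noise, interference spurs and deleted branches for
end-to-end validation.

## Worked example

Simulate a reference/sensed pair, register it, and score the result against
the generated ground truth:

```sh
$ vesselreg simulate --out demo --seed 11
reference: 123 nodes | sensed: 121 nodes (6 deleted, 4 spur) -> demo/

$ vesselreg register --reference demo/reference.json \
                     --sensed demo/sensed.json --out demo/fused.json
salient pairs: 6 | branch pairs: 13 | matched nodes: 117/121 | fused graph: demo/fused.json

$ vesselreg evaluate --fused demo/fused.json --truth demo/truth.tsv
n=117 mean=0.2339 median=0.0728 max=4.7121 within_2%_extent=94.0%
```

The sensed copy lost one leaf branch (6 nodes) and gained two interference
spurs (4 nodes) on top of a smooth warp and 10% radius noise.  Six salient
bifurcations were paired, 13 branches matched, and 117 of the 121 sensed
nodes were placed on the reference frame; 94% of the ground-truth
correspondences land within 2% of the image extent (mean error 0.23 image
units).  `register` also writes TSV reports next to the fused graph: the
salient pairs with their NSI values, the branch feature table (tortuosity,
sum radius, forward direction), the branch pairing report with the deciding
criterion, and the per-node correspondence table with deviation vectors.

The library mirrors the CLI one-to-one:

```python
from vesselreg import TreeConfig, DeformConfig, generate_tree, deform, register

ref = generate_tree(TreeConfig(seed=11))
sensed, truth_map, info = deform(ref, DeformConfig(seed=12))
result = register(ref, sensed)
result.salient_pairs, result.branch_pairs, result.fused
```

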