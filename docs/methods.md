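# Methods

`surfaceid` encodes fixed-radius geodesic patches of a protein's
molecular surface into descriptors with a contrastively trained
geodesic convolutional network, then finds, groups, scores and rigidly
aligns similar surface regions between proteins.  This note documents
the model, the numerical choices, and what the synthetic study
conditions do and do not establish.

## Surface construction and featurization

The molecular surface is built as a Gaussian-density isosurface: each
atom contributes an isotropic Gaussian of width `(r_atom + probe)/2`,
the summed density is sampled on a regular grid (voxel pitch =
`target_edge_len`, default 1.0 Å) and contoured by marching cubes at
isovalue `e^-2`, so a lone atom yields a sphere of radius exactly
`r_atom + probe` (verified to 0.05 % in area at 0.5 Å pitch).  Only
the largest connected component is kept; the result is watertight with
outward normals.  `probe = 1.4 Å` approximates a water-probe surface,
`probe = 0` the van der Waals envelope.  Because the density grid is
axis-aligned, strict feature equivariance under rigid motion holds
exactly for whole-voxel translations and up to re-meshing jitter
otherwise; the per-vertex features themselves depend only on the local
geometry and the atoms, not on the grid orientation.

Five per-vertex channels are computed:

* **shape_index** `s = (2/π)·atan((κ1+κ2)/(κ1−κ2))`, with principal
  curvatures `κ = H ± sqrt(H²−K)` from the cotangent-Laplacian mean
  curvature `H` (sign convention: convex positive) and the angle-defect
  Gaussian curvature `K`.  Umbilic vertices (κ1 ≈ κ2) get `sign(κ1)`,
  never NaN; the channel is clipped to [−1, 1].
* **mean_curvature** `(κ1+κ2)/2` in Å⁻¹.
* **charge** — a distance-weighted partial-charge sum
  `Σ q_a/(1+d²)` over atoms within 8 Å, with a small fixed per-atom
  charge table (ionizable side chains ±, backbone amide dipole).  This
  is a deliberately simplified Coulomb-like field, not a
  Poisson–Boltzmann potential; since every channel is standardized per
  protein, only its sign structure and relative magnitude matter.
* **hydropathy** — Kyte–Doolittle value of the nearest atom's residue.
* **hbond** — +1/−1/0 from the nearest heavy atom's donor/acceptor
  class (amide and side-chain N donors +1; carbonyl/carboxyl O
  acceptors −1; ambivalent hydroxyls 0).  When hydrogens are present in
  the input they are kept, but no protonation is performed.

All channels are standardized per protein (zero mean, unit variance;
constant channels are only centered) and the (μ, σ) pairs are recorded
in the mesh metadata.

## Patches and the soft polar grid

A patch is every vertex within a 6 Å geodesic radius of a center — the
minimum unit on which the network convolves.  Geodesic distance is the
Dijkstra metric on the mesh edge graph; it upper-bounds the Euclidean
distance and is exact along lattice directions (on a spoke-triangulated
flat disc the radial distances are exact).  The angular coordinate θ is
obtained by projecting patch vertices into the tangent plane at the
center (normal = area-weighted vertex normal), with the zero direction
anchored at the projected edge to the lowest-index neighbor.  This
origin is arbitrary but deterministic, smooth over the whole patch
rather than only the 1-ring, and exactly covariant under rigid motion;
the encoder's rotation max-pooling absorbs the residual origin
ambiguity.

Patch vertices are projected onto a 5 × 16 (radial × angular) soft
pixel grid: vertex `v` contributes to bin `k` with weight
`∝ exp(−(ρ_v−ρ̄_k)²/2σ_ρ²)·exp(−Δθ²/2σ_θ²)` (angular difference
wrapped to [−π, π]), each vertex row normalized to sum 1 in shifted log
space.  Pooled bin values are weight-normalized feature averages, so
they are independent of mesh resolution.  Bin centers and widths live
in the model state; the default training keeps them fixed (widths =
half the bin spacing), which lets the pooled patch tensors be
precomputed once per corpus — the main reason CPU-only training of the
desk-scale corpus takes minutes.  Treating them as trainable is a
config-level extension, not the default.

## Encoder and contrastive objective

Architecture (all sizes config-exposed): two per-bin 1×1 filter layers
(5→16→8 channels, ReLU), then a rotation layer that applies a dense
readout of the 5×16×8 grid under all 16 discrete angular rotations and
max-pools over them, followed by ReLU and a linear head to the 80-dim
descriptor.  Because the rotation count equals the angular bin count,
shifting θ by any whole bin changes the descriptor only at float
round-off; descriptors are exactly invariant to vertex order and, via
ρ/θ invariance, to rigid motion of the protein.

Training pairs are sampled per surface: anchors uniformly without
replacement, one positive center within 1.5 Å (Euclidean), four
negative centers beyond 5 Å.  The loss is the margin hinge

    L = ‖a−p‖² + Σ_n max(0, margin − ‖a−n‖)²,  margin = 5,

the margin echoing the spatial negative cutoff so that the operational
descriptor cutoff of 3.5 sits between the positive and negative modes.
Optimization is minibatch Adam (lr 2·10⁻³, batch 64, ≤15 epochs,
early stopping on validation separation with the best-epoch parameters
kept).  Forward and backward passes are written directly on numpy
arrays (the rotation layer as one BLAS matmul over gathered rotations;
gradients verified against finite differences).  Data are split at the
structure level — a structure appearing in two splits is a hard error —
mirroring the original corpus design of 2700/100/50 structures at 200
patches each; the packaged study conditions use 50 synthetic surfaces
at 100 patches (40/5/5 split), which one CPU trains in ~2 minutes.

The distance report histograms positive vs negative pair distances on
the test split, computes their overlap coefficient (∫min of the two
densities) and suggests a classification threshold at the equal-density
crossing between the two modes (undefined, with a reason, when the
distributions are degenerate).  Measured on the packaged conditions:
held-out ROC-AUC ≈ 0.995, overlap ≈ 0.05, suggested threshold ≈ 3.1–3.2
— consistent with the fixed operational cutoff of 3.5.

## Search, grouping and scores

`find_hits` is an exact all-pairs descriptor search at cutoff 3.5 (no
approximate NN at desk scale).  Grouping turns scattered hits into
matched regions:

1. Every query vertex is assigned to its best (lowest-distance) hit,
   and every candidate vertex likewise; only hits that are best for
   *both* endpoints anchor the grouping graph.  The symmetric rule is
   essential: with ~3–6 % of unrelated patch pairs falling under any
   fixed cutoff by chance, an unfiltered hit graph percolates into one
   global component on whole-surface searches.
2. Two anchor hits are connected when their query vertices are within
   the neighbor radius (3 Å, Euclidean) *and* their candidate vertices
   are too, so groups are contiguous on both surfaces.
3. Components below `min_group_size` query vertices are discarded.
   `group_hits` defaults to 2 (exactly the singleton rule);
   region-level searches (`match_surfaces`) default to 10, i.e. a
   matched region must span about a patch-unit's worth of centers.  On
   planted-pair benchmarks spurious components measured ≤ 8 vertices
   while planted regions measured ≥ 19, across generator seeds and
   training seeds.
4. Surviving groups keep all hits of their member query vertices as
   correspondences for scoring and are extended by every vertex within
   6 Å geodesic distance of a member, on both surfaces.

Scores: the reciprocal-mean similarity `ss = 1/(1 + mean d)` maps mean
correspondence distance onto (0, 1] without a singularity at d = 0;
the joint interface score `SS_AB = ss_AB · ss_A′B′` multiplies the
similarities of the two partner sides of two interfaces (so both sides
must match); the coverage ratio — the fraction of an interface's
vertices covered by any extended group — drives epitope/paratope
clustering.  `all_vs_all` symmetrizes directed coverage by the mean,
then clusters with average linkage on (1 − score) at a configurable
cut.  Interface regions are defined by Euclidean distance to reference
atoms: 3.5 Å from interface residues for protein–protein queries, 2 Å
from CDR atoms for paratopes, 4.5 Å from the antibody for epitopes.

## Rigid alignment and grafting

Alignment of a matched region follows centroid superposition followed
by gradient descent of the RMSD over rotations: the loss depends on the
rotation only through `tr(R·M)` with `M = Σ q̃ᵢc̃ᵢᵀ` precomputed, the
gradient with respect to a left-multiplicative axis-angle increment is
estimated by central differences (ε = 10⁻⁵) on the three generators,
and steps are taken on SO(3) with backtracking; 8 seeded random
restarts plus the identity guard against local minima, so the result
can never exceed the centroid-only RMSD.  The closed-form Kabsch
solution exists for this objective and serves as the test oracle (the
gradient-descent result must match it to 10⁻³ Å); it is deliberately
not the production path.  The alignment score is
`(fraction of correspondences within 2 Å after alignment)/(1 + RMSD)` —
a stand-in for the original pipeline's supplementary alignment score,
with no claim of reproducing its published values.  The resulting
transform can be applied to any atom set (antibody grafting) and a
clash report lists interatomic pairs below a cutoff (default 2.5 Å).

## Synthetic study conditions

The generators provide all fixtures: icospheres (10·4ˢ+2 vertices),
bumpy spheres (radius 9 Å, subdivision 3 → 642 vertices, ~1.3 Å mean
edge; 40 seeded Gaussian bumps/dents of ≤1.2 Å amplitude and 2.5 Å
width so the whole surface carries texture, as real protein surfaces
do), and graph-smoothed Gaussian random feature fields (correlation
length 3 Å — iterated neighbor averaging with steps = correlation
length / mean edge; very long correlation lengths return exactly
constant channels).  A planted pair shares one 6 Å-radius cap between
two otherwise independent surfaces — geometry and features copied,
features perturbed with N(0, noise_sd), blended over a 2 Å smoothstep
band so no seam marks the region — with mesh B moved by a seeded rigid
transform and an antipodal same-size control cap recorded for
false-positive checks.  The default noise (0.1) represents measurement
noise well below the unit feature scale.  Toy peptides (backbone + CB
along an extended chain) exercise PDB parsing and meshing end to end.

What passing these conditions shows: the encoder separates overlapping
from distant patches on unseen surfaces, the search/group/align chain
recovers a planted common region at the operational cutoff without
flagging unrelated regions, and the alignment reproduces a known rigid
offset.  What they do not show: performance on real protein surfaces,
whose feature fields are richer than five smoothed Gaussian channels
and whose similar regions are near- rather than exactly-isometric; no
claim about the original publication's benchmark figures is made or
reproducible here.

## Numerical choices and degenerate inputs

* Curvature at vertices with near-zero mixed area is regularized with a
  1e-12 floor; shape index is clipped to [−1, 1].
* Soft-grid rows are normalized after a max shift in log space, so a
  vertex far from every bin still yields a valid distribution.
* Patches with fewer than 8 vertices raise ("too sparse"): the grid
  cannot be supported.
* Degenerate alignment inputs (k < 3, collinear, non-finite) raise;
  coincident negative descriptors contribute the hinge value with zero
  gradient direction.
* All generators, samplers and the trainer are pure functions of their
  seeds; training determinism is subject only to BLAS reduction order.
* Mesh PLY files store float32 (conventional PLY precision);
  write→read→write is bitwise stable.

## Known limitations

* Dijkstra overestimates true polyhedral geodesics off-lattice (up to
  ~15 % in the worst direction on a regular lattice); patch radii are
  small relative to curvature so the bias is shared by both members of
  a pair, but absolute ρ values should not be over-interpreted.
* The charge model ignores solvent screening and conformational
  protonation states.
* `min_group_size` trades recall for precision at region level; with
  very small genuine matched regions (< ~10 patch centers at 1.3 Å
  vertex spacing) it must be lowered.
* First NMR model only; no mmCIF, glycans, or ligand surfaces.
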