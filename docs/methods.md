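# Methods

`microconnectome` turns mesoscale constraints on cortical long-range
connectivity into statistical instances of a neuron-to-neuron connectome.
This note describes the models implemented, the parameters that matter, the
numerical choices made where the design was open, what the synthetic
fixtures do and do not emulate, and the known limitations.

## The modeling problem

Tracer-based mesoscale connectomes give region-to-region projection
strengths — a measure proportional to the mean volumetric density of
projection axons in each target region — for five projection classes of
source neurons (L2/3, L4, L5IT, L5PT, L6). Single-axon reconstructions show
that an individual neuron innervates only a subset of the regions its
population projects to (its *p-type*), with strong pairwise interactions.
The pipeline combines four constraint families into a generative recipe:

1. **Densities** — projection strengths scaled into volumetric synapse
   densities (µm⁻³) and split into per-class matrices.
2. **Layer profiles** — one of six prototype laminar profiles per
   projection.
3. **Topographic mapping** — a pair of barycentric coordinate systems per
   projection mapping source locations to target locations in a flattened
   (2-D) representation of the cortex, with a Gaussian kernel width for the
   spatial extent of single-axon arborization.
4. **P-types** — a directed tree over regions with per-edge crossing
   probabilities generating which region subsets single axons innervate.

A stochastic instantiation step then turns the recipe plus a neuron and
dendritic-segment table into a concrete synapse table.

## Synapse densities

The total cortical synapse count is mean density × volume
(0.72 µm⁻³ × 123.2 mm³ ≈ 8.87 × 10¹⁰). The long-range share is an explicit
configuration value (default 6.874 × 10¹⁰); the scaling factor σ solves

    σ · Σ_{a,b} (M_i + M_c)[a,b] · V[b] · C_t[a,b] = budget

exactly, with `V` the region volumes and `C_t` the target-coverage
fractions (default all ones). Within-region entries are forced to zero:
local connectivity is a separate problem, outside this model.

Class splitting scales module-to-module submatrices of the wild-type
matrix by per-class weights normalized to sum to 1 per module-block cell.
Conservation (Σ over classes = wild type) is enforced *bit-exactly* with
respect to sequential summation in class order: the final class absorbs
the float rounding residual, nudged by ulps where a single correction
still rounds away. Source regions lacking layer 4 have their L4 row zeroed
and that share absorbed by the residual class, so conservation still
holds.

The strength cutoff removes the weakest projections: the cutoff is the
largest value in the multiset of projection densities such that the
removed synapse count (density × target volume × coverage) stays strictly
below a loss bound (default 5%), evaluated after class splitting on the
per-class densities. Raising the cutoff to the next distinct density value
violates the bound by construction. Hemisphere symmetry is enforced by
averaging the nonzero members of each mirror-pair orbit, which copies
single-hemisphere data to the other side unchanged and leaves symmetric
input untouched.

## Layer profiles

Each projection gets one of six prototype profiles (relative density per
layer, thickness-weighted mean 1). The assignment combines (a) base
profile frequencies per projection class, (b) observed frequencies per
source module and intra-/inter-module kind, and (c) the
feedforward/feedback character from hierarchy scores (feedforward iff
source score ≤ target score; ties feedforward). Expected frequencies are
the projection-count-weighted average of class vectors; adjustment factors
are observed/expected (1 where both are zero; observed > 0 with zero
expectation is an input error). For feedforward projections the factors of
the feedback-type profiles (2, 4, 6) are halved, and vice versa — the
halving is applied to the adjustment factors, which can change the argmax
relative to halving frequencies. Ties break toward the lowest profile id.
Validation z-scores require at least five raw experimental profiles.

## Topographic mapping

Regions are flattened by an orthographic projection collapsing depth (the
fixtures' stand-in for a curvature-respecting flat map; the pipeline only
consumes the lookup interface). The source system picks the three region
pixels maximizing the sum of pairwise distances — the search is restricted
to convex-hull vertices, which provably contains the maximizer — then
moves each 25% toward the region-mask centroid.

The projection image assigns each source voxel the color of its
barycentric coordinates (clipped at zero); voxels with HSV saturation
below 0.5 are discarded because near-centroid colors carry no directional
information. Pixel colors are normalized by max(channel sum, σ_tgt) with
σ_tgt = 25% of the image's maximum channel sum, so weakly innervated
pixels fade to black.

The target system minimizes J = mean per-pixel L1 color difference between
the anchor-induced coloring and the normalized image **over bright pixels**
(channel sum ≥ 0.5 — dark pixels are dark by construction of the
saturation filter and carry no signal), plus λ (default 1) times the
fraction of the source region mapped outside the target mask. The
anchor-induced coloring is clipped at zero and renormalized to unit
channel sum, making model and data colors directly comparable. The
optimizer is Nelder–Mead (xatol = fatol = 1e−6) from 14+ restarts: the 8
axis-aligned rotation/reflection images of the source triangle centered on
the target (the orientation hypothesis class), the 6 label permutations of
the target's own geometric triangle, and seeded random perturbations.
Without the orientation hypotheses, rotated mappings converge to local
minima.

The Gaussian kernel width is chosen on a logarithmic grid (0 and 16 steps
from 0.25 to 32 pixels) minimizing the Kolmogorov–Smirnov distance between
the saturation distributions of the blurred model coloring and the data.
The relative error metric is Σ|M − N| divided by the mean of (M + N)/2 and
by the pixel count — zero iff identical, symmetric.

Transform characterization decomposes the linear part of the affine map
between anchor triangles as Rot(θ)·diag(1, −1)^k: reflection iff the
signed triangle area flips, rotation is the polar-decomposition angle
(after factoring out the reflection) snapped to the nearest multiple of
90°.

## The p-type tree model

Leaves are regions (both hemispheres); each edge carries two directed
crossing probabilities; length = −log₁₀ p. An axon percolates outward from
its source leaf, one Bernoulli draw per directed edge reached; closed
edges stay closed. Consequences, all tested against exhaustive enumeration
of the 2^E edge-crossing outcomes:

- First-order innervation probability: P(S→T) = 10^(−L(S,T)) along the
  unique path.
- Conditional increase of T1 given T2: 10^(L(S→m)) where m is the node at
  which the paths S→T1 and S→T2 diverge. When the source lies outside the
  subtree below lca(T1, T2) — the typical case — m *is* that lowest common
  ancestor; the divergence-node form is the one that matches enumeration
  for every source placement, and is always ≥ 1 (shared-path percolation
  can only correlate innervation positively).

First-order probabilities are predicted from normalized projection
strength as P = k·√nps with k = 0.5 (L2/3, L6), 0.33 (L4, L5PT), 0.22
(L5IT), clipped at 1. In the recipe builder, nps (synapse count over
source volume as the axon-amount proxy) is rescaled to median 1 over
present projections before applying the constants: the tracer units in
which the constants were calibrated put typical probabilities at
O(0.1–1), and the median normalization reproduces that scale regardless of
the configured synapse budget.

**Topology.** The symmetrized normalized-connection-density matrix is
clustered with the Louvain heuristic (networkx implementation, seeded per
step) while the resolution γ is lowered from 6.0 to 0 in steps of 0.05.
Every region starts as a leaf; two active communities merge under a new
inner node when a detected community contains more than half of the
regions of each. Multi-way merges are processed pairwise in lexicographic
region order; anything left at γ = 0 merges into the root.

**Edge fitting.** A post-order pass solves, for each sibling pair with
parent R, the 4 × 4 least-squares system relating the motif's four
directed lengths to (i) mean row and column differences of the working
distance matrix over active nodes outside the motif and (ii) the two
between-sibling distances. The system is structurally rank 3 with null
direction (1, 1, −1, −1): length can move between a node's parent edge and
its child edges without changing any leaf-to-leaf distance. Numerically
this is handled in two stages: the minimum-norm solution is shifted along
the null direction into the nonnegative orthant when locally feasible,
and after the recursion a global *gauge repair* redistributes length along
parent/child edges — a difference-constraint system solved by
Bellman–Ford relaxation — to remove any remaining negative lengths without
changing leaf-to-leaf sums. For input that is exactly tree-additive with
nonnegative lengths, this recovers all leaf-to-leaf path lengths to
machine precision (the tests assert 1e−6 over 50 random trees of 8–20
leaves, observed ~3e−15); for inconsistent input the repair is
best-effort and residual negatives are clamped to zero, with lengths
capped at −log₁₀(1e−6). Missing or infinite entries become −log₁₀(1e−6)
before fitting.

**Statistics.** Pairwise co-innervation is tested with the two-tailed
hypergeometric test (reject at p < 0.05, i.e. the observed overlap in the
first or last 2.5% of the distribution); profile sets are compared by the
distribution of pairwise Hamming distances with a two-sample
Kolmogorov–Smirnov test, against a naive control drawing regions
independently at the first-order probabilities.

## Instantiation

Per source population, neurons are allocated to projections by a greedy
pass: each projection samples round(fraction × N) neurons; each specified
pair's overlap is raised to round(f_a·f_b·interaction·N) by moving
non-shared members across (unspecified pairs default to the independence
product). Demands exceeding the smaller group raise an error; the
end-to-end driver falls back to independent allocation in that case.
Densities become per-voxel counts (expected total = density × targeted
volume, split across layers ∝ profile × thickness, uniform within a
layer) with stochastic rounding, which preserves expectations. Synapses
are placed on segments sampled with replacement ∝ length, offsets uniform
in [0, 1]; a voxel with counts but no segments hands its count to the
nearest voxel that has segments. Presynaptic assignment maps allocated
source neurons through the barycentric pair, queries the k = 100 nearest
mapped locations per synapse (k-d tree), and draws ∝ a Gaussian of the
fitted kernel width; zero width degenerates to a uniform choice among tied
nearest candidates. Output is an HDF5 edge file in the SONATA population
layout plus one MatrixMarket connection-count matrix per target region;
the round trip is lossless.

## Micro-structure analyses

*Reciprocity:* disk subvolumes in region B are mapped into region A
(center shifted by the sampling offset in a seeded random direction);
unidirectional and reciprocal connection probabilities are pooled over
samples, and the over-expression ratio is observed reciprocal over the
product of unidirectional probabilities. *Triplets:* one neuron per region
per triplet; the 64 directed motif states are counted and compared with
the independence expectation built from the six edge probabilities
estimated on the same sampled triplets (sample-based estimation makes the
null calibration exact; matrix-based estimates leak finite-matrix
fluctuations into the z-scores). *Modules:* within-region modules come
from seeded Louvain on the symmetrized internal graph; edge densities
between module pairs are compared with degree-preserving edge-swap
controls (10 swaps per edge burn-in; all in- and out-degrees conserved
exactly); the comparison statistic is the width at half height of a
Gaussian-KDE-smoothed density histogram (Scott bandwidth, 512-point grid,
outermost half-maximum crossings).

## Synthetic fixtures and what they show

The atlas generator builds a slab cortex: two mirror-symmetric hemispheres,
rectangular region patches tiling the flattened sheet, layers stacked along
depth, 100 µm voxels. Projection tensors are generated from *planted*
topographic mappings (expected strength = base × Gaussian of the distance
to the mapped pixel, plus optional half-normal noise); neurons and
segments are Poisson-placed with per-layer densities and a morphological
type mix that includes thick-tufted and slender-tufted/untufted L5 cells.
All generators draw from streams keyed by a root seed and a stage name, so
any stage can be re-run in isolation reproducibly.

Fixture scale is deliberately small: atlases of 2–4 regions per hemisphere
on ~12³ voxel grids, ~10⁴ neurons, synapse budgets of ~10⁴–10⁵, 10⁴
sampled axon profiles, 10⁵ sampled triplets, 50 random trees of 8–20
leaves. At these sizes the full test suite runs in about 90 seconds and
the acceptance script in about a minute on one CPU.

What passing tests show: the arithmetic and conservation laws are exact;
the fitting stages recover planted parameters (mappings to sub-pixel
accuracy on noise-free tensors, tree path lengths to machine precision);
the samplers converge to the closed forms at the Monte-Carlo rate; and the
mapped-reciprocity and modular edge-density phenomena emerge qualitatively
on planted instances. What they do not show: performance or biological
accuracy at the 43-regions-per-hemisphere, 10⁷-neuron scale; fidelity of
real tracer data to the planted generative forms (real projection images
are noisier and partly non-affine); or the correctness of any constants
calibrated on real reconstructions (the class constants k and the six
prototype profiles are inputs here, not re-derived).

## Known limitations

- The mapping model is affine (barycentric pairs); regions whose
  projections carry several topographic patches per body part would need
  sub-region splitting.
- The greedy allocation satisfies pairwise overlap constraints
  approximately and sequentially; later pairs can perturb earlier ones.
- Edge-length gauge freedom means individual directed edge probabilities
  of a fitted tree are not identifiable — only path products are; any
  consumer should treat leaf-to-leaf quantities as the model's output.
- The within-region module detection resolution is a free parameter; the
  reported module counts depend on it.
- GABAergic projection classes and extracortical synapse sources are out
  of scope; no explicit space is reserved for them.
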