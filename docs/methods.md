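# Methods

## Data model

A `SpatialARG` wraps an immutable succinct tree sequence (node and edge
tables, `tskit` conventions: 0-based half-open genomic intervals in
base pairs, node times in generations before present) together with an
optional `LocationTable` mapping node ids to planar (x, y) coordinates
and a coordinate-reference-system tag (`unit_grid`, `lonlat`, or
`custom`). Invariants enforced on construction: every edge's parent is
strictly older than its child; edge intervals lie inside
[0, sequence_length); when locations are present every sample node is
located (internal nodes may be unlocated).

Locations are serialized into per-node JSON metadata (keys `x`, `y`)
and the CRS into the top-level table metadata, so saved files remain
readable by ordinary tree-sequence tooling. The compressed `.tsz`
variant written by this package is a gzip stream over the standard
tables format (with a fixed gzip timestamp so outputs are byte-stable);
it is read back transparently by `load_tree_sequence`. Recombination
event nodes carry the same node-flag bit msprime uses for full-ARG
recombination records, so simulated ARGs from either source
interoperate.

The on-disk tables format embeds a fresh UUID on every write, so two
saves of identical data differ at the byte level; reproducibility
checks therefore use `ts_io.content_digest`, a SHA-256 over the table
columns with provenance and UUID excluded.

## Subsetting

*Samples.* `subset_samples` delegates to tree-sequence simplification
(ancestry of the retained samples, unary-through nodes removed) and
then renumbers nodes contiguously in (time, old id) order, returning
the old→new id map alongside the new ARG. TMRCAs among retained
samples are preserved. A single-sample subset is rejected: it has no
genealogy.

*Genome.* `subset_genomic` intersects edges with the window, shifts
coordinates so the new sequence spans [0, right−left), and drops nodes
no longer referenced by any edge (samples are always kept). No
simplification is applied, so marginal trees inside the window keep
their exact shape, unary nodes included.

*Time.* Two semantics are offered because they serve different uses.
`strict` removes out-of-window nodes with their incident edges (the
result may be a forest; a window excluding every sample is an error).
`clip` — the default — truncates edges crossing a bound by inserting a
synthetic boundary node at the bound's time, one per (parent, child)
pair, with its location linearly interpolated between the child's and
parent's locations when both exist. Clip conserves each surviving
edge's total genomic span.

## Display graph

`build_display_graph` collapses two node-group kinds. (1) The two
parent records of one recombination event: flagged nodes with
consecutive ids, equal times, and the same single child. (2) Pairs of
sample nodes interpreted as two haplotypes of one individual: adjacent
ids, identical locations, and (a condition added here so every display
node has one well-defined time) equal times. Haplotype pairing is
greedy over ascending ids, pairing at most two haplotypes per
individual, matching diploid genomes. Display edges aggregate the
genomic span of all member edges; member sets partition the node set.

## Genealogical distances and toy coordinates

The distance between samples i and j is the span-weighted expected
tree-path length, Σ_trees (span/L) · 2 · TMRCA(i, j) — the standard
tree-metric choice; per-tree equal weighting is available via
`span_weighted=False`. For contemporaneous samples this is an
ultrametric within each tree. Classical (Torgerson) MDS double-centers
the squared-distance matrix, takes the top-two eigenpairs (negative
eigenvalues clamped to zero), and fixes the reflection ambiguity by
making each axis's first nonzero loading positive, so the embedding is
fully deterministic — the reason classical MDS was chosen over
stress-minimizing variants that need a starting point and a seed.
`fit_to_extent` applies one isotropic scale plus translation to place
the cloud in a target box, preserving all inter-point distance ratios.

## Location inference

Under Brownian dispersal with rate σ², the displacement along an edge
of duration Δt is Gaussian with per-axis variance σ²Δt, giving the
quadratic cost C = Σ_e w_e‖x_p − x_c‖² with w_e = span(e)/Δt(e).
Span-weighting counts each genomic unit of inherited material once;
parallel edges between the same node pair accumulate. σ² cancels in
the minimization, so no dispersal-rate estimate is needed.

`infer_midpoint` processes nodes tips-to-root in increasing time
order, assigning each ancestor the unweighted mean over its *distinct*
children's locations (a child counted once however many genomic edges
connect it; per-edge span weighting is available behind a flag). It is
a fast heuristic with no model interpretation.

`solve_exact_quadratic` solves the normal equations directly: the
weighted graph Laplacian restricted to free (non-sample) nodes, sample
locations as boundary conditions, via a sparse factorization. The
system is positive definite exactly when every free node has a path to
a sample; disconnected nodes are detected first and reported by id.

`infer_fast_weighted` solves the same system iteratively, starting
from the midpoint solution. The natural update is a Gauss–Seidel sweep
in increasing-time then decreasing-time order (each free node moved to
the w-weighted mean of its neighbours), but a plain sweep contracts
arbitrarily slowly when the ARG contains a near-zero-weight edge — a
few base pairs of span over a long branch — which full-ARG
recombination records produce routinely. The symmetric up/down sweep
is therefore used as the preconditioner of a conjugate-gradient
iteration on the same equations; the sweep supplies locality and
ordering, CG the acceleration. Convergence is declared when one
further full sweep would move no coordinate by more than `tol`
(default 1e-8 coordinate units; `max_iter` 10,000); non-convergence
sets a flag on the result rather than raising. On simulated ARGs the
iterative and direct solutions agree to ~1e-12 per coordinate.

Both methods are linear averaging schemes, hence equivariant under
rigid motions of the sample locations, and both keep every inferred
location inside the convex hull of the samples. Coordinates are
treated as planar in every CRS; no great-circle corrections are made
for lon/lat data (known limitation).

## Layout

Per-tree tip order: depth-first traversal with children (and root
subtrees) visited by increasing minimum descendant sample id — fully
deterministic. The consensus order aggregates per-tree orders by
span-weighted Borda rank averaging with ties broken by sample id; its
reported score is the span-weighted sum of Kendall-tau distances to
the per-tree orders. Borda weights are span fractions, so uniform span
rescaling cannot change the consensus. `layout_2d` places samples at
(rank, time) and internal nodes at the mean rank of their descendant
samples — a deterministic stand-in for force-directed placement — and
`count_crossings` evaluates a candidate order by exact straight-segment
crossing counts per marginal tree (shared endpoints excluded), with a
brute-force minimum available for small sample counts.

## Spatial diff

`spatial_diff` requires byte-level equality of node and edge tables
(times, flags, intervals, topology) and reports per-node displacement,
Euclidean distance, and midpoint; unlocated nodes are excluded and
counted. A lenient isomorphism mode is deliberately not offered —
silently matching "similar" ARGs is how comparison bugs hide. Sample
nodes are included (their distances are simply zero in the usual
truth-vs-inference use); consumers can filter. `diff_summary` bins
distances into equal-width time bins over [0, max node time], each bin
reporting count, mean, RMSE, and max; RMSE ≥ mean by Jensen's
inequality, with equality only for constant distances.

## Simulation

`simulate_arg` implements the back-in-time Hudson process: lineages
carry ancestral-segment lists; pairs coalesce at rate k(k−1)/2 · 1/(2Ne)
per generation; recombination strikes each lineage at rate
`recomb_rate` per base pair of ancestral material it carries, with the
breakpoint uniform within that material. Coalescence records one node
and edges over both children's segments; recombination (with
`record_full_arg`, the default) records two flagged parent nodes with
consecutive ids and equal times splitting the child's material at the
breakpoint. Per-interval lineage counts are tracked so each genomic
position stops being followed once it reaches its MRCA; the process
ends when no ancestral material remains. With recombination rate zero
this reduces to the Kingman coalescent: exactly 2n−1 nodes, and
pairwise TMRCA exponential with mean 2Ne generations — both checked
against theory in the test suite.

`simulate_brownian_locations` generates ground truth forward in time:
roots uniform in the unit square, every other node displaced from its
*primary parent* (the parent covering the largest genomic span, ties
to the lower id) by N(0, σ²Δt) per axis. A node has one location but
possibly several parents across the genome, so the truth follows this
single spanning tree — mirroring how spatially explicit forward
simulators give each individual one location. An optional reflecting
boundary folds coordinates into [0, 1].

Default study conditions used throughout the tests and the acceptance
script: n = 20–30 samples, sequence length 1000 bp, recombination rate
7.5e-4 per bp per generation with Ne = 0.5 (time in units of 2Ne = 1
generation), yielding roughly 3–15 marginal trees per ARG, and
dispersal σ = 0.05 coordinate units per √generation on the unit
square. These sizes keep every simulation in the suite at a few
seconds while exercising multi-tree structure; they emulate dispersal
that is small relative to the habitat, which is the regime where
location inference is informative. The generator omits real-data
features such as habitat boundaries shaping dispersal (unless the
reflecting option is used), anisotropy, long-range jumps, sampling
bias, and inference noise in the ARG topology itself — so passing
recovery tests demonstrate correctness of the estimators under the
model, not robustness to model misspecification.

## CLI and session store

The command-line interface is a thin layer over the library. A session
is a plain directory of `.trees` files plus a JSON index recording each
entry's source and full operation chain (provenance completeness); no
daemon or lock files. Exit codes: 0 success, 2 usage, 3
validation/format error, 4 numerical failure. All commands are
deterministic given their seeds; reproducibility is asserted via
content digests (see above).

## Known limitations

- Planar geometry throughout; lon/lat coordinates are not projected.
- The haplotype-merge heuristic is positional (adjacent ids, identical
  location); it consults no individual table.
- The simulator covers the neutral constant-size coalescent only — no
  demography, mutations, or selection.
- `spatial_diff` requires exact structural identity; comparing ARGs
  from different inference runs requires aligning their tables first.
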