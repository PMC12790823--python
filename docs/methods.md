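# Methods

This note documents the models and procedures `stgap` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Spatial neighbor graph

Adjacency is thresholded Euclidean distance: spots *i ≠ j* are neighbors iff
‖cᵢ − cⱼ‖ < r, strictly — ties at exactly r are excluded, so lattice data
behaves predictably. Every node carries a self-loop, which guarantees every
attention neighborhood is non-empty and lets a node attend to itself. All
edges are unweighted; node weights start at 1 and only become meaningful
under coarsening. Construction uses a k-d tree (`scipy.spatial.cKDTree`), so
all-pairs distances are never materialized.

**Adaptive radius.** Coordinates arrive in platform units (µm for imaging
platforms, array units for spotted arrays), so a fixed r is not portable.
`adaptive_radius` targets a mean non-self neighbor count of 20, the midpoint
of a 10–30 band in which clustering quality is empirically stable across
resolutions; any radius whose count lands inside the band is accepted. The
mean count is a nondecreasing step function of r, so bisection converges
deterministically. The lower bracket is the minimum nearest-neighbor
distance; because no bracket derived from nearest-neighbor distances alone
can reach ~20 neighbors, the upper bracket grows geometrically from the 0.9
quantile of nearest-neighbor distances until the midpoint is bracketed
(capped at the bounding-box diagonal). Sections too small to reach the band
get the radius that maximizes the count, with a warning. Pair counting uses
`count_neighbors` at `nextafter(r, 0)`, which converts the library's ≤ r
semantics into the strict < r the graph definition requires.

## Multilevel k-way partitioning

Sizing follows the mini-batch design: `num_parts = round(10·N/B)` (floor 1;
half-up rounding, exact whenever B divides 10N) and `cap = B/10` with the
default B = 256 giving cap = 25.6. **Capacity is interpreted as total
original-spot weight per subgraph**, evaluated in real arithmetic without
rounding — so 10 subgraphs per batch carry ≈ B spots. The alternative
reading (a count of supernodes) would make the bound level-dependent and
incompatible with balanced spot loads.

*Coarsening* is seeded random matching: visit nodes in a seeded random
order; an unmatched node merges with a uniformly chosen unmatched neighbor,
skipping merges that would push a supernode past `cap` (so no supernode is
ever unsplittable). Supernode weights add; supernodes are adjacent iff any
constituent pair was; self-loops are re-added. Coarsening stops when the
node count reaches `max(num_parts, ceil(N/cap))`, when a pass shrinks the
graph by less than 10 % (matching has stalled against the weight limit), or
when another pass would drop below `num_parts`. A fixed classical threshold
can be supplied via `target_nodes` instead.

*Initial partitioning* grows parts one at a time from seeded random start
supernodes, absorbing the unassigned neighbor of highest degree (ties to the
lowest index) until the capacity would be exceeded or the frontier is empty.
Supernodes left unassigned after `num_parts` parts are attached to the
lightest adjacent part, iterating to a fixed point; supernodes isolated from
every part go to the lightest part overall. Parts that receive leftovers may
exceed cap; they are flagged in `diagnostics["overweight_parts"]`.

*Refinement* runs after every projection step: boundary nodes migrate to the
neighboring part of best strictly-positive cut gain, provided the
destination stays within cap; ties go to the lowest part id; sweeps repeat
until stable or 10 passes. Only positive-gain moves are applied, so the edge
cut is non-increasing — a property the test suite asserts on an exhaustive
small-graph oracle suite. The method is heuristic: on ≤ 8-node graphs the
final cut is compared against (not required to equal) the exhaustive minimum
balanced cut.

## Graph attention autoencoder

Architecture `layer_dims = [d_in, 128, 64, 30]` by default: three layers
with a 30-dimensional latent space. (Published descriptions of this family
of models quote both 30 and 64 for the embedding width; 30 is the default
here and everything is configurable.) Hidden activation is ELU; the latent
layer and the final reconstruction layer are linear — standard autoencoder
output heads, and the choice that makes the weight-tying inverse property
(orthogonal W, isolated nodes ⇒ exact reconstruction) hold exactly.

Attention scores are `sigmoid(aᵀ[W zᵢ ‖ W zⱼ])`, softmax-normalized over the
self-inclusive neighborhood with max-subtraction for stability; non-neighbors
are excluded from the softmax rather than zero-scored, so coefficients are a
proper distribution over N_i. A single attention head is used. The decoder
mirrors the encoder — transposed weights, the encoder's cached α per layer —
and owns no trainable parameters; an optional linear head
(X̂ = Z W_d + b, `linear_head=True`) is provided as the alternative
reconstruction path.

**Gradients.** PyTorch is not a dependency; forward passes cache
intermediates and `gaae_gradients` implements exact reverse-mode
differentiation, including the flow of gradients through the attention
coefficients from *both* their encoder and decoder uses (the decoder's reuse
of α feeds back into W and a). Finite-difference agreement to < 10⁻⁴
relative error is part of the acceptance tests. Training is Adam
(β = 0.9/0.999, ε = 10⁻⁸) with L2 weight decay added to the gradient and
global-norm clipping at 5 applied after the decay term, matching the
convention of the common reference optimizer. Runs are bitwise deterministic
on CPU for a fixed seed.

**Mini-batches.** Subgraph ids are reshuffled every epoch (seeded by
(seed, epoch)) and grouped into batches of 10; each batch is the
block-diagonal union of induced subgraphs. Cut edges are dropped in training
and in the default inference path, consistent with independent subgraph
training; `full_graph=True` at inference runs one pass over the intact
graph. On partitions that cut nothing the two inference modes agree exactly
(tested); on real partitions full-graph inference can sharpen domain
boundaries because boundary spots see their severed neighbors again.

The loss is the summed squared Frobenius error over the batch's subgraphs;
the per-epoch history stores the raw sum, and logs additionally report the
per-spot mean for comparability across dataset sizes.

## Synthetic sections

`generate_fixture` emulates a layered tissue section: spots on a jittered
unit grid (uniform jitter ±0.05 spacing by default), K spatially contiguous
domains (horizontal bands, or Voronoi cells for irregular shapes), and
Poisson counts — each domain's private marker genes at mean 5 inside the
domain, all other entries at mean 0.2. Defaults: 50×40 grid (2000 spots),
K = 4, 200 genes, 10 markers/domain. Poisson (not Gaussian) counts exercise
the normalization/log1p path realistically.

What the generator does **not** emulate: platform artifacts (bin boundaries,
optical noise, segmentation errors), within-domain expression gradients,
cell-type mixtures inside a domain, or batch effects. Consequently a green
domain-recovery test establishes that the pipeline recovers clean contiguous
expression domains — not performance on real tissue. At the default rates
the naive mean-marker classifier is essentially 100 % accurate, i.e. the
planted domains are separable from single-spot expression alone; on such
data a plain PCA + k-means baseline already scores ARI 1.0, leaving no room
for spatial context to *improve* the score — spatial information is
demonstrably not harmful here (ARI ≥ 0.96, and 1.0 with full-graph
inference), but a fixture with weaker markers would be needed to show it
helping, which the present generator's stated defaults do not provide.

## Preprocessing

Total-count normalization to 10⁴ per spot, then log1p (both via scanpy);
all-zero spots are kept (dropping them would change the graph topology) and
warned about. Double normalization raises rather than silently rescaling.
Highly variable genes are ranked by plain dispersion (variance/mean of the
normalized matrix, degenerate genes scoring 0, stable ties), with default
n_top = 3000; the mean-binned variant used by some toolkits degenerates on
very small gene panels (a near-empty bin makes a constant gene look
variable), which matters for the small fixtures this package must handle
deterministically.

## Defaults that matter

| parameter | default | unit / note |
|---|---|---|
| target_sum | 1e4 | counts per spot after normalization |
| n_hvg | 3000 | genes kept (capped at panel size) |
| neighbor band | 10–30 | mean non-self neighbors; midpoint 20 targeted |
| spot_batch_size | 256 | spots per training batch; sets num_parts and cap |
| subgraphs_per_batch | 10 | parts per optimizer step |
| epochs | 1000 | examples/tests use 100 (converged on the fixture) |
| learning rate / weight decay | 1e-3 / 1e-4 | Adam |
| grad clip | 5 | global L2 norm |
| layer_dims | [d_in, 128, 64, 30] | latent = 30 |
| refinement passes | 10 | per level |

## Known limitations

- Single section only: no multi-slice integration, no image features.
- Pure-NumPy training is CPU-bound; practical up to ~10⁵ spots. The
  algorithmic structure (subgraph mini-batches) is what scales; swapping the
  linear algebra onto an accelerator framework would not change any
  interface.
- Leftover-supernode attachment can overfill parts on graphs with many
  small components; flagged in diagnostics rather than repaired.
- Refinement may empty a part entirely (the capacity rule constrains only
  the destination); batches are formed from non-empty parts.
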