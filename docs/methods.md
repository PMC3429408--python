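# Methods

## Problem and model

Given n points in d dimensions (rows of a feature matrix; in the
motivating application, expression probes or derived metafeatures
measured over patient samples), the package constructs the exact
directed kNN graph: for every point, edges to its k closest points
under a chosen metric, weighted by the distance. The defining
constraint is memory: the full n × n distance matrix is never stored.
Instead the *virtual* distance matrix is covered by square chunks of
side n_c; distances exist only for the lifetime of one chunk, after
which a streaming top-k update has absorbed them into fixed-size
neighbour buffers. Peak distance storage is n_c² entries per worker.

Chunks sharing a row range form a *split*; once all chunks of a split
are processed, the neighbour lists of those rows are complete (every
candidate column has been offered) and the rows' edges are final.
Splits are grouped into *segments* — the unit of coarse parallelism.
Segments share no mutable state, so their partial graphs concatenate
by source row into the full graph; this implementation executes them
sequentially, which is trivially bit-identical to any correct parallel
schedule and keeps single-CPU runs deterministic.

## Metrics

- `euclidean`: sqrt(Σ(xᵢ−yᵢ)²); `manhattan`: Σ|xᵢ−yᵢ|.
- `pearson` / `spearman`: similarity r mapped to distance d = 1 − r,
  range [0, 2]; Spearman is Pearson on per-row average ranks
  (ties averaged). 1 − r is monotone in r, zero iff perfectly
  positively correlated, and — unlike 1 − |r| or 1 − r² — keeps
  anti-correlated profiles maximally distant, which matches the
  "nearest = most positively correlated" reading used when querying a
  phenotype row. Pearson distance is invariant to positive affine
  rescaling of either argument, which is why a phenotype "dummy probe"
  on a different scale than log-ratios can sit in the matrix as an
  ordinary row.
- Degenerate rows (zero variance, e.g. a constant probe) have no
  defined correlation. They receive the largest finite float32 value
  (`MAX_DISTANCE`, ≈3.4e38) instead of NaN: far beyond the metric's
  range, so such points are never preferred as neighbours, yet still
  finite so a buffer slot can be filled when k forces it. Degeneracy
  is detected exactly via per-row min == max (plus a centred
  sum-of-squares that underflows to zero), never via a variance
  threshold.

## Numerical determinism of the kernels

The blocked kernel consumes the dimension axis in tiles of width b
(default 16, a legacy of warp-aligned data blocks; any b ≥ 1 is valid)
but accumulates partial sums **one dimension at a time in ascending
order**, avoiding shape-dependent BLAS reductions. Consequently the
distance of a given pair is bit-identical whatever the tile width,
chunk size, or companion rows in the block — this is what lets the
engine promise *identical* (not merely close) graphs across chunk
sizes and segment counts, and bit-equality with the brute-force
oracle. The cost is a constant-factor slowdown relative to a GEMM
formulation, irrelevant at the problem sizes the test suite and
acceptance script use (n ≤ 2,000 there; the design scales as
O(n²d / n_c²) chunk evaluations regardless).

Pearson sums are accumulated on *centred* values (row means from a
first pass), so the zero columns introduced by padding d up to N
cannot perturb the statistic, and cancellation in n·Σxy − ΣxΣy is
avoided.

## Padding and skip rules

M = smallest multiple of n_c ≥ n; N = smallest multiple of b ≥ d
(n_c must be a multiple of b so chunks decompose into whole data
blocks). Tile entries whose row or column index falls in [n, M) are
set to `MAX_DISTANCE` and, independently, the top-k update skips pad
columns *structurally* (by index range, not by sentinel value) — a
real degenerate point also carries the sentinel weight and must remain
eligible, while pad indices must never appear in an edge. Diagonal
entries are skipped only on diagonal chunks, where a row's own point
index falls in the chunk's column range.

## Tie rule and the top-k update

The reference formulation of the update is streaming: each candidate is compared
against the entry at the farthest-neighbour locator (`maxk_pos`) and
replaces it when **strictly** closer, after which the locator is
re-found by a linear scan (k is small; no heap). Two conventions make
the result exactly the k smallest distances under the lexicographic
(weight, index) order, independent of work partition:

1. strict `<` replacement — an equal-distance later candidate never
   displaces an earlier (smaller-index) one, because columns are
   offered in ascending global index;
2. among buffer entries tied at the maximum weight, the rescan locates
   the one with the **largest** neighbour index, so ties at the
   boundary are evicted newest-first.

`update_topk`, the engine's production path, implements the same
semantics as a vectorised per-row merge: current buffer plus the
chunk's valid candidates, `lexsort` by (weight, index), keep k, with
exact duplicate (index, weight) pairs dropped so the operation is
idempotent. `NeighborList.offer` is the literal streaming reference;
a property test drives both with the same candidate streams and
asserts identical buffers. Empty slots hold index −1 and weight +inf
(strictly above the finite degeneracy sentinel, so a sentinel-weight
candidate can still fill an empty slot — matching the oracle, which
sorts such candidates last but does not exclude them).

Ordering of the emitted edge list: by source, then ascending weight,
then target — a deterministic file for a deterministic input.

## Metafeature expansion

Each unordered feature pair {i, j}, i < j in input order, combined
with each selected operator exactly once, in the fixed orientation
row_i ∘ row_j: n features and m operators give n + m·n(n−1)/2 rows
(876 → 384,126 with difference only; → 1,533,876 with all four). The
pair-per-operator uniqueness is what those closed-form counts require;
the orientation itself is a free choice and is fixed to i ∘ j.
Division guards denominators with |den| < ε (default 1e−12) by
clamping to ±ε with the denominator's sign, keeping every derived
value finite (required downstream, where distances must be finite);
clamp counts are logged as warnings.

## Synthetic data generator

`generate_fixture(n, d, n_blocks, noise_sd, seed)` emulates the
block-correlated structure of a co-expression matrix: n_blocks latent
standard-normal profiles of length d, contiguous near-even point
groups sharing a profile, i.i.d. N(0, noise_sd²) noise on top. With
noise_sd = 0.1 against unit-variance profiles, within-block
correlation is ≈0.99, so 1-NN block recovery is essentially perfect —
the fixture tests graph mechanics, not statistical difficulty. What it
does **not** emulate: heavy-tailed expression distributions, missing
values (inputs with NaN are rejected, not imputed), probe-level
platform artefacts, or correlated noise across samples; passing tests
therefore certify algorithmic correctness (exactness, invariance,
memory bounds), not biological recall on real microarray data.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| k | — (always explicit) | neighbours per point; 1 ≤ k ≤ n−1 |
| metric | pearson | scale-free comparison of expression profiles |
| chunk_size_nc | 1024 | side of the distance tile; memory/throughput trade-off only — any valid value gives the same graph |
| block_size_b | 16 | dimension-axis tile; kept as default for its data-block heritage, semantically free |
| n_segments | 1 | worker contract; clamped to the split count with a warning on tiny inputs |
| division_epsilon | 1e−12 | metafeature division guard |

## Problem sizes used by the checks

The test suite and acceptance script run the engine at n up to 2,000
(memory-bound check, chunk 128 → 256 chunk evaluations) and randomised
oracle-equivalence instances with n ∈ [50, 400], d ∈ [3, 50], all four
metrics, k ∈ {1, 5, 20}; metafeature expansion is executed at the full
876-feature scale (1,533,876 rows). These sizes exercise every code
path (multi-chunk splits, pad bands, segment clamping) while keeping a
complete run in tens of seconds.

## Known limitations

- Points must fit in memory as a dense float64 matrix; only the
  distance matrix is chunked, not the input data.
- The engine computes the self-graph of one matrix; query-vs-reference
  search is available through `ChunkedKNeighborsTransformer.transform`,
  which reuses the blocked kernel over query bands.
- No approximate modes (k-d trees, LSH); exactness is the point.
- k is never inferred from n; callers choose it.
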