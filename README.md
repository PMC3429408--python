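# knng — exact kNN graphs from large feature matrices, one chunk at a time

`knng` builds the **exact k-nearest-neighbour graph** of a numeric feature
matrix (rows = points, e.g. expression probes or metafeatures; columns =
dimensions, e.g. samples) without ever materialising the full pairwise
distance matrix. It is aimed at network-based analysis of high-throughput
biological data — e.g. finding the genes whose expression profiles most
closely track a clinical phenotype row — where the point count can reach
the hundreds of thousands and an n × n distance matrix is out of the
question.

## The method

For n points the virtual n × n distance matrix is covered by square
**chunks** of side n_c. The chunks sharing a row range form a **split**;
splits are grouped into **segments**, each processable by an independent
worker. The point count is padded up to M, the smallest multiple of n_c
≥ n, and the dimension count up to N, the smallest multiple of the
data-block size b ≥ d, so all tiles align; pad entries carry a sentinel
and are skipped.

For each chunk, a distance kernel fills the n_c × n_c tile (Euclidean,
Manhattan, or the correlation distances d = 1 − r for Pearson and
Spearman), then a streaming top-k update folds the tile into per-row
neighbour buffers: each candidate is compared against the current
farthest entry (tracked by a `maxk` locator) and replaces it when
strictly closer, skipping the diagonal and the pad region. When every
chunk of a split has been seen, that row band's k-best lists are final
and are emitted as directed weighted edges {source, target, weight}.
Peak distance storage is one chunk — O(n_c²) — per worker.

With a deterministic tie rule (strictly-closer replacement; equal
distances at the k-th position resolved to the smaller index) the output
is **identical for every chunk size and segment count**, and equal
edge-for-edge to the exhaustive brute-force oracle that is also shipped
(`brute_force_knn`).

The package also implements **metafeature expansion**: every unordered
pair of feature rows {i, j}, i < j, combined with difference, summation,
product and/or division, appended below the original rows — n features
and m operators yield n + m·n(n−1)/2 rows (876 features → 384,126 rows
with one operator, 1,533,876 with all four).

## Worked example

```python
>>> import numpy as np
>>> from knng import ExpressionMatrix, build_knn_graph, query_neighbors
>>> m = ExpressionMatrix(np.array([[0.], [1.], [3.], [7.]]),
...                      ["a", "b", "c", "d"], ["x"])
>>> g = build_knn_graph(m, k=1, metric="euclidean",
...                     chunk_size_nc=2, block_size_b=1, n_segments=2)
>>> g.edges()
[(0, 1, 1.0), (1, 0, 1.0), (2, 1, 2.0), (3, 2, 4.0)]
>>> query_neighbors(g, "d")
[('c', 4.0)]
```

Four points on a line at 0, 1, 3 and 7: each point's single nearest
neighbour and its distance — point `d` (at 7) is closest to `c` (at 3),
4 units away. The same graph comes out for any chunk size or segment
count, and from the brute-force oracle.

From the shell, the same pipeline on a synthetic block-structured matrix:

```bash
knng fixture --n 100 --dims 20 --blocks 4 --seed 1 --output matrix.tsv
knng build --input matrix.tsv --metric pearson --k 5 \
           --chunk-size 32 --block-size 16 --segments 2 --output edges.tsv
# -> "wrote 500 edges (k=5, n=100, metric=pearson) to edges.tsv"
knng query --input matrix.tsv --id p0000 --k 3 --metric pearson --chunk-size 32
# -> p0008  0.0121066
#    p0012  0.0123116
#    p0015  0.0124051
```

`edges.tsv` holds k·n = 500 lines of `source_id  target_id  weight`;
`--graphml out.graphml` additionally exports the graph for network
visualisation tools. `knng expand --input filtered.tsv --operators
difference,summation,product,division --output expanded.tsv` performs the
metafeature expansion.

scikit-learn users can drive the same engine through
`knng.ChunkedKNeighborsTransformer` (a drop-in analogue of
`KNeighborsTransformer` returning a sparse distance graph) and
`knng.MetafeatureExpander` (a `PolynomialFeatures`-style column
expander); both compose with pipelines.

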