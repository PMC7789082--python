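# mscd — persistent multiscale community detection

Biological similarity networks — protein–protein interaction maps,
shared-nearest-neighbor graphs of single-cell transcriptomes — contain
meaningful structure at many scales at once: protein dimers inside
complexes inside organelle-scale assemblies, cell subtypes inside broad
lineages.  Any single community-detection run commits to one scale.
`mscd` instead sweeps the scale parameter, keeps only the communities
that are *stable across scales*, and organizes them into a hierarchy of
nested and overlapping groups.  It is aimed at computational biologists
who have a weighted undirected network (or an embedding to build one
from) and want a multiscale map of its modules rather than a single flat
partition.

## Method

For a graph *G* with adjacency *A*, node strengths *k* and total edge
weight *m*, a partition is scored at resolution γ by the generalized
(Reichardt–Bornholdt configuration-model) modularity

```
Q(G, γ) = Σ_ij (A_ij − γ k_i k_j / 2m) δ(i, j)
```

and optimized with the Leiden refinement of the Louvain algorithm.  The
workflow has three phases:

1. **Resolution sweep.**  γ is sampled log-uniformly on
   [γ_min, γ_max] (defaults 10⁻³ to 50), densely enough that every
   interior grid point has ≥ 10 *γ-proximal* neighbors (log₁₀ ratio
   < 0.1 decades); one partition is detected per γ.
2. **Persistence.**  All communities from all resolutions become
   vertices of a community graph *G_C*; edges join communities from two
   different γ-proximal resolutions with Jaccard similarity *J* > τ
   (default 0.75).  A connected component of *G_C* is one community
   "tracked" through scales, and its **persistence** is the number of
   distinct γ values it spans.  Components with persistence ≥ χ
   (default 5) yield a consensus community: the nodes present in > p %
   (default 75 %) of the component's instances.
3. **Hierarchy.**  Persistent communities become vertices of a rooted
   DAG.  Containment is scored by CI(v, w) = |v ∩ w| / |w|; mutual
   containments at τ merge into their union, edges run from strictly
   larger to smaller sets when CI > σ (default σ = τ), redundant edges
   are removed by transitive reduction, and memberships are expanded so
   each community includes its descendants' members.

The package also ships a planted two-level benchmark generator
(power-law degrees, micro communities nested in macro communities, with
mixing fractions μ_c ≤ μ_f controlling how many edges violate each
level) and the matching recovery metric (average best-match F1), so the
whole method is testable end-to-end without any external data.

## Worked example

Simulate a benchmark, build the hierarchy, and score it:

```bash
$ mscd simulate --n 1000 --seed 7 --out bench
benchmark: 1000 nodes, 4492 edges, 14 macro / 87 micro communities -> bench.edges, bench.truth

$ mscd build bench.edges --seed 7 --out hier
206 persistent communities (1000 nodes, 4492 edges) -> hier.nodes, hier.edges

$ awk '{print $1"\t"$2}' bench.truth > macro.tsv   # (node, macro label)
$ mscd evaluate --detected hier.nodes --reference macro.tsv | tail -1
average_f1	0.9205
```

The simulator planted 14 macro communities (50–100 nodes) each split
into micro communities (5–20 nodes); 10 % of edge ends leave their macro
community and 20 % their micro community.  `build` swept 471 resolutions
and retained 206 persistent communities as a rooted DAG
(`hier.nodes` / `hier.edges` TSVs: member lists and persistence per
community, parent→child containment edges).  The evaluation line says
that, averaged over the 14 planted macro communities, the best-matching
detected community reaches F1 = 0.92; the same command with the micro
labels gives average F1 = 1.00 — both levels are recovered from one run
without choosing a scale in advance.

The same pipeline is available as a scikit-learn-style estimator:

```python
from mscd import PersistentCommunityDetector

est = PersistentCommunityDetector(random_state=7).fit(adjacency)  # or a WeightedGraph
est.communities_    # list of member frozensets
est.persistence_    # persistence score per community
est.hierarchy_      # rooted containment DAG
```

Other subcommands: `mscd snn` builds a shared-nearest-neighbor graph
from an embedding TSV (Euclidean k-NN, Jaccard overlap weights), and
`mscd expand` extracts the subnetwork around a seed-node list (keeping
non-seeds linked to ≥ 2 seeds), the standard preparation for
virus–host interactome analyses.

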