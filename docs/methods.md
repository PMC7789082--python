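# Methods

## Model and assumptions

`mscd` treats its input as an undirected, positively weighted similarity
graph.  For weighted graphs the degree `k_i` in the modularity null term
is the node *strength* (sum of incident weights) and `m` the total edge
weight; with unit weights this reduces to the ordinary degree/edge-count
form.  Self-loops are dropped and duplicate input edges collapse by
summing weights (both logged): the quality function assumes `A_ii = 0`,
and summing is the least surprising reading of a repeated similarity
record.

The detected object is not a single partition but the set of communities
that recur across resolutions.  The underlying assumptions are that
(a) a community that is an artifact of one particular resolution will
not reappear, essentially unchanged, across many nearby resolutions, and
(b) comparing communities only between γ-proximal resolutions is enough
to track a stable community through the sweep, because community
structure evolves slowly on the log-γ axis.

### Quality function and optimizer

The per-resolution score is the Reichardt–Bornholdt generalized
modularity, reported in its unnormalized double-sum form (the diagonal
`i = j` terms are included, so a singleton partition scores
`−γ Σ k_i² / 2m`).  A normalized variant (divide by `2m`) is available
behind a flag; it never changes which partition is optimal.  The
optimizer is `leidenalg`'s `RBConfigurationVertexPartition` (the Leiden
refinement of Louvain), run with a fixed per-resolution seed derived
from the global seed and the grid index, so a run is bit-reproducible.
A `repeats` option keeps the best-scoring of several independently
seeded runs; the default is one run per γ.

### Resolution grid

Resolutions are sampled uniformly in log₁₀ on `[gamma_min, gamma_max]`
(defaults 1e-3 and 50; 20 is the customary upper bound for single-cell
SNN graphs and is reachable by flag).  Two resolutions are *γ-proximal*
when their log₁₀ values differ by less than `proximity_radius` (0.1
decades, strict).  The requested `log_step` (default 0.02 decades) is
halved until every interior grid point has at least `min_proximal` (10)
proximal neighbors; with the defaults this settles at step 0.01 and 471
grid points, each interior point having 18 proximal neighbors.  At the
default lower bound γ = 10⁻³ the optimum partition is the connected
components (merging components strictly lowers Q, and the within-
component penalty is negligible at that γ), which gives the sweep a
well-defined coarse end.

### Persistence

All communities from all resolutions form the pan-resolution community
graph; edges require `J > tau` *strictly* (a pair at exactly τ is not
linked) and different, γ-proximal resolutions — communities within one
resolution never overlap, so comparing them is pointless.  Similarities
are accumulated per resolution pair by counting co-assigned nodes in
the two label vectors, which is equivalent to all-pairs set comparison
but linear in the node count.  Persistence of a connected component is
the number of *distinct* resolutions it touches (a resolution
contributing two instances counts once).  Components with persistence
≥ χ (the threshold is inclusive, which is what makes re-thresholding at
χ′ > χ equivalent to filtering the χ result) yield a consensus
community: nodes present in strictly more than `p_percent` % of the
component's instances.  Consensus sets smaller than
`min_community_size` (default 4, the customary cutoff for protein
complexes; set 1 to keep everything) are dropped with a log message.

### Hierarchy assembly

Vertices are the persistent communities plus a root holding every graph
node (persistence recorded as 0).  Construction order: exact-duplicate
member sets merge (keeping the larger persistence); pairs with mutual
containment `CI ≥ tau` both ways are replaced by their union
(persistence = max of the pair) and the pass iterates to a fixed point,
since a union can create new mutual containments; directed edges
`v → w` are then added when `CI(v, w) > sigma` **and** `|v| > |w|`.
The strict size ordering resolves a genuine ambiguity — the containment
index alone does not orient an edge between same-size or
mutually-overlapping sets — and makes the edge relation acyclic by
construction (size strictly decreases along every edge).  When all
pairwise Jaccard similarities are below τ, the choice
`sigma ≥ 2τ/(1+τ)` already guarantees acyclicity of the raw CI
relation without the size rule; the default is the relaxed
`sigma = tau`, which admits more containment relations.  Equal-size
non-identical pairs get no edge (they are union candidates only).
Finally the DAG is transitively reduced (the reduction of a DAG is
unique) and memberships are expanded bottom-up so every parent includes
its descendants' members, making `CI(parent, child) = 1` along every
edge.

## Parameters

| name | default | meaning |
|---|---|---|
| `gamma_min`, `gamma_max` | 1e-3, 50 | resolution range of the sweep |
| `log_step` | 0.02 decades | requested grid spacing (auto-refined to 0.01) |
| `proximity_radius` | 0.1 decades | γ-proximality window (strict) |
| `min_proximal` | 10 | minimum proximal neighbors per interior grid point |
| `tau` | 0.75 | Jaccard threshold linking communities across resolutions |
| `chi` | 5 | minimum persistence (distinct resolutions) to keep a component |
| `p_percent` | 75 | consensus membership percentage (strict >) |
| `sigma` | = `tau` | containment-index threshold for hierarchy edges |
| `min_community_size` | 4 | smallest reported community |
| `seed` | 42 | master seed; per-γ seeds derive deterministically |

## Benchmark generator

The generator emulates the standard two-level planted-partition regime:
N = 1000 nodes, mean degree 10, maximum degree 40, degree exponent 2,
community-size exponent 1, micro sizes 5–20 nested inside macro sizes
50–100 (so 10–20 macro and 50–200 micro communities are forced by the
size bounds).  Each node's degree is split into within-micro,
within-macro/cross-micro, and cross-macro stub counts by rounding
`mu_c·k` and `(mu_f−mu_c)·k`, with the rounding remainder assigned to
the within-micro pool.  The defaults μ_c = 0.1, μ_f = 0.2 are a mild
mixing regime in which both levels are clearly present but not trivial.

Community sizes come from a truncated power law resampled to sum
exactly to the block size.  The degree law's lower bound is solved by
bisection so the truncated distribution's mean hits `k_avg`.  Within-
micro edges are realized by a Havel–Hakimi construction followed by
degree-preserving double-edge swaps (micro communities are dense —
near-complete subgraphs — where random stub pairing stalls); the
sparser cross-micro and cross-macro pools use randomized stub pairing
with retry passes.  Stubs that cannot be placed without self-loops or
multi-edges — chiefly hubs whose within-micro demand exceeds their
community's capacity, an infeasibility inherent to max-degree 40 with
micro sizes ≤ 20 — are dropped and logged; empirically the realized
mean degree is ≈ 9.2 and the realized mixing fractions track μ_c and
μ_f within ±0.01.

What the generator does *not* emulate: weighted similarity edges,
degree–community-size correlation beyond the capacity constraint,
overlap between planted communities within a level, and more than two
levels.  Passing the recovery tests therefore shows the pipeline
recovers clean nested block structure under moderate mixing noise; it
does not certify behavior on real interactomes, where noise is
structured and reference communities overlap.

## Evaluation metric

Recovery is scored one-directionally: for each reference community the
best-matching detected community by F1 (harmonic mean of precision and
recall over member sets) is found, and the per-reference maxima are
averaged.  This is deliberately not the symmetrized mean some packages
compute: it measures whether every planted community was found, not
whether every detected community is planted (a multiscale method
legitimately reports communities at scales the reference lacks).  Ties
in the argmax break by larger Jaccard, then lexicographic name, making
reports deterministic.  A per-reference "recovered" flag uses Jaccard
> 0.5.  Ranking communities by persistence (ties: larger size, then
smallest member) yields recovery-vs-top-N curves, which are
non-decreasing in N because adding a candidate can only improve a
best-match.

## Numerical choices and degenerate inputs

- Strict threshold comparisons (`J > τ`, consensus `> p %`, `CI > σ`)
  are evaluated with exact integer set cardinalities against float
  thresholds, so boundary cases like J = 3/4 at τ = 0.75 are excluded
  exactly.
- γ-proximality on the float grid uses a relative guard of 1e-9 so a
  spacing that should equal the window (e.g. 10 steps of 0.01 against a
  0.1 window) is excluded despite rounding.
- Empty graphs, empty member sets, non-positive weights, and
  partition/graph size mismatches raise `ValueError`/`ParseError` with
  the offending line where applicable; an edgeless graph is rejected by
  the sweep (m must be positive).
- Isolated nodes form singleton communities at every resolution and are
  absorbed only by the consensus/size filters.

## Problem sizes

The test suite and the acceptance script run the full default sweep
(471 resolutions) on the 1000-node benchmark — about 10 s on one CPU —
and use graphs of 4–60 nodes for the oracle-checked property tests
(exhaustive partition enumeration is feasible to 8 nodes).  Randomized
bulk checks use 50–1000 repetitions per property.

## Known limitations

- Hierarchy quality depends on Phase II's guarantee that retained
  communities have pairwise J < τ; callers constructing hierarchies
  from arbitrary set collections with `sigma < 2τ/(1+τ)` rely on the
  union pass and the size-orientation rule instead (still acyclic, but
  more unions than the threshold theory anticipates).
- Persistence is a count of resolutions, not a topological persistence
  diagram; no birth/death pairing is computed.
- The SNN builder is a generic Euclidean k-NN/Jaccard implementation
  with Seurat-like defaults (k = 20, prune = 1/15, neighborhoods include
  the node itself); it does not reproduce any specific toolkit's output
  bit-for-bit.
- `fit_predict` flattens the overlapping result by assigning each node
  to its smallest containing community, which discards the multiscale
  information; it exists for scikit-learn interoperability only.
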