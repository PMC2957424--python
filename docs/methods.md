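# Methods

This note documents the model, the algorithms, the defaults and the
numerical conventions implemented in `dysnet`, and what the synthetic
benchmark does and does not establish.

## Data model

The input is an undirected simple graph G = (V, E) over gene identifiers
(protein–protein interactions) and a gene × sample matrix of log2-scale
expression values, with every sample labeled `case` or `control`. Probe-level
matrices are collapsed to genes by arithmetic mean per sample (on the log
scale, i.e. a geometric mean of intensities; the pipeline collapses after any
log transform, a deliberate ordering choice). Expression genes absent from
the network are carried through dysregulation calling and dropped only when
the cover instance is built; network nodes without expression are kept with
empty cover sets — they can still enter a module as connectors ("back
nodes"), which is one of the method's features: a gene can be implicated by
its interaction pattern alone.

## Dysregulation calling

For each gene the control samples define a normal null: mean μ_v and sample
standard deviation σ_v (ddof = 1; at least two controls required). Gene v is
called dysregulated in case u when both gates pass:

* tail p-value < `p_threshold` (default 0.05): upper tail for UP, lower for
  DOWN, two-sided 2·min(tails) capped at 1 for DIFF;
* fold change 2^(x_vu − μ_v) ≥ `fold_threshold` (default 1.4) for UP,
  ≤ 1/1.4 for DOWN, either deviation for DIFF. Values are assumed log2
  (Affymetrix convention); a `log2_transform` flag applies log2(x+1) to raw
  intensities at load time to avoid silent double-logging.

Genes with σ_v = 0 are flagged and never called — the normal model is
undefined and calling them would be anti-conservative. For DIFF the fold
gate accepts a deviation in either direction; DIFF calls are therefore a
subset of the union of UP and DOWN calls (the two-sided p is stricter).
No multiple-testing correction is applied at this stage by design: the
per-entry 5% leakage is part of the model and is absorbed downstream by the
cover search and the permutation null. Under the null the per-entry call
rate is bounded by `p_threshold` (the fold gate only removes calls); the
test suite verifies this by simulation.

## The cover problem

The calls form a binary genes × cases incidence; row v is the cover set S_v.
A **connected (k,l)-cover** is C ⊆ V inducing a connected subgraph with at
least n − l of the n cases covered ≥ k times by the sets of C. Minimizing
|C| (MCC) generalizes set cover (complete graph, k = 1, l = 0) and set
multicover, hence is NP-hard. Because biologically coherent modules tend to
be compact, the driver solves the minimal-radius variant (MRMCC): find the
smallest r_min such that some node's r_min-neighborhood contains a valid
cover, then return the smallest cover found within any such neighborhood.

* **Radius scan.** From every root, a BFS increments a per-case counting
  array as nodes are reached; after each completed level the coverage
  condition is tested (the root's level 0 counts before the first test —
  the r-neighborhood includes the root). A running cap (the best radius so
  far) halts later BFS runs one level past the cap. Any BFS ball is
  connected, so feasibility of the whole ball equals existence of a cover
  inside it. A per-component coverage pre-check short-circuits infeasible
  instances.
* **Greedy expansion.** Rooted at each candidate, the partial cover W grows
  by the adjacent allowed node with the largest gain, where gain counts
  cases u ∈ S_v still below k coverage (partial progress toward k counts —
  the natural multicover refinement). Ties are broken by the number of
  distinct cases covered by the candidate's neighbors within the search
  region ("total elements covered by their neighbors", read as a set union),
  then lexicographically by identifier; iteration everywhere follows sorted
  node order, so results are deterministic and label-permutation equivariant.
  The expansion stops when ≤ l cases remain under-covered, or fails if the
  frontier empties first (impossible for roots found by the radius scan).
  Zero-gain connectors are added by the same rule when no candidate gains.
* **Two-phase outlier pass.** The single pass only reveals its l outliers at
  the end, so it can spend nodes on cases that end up discarded. Pass 1 runs
  plainly; its l least-covered cases (from the raw, pre-clean-up cover; ties
  lexicographic) are removed from the universe and pass 2 re-runs with
  l = 0. Both results are cleaned up and the smaller kept (pass 1 on ties),
  so the two-phase result is never worse.
* **Clean-up.** Nodes whose removal preserves both connectivity and the
  (k,l) condition are removed iteratively (lexicographic scan to a fixed
  point; the root is never removed so that the root/radius record stays
  well-defined). The operation is idempotent and validity-preserving.
* **Hub hiding.** Before solving, nodes with degree > `hub_degree` (100)
  whose neighborhood dysregulation score — mean |S_w| over direct neighbors
  w — falls below the `hub_quantile` (0.75, nearest-rank over all nodes'
  scores) are removed in one simultaneous pass. Degree ≤ 100 nodes are never
  touched. This counters the inclusion of heavily studied, highly connected
  genes on connectivity grounds alone.

The greedy carries no approximation guarantee — adversarial instances can
make it Θ(|V|)-suboptimal — which is why the test suite tracks (not asserts)
its exact-match rate against an exhaustive enumerator on instances with
|V| ≤ 12, and asserts only validity and never-better-than-optimal.

## Significance and choice of k

The null model shuffles gene identities over the fixed topology: a uniform
permutation reattaches the cover sets to network positions, preserving the
degree sequence, |V|, |E| and the multiset {S_v}, destroying only the
association between dysregulation and network position. Edge rewiring is
deliberately *not* used. Each shuffled network traverses the full pipeline
(hub hiding is re-applied — neighborhood scores change under relabeling) and
contributes its smallest module size; permutations with no feasible cover
count as larger than any real module (they are evidence for the real
signal). The empirical p-value uses the add-one correction
p = (#{null ≤ real} + 1)/(N + 1), never zero, floor 1/(N+1); the ≤
(equal-or-smaller) comparison is the conservative reading. Default N = 200.

k is scanned over a grid (default 5, 10, 15, 20, 25, 30) with the same
permutation stream reused across k for variance reduction; the chosen k
minimizes p, ties resolved by the most negative z-score of the real size
against a normal fit (mean, ddof-1 sd) of the finite null sizes, then by
smaller k. A z-score is undefined (and excluded from tie-breaks) with fewer
than two finite null sizes or zero variance. l is set to
floor(`outlier_fraction` · n_cases) with `outlier_fraction` = 0.20 by
default; the floor is a conservative choice. Module overlap with reference
gene sets is scored by the upper-tail hypergeometric test.

## Synthetic benchmark

`generate_network` produces a connected preferential-attachment graph
(default m = 2), matching the heavy-tailed degree distribution of curated
interaction networks, or an Erdős–Rényi graph re-grown to size. `plant_dp`
draws control values from N(0, 1) per gene on the log2 scale, grows a
connected planted module by randomized BFS (small radius by construction,
matching the search objective's bias), and in each non-outlier case shifts a
fresh random subset of `per_case_active` (default k) planted genes by +δ
(UP; mirrored for DOWN). Planted outlier cases receive no shift. Background
entries are independently shifted with probability `fp_rate` (default 0.05),
mimicking the calling threshold's null leakage. All generators are
bit-reproducible from the seed.

Benchmark conditions used by the tests and the acceptance script: 100-node
network, 15-gene planted module, k = 10 with per-case active set of 10,
20 cases with 2 planted outliers (l = 4), 10 controls, δ = 4 control-sds.
At these settings the pipeline recovers the planted module with Jaccard
≥ 0.6 in the large majority of seeds and the grid scan selects k within ±5
of the truth. Permutation counts in tests (20–99) and the test problem sizes
(12–120 nodes) are deliberately desk-scale; they are the package's benchmark
choices and exercise every code path of a genome-scale run.

What the generator does *not* emulate: probe-level microarray noise, batch
effects, correlated co-expression among background genes, degree-coverage
correlation (true hubs in real networks are also better measured), or
literature bias in the network itself. Passing the benchmark therefore shows
the machinery is correct and calibrated under its own model assumptions, not
that any particular biological dataset will yield a significant module.

## Numerical conventions and degenerate inputs

* Sorted-identifier iteration everywhere; all residual ties lexicographic.
* Cover sets are bitmasks over case indices; counting arrays are plain
  integer vectors — exact arithmetic, no floating-point in the combinatorial
  core.
* Empty cover C is invalid (not an error); l must satisfy 0 ≤ l < n;
  k ≥ 1; at least 2 controls and 1 case are required.
* Hub hiding may disconnect the graph; the solver treats components
  independently (a cover lives inside one component).
* Infeasible instances raise a distinct error in the library and exit code 3
  in the CLI; input errors exit 2.

## Known limitations

* The greedy solver is a heuristic; no approximation ratio is claimed.
* Exactly one module is reported per run (plus ties); no iterative removal
  of the first module to find secondary pathways.
* The permutation null conditions on the observed incidence matrix; it does
  not model uncertainty in the calling stage itself.
* Runtime of the permutation machinery scales as (permutations × grid size ×
  solve cost); genome-scale networks are feasible but benefit from fewer
  grid points.
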