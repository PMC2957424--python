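# dysnet

Detection of minimal connected **dysregulated pathways** in case/control
expression studies, on a protein-interaction network.

## The problem

In most human diseases only a handful of genes are consistently
differentially expressed across patients, yet many patients carry
dysregulated genes belonging to the *same* pathway — just not the same genes.
A per-gene test misses this. dysnet instead looks for a small connected
subnetwork of the interaction network in which **every case sample (up to a
few outliers) has at least k dysregulated genes**, allowing the affected
genes to differ from patient to patient.

Formally, given an undirected network G = (V, E) and, for every gene v, the
set S_v of case samples in which v is dysregulated, a **connected
(k,l)-cover** is a node set C that induces a connected subgraph of G and
satisfies |{v ∈ C : u ∈ S_v}| ≥ k for at least n − l of the n cases. The
method seeks a minimum-cardinality cover among those of minimal radius
(MRMCC): the smallest radius r_min such that some node's r-neighborhood
contains a valid cover, then the smallest cover found inside any such
neighborhood. Minimality makes the module the most focused "explanation" of
the disease signal; the radius constraint biases it toward compact,
biologically coherent neighborhoods. The problem generalizes set cover and
is NP-hard, so the solver is a rooted greedy expansion with practical
heuristics (hub hiding, a two-phase outlier pass, a clean-up step), validated
against an exhaustive oracle at small scale.

The pipeline:

1. **Dysregulation calling** — per gene, fit a normal distribution to the
   control samples (mean, sd with ddof=1 on log2 values); call gene v
   dysregulated in case u when the directional tail p-value is < 0.05 *and*
   the fold change `2**(value − control mean)` is ≥ 1.4 (UP), ≤ 1/1.4
   (DOWN), or either (DIFF).
2. **Hub hiding** — drop nodes of degree > 100 whose direct neighborhoods
   show little dysregulation (mean cover-set size below the 75% quantile of
   all neighborhoods), countering study bias in curated networks.
3. **Minimal-radius search** — BFS from every node with a per-case counting
   array finds r_min and the candidate roots; a rooted greedy expansion
   (largest gain in not-yet-k-covered cases; ties by neighborhood coverage,
   then lexicographic) solves the cover problem in each r_min-neighborhood.
4. **Significance and k selection** — shuffle gene labels over the fixed
   topology (200 networks by default), re-run the full pipeline on each, and
   report the add-one empirical p-value of the real module size; k is chosen
   over a grid as the most significant value, with z-score tie-breaks.

## Worked example

Everything below is generated — no downloads. We plant a 15-gene connected
module in a 100-node scale-free network: in each of 20 cases (except 2
outliers) a random 10 of the 15 planted genes are shifted by 4 control-sds;
10 controls are pure noise; 5% of background entries are sporadically
shifted.

```python
from dysnet import DysregulatedPathwayModel, generate_network, plant_dp, recovery_metrics

network = generate_network(100, "ba", seed=11)
truth = plant_dp(network, n_cases=20, n_controls=10, k=10,
                 outlier_cases=2, delta=4.0, seed=11, planted_size=15)

model = DysregulatedPathwayModel(network, truth.study, direction="UP",
                                 k_grid=[5, 10, 15, 20, 25, 30])
res = model.fit(n_permutations=99, seed=0)
print(res.summary())
```

```
Dysregulated subnetwork search
==============================================
direction:        UP
cases/controls:   20 / 10
network:          100 nodes, 196 edges
k (per-case):     10
l (outliers):     4
module size:      17
module radius:    2 (root g001)
tying modules:    1
empirical p:      0.01
z-score:          -2.561

k-selection (size / p / z):
  k=5      9 / 0.28 / -0.90
  k=10    17 / 0.01 / -2.56 <- chosen
  k=15    45 / 0.86 / 0.76
  k=20  infeasible
  k=25  infeasible
  k=30  infeasible

module genes: g001 g002 g003 g008 g009 g010 g014 g016 g026 g028 g038 g039 g044 g050 g057 g060 g068
```

The grid scan lands on the planted k = 10: a 17-gene module whose size is
smaller than in 99 label-shuffled networks (p = 1/100), with
`recovery_metrics(res.nodes, truth.planted_nodes)` giving precision 0.82,
recall 0.93, Jaccard 0.78 against the planted truth. At k = 5 a small module
exists even in shuffled networks (p = 0.28); at k = 15 no case has enough
dysregulated genes for a compact cover.

The same pipeline runs from the shell on TSV inputs:

```bash
dysnet simulate --n-nodes 100 --n-cases 20 --k 10 --out-dir fixture/
dysnet run --network fixture/network.tsv --expression fixture/expression.tsv \
           --labels fixture/labels.tsv --direction UP --out-dir results/
dysnet evaluate --module results/module.json --gene-set pathway.txt --background 100
```

`run` writes the module as JSON/TSV/GML plus a k-selection report and a
reproducibility manifest; `evaluate` reports the hypergeometric overlap
p-value of a module with a reference gene set.

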