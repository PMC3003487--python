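# signet

**signet** is a Python library and command-line toolkit for *signed, typed
gene/protein regulation networks* of the kind assembled by literature
curation for mouse pluripotency: each node is one gene (and its protein
product), and each link is a curated mechanism of one of three types —
directed **stimulation** (SBO:0000170), directed **inhibition**
(SBO:0000169) or undirected **interaction** (SBO:0000231) — annotated with
PubMed references, curator and date.

It is written for systems biologists who keep such networks in Cytoscape
dialects (SIF, XGMML, GraphML, node/edge attribute tables) and want to

* compute the standard undirected topology statistics (average degree,
  clustering coefficient, characteristic path length, diameter, components)
  on the simple projection of the typed multigraph;
* test a network's gene set for GO(-slim) overrepresentation with the
  one-sided hypergeometric test and Benjamini–Hochberg FDR correction;
* **condense** a network against two-condition expression data: every link
  is scored by the change along it,

  `score(s → t) = v2(s)·v2(t) − v1(s)·v1(t)`,

  where `v_c(g)` is gene *g*'s mean (optionally log2-transformed,
  optionally variance-corrected) expression in condition *c*; positive
  scores are *startup* hypotheses, negative ones *shutdowns*, and the top
  k% of each tail is retained;
* overlay per-gene two-condition expression as green/white/red colors;
* compare networks (node/link overlap under configurable link-identity
  semantics) and diff versions;
* generate synthetic networks and two-condition expression matrices with
  *planted* differential links, so every analysis is testable offline with
  known ground truth.

## Worked example

```python
from signet import (
    NetworkGenParams, ExpressionGenParams, simulate_network, choose_planted,
    simulate_expression, topology_summary, condense, recovery_rate,
)

# a synthetic curated-scale network: 274 genes, 574 typed links
net = simulate_network(NetworkGenParams(seed=1))
print(topology_summary(net))

# plant 10 differential links (5 startups, 5 shutdowns) at 3-SD effects
planted = choose_planted(net, 10, seed=1)
params = ExpressionGenParams(direction=planted, effect_size=3.0,
                             n_replicates=3, seed=99)
pair = simulate_expression(net, params)
result = condense(net, pair, fraction=0.05)
print(len(result.startups), len(result.shutdowns), result.n_scored)
print(recovery_rate(result, params))
```

prints

```
TopologySummary(n_nodes=274, n_link_records=574, n_simple_edges=561,
avg_degree=4.094890510948905, clustering_coefficient=0.03191666651051747,
characteristic_path_length=3.3136520241171405, diameter=7, n_components=59)
28 28 574
1.0
```

Reading: the 574 curated link records collapse to 561 simple undirected
edges (average degree 4.09); condensation at 5% keeps the 28
highest-scoring startups and the 28 strongest shutdowns out of 574 scored
links, and every one of the 10 planted links lands in its correct tail
(recovery rate 1.0).

The same operations are available from the shell:

```sh
signet simulate network --nodes 274 --links 574 --seed 1 --out net.sif
signet stats --network net.sif --out report.tsv
signet condense --network net.sif --expr expr.tsv --fraction 0.05 --out condensed.sif
signet enrich --genes genes.txt --annot annotations.tsv --alpha 0.05 --out enrich.tsv
signet compare --a net.sif --b other.sif --out overlap.tsv
signet convert --in net.sif --out net.graphml
```

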