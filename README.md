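# micronet

Module-aware co-occurrence network analysis for microbiome abundance
tables.

Microbial community studies routinely summarize an OTU/ASV count table as a
**co-occurrence network**: taxa are nodes, and an edge connects two taxa
whose abundances are significantly correlated across samples.  The
interesting biology usually lives in the network's **modules** — groups of
densely inter-correlated taxa — but general-purpose graph drawing scatters
module members across the canvas.  `micronet` builds the network, finds the
modules, and lays the network out with **ten module-aware layout
algorithms** that render each module as a visual unit (rings on polygon
vertices, size-scaled discs, progressively packed circles, a shared circle
with per-module arcs, and a force-directed embedding), then mines the
result: network/node property tables, Zi–Pi node roles, and an
Erdős–Rényi null-model comparison.

## The statistics at the core

* **Correlation networks.**  For taxa $i, j$ with abundance vectors over
  $n$ samples, `micronet` computes Pearson, Spearman (Pearson on
  midranks) or Kendall $\tau_b$ correlations with two-sided p-values
  (the $t = r\sqrt{(n-2)/(1-r^2)}$ approximation for Pearson/Spearman),
  or the basic **SparCC** estimator for compositional counts: with
  log-ratio variances $t_{ij} = \mathrm{Var}\log(x_i/x_j)$ and the sparsity
  approximation, basis variances solve
  $\omega_i^2 = (t_i - T_\omega)/(D-2)$ and
  $r_{ij} = (\omega_i^2 + \omega_j^2 - t_{ij}) / (2\,\omega_i\,\omega_j)$.
  Edges are retained when $|r| \ge r_{\min}$ (default 0.6) and
  $p \le p_{\max}$ (default 0.05), optionally after Benjamini–Hochberg
  adjustment.  A bipartite mode (e.g. bacteria–fungi) masks all
  within-group correlations before filtering.
* **Modules.**  Greedy (Clauset–Newman–Moore) modularity maximization;
  $Q = \sum_s [\, l_s/L - (d_s/2L)^2 \,]$.
* **Node roles.**  Within-module degree z-score
  $Z_i = (\kappa_i - \bar\kappa_{s_i}) / \sigma_{\kappa,s_i}$ and
  participation coefficient $P_i = 1 - \sum_s (\kappa_{is}/k_i)^2$;
  thresholds $Z = 2.5$, $P = 0.62$ classify peripherals, connectors,
  module hubs and network hubs.
* **Null model.**  $G(n, m)$ ensembles matched to the observed node and
  edge counts give a mean, sd and z-score for each compared property.

## Worked example

Simulate a 60-taxon, 50-sample table with 4 planted modules, then run the
default pipeline (Spearman, $|r| \ge 0.6$, $p \le 0.05$, maptree layout,
100 null replicates):

```bash
micronet simulate --seed 7 --out demo/sim
micronet pipeline demo/sim/abundance.csv --seed 1 --out demo/net
```

which prints

```
wrote demo/sim/abundance.csv (60 taxa x 50 samples)
INFO correlation: 60 taxa kept, method=spearman
INFO filter: 410 edges retained (|r|>=0.6, p<=0.05, adjust=none)
INFO modules: 4 detected, Q=0.7497
INFO zipi: roles {'peripheral': 60}
done: 410 edges, 4 modules (Q=0.7497) -> demo/net
```

The four planted modules are recovered exactly (Q = 0.75 is the
theoretical maximum for four equal disconnected modules), and every node
is peripheral — planted blocks have no hub structure.  `demo/net/`
contains `edges.csv`, `nodes.csv` (module, coordinates, degree, Zi, Pi,
role), `network.graphml` (opens in Gephi/Cytoscape), `netprops.csv`,
`nullcomp.csv`, `zipi.csv`, `plot.svg` and a `manifest.json` recording the
configuration and per-stage seeds.  `nullcomp.csv` shows the planted
structure is wildly non-random, e.g.

```
property,observed,null_mean,null_sd,z
transitivity,0.979,0.230,0.008,89.1
modularity_Q,0.750,0.177,0.008,68.1
```

Layouts can also be run on their own
(`micronet layout demo/net/edges.csv --algorithm PolygonRrClusterG --out demo/lay`),
and everything is available as a library:

```python
from micronet import (SynthSpec, simulate_abundance, correlate,
                      filter_edges, build_graph, detect_modules, layout)

table, truth = simulate_abundance(SynthSpec(seed=7))
net = build_graph(filter_edges(correlate(table, "spearman")))
part = detect_modules(net)
coords = layout(net, part, "model_maptree")
```

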