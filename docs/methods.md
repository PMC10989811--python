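# Methods

This note documents the models and algorithms implemented in `micronet`,
the defaults and why they were chosen, the synthetic benchmark the tests
rely on, and known limitations.

## Correlation stage

`correlate()` operates on a taxon-by-sample table with at least 4 samples.
Taxa observed in fewer than `min_prevalence` of samples are dropped first
(default 0: keep everything; prevalence filtering is a common pre-step but
its threshold is study-specific).

* **Pearson**: moment correlation; two-sided p from
  `t = r·sqrt((n−2)/(1−r²))` on `n−2` df.
* **Spearman**: Pearson applied to midranks, same t approximation.  This
  identity is asserted against an explicit tie-group-averaging midrank
  oracle in the tests.
* **Kendall**: τ-b with the tie-corrected normal approximation
  (scipy's asymptotic method).  Exact enumeration is pointless at
  microbiome sample sizes.
* **SparCC** (basic one-pass estimator): counts plus a pseudocount
  (default 1) are closed per sample into fractions; `t_ij` is the sample
  variance of `log(f_i/f_j)`; with `t_i = Σ_j t_ij` and
  `T_ω = Σ t_i / (2(D−1))`, basis variances are
  `ω_i² = max((t_i − T_ω)/(D−2), 1e−12)` — algebraically the exact
  solution of the sparsity-approximated linear system
  `t_i = (D−2)ω_i² + Σ_j ω_j²`, which the tests verify by solving that
  system with a dense matrix inverse.  Correlations are clamped to
  [−1, 1].  The iterative strong-pair-exclusion refinement of full SparCC
  is deliberately omitted: the one-pass estimator is transparent,
  deterministic, and adequate at the module-detection thresholds this
  toolkit uses.  SparCC requires D ≥ 4 taxa (the approximation divides by
  D−2).  P-values, when requested, come from a permutation test that
  shuffles each taxon's samples independently (default 100 permutations,
  two-sided empirical p with the +1 correction); otherwise the P matrix is
  an all-zero placeholder and the result is flagged.

Constant taxa get r = 0, p = 1 and are reported in a warning list rather
than raising — dropping them silently would desynchronize taxon sets
between stages.

**Edge filter.** Pairs survive when `|r| ≥ r_min` and (BH-adjusted, if
requested) `p ≤ p_max`.  Thresholding |r| keeps both co-presence and
mutual-exclusion edges; signs are carried through to the graph, the
GraphML export and the renderer.  Defaults r_min = 0.6, p_max = 0.05, no
adjustment — the conventional settings for microbiome co-occurrence
networks; BH is available because edge counts are threshold-sensitive.
The bipartite restriction zeroes within-group entries (r = 0, p = 1)
before filtering, so only cross-group edges can survive.

## Module detection

Greedy agglomerative (CNM) modularity maximization on the unweighted
skeleton, via networkx's `greedy_modularity_communities`; an |r|-weighted
variant sits behind a flag.  The unweighted default reflects standard
practice for thresholded co-occurrence networks, where edge presence, not
magnitude, is the signal.  Zero-edge graphs fall back to all-singleton
partitions with Q = 0.  Module labels are `module_1, module_2, …` ranked
by decreasing size, ties broken by the lexicographically smallest member
taxon, so labels are deterministic and stable across runs.  Greedy
merging is deterministic but, like any agglomerative scheme, can differ
from other fast-greedy implementations in tie situations; the tests pin
its behavior to the exhaustive-search optimum on small benchmark graphs
(disjoint cliques, barbells) instead of to another library's tie-breaks.

`pool_small_modules(min_size)` merges sub-threshold modules into a single
`module_other` for legible layouts; default min_size = 1 (off) so module
counts match detection output unless explicitly requested.

## Layout algorithms

All ten algorithms are pure functions of (graph, partition, parameters,
seed).  Shared conventions, chosen once where the field leaves them open:

* modules are processed in size-rank order;
* within a ring, nodes are sorted by degree descending (ties by taxon ID)
  so hubs occupy corresponding angular positions across modules;
* on-ring layouts scale ring radius linearly with node count
  (circumference ∝ n), fill-the-disc layouts with √n (area ∝ n);
* a single `gap` parameter (default one tenth of the largest module
  radius) governs all separations, which makes every disc-based layout
  scale-equivariant: multiplying radius/scale parameters by c multiplies
  all coordinates by c.

The individual algorithms:

* **PolygonClusterG** — equal-radius rings on the vertices of a regular
  m-gon.  Circumradius `R = (2·max r + gap)/(2 sin(π/m))` guarantees
  adjacent (hence all) discs clear each other by ≥ gap; module_1 sits at
  the top vertex, subsequent modules counterclockwise.
* **PolygonRrClusterG** — same placement, ring radius `scale·n_k/(2π)` so
  inter-node arc length is `scale` in every module.
* **randomClusterG** — equal rings at rejection-sampled centers, uniform
  in a square of side `2√m(2r+gap)`; after 1000 consecutive rejections
  the square doubles, so placement always terminates.
* **ArtifCluster** — rings at user-supplied centers; overlap is honored
  (user intent) with a warning.
* **randSNEClusterG** — each module's induced subgraph laid out by a
  classical sublayout (Fruchterman–Reingold or circle), centered and
  rescaled to the module disc, discs placed by the randomClusterG scheme.
  The sublayout is a parameter rather than a fixed list.
* **PolygonModsquareG** — size-scaled rings in rows of `row_len`
  (default ⌈√m⌉); horizontal neighbor spacing `r_prev + r_next + gap`,
  vertical row spacing the sum of adjacent rows' largest radii plus gap,
  which makes discs provably disjoint.
* **PolyRdmNotdCirG** — discs of radius `scale·√n_k` on polygon vertices,
  nodes i.i.d. uniform in their disc (`ρ = r√u`, `θ = 2πv`); the √u law
  gives uniform area density (tested against the closed form E ρ = 2r/3).
* **model_Gephi.2** — one shared circle; modules occupy contiguous arcs
  proportional to module size with an angular gap between consecutive
  modules.  The underlying idea (single circle, clusters re-assigned along
  it) admits several readings; contiguous proportional arcs is the
  well-defined one implemented here.
* **model_igraph** — textbook Fruchterman–Reingold: `k = √(area/n)`,
  repulsion `k²/d` between all pairs, attraction `d²/k` along edges,
  displacement capped by a temperature cooled linearly from `0.1√area`
  over 200 iterations, initial positions uniform in the area square
  (default area = n).  Pure-numpy and bitwise deterministic given a seed.
  Degree-based grouping is an emergent property, not a constraint.
* **model_maptree** — module circles of radius `scale·√n_k + pad` packed
  progressively: first at the origin, second tangent on the +x axis, each
  later circle externally tangent to a pair of placed circles, choosing
  among all non-overlapping tangency candidates (tolerance 1e−9) the
  center nearest the origin, ties by smaller polar angle in [0, 2π).
  The candidate search is the naive O(n³) scan — module counts are tens,
  not thousands, so the front-chain optimization is not worth its
  complexity.  Within a circle, nodes follow a sunflower (phyllotaxis)
  spiral, `ρ_j = 0.9·r·√((j+0.5)/n)`, `θ_j = j·π(3−√5)`; the 0.9 factor
  keeps every node strictly interior.

## Network, node and role statistics

`net_properties` reports 16 whole-network quantities.  Path-based
statistics average over finite within-component ordered pairs (the igraph
convention; no infinity propagation); edge connectivity is the global
min-cut of the largest component; closeness and betweenness
centralization use Freeman's formula normalized by the star-graph
maximum, so a star scores exactly 1 on both.  `node_properties` uses
Brandes betweenness (normalized), unscaled closeness `reachable/Σd`
restricted to the node's component (isolates get 0), and eigenvector
centrality by power iteration (tolerance 1e−10, ≤ 10⁴ iterations,
uniform start, max-normalized).  The iteration multiplies by A + I rather
than A: identical dominant eigenvector, but convergent on bipartite
graphs whose ±λ eigenvalue pair stalls plain power iteration.
Non-convergence raises.

`zipi` uses the population (n-denominator) standard deviation for Zi,
with Zi = 0 flagged when a module's κ values are constant (including
singleton modules), and Pi = 0 for isolated nodes.  Default thresholds
Zi = 2.5 and Pi = 0.62 are the Guimerà–Amaral convention; only the
four-quadrant classification is implemented, not the seven-region
taxonomy.

## Null model

`compare_to_random` draws `n_reps` (default 100) G(n, m) graphs with the
observed node and edge counts — m distinct pairs sampled uniformly
without replacement — and re-detects modules per replicate, comparing
average path length, diameter, transitivity, mean local clustering and
modularity Q.  Matching m exactly (rather than G(n, p)) removes edge-count
variance from a per-network comparison; every replicate conserves n and m
exactly and each specific pair appears with probability m/C(n, 2)
(verified at ±0.01 over 10⁴ draws).  A degree-preserving
configuration-model ensemble is available behind a flag.  z-scores with a
zero null sd are reported as NaN rather than ±∞.

## Synthetic benchmark

`simulate_abundance` draws, per sample, one standard-normal factor per
module (plus an optional global factor when rho_out > 0) and sets each
taxon's latent value to
`√rho_out·h + √(rho_in−rho_out)·g_module + √(1−rho_in)·noise_sd·ε`,
giving within-module latent correlation rho_in and between-module
correlation rho_out when noise_sd = 1.  Latents are softmax-normalized
per sample into relative abundances and observed as Poisson counts at
mean depth `depth`.  Defaults — 60 taxa, 50 samples, 4 modules,
rho_in = 0.8, rho_out = 0, depth = 10⁴ — describe a modest amplicon
study with strong planted structure; depth 10⁴ over 60 taxa leaves
enough counts per taxon that rank correlations track the latent layer.
`simulate_bipartite` plants correlated pairs only across two groups
(defaults: 10 + 10 taxa, 5 planted pairs), so the bipartite restriction
can never mask a planted signal.

Every generator operation uses its own `default_rng([seed, label])`
PCG64 stream with a fixed integer label (abundance = 1, bipartite = 2):
identical seeds give identical tables across platforms, and new
operations never perturb existing fixtures.

What the generator does **not** emulate: overdispersion beyond Poisson,
zero inflation, taxon-specific mean/variance structure, sample covariates
or longitudinal designs.  Passing the recovery benchmarks therefore shows
the pipeline machinery is correct under clean planted structure, not that
the default thresholds are optimal for any particular real dataset.

The pipeline derives per-stage seeds from the master seed by fixed offsets
(recorded in the manifest), so stage-by-stage manual invocation reproduces
`run_pipeline` outputs exactly; benchmark problem sizes in the test suite
(≤ 60 taxa, ≤ 30-node oracle graphs, 10⁴ null draws) were chosen so the
brute-force oracles stay exact while the whole suite runs in seconds.

## Known limitations

* SparCC is the one-pass estimator; strongly correlated pairs bias the
  basis variances more than in the iterative original.
* Greedy modularity can split or merge modules differently from other
  fast-greedy implementations in tie situations, and is not guaranteed
  optimal on arbitrary graphs.
* The renderer is a minimal, deterministic SVG writer (module-colored
  nodes, sign-colored edges); it aims at faithful coordinates, not
  publication styling.
* No BIOM/HDF5 ingestion; tables are CSV/TSV.
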