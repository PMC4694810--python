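# Methods

## Model and assumptions

The pipeline infers functional synergy between lncRNA pairs by
guilt-by-association: a gene set jointly co-expressed with both lncRNAs,
coherent under one GO Biological Process term, and proximal in the protein
interaction network is taken as evidence that the pair co-regulates that
process. The statistical machinery assumes:

- expression matrices are already normalized and log2-transformed, with
  complete (no missing) finite values; no normalization is performed, and
  missing values are rejected rather than pairwise-deleted;
- lncRNA and mRNA identifier universes are disjoint (validated at load);
- the PPI network is an undirected simple graph; only its maximum connected
  component is analysed (ties between equal components are broken by the
  lexicographically smallest sorted node list so loads are deterministic);
- samples are exchangeable across the expression and clinical tables and are
  matched by sample id.

### Stage 1 — expression-correlated genes (LCGs)

Each mRNA is regressed on each lncRNA by ordinary least squares; the
two-sided t-test on the slope is numerically identical to the Pearson
correlation t-test, which the vectorized screen exploits. Genes with
p strictly below `alpha_lcg` form the lncRNA's LCG set. Constant vectors
admit no association test and get p = 1 with a degeneracy flag.

### Stage 2 — shared-LCG enrichment

Pairs sharing at least `min_common_lcgs` genes (default 3) are enumerated
through an inverted gene→lncRNA index, never by an all-pairs scan. The shared
set is tested against every retained GO term with the upper-tail
hypergeometric probability, computed by log-space summation
(`math.lgamma`-based log-binomials with a max-shifted `fsum`), so
transcriptome-scale arguments do not underflow. The background N is the
number of measured genes annotated to at least one retained term, and both
the shared-set size M and the overlap x are counted inside that background —
otherwise M could exceed N and the hypergeometric model would be incoherent.
Per pair, p-values across all I retained terms are corrected by
Benjamini–Hochberg by default (`enrich_correction` ∈ {none, BH, bonferroni})
at `alpha_enrich` = 0.01; the enrichment level and correction are deliberate
configuration, since only the test itself — not its level — is fixed by the
method definition.

### Stage 3 — PPI topology filter

Distances are shortest paths in the **full** PPI graph, not the induced
subgraph: induced subgraphs of 3–10 genes are almost always disconnected,
which would make the criteria vacuous. Criterion (i) follows the "nearest
other member ≤ 2" reading (`min_dist_rule="nearest"`); the stricter all-pairs
reading is available as `all_pairs`. Criterion (ii) compares the module's
characteristic path length (CPL; +∞ when any pair is unreachable) against a
pool of `n_random` degree-preserving randomizations produced by edge
switching (10 attempted swaps per edge; swaps creating self-loops or
parallel edges are rejected, so the degree sequence is exactly invariant).
One pool is generated per input network and reused for every module — the
null randomizes the network, not the module — and identical gene sets are
evaluated once. The empirical p-value is (1 + #{CPL_random < CPL_real}) /
(1 + n_random): the pseudocount avoids p = 0, and ties count as *not*
shorter. Because of the strict inequality, p is slightly conservative under
heavy ties; the calibration test therefore uses module sizes whose CPL takes
many distinct values. Criterion (ii) is skipped when (i) already failed.

### Downstream analyses

- **Power law.** Discrete maximum-likelihood exponent (zeta-normalized
  likelihood, bounded search over α ∈ (1, 12]) with the lower cutoff xmin
  chosen by KS minimization. A degenerate (all-equal) degree sequence is an
  error.
- **Hubs.** The ⌈fraction·n⌉ highest-connectivity nodes (default fraction
  0.10); ties at the cutoff break lexicographically. In the weighted variant,
  connectivity is node strength (sum of incident edge weights) and modules
  are re-detected after thresholding edges at a gradient of minimum weights.
- **Clique percolation.** Communities are connected components of the
  k-clique adjacency graph (two k-cliques adjacent iff they share k−1
  nodes); nodes may belong to several communities. Default k = 3, with a
  k-sweep reporting counts and cumulative lncRNA participation.
- **Chromosome co-localization.** Pair distance is the gap between the two
  intervals (0 if they overlap); "within 10 Mb" is a strict inequality. The
  permutation p-value shuffles the lncRNA→coordinate assignment
  ((1+r)/(1+n_perm) form). The choice of permutation null is ours; no
  specific test is prescribed for this quantity.
- **Wilcoxon / Fisher.** The rank-sum test is exact (full enumeration via
  the Mann-Whitney exact distribution) on small tie-free samples and a
  tie-corrected normal approximation otherwise; an all-tied input returns
  p = 1 by convention. Fisher's exact test is the standard two-sided
  conditional test; the fully degenerate table (special = target = universe)
  is flagged and given p = 1.
- **Hallmarks.** An edge enters a hallmark subnetwork when ≥ 1 of its
  modules' terms maps to that hallmark; a hallmark is "present" when its
  subnetwork has ≥ 1 edge. The GO-term→hallmark map is a user-supplied TSV
  (a toy ten-hallmark map ships with the synthetic generator); re-curating a
  published map is out of scope.
- **Prognostic modules.** Modules are MCL clusters (expansion 2, inflation
  2.0, self-loops added, column renormalization, convergence at max-change
  < 1e-6 or 100 iterations — the algorithm's canonical defaults) inside each
  hallmark subnetwork. Clusters smaller than 3 lncRNAs are discarded: two
  expression profiles are too few to cluster patients on. "K means
  agglomerative clustering (K = 2)" is contradictory on its face; we read
  "K = 2" as the operative constraint and implement K-means with 20 seeded
  restarts (Ward agglomerative clustering cut at 2 is available via
  `cluster_method="ward"`). Group 1 is always the higher
  mean-module-expression group so hazard ratios orient consistently. The
  log-rank screen uses p < 0.05; surviving modules are re-fit in a Cox
  proportional-hazards model with the clinical covariates (Breslow tie
  handling, lifelines). Separation or non-convergence yields a flagged,
  non-significant result rather than a crash; a covariate collinear with the
  group indicator is an error.
- **Confounder exclusion.** Co-localization is an interval gap ≤ 5,000 bp
  (inclusive, BEDTools-window semantics; overlap = gap 0; strand-agnostic).
  Co-regulation uses active TF→target edges (univariate regression,
  Benjamini–Hochberg FDR < 0.01 across all candidate edges jointly) and the
  score r = √(r_AB·r_BA), with strict r > 0.8; r is defined as 0 when either
  TF set is empty, preventing spurious exclusions. The filter is off by
  default — it is a robustness analysis, not part of the core definition.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha_lcg` | 1e-10 | p-value | Bonferroni-scale cutoff for a ~10^4 × ~2·10^4 regression screen; exposed rather than recomputed per dataset |
| `min_common_lcgs` | 3 | genes | a functional module needs at least three genes |
| `alpha_enrich` / `enrich_correction` | 0.01 / BH | p-value | enrichment level is not fixed by the method; BH across the I terms per pair |
| `n_random` | 1000 | networks | randomization pool size (tests and desk-scale runs use 100; repeated-null studies 30) |
| `cpl_threshold` | 0.05 | p-value | "significantly shorter" operationalized at the conventional level |
| `hub_fraction` | 0.10 | fraction | top decile of connectivity |
| `k_min..k_max` | 3..6 | clique size | k-sweep of clique percolation |
| MCL inflation / expansion | 2.0 / 2 | — | canonical MCL defaults |
| co-localization gap | 5,000 | bp | inclusive window |
| co-regulation r | > 0.8 | ratio | strict inequality |
| colocalization window | 10 Mb | bp | strict inequality on interval gap |

## The synthetic generator

`ScenarioConfig` defaults define the package's reference desk-scale study:
60 lncRNAs, 600 genes, 120 samples, 6 planted pairs of 8 genes each, joint
effect 0.9 with residual noise sd 0.5 on a log2 scale with baseline 8 and
lncRNA sd 1.5 (typical of log2 array intensities), a Barabási–Albert PPI
backbone (m = 2, scale-free like observed PPI networks) with each planted
module densified into a clique, one superset GO term per planted module plus
30 decoy terms, an exponential proportional-hazards survival model
(baseline median 1000 days, ~70% events via independent exponential
censoring, log-hazard shift `risk_effect` = 1.5 per standardized unit of the
risk module's mean lncRNA expression), and a 5% confounded fraction
(lncRNA–gene pairs placed within 5 kb or given identical TF complements).

Planted gene expression is `effect · (lncA + lncB)/2 + noise`: each planted
gene correlates with either driver at most at 1/√2 even without noise, so
detection at α = 1e-10 with 120 samples has a finite margin and pair
recovery is seed-dependent at the edges (across seeds, precision is
essentially always 1 while recall typically sits between 0.83 and 1.0).
When ≥ 3 pairs are planted, the first three form a triangle over three
lncRNAs; the triangle is the survival risk module, because a prognostic
module must have ≥ 3 members to survive module-size filtering, and its three
GO terms map to one hallmark so the module stays intact inside a single
hallmark subnetwork.

What the generator does **not** emulate: probe/batch structure, realistic
genome annotation or gene length distributions, GO term overlap hierarchies,
correlated survival covariates, or mRNA–mRNA co-expression beyond the
planted modules. Passing tests therefore demonstrate the pipeline's internal
correctness and its recovery of the planted generative structure — not
performance on real tumor transcriptomes.

## Numerical choices and degenerate inputs

- Hypergeometric tails: log-space summation, exact 1.0 at x = 0; inconsistent
  counts (x > min(K,M), K or M > N) are domain errors.
- Regression p-values are clipped to [0, 1]; |r| = 1 maps to p = 0.
- Empirical p-values always use the (r+1)/(n+1) pseudocount form.
- BED coordinates are 0-based half-open everywhere; reciprocal-overlap
  matching (80% of both intervals) breaks ties by larger overlap fraction,
  then lexicographic id.
- K-means uses `n_restarts` = 20 seeded initializations; identical samples
  are a "degenerate clustering" error.
- MCL prunes entries below 1e-12 during iteration and reads clusters from
  attractor rows at threshold 1e-8; numerically orphaned nodes become
  singletons so every node is assigned.
- All stochastic stages draw from named SHA-256-derived substreams of the
  single run seed; reruns are byte-identical.

## Problem sizes used by the test suite and acceptance script

The shipped checks run at desk scale by design: randomization pools of 100
networks (30 in repeated-null studies), 5 replicate reference scenarios,
20 seeds for the no-co-expression null and 100 seeds for the no-survival-
signal null, exhaustive hypergeometric verification up to N = 60, and oracle
comparisons on graphs of ≤ 12 nodes. These sizes give stable Monte-Carlo
estimates while keeping a full run in the minutes range on one CPU.

## Known limitations

- The LCG screen is univariate; partial correlation, multivariate or
  regularized models are out of scope, so dense co-expression (e.g., strong
  global factors) inflates shared LCG counts.
- GO terms are used as flat sets (no true-path propagation); overlapping
  terms yield one candidate module per term by design.
- The CPL null conditions only on the degree sequence; real PPI networks
  carry additional structure (clustering, assortativity) that the null does
  not preserve, so CPL p-values are calibrated against the degree-sequence
  null, not against "biological randomness".
- Cox models assume proportional hazards; no diagnostics or competing-risk
  handling are provided.
- The prognostic false-flag rate under a null survival signal sits near its
  nominal 5% bound by construction (log-rank screen at 0.05 followed by a
  strongly correlated Cox Wald test), so small-sample estimates of that rate
  fluctuate around 0.03–0.05.
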