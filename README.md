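# lfsn — lncRNA functional synergistic networks

`lfsn` builds and analyses **lncRNA–lncRNA functional synergistic networks
(LFSNs)** from paired lncRNA/mRNA expression profiles, GO Biological Process
annotation and a protein–protein interaction (PPI) network. It is aimed at
computational biologists studying the combined (synergistic) action of long
non-coding RNAs in cancer transcriptomes, where single-lncRNA analyses miss
joint regulation.

## The method

Two lncRNAs *A* and *B* are called **functionally synergistic** when they
co-regulate at least one *functional module* — a gene set that passes three
successive gates:

1. **Shared correlated genes.** For every lncRNA, the set of
   lncRNA-expression correlated genes (LCGs) is found by univariate linear
   regression of each mRNA on the lncRNA, keeping genes with a two-sided
   slope-test p < α (default α = 1e-10, a Bonferroni-scale cutoff for
   transcriptome-wide screens). A pair is only considered if its LCG sets
   share at least three genes.
2. **Functional coherence.** The shared LCGs are tested against every GO BP
   term (terms restricted to 5–500 annotated genes) with the upper-tail
   hypergeometric probability

   p_i = 1 − Σ_{t=0}^{x−1} C(K_i, t) C(N−K_i, M−t) / C(N, M),

   where *N* is the annotated background, *K_i* the term size, *M* the shared
   LCG count and *x* their overlap. Each enriched term yields a candidate
   module *G_AB* (the shared LCGs annotated to that term).
3. **PPI proximity.** A candidate module must satisfy (i) every member gene
   lies within shortest-path distance 2 of its nearest other member, and
   (ii) its characteristic path length (mean pairwise shortest-path distance)
   is significantly shorter than in 1,000 degree-preserving (edge-switched)
   randomizations of the PPI network (empirical p < 0.05).

All surviving pairs are assembled into the LFSN (edge weight = number of
shared modules). Downstream analyses: discrete power-law fit of the degree
distribution, top-decile hubs, k-clique-percolation modules, chromosome
co-localization of synergistic pairs, hallmark-of-cancer subnetworks,
Markov-clustering (MCL) modules within each hallmark subnetwork, and
prognostic-module testing (K = 2 sample clustering on module expression →
log-rank screen → covariate-adjusted Cox proportional-hazards model).
A confounder filter can exclude lncRNA–gene pairs that are co-localized
(≤ 5 kb) or co-regulated by shared transcription factors
(r = √(r_AB·r_BA) > 0.8).

Every stage is exercisable end-to-end on seeded synthetic data with planted
ground truth (`lfsn.synthetic_data`), so the pipeline is fully testable
without external downloads.

## Worked example

```python
from lfsn import ScenarioConfig, generate, RunConfig, run_bundle, truth_eval

bundle = generate(ScenarioConfig(seed=1))        # 60 lncRNAs, 600 genes,
res = run_bundle(bundle, RunConfig(n_random=100, # 120 samples, 6 planted pairs
                                   seed=1))
print(res.counts["n_edges"], res.counts["n_network_lncs"])
print(truth_eval(res.lfsn.edges(), bundle.truth_pairs))
for r in res.prognostic:
    if r.significant:
        print(sorted(r.members), round(r.logrank_p, 6), round(r.hazard_ratio, 2))
```

prints

```
6 9
{'n_predicted': 6, 'n_truth': 6, 'n_true_positive': 6, 'precision': 1.0, 'recall': 1.0}
['lnc0000', 'lnc0001', 'lnc0002'] 0.0 7.41
```

All six planted synergistic pairs are recovered with no false edges
(precision = recall = 1.0), and the planted survival-associated module — the
triangle of lncRNAs whose mean expression drives the simulated hazard — is
flagged as prognostic (log-rank p ≈ 8.5e-15; covariate-adjusted hazard ratio
7.4 between the high- and low-expression patient groups).

The same run is available from the shell:

```bash
lfsn simulate --seed 1 --out bundle/
lfsn run --config run.yaml --out results_dir/   # paths + thresholds in YAML
lfsn report --run-dir results_dir/
```

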