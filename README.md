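# rmtnet

Co-occurrence network analysis for microbial community profiles, with the
similarity threshold chosen automatically by random matrix theory (RMT).

Microbial ecologists routinely infer "who occurs with whom" networks from
OTU-by-sample abundance tables: OTUs are nodes, and two OTUs are linked when
the absolute Pearson correlation of their abundance profiles exceeds a
threshold.  The weak point of such relevance networks is the threshold
itself, usually picked by hand.  `rmtnet` removes that arbitrariness and
implements the full downstream analysis: topology, modules, node roles,
module eigengenes, degree-preserving null models and trait association.

## The method

Given an abundance matrix Y (n OTUs x m samples):

1. **Preprocess** — per-sample relative abundance, prevalence filter
   (keep OTUs present in >= `min_samples` samples), per-OTU
   standardization x_ik = (y_ik − ȳ_i)/σ_i.
2. **Similarity** — Pearson correlations r_ij = cor(x_i, x_j); similarity
   s_ij = |r_ij|.
3. **RMT threshold** — for a candidate cutoff s_tb, zero all s_ij < s_tb
   and examine the nearest-neighbour spacing distribution (NNSD) of the
   matrix eigenvalues after unfolding.  Random matrix theory predicts
   Gaussian-orthogonal-ensemble statistics,
   P(d) ≈ (πd/2)·exp(−πd²/4), for noise and Poisson statistics,
   P(d) = exp(−d), for system-specific (modular) structure.  The scan
   ascends from 0.3 in steps of 0.1, then refines in steps of 0.01; the
   smallest cutoff whose NNSD passes a χ² goodness-of-fit test against
   exp(−d) at α = 0.01 becomes the network threshold s_t.
4. **Network** — unweighted: a_ij = 1 iff s_ij ≥ s_t; the sign of r_ij is
   kept as an edge attribute.
5. **Analysis** — per-node indices (connectivity, stress centrality,
   betweenness, eigenvector centrality, clustering coefficient,
   vulnerability) and whole-network indices (avgK, GD, efficiency E,
   HD = 1/E, four centralizations, density, avgCC, transitivity,
   connectedness), power-law and C(k) ~ k^−γ fits; fast-greedy modularity
   M = Σ_b [l_b/L − (K_b/2L)²] with Zi–Pi role classification
   (z_i = within-module degree z-score, P_i = 1 − Σ_c (k_ic/k_i)²,
   boundaries z = 2.5, P = 0.62); SVD module eigengenes with variance
   explained Φ_b and module membership MM = cor(x_i, E^b); Maslov–Sneppen
   degree-preserving null ensembles with Z-tests; trait-based OTU
   significance GS_ih = cor(x_i, T_h)² with Mantel / partial Mantel tests
   against connectivity.

## Worked example

No public dataset ships with the package; the built-in generator plants a
known correlation-block community (4 blocks x 20 co-varying OTUs + 120
background OTUs, 30 samples) so every claim can be checked against ground
truth:

```python
import rmtnet

com = rmtnet.generate_community(seed=1)
std = rmtnet.standardize_rows(com.table)
sim = rmtnet.similarity_from_correlation(rmtnet.correlation_matrix(std))
scan = rmtnet.detect_threshold(sim)
net  = rmtnet.build_network(sim, scan.final_threshold)
part = rmtnet.detect_modules(net)
print(scan.final_threshold, net.n, net.L, round(part.modularity, 3))
```

prints `0.47 177 958 0.77`: the NNSD transition is found at s_t = 0.47,
the network keeps 177 of 200 OTUs with 958 links, and fast-greedy
modularity is 0.77 (the four planted blocks are recovered exactly; the
null-ensemble Z-score for M is ≈ 100, see `examples/04_null_models.py`).
The `examples/` directory walks through every capability — construction,
topology + roles, eigengenes + traits, null models, noise robustness —
each printing the numbers it computes and what they mean.

A thin CLI mirrors the library (`rmtnet pipeline --abundance table.tsv
--traits env.tsv --out run/` runs both phases end to end and writes
Cytoscape-ready SIF/TSV exports; per-stage subcommands `simulate`,
`threshold`, `construct`, `topology`, `modules`, `eigengene`, `randomize`,
`traits`, `robustness` operate on the same files).

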