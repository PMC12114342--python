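# wetmicro

Analysis toolbox for wetland litter-decomposition / soil-microbiome
studies. It covers the full computational stack such a study needs once
the field and sequencing work is done:

- **Litter decomposition** — mass loss `R = (M_t0 − M_t)/M_t0`,
  two-time-point decomposition rate `SL = (M_t1 − M_t2)/(t2 − t1) × 100`,
  expected nutrient retention of a two-component mixture
  `(M_ta X_ta Y_ta + M_tb X_tb Y_tb)/(M_ta X_ta + M_tb X_tb)`, and the
  non-additive mixing effect `YME = (observed − expected)/expected`
  (YME > 0 antagonism, < 0 synergism).
- **Diversity** — bias-corrected Chao1, Shannon (nats), Bray–Curtis
  dissimilarity, PCoA, one-way PERMANOVA, Levins' niche breadth
  `B_j = 1/Σ_i P_ij²`.
- **Neutral community model** — Sloan's occurrence-frequency model
  `F(p) = 1 − BetaCDF(d; N m p, N m (1−p))`: fitted migration rate m,
  dispersal index Nm, R², 95 % Wilson prediction envelope and per-taxon
  classification, taxon-bootstrap CI on m.
- **Assembly processes** — abundance-weighted βMNTD, βNTI against a
  taxa-shuffle null, abundance-based Raup–Crick on Bray–Curtis, and the
  five-process partition (heterogeneous / homogeneous selection,
  dispersal limitation, homogenizing dispersal, undominated) from the
  (βNTI, RC) decision rules with thresholds ±2 and ±0.95.
- **Co-occurrence networks** — Spearman correlation networks
  (|ρ| ≥ 0.6, BH-adjusted p ≤ 0.05 by default) and the usual topology
  row: nodes, edges, signed-link percentages, Louvain modularity, mean
  clustering, average degree 2E/N, mean shortest path.
- **PLS path modeling** — reflective (mode A) blocks, centroid inner
  scheme, OLS path coefficients, communalities, R²,
  `GOF = sqrt(mean communality × mean R²)`, bootstrap CIs.
- **Synthetic data** — generators for every regime (birth–death and
  clustered phylogenies, neutral sampling with tunable m, environmental
  filtering with a phylogenetically conserved trait, exponential litter
  decay with injectable mixing interactions, linear structural models
  with exact in-sample coefficients), plus small bundled fixtures.

The audience is microbial ecologists who work from Python: the package
is a library (no CLI); `examples/` holds one short narrative script per
capability.

## Worked example

Fit the neutral model to a simulated neutral community
(`python examples/neutral_model_fit.py`):

```
fitted migration rate m = 0.0996 (true 0.1)
bootstrap 95% CI on m: [0.0943, 0.1039]
Nm = 100   R2 = 0.929
envelope classification:
above      18
within    654
below      31
```

The fitted m recovers the migration rate the community was generated
with; Nm = N·m indexes dispersal, and R² ≈ 0.93 says the neutral
occupancy–abundance curve explains the data almost perfectly — as it
should for data that are neutral by construction. Partitioning assembly
processes on the bundled fixtures
(`python examples/assembly_processes.py`) gives the complementary
picture: the environmental-filtering fixture is dominated by
homogeneous selection (βNTI < −2 for most sample pairs), the neutral
fixture by the stochastic classes.

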