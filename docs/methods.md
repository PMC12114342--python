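# Methods

This note documents the models implemented in `wetmicro`, the numerical
and design choices behind them, what the synthetic generators do and do
not emulate, and the known limitations.

## Litter decomposition statistics

Mass loss and retention quantities are stored as **fractions**; ×100 is
presentation only (`percent=True`). The one deliberate exception is the
two-time-point decomposition rate, which reproduces the conventional
field formula `SL = (M_t1 − M_t2)/(t2 − t1) × 100` literally. Its
absolute value depends on the initial bag mass and carries awkward
"formula units" (g/day × 100); between-group **ratios** of SL are
unit-free and are what the package uses for organ and flooding
contrasts. Bags that gain mass (mineral accretion is common in buried
litter bags) produce a warning and a negative loss rather than a
clamped zero, unless `allow_gain=True`.

Nutrient retention, when not measured directly, is reconstructed as
`(M_t · conc_t)/(M_t0 · conc_t0)` — the fraction of the initial
nutrient pool still in the bag; values above 1 mean nutrient import.
The expected retention of a two-component mixture is the
nutrient-pool-weighted mean of the single-organ retentions, which is
always a convex combination of them; the mixing effect
`YME = (obs − exp)/exp` is classified antagonistic (> 0), synergistic
(< 0) or additive. The default mixture composition is root:rhizome =
1:2 by mass, the composition typical of reed belowground biomass;
overridable per `MixtureSpec`.

## Diversity and ordination

- Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` so
  that tables without doubletons are defined, and refuses non-integer
  input (the estimator is meaningless on relative abundances).
- Shannon uses natural log, the common ecology default.
- Bray–Curtis is computed on the abundances as given; it is a
  semimetric, so no triangle inequality is asserted anywhere.
- PCoA is the eigendecomposition of the Gower-centred matrix
  `−½ J D² J`. Negative eigenvalues (expected for Bray–Curtis input)
  are reported but coordinates are restricted to positive-eigenvalue
  axes, and proportions explained are computed over the positive part.
  The eigenvalue cutoff is `1e−10` relative to the largest eigenvalue.
- PERMANOVA partitions squared distances into among/within-group sums;
  `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` with label permutation.
  With identical replicates in every group the within-group sum is 0
  and F is reported as infinity. The permutation loop is vectorised
  enough that the 500-dataset type-I-error study used in the tests runs
  in seconds. Rarefaction exists (`AbundanceTable.rarefy`, seeded) but
  is **off** by default — depth handling is a study-level decision.
- Levins' niche breadth `B_j = 1/Σ_i P_ij²` is computed from each
  taxon's distribution across samples, so `1 ≤ B_j ≤ n_samples`, and is
  invariant to rescaling a taxon's abundances. The community-level
  value is the within-sample abundance-weighted mean of B over the taxa
  present.

## Sloan neutral community model

Predicted detection frequency is `1 − BetaCDF(d; Nmp, Nm(1−p))`; m is
fitted by bounded scalar least squares on (1e−6, 1], N defaults to the
mean read depth (rounded), and R² = 1 − SSres/SStot is **never
clipped** — negative values are the meaningful statement that the
neutral curve fits worse than a flat frequency.

**Detection limit.** For count tables, "detected" means "drew at least
one read", an event with probability `1 − (1−q)^N` for true relative
abundance q. That soft threshold crosses ½ at `q = ln 2 / N`, so the
default detection limit is `d = ln 2 / N` (`detection="reads"`). The
classical hard threshold `d = 1/N` (`detection="threshold"`) is kept as
an option, but it is measurably inconsistent under read sampling: on
simulated neutral data (N = 1000, m = 0.1) it inflates the fitted m by
roughly a third, while `ln 2 / N` recovers m to within a few percent
across m from 0.05 to 0.5. The 95 % envelope uses Wilson binomial
bounds on the predicted frequency at n = number of samples; taxa are
classed above / within / below it. The bootstrap resamples taxa
(seeded, 999 by default) and reports a percentile CI on m.

## Assembly null models

βMNTD between samples A and B is the abundance-weighted mean distance
from each taxon to its nearest neighbour in the other community
(`0.5·[Σ f_iA min_j δ_ij + Σ f_jB min_i δ_ij]`), with patristic
distances computed once per tree and reused. The βNTI null shuffles
taxon labels across **all** tree tips — richness and abundances remain
untouched — which is implemented as a joint row/column permutation of
the distance matrix; 999 draws by default, seed mandatory for
reproducibility, and a degenerate null (sd = 0, e.g. a star phylogeny)
yields βNTI = 0 with an explicit flag rather than a division error.

Raup–Crick (abundance-based, Bray–Curtis) draws, for each sample pair,
null communities that preserve the sample's richness and read total:
taxa are selected with probability proportional to occurrence frequency
(a weighted sample without replacement via exponential keys), each
selected taxon is seeded with one read, and the remaining reads are
distributed multinomially in proportion to metacommunity relative
abundance. `RC = 2[(#{BC_null < BC_obs} + ½·ties)/n_null] − 1`; ties
are counted at 1e−12 tolerance, so the one-taxon table gives exactly 0.

Pairs are classified: βNTI > +2 heterogeneous selection, βNTI < −2
homogeneous selection, else RC > +0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, otherwise undominated. Fractions are
over all pairs and must sum to 1. `assembly_partition` computes pairs
within treatment×flooding groups when metadata is present (between-
group pairs mix selective environments and answer a different
question); all-pairs is available by passing explicit groups.

## Co-occurrence networks

Defaults: Spearman ρ on taxa present in ≥ 1/3 of samples, edges kept at
|ρ| ≥ 0.6 and Benjamini–Hochberg adjusted p ≤ 0.05, sign = sign(ρ).
These are community-standard settings and are recorded in the network's
`params` so outputs are self-describing. Constant taxa are dropped with
a warning (their rank correlation is undefined). Topology: average
degree is exactly 2E/N; mean local clustering counts degree < 2 nodes
as 0; the mean shortest path is computed on the largest connected
component (reported with its coverage fraction); modularity comes from
seeded Louvain on the unsigned graph — greedy alternatives can give
slightly different Q through tie-breaking, which is why the seed is
part of the interface.

## PLS path modeling

Reflective (mode A) outer estimation with the centroid inner scheme:
iterate (1) latent scores as standardised weighted sums of their block,
(2) inner proxies as sign-of-correlation-weighted sums of neighbouring
scores, (3) outer weights as manifest–proxy covariances, until the
largest normalised weight change is below `tol = 1e−6` (maximum 300
iterations; non-convergence raises). PLS scores are sign-indeterminate,
so each score is forced to correlate positively with its block's first
manifest — without this, bootstrap draws can flip sign and destroy
reproducibility. Path coefficients are OLS of each endogenous score on
its predecessors' scores; `GOF = sqrt(mean communality × mean R²)`.
A single-manifest chain reduces exactly to standardised OLS (tested to
1e−10 against the Pearson correlation). Missing data are handled by
complete-case deletion only. With measurement noise the PLS path
estimates are mildly attenuated relative to the generating structural
coefficients (score unreliability); at loadings 0.9 and n = 200 the
attenuation is well inside ±0.1.

The "assembly" block of a typical path model needs a per-sample scalar
from the pairwise βNTI matrix; the intended reduction is the first PCoA
axis of that matrix per sample group, and the PCoA routine here accepts
any symmetric dissimilarity, including a βNTI matrix shifted to
non-negative values.

## Synthetic generators: what they emulate

Every generator is a pure function of (parameters, seed); reruns are
bit-identical.

- **Trees.** `simulate_tree` produces plain reconstructed birth–death
  trees (default birth 1.0, death 0.5). For trait-based work the
  package uses `clustered_tree`: 5-tip pure-birth radiations at 5 % of
  tree depth grafted on a Kingman-coalescent backbone. Two facts force
  this shape. First, on a reconstructed birth–death tree the terminal
  branches are long, so a Brownian trait is nearly independent between
  sister tips — filtering on such a trait selects a phylogenetically
  random set and no βNTI signal can exist. Second, βNTI's contrast
  between within-clade and between-clade distances is sharpest when
  deep splits are old and roughly equidistant; coalescent backbones
  have exactly that geometry, and so do real OTU phylogenies (ancient
  phylum-level divergences, shallow terminal radiations).
- **Neutral communities.** Metacommunity relative abundances are
  log-normal (σ = 1.5 by default, the typical amplicon shape), assigned
  to taxa in random order so abundance carries no phylogenetic signal.
  Each sample's composition is Dirichlet(Nmp) — whose marginals are the
  Sloan Beta(Nmp_i, Nm(1−p_i)) — followed by multinomial reads at depth
  N = 1000. Defaults: 12 samples × 300 taxa, m = 0.1.
- **Selection communities** (`selection_config`): a Brownian trait
  evolved **once per tree** (the trait belongs to the taxa, not the
  replicate) sets each taxon's optimum; sample weights are
  `p_i · exp(−s(τ_i − e)²)` with strength s = 5 and every sample at
  e = +1.5 trait SD — filtering toward a trait extreme concentrates the
  community into few clades, the signature of homogeneous selection.
  A per-sample dispersal lottery (`availability = 0.5`: each sample
  reaches a random half of the metacommunity) supplies taxon turnover
  **within** the selected clades. This matters because pairwise
  weighted βMNTD is blind to shared taxa (their nearest-neighbour
  distance is 0 under any relabeling): without turnover among close
  relatives there is nothing for the null to contrast. The lottery is
  phylogeny-blind, so under `selection_strength = 0` (which reduces the
  generator to the neutral one, draw for draw, at `availability = 1`)
  it adds no phylogenetic signal. The regime's remaining preset values
  (m = 0.3, metacommunity σ = 0.3) keep per-sample weights faithful to
  the filtered pool and spread the turnover across enough taxa for the
  null z-scores to resolve. Opposite-extreme environments between
  groups produce βNTI > +2 between groups (heterogeneous selection).
- **Litter.** Exponential decay with organ-specific constants
  (k_root = 0.0020 d⁻¹ > k_rhizome = 0.0013 d⁻¹, matching the observed
  ordering that nitrogen-rich root litter decomposes fastest) and
  flooding multipliers ME 1.55 > HI 1.25 > LO 1.00, reproducing the
  intermittent > permanent > non-flooded ordering and ME/LO mass-loss
  ratios around 1.3. Single bags start at 6 g; C and N pools decay with
  their own constants so concentrations and C/N follow. Mixture
  "observations" equal the additive expectation times
  `(1 + interaction + η)`, η ~ N(0, 0.02), so an injected interaction
  of either sign is recoverable and the additive null averages to zero.
- **Structural covariates.** Latents are built in topological order
  with in-sample orthogonalised unit-variance residuals, so the
  **sample** standardised path coefficients equal the requested ones
  exactly; manifests are `λ·latent + sqrt(1−λ²)·noise`. This makes the
  noiseless single-manifest model recover coefficients to machine
  precision — a sharp identifiability oracle — at the cost that the
  generator's "population" is defined in-sample. Presets: the
  identifiability chain (0.6, −0.5; λ = 0.9) and a strong-signal chain
  (0.85, −0.8; λ = 0.95) whose GOF clears the conventional 0.6 bar.

**What the generators do not emulate:** sequencing error and chimeras,
compositional biases of PCR, spatial structure within samples,
time-resolved decay (two time points only), and multi-factor selection.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to those artefacts.

## Problem sizes

Test and acceptance runs use 12 samples × 300 taxa fixtures with 999
null draws for the assembly stage, 50 samples × 800 taxa for the
neutral-model recovery (20 replicate seeds), 500 replicate datasets for
the PERMANOVA calibration, and n = 200 for PLS-PM recovery — sizes at
which every stochastic check is stable across seeds while the whole
suite stays fast.

## Known limitations

- The NCM fit treats taxa as independent observations in both the loss
  and the bootstrap; compositional coupling between abundant taxa is
  ignored (as in standard practice).
- Raup–Crick draws both null communities per pair independently; RC
  values for pairs sharing a sample are still correlated, as in any
  pairwise null analysis, so "fractions of pairs" are descriptive, not
  independent counts.
- Louvain modularity is a heuristic optimum; only ≥-closed-form-Q is
  guaranteed (and tested) on structured graphs.
- PLS-PM supports reflective blocks and the centroid scheme only;
  formative blocks and factorial/path weighting are out of scope.
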