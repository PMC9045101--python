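# Methods

This note documents the models implemented in `mica`, the assumptions they
make, the synthetic data used to validate them, and the numerical and
design choices a maintainer or careful user should know about.

## Data model

All analyses consume an integer OTU table (samples × taxa) with unique
identifiers, positive library sizes and non-negative counts; a rooted
phylogeny with branch lengths over the OTU labels; and per-sample metadata.
Counts are converted to relative abundances per sample for every analysis
by default. Rarefaction (seeded subsampling without replacement) is
available but off by default: no normalization is assumed by the input
format, and relative abundance is the least destructive default. OTUs
missing from the phylogeny are a hard error; an opt-in
`prune_to_intersection` restricts table and tree to their common taxa and
reports what was dropped.

## Sloan neutral community model

The model treats each local community as a sample of N individuals (reads)
connected to a large metacommunity by immigration at rate m. At
stationarity the local relative abundance of a taxon with metacommunity
abundance p is Beta(N·m·p, N·m·(1−p)); the expected occurrence frequency
across samples follows.

**Detection.** A taxon is "observed" when at least one of N multinomial
reads hits it, an event of probability 1 − (1 − x)^N given local abundance
x. Averaging over the Beta gives the exact prediction

    F(p) = 1 − B(a, b + N) / B(a, b),   a = N·m·p, b = N·m·(1−p),

the zero-class of a beta-binomial. The classical convention instead
replaces the smooth detection curve with a step at a detection limit
d = 1/N, i.e. F(p) = 1 − BetaCDF(d; a, b). We implement both
(`detection="betabinomial"` default, `"threshold"` optional) and default to
the exact form for a concrete reason established during development: on
data generated by the model itself (beta-distributed local composition
closed to counts by multinomial sampling — which is also how real amplicon
data arise), the step form at d = 1/N inflates the fitted m by roughly
+20–25% independent of the abundance-pool shape, and no single step
position repairs this across the range of m (d = ln2/N, the
half-detection point, is unbiased at small m but underestimates m ≈ 1 by
~35%). The beta-binomial form recovers m essentially without bias over the
whole range (e.g. truth 0.05 → 0.050, truth 1.0 → 1.017 at 200 samples,
depth 10⁴). Users comparing against published fits should use
`detection="threshold"` and expect the published biases.

**Fitting.** m is estimated by bounded nonlinear least squares of observed
occurrence frequency on F(p), optimized on log m in [10⁻⁶, 10³] from
several starts (the objective is flat in m at both extremes; the log scale
and multi-start make the solve reliable). N defaults to the mean library
size. R² = 1 − SSE/SST over fitted OTUs; taxa never observed are excluded.
The fit is fully deterministic.

**Classification.** Each OTU is compared to a Wilson score interval (at
n = number of samples, level 95% by default) around its predicted
frequency. Because observed frequency lives on the grid k/n, comparisons
are padded by half a grid step; without this, taxa with predicted frequency
≈ 1 are spuriously flagged "above" when the Wilson upper bound at a
non-integer pseudo-count falls infinitesimally below 1.

## Null-model process partition

**βMNTD / βNTI.** For a sample pair, βMNTD is the mean (abundance-weighted
by default) patristic distance from each taxon in one community to its
nearest taxon in the other, averaged over both directions. The null
shuffles taxon identities across the phylogeny's tips (equivalently,
permutes rows/columns of the patristic distance matrix) and recomputes
βMNTD; βNTI is the z-score of the observation against 999 shuffles by
default (tests use 199 for speed). Because it is a z-score, βNTI is
invariant to a global rescaling of branch lengths (verified by test).
Pairs whose null has zero spread (e.g. identical one-taxon communities)
are reported as missing with a warning and excluded from partitions.

**Raup-Crick (Bray-Curtis flavor).** Null communities preserve each
sample's richness and total reads: taxa are drawn without replacement with
probability proportional to metacommunity occurrence frequency; each drawn
taxon receives one individual and the remaining reads are assigned
multinomially in proportion to metacommunity relative abundance. RCI
rescales the position of the observed Bray-Curtis within the null
distribution to [−1, 1], counting ties at half weight. Each pair's null
uses an independent, logged sub-seed, so results do not depend on
evaluation order; richness and depth preservation is asserted on every
draw.

**Partition.** Variable selection βNTI > 2; homogeneous selection
βNTI < −2; otherwise dispersal limitation RCI > 0.95, homogenizing
dispersal RCI < −0.95, else drift. The homogenizing-dispersal threshold is
RCI < −0.95 (a negative bound); stating it as RCI < 0.95 would make the
category overlap drift, so the non-overlapping standard thresholds are
implemented. Every valid pair lands in exactly one category and the five
fractions sum to 1.

**Environmental correlates.** Pairwise |Δ| matrices of latitude,
longitude, temperature or precipitation feed a Mantel test against βNTI
(Pearson by default, Spearman optional; the statistic choice is exposed
because conventions differ).

## Co-occurrence networks

The primary network is Spearman-based: pairwise ρ on relative abundances,
Benjamini–Hochberg correction across all tested pairs, edge iff |ρ| > 0.6
AND q < 0.05 (both thresholds configurable; both printed conventions in
the literature apply them jointly). p-values use the t-approximation with
midrank ties, or exact permutation enumeration when n ≤ 9 samples.
Constant taxa are skipped with a log entry. A SparCC-style estimator
(basis correlations from log-ratio variances under a sparsity assumption,
iteratively excluding the single most correlated pair; pseudocount +1 on
counts before closure) can replace Spearman while keeping the same
thresholding. Topology metrics use the standard closed forms; path length
and diameter are computed on the largest connected component, since
thresholded microbial networks are routinely disconnected. "Degree
centralization" is Freeman's. The random baseline is an Erdős–Rényi
ensemble with matched node and edge counts, reported as per-metric means,
SDs and observed z-scores.

## EM source tracking

The sink count vector is multinomial over Σⱼ αⱼ·γⱼ, where the γⱼ are
source compositions, themselves observed only through multinomial source
counts, and one optional unknown source. EM alternates read
responsibilities (E) with closed-form α and γ updates (M); with source
re-estimation on (default), the tracked objective is the joint sink+source
log-likelihood, which EM never decreases (asserted in tests). The sink-only
mixture log-likelihood is exposed separately; it is not guaranteed
monotone when γ is re-estimated. Convergence is a relative change
< 10⁻⁶ or 1000 iterations; 5 restarts by default, best by final
log-likelihood.

**The unknown source is support-restricted**: its profile is confined to
OTUs with zero counts in every observed source (zeros are absorbing under
multinomial EM). This choice is what makes the unknown identifiable — an
unrestricted extra component converges to the sink's own empirical
composition and absorbs arbitrary amounts of real source mass. The cost is
a known, documented bias: an unknown source whose support overlaps the
observed sources is underestimated (in simulation, a true overlapping
unknown fraction of 0.20 is estimated at ≈ 0.13, with the deficit credited
to the overlapping sources). When the sources jointly cover every OTU the
unknown becomes a frozen uniform background component. A fixed-source mode
(no γ re-estimation, no unknown) reduces to constrained maximum likelihood
and matches a direct optimizer to 10⁻³ on test instances.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of parameters and a seed, and their
outputs pass the same validation as file inputs.

* **Neutral** — local composition ~ Dirichlet(N·m·p) around a log-normal
  metacommunity pool (σ = 1.5 by default; a few dominant taxa, a long rare
  tail), closed to counts by a multinomial of size `depth`. The Dirichlet
  concentration N·m·p gives exactly the Sloan Beta marginals, so this *is*
  the discrete Sloan model rather than an ad-hoc perturbation.
* **Selection** — Yule tree, Brownian trait, Gaussian fitness filter
  exp(−s·(trait − optimum)²) on a base pool. The bundled scenario
  standardizes the trait across tips and places two habitat optima at
  ±1.5 SD with s = 50 on a 400-taxon pool. These values were chosen once
  for statistical power: on the raw trait scale the realized trait SD
  varies between simulations, and with ~100 taxa the filtered communities
  hold so few taxa (~9) that the tip-shuffle null is too noisy to resolve
  z > 2 even when observed βMNTD is clearly elevated. With the
  standardized configuration (~50 taxa per sample), between-habitat pairs
  exceed βNTI = 2 in the large majority across independent realizations.
* **Drift** — the Raup-Crick null process itself used as a generator
  (fixed richness and depth, occurrence-weighted taxon draws, abundance-
  weighted read assignment), giving communities with no assembly signal by
  construction.
* **Mixture** — sink = multinomial over a known convex combination of
  source profiles plus an unknown profile drawn from symmetric
  Dirichlet(0.5) over all OTUs (weakly informative, support everywhere).
* **Correlated composition** — log-normal latent abundances with a given
  basis correlation, closed by multinomial sampling; used to calibrate the
  compositional correlation estimators.

What the generators do **not** emulate: sequencing error and chimeras, OTU
clustering artifacts, batch effects, spatial or temporal autocorrelation
between samples, and phylogenetic signal in abundances (the pool is drawn
independently of the tree). Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions and honest
null behavior — not robustness to upstream bioinformatic noise.

## Statistical calibration

PERMANOVA and Mantel p-values respect the (1 + #exceedances)/(1 + perms)
floor and are seed-reproducible; their type-I error at α = 0.05 is checked
against binomial bounds over hundreds of null simulations. The network's
BH step is checked under a global null (any-rejection rate ≤ q up to
Monte-Carlo error). βNTI on stochastically assembled communities stays
within |βNTI| < 2 for ≥ 95% of pairs (the z-scores are mildly
under-dispersed for shared-pool data, so the check is conservative); RCI
on drift-generated communities is approximately uniform, with ~95% of
pairs inside ±0.95.

## Problem sizes

Defaults in examples and the acceptance script: 200–500 OTUs, 30–200
samples, read depths 2 000–100 000, 199 null randomizations in validation
runs (999 in production defaults), 500–1000 permutation-test replicates.
These sizes give stable Monte-Carlo estimates while keeping a full
validation run in the seconds-to-minutes range on one CPU.

## Known limitations

* The Raup-Crick generator and null share their construction; the RCI
  calibration is therefore a self-consistency check, not evidence about
  other stochastic regimes (e.g. iid multinomial sampling, which is
  genuinely tighter than the richness-constrained null and reads as
  RCI < 0).
* βNTI power depends on per-sample richness; below ~15 taxa per community
  the tip-shuffle null is too noisy to flag even strong filtering.
* The unknown-source estimate is a lower bound when the unknown overlaps
  observed sources (see above).
* PERMANOVA's R² is derived from the pseudo-F partition; with strongly
  unbalanced groups it should be read qualitatively.
* SparCC assumes sparse true correlation; dense correlation structures
  violate its identifying assumption and bias all estimates.
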