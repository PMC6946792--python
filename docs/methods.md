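# Methods

## Scope and data model

`adnet` implements a co-occurrence network analysis for anaerobic-digester
microbiomes. Its inputs are a taxon × sample abundance table (integer 16S
OTU counts, or non-negative organism-level signal intensities aggregated
from a functional-gene array by per-organism mean) and a sample metadata
table carrying the experimental design (digester, feeding group, day) plus
environmental parameters (VS load in g/L/day, pH, acetate, total ammonia)
and performance parameters (VS removal %, biogas and methane production).
The design assumed throughout is 66 samples: control and treatment groups ×
3 replicate digesters × 11 sampling days (45–97), split into four phase
groups (C 45-76, T 45-76, C 80-97, T 80-97) by the treatment group's
loading-rate step between the two windows.

Raw-read processing and array signal QC are out of scope; tables enter the
package already quantified. Rarefaction (sampling without replacement via
the multivariate hypergeometric distribution) is provided for count tables;
samples below the requested depth are dropped rather than up-sampled, the
standard conservative practice.

## Network inference

* **Prevalence filter.** Taxa detected in strictly more than `min_samples`
  samples are kept (default 9 of 66). The strict inequality matters at the
  boundary: a taxon present in exactly 9 samples is removed.
* **Correlation.** All-pairs Spearman ρ with average-rank ties and
  two-sided p values. Taxa constant across samples yield undefined
  correlations; these are excluded from the multiple-testing correction and
  from the network rather than being set to 0, which would fabricate nulls.
* **FDR.** Benjamini–Hochberg step-up adjustment
  (`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1), computed by
  `scipy.stats.false_discovery_control`.
* **RMT threshold.** For each candidate cutoff `s` (default scan
  0.30–0.99, step 0.01) the correlation matrix is hard-thresholded
  (`|ρ| < s → 0`, unit diagonal) and its eigenvalues computed. Degenerate
  eigenvalues (equal to 8 decimals — e.g. the unit eigenvalues contributed
  by fully isolated taxa, or exactly repeated block spectra) are collapsed
  before unfolding; a spectrum left with fewer than 10 spacings is the
  fully modular/diagonal limit and is scored Poisson-consistent (this also
  realises the identity-matrix edge case, where the scan stops at its
  start). Otherwise the cumulative spectral function is smoothed with a
  cubic smoothing spline (smoothing factor = number of eigenvalues;
  Gaussian broadening is available as `unfolding="gaussian"`), spacings of
  the unfolded eigenvalues are tested by chi-square goodness of fit on
  equal-probability bins (between 5 and 20, ≥ 5 spacings per bin) against
  the Poisson form `e^(−d)` and the GOE Wigner surmise
  `(π/2) d·exp(−π d²/4)`, both at α = 0.05. The chosen cutoff is the
  smallest `s` that is Poisson-consistent *and* GOE-inconsistent; if none
  exists in the range, the scan errors and advises widening. All per-cutoff
  statistics are recorded for audit.
* **Edges.** `(i, j)` is an edge iff `q ≤ 0.001` and `|ρ| ≥ s*`; the sign
  is the sign of ρ; isolated taxa are not nodes.

On the 66-sample synthetic design the GOE→Poisson transition occurs at the
*bulk* noise scale of the null correlations (≈ 0.28–0.32 for 100 taxa ×
66 samples), not above the most extreme single null |ρ|. Occasional noise
pairs above the cutoff are removed by the q ≤ 0.001 condition, which is the
binding constraint at these sample sizes; planted-edge precision is ~1.0
regardless (see Validation). With many more taxa or fewer samples the
transition moves up, which is the behaviour that produced high cutoffs
(≈ 0.86) on the original data.

## Topology

Metrics are computed on the undirected simple graph, ignoring edge signs
except for the percent-positive column:

* `avgK = 2E/N` (average connectivity).
* Harmonic geodesic distance `GD = N_pairs / Σ_{i<j} 1/d_ij`, with
  unreachable pairs contributing zero reciprocal — the only convention
  under which "harmonic" yields a finite, meaningful value on disconnected
  graphs.
* Average local clustering, with degree < 2 nodes contributing 0.
* Power-law fit of the degree distribution by OLS of log frequency on log
  degree over nonzero-frequency degrees (reported as R² with the slope's
  significance p). This histogram-R² convention matches how such tables
  are usually reported; a maximum-likelihood fit is deliberately not the
  default.
* Modularity: deterministic greedy agglomeration
  (igraph `community_fastgreedy`), Newman's
  `Q = Σ_m (e_mm − a_m²)`; leading-eigenvector available via
  `method="leading_eigenvector"`. Isolated nodes become singleton modules.
  When an initial partition is supplied, a pure-Python greedy merge starts
  from it and only applies Q-increasing merges, so the returned Q never
  falls below the initial partition's.
* Node roles by the Guimerà–Amaral scheme: within-module degree z-score
  (z = 0 when the module's within-degree SD is 0) and participation
  coefficient `P = 1 − Σ_m (k_im/k_i)²`; module hub iff `z > 2.5` and
  `P ≤ 0.62`, network hub if both thresholds are exceeded, connector if
  only P. The z/P thresholds are the conventional ones; the source study
  does not state its criterion.
* Freeman centralizations (degree, betweenness, closeness) with star-graph
  maxima as denominators.
* Per-sample subnetworks are induced subgraphs on the taxa with nonzero
  abundance in the sample; their summaries are correlated (Spearman,
  two-sided) with every environmental/performance parameter, masking
  constant properties.

## Null models and effect sizes

The random ensemble is **uniform G(n, m)**: simple labelled graphs with
exactly the empirical node and edge counts, edge positions fully
randomized (edges drawn as a uniform sample of the C(n,2) pairs without
replacement). This is the reading of "edges randomly rewired, node and
edge numbers unchanged" consistent with the published random clustering
values, which match the G(n, m) closed form 2m/(n(n−1)); degree-preserving
rewiring would inflate them. Comparisons report per-metric z-scores and
two-sided empirical rank p values; when the ensemble SD is 0 and the
observation differs from the mean, z is flagged infinite and p reported as
1/reps.

Between-group effect sizes count edges between every unordered pair of
taxon groups (domain, phylum or class; within-group pairs included) in the
observed network — optionally restricted to positive or negative edges —
against the distribution of counts between the same label sets across the
ensemble graphs: `effect = (observed − mean)/SD`, NA when SD = 0, flagged
when |effect| > 2. Edge totals are conserved by construction in every
replicate.

## Group-specific edges (omission scores)

For each edge and each phase group, the omission score (OS) is the
Spearman ρ recomputed over the samples *not* in the group. The null is 500
random same-size sample omissions drawn without replacement, shared across
edges within a group for efficiency (the draws remain independent across
the 500 replicates, which is what the p value requires). The nonparametric
p is the fraction of random omissions with `|OS_random| < |OS_group|`, so
its resolution is exactly 1/500. An edge is specific to a group when
`|OS| < |ρ_original|` and p < 0.05; magnitudes are compared sign-blind so
negative edges are classifiable. Edges specific to no group are global.
Group subnetworks are built from the group-specific edges only by default;
`include_global=True` reproduces the alternative composition in which
shared edges are retained (the published subnetwork sizes imply some
shared-edge rule, but the exact composition is not stated — both readings
are available, neither asserted).

## Gene significance and Mantel tests

GS is the squared Pearson r of a taxon's abundance profile (raw relative
abundance; no transform, since none is specified upstream) against one
parameter at a time; the per-parameter columns are stacked into
environment (total ammonia, acetate, pH, VS load) and performance (biogas,
methane, VS removal) GS matrices. Distances among taxa are Euclidean on GS
row-vectors (the metric is not specified in the source; Euclidean is the
common default, Bray–Curtis/Manhattan available via `metric=`), and
connectivity distance is `|k_i − k_j|` with degrees always taken from the
overall network, also for domain/class subsets.

The Mantel statistic is the Pearson correlation of the two upper
triangles; p is one-sided (greater) by simultaneous row/column permutation
of one matrix, `p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)`, default 999
permutations (resolution 0.001). The partial Mantel statistic correlates
the residuals of both triangles after OLS on the control triangle,
permuting the second matrix while the control stays fixed; a constant
control falls back to the plain test with a warning. Degenerate inputs
(constant distance matrix, constant residuals) return NaN statistics with
NaN p rather than a spuriously small p. Subsets (All, Archaea, Bacteria,
every class) require ≥ 3 taxa with defined GS; smaller ones are reported
as skipped.

## Synthetic communities

The generator produces the statistical structure the analysis assumes,
with ground truth:

* **Latent model.** Module m has a standard-normal factor per sample;
  member i loads on it with `λ_i = √ρ · U(0.65, 1.05)` (clipped below 1),
  so pairwise latent correlations are `λ_iλ_j`, spread around the nominal
  `within_module_rho`. The spread is what gives module members *different
  degrees* downstream — pairs whose product falls below the effective edge
  threshold drop out — without which connectivity-based Mantel tests would
  be degenerate (all members of a complete block share one degree).
  Background taxa (fraction `sparsity`, default 0.6) are independent.
  Extra independent noise (`noise_sd`, default 0.1) is added and the
  latent field restandardized.
* **Compositional counts.** Per-taxon baselines `μ_i ~ N(0, 0.5²)` set the
  abundance hierarchy; counts are one multinomial draw per sample of size
  `library_size` (default 11 558, the study's rarefaction depth) over
  `exp(μ_i + z_is)`. The 0.5 baseline SD keeps the effective diversity
  (inverse Simpson) of most samples above ~20, the regime in which
  compositional closure has a minor effect on pairwise correlations; the
  multinomial closure is still present, so the caveat is represented.
* **Modules.** Default 100 taxa, 4 ordinary modules over 40% of the taxa,
  with the first (archaeal) module taking ~40% of the planted taxa so the
  per-domain Mantel contrasts have comparable power. Two additional
  4-taxon modules are group specific: their factor is active only in the
  samples of one phase group (defaults: one in T 45-76, one in T 80-97),
  independent noise elsewhere. All within-module pairs are recorded as
  planted edges; group-specific pairs carry their phase-group label.
* **Metadata.** Performance parameters are
  `base + amp·(β·d + ε)`, `ε ~ N(0, 0.35)`, where `d` is the
  loading-weighted mean of the archaeal drivers' standardized relative
  abundances (≈ the module factor) — so a taxon's GS rises with its
  loading exactly as its degree does. Environmental parameters follow the
  loading-rate step: control flat at 1.0 g VS/L/day, treatment 1.3 →
  1.5 between the phase windows, with matching steps in ammonia and
  acetate and small Gaussian noise; pH stays flat. The affine placement of
  all scales is cosmetic (GS and Mantel statistics are affine-invariant).
* **What it does not emulate.** Time autocorrelation within digesters,
  digester-level random effects, taxon-specific sequencing biases, and
  mechanistic digestion kinetics. Passing tests therefore show that the
  estimators recover the statistical structures they target, not that real
  digester data satisfy those structures.

## Validation strategy and problem sizes

* Every topology metric is checked against independent pure-Python
  brute-force recomputations (Floyd–Warshall distances, triangle counting,
  modularity from its definition) over an exhaustive atlas sample of all
  graphs on 4–7 nodes; Mantel r and p are checked against full enumeration
  of all row/column permutations on 5–6 taxa, and against an independent
  library implementation on larger matrices.
* Planted-truth recovery runs the full pipeline over 20 generator seeds at
  the default design (100 taxa, 66 samples, ρ = 0.9): median planted-edge
  precision ≥ 0.9 and recall ≥ 0.5; group-specific couplings flagged for
  their own group at ≥ 3× the rate of globally planted edges; the archaeal
  partial-Mantel contrast significant in a majority of seeds with the
  bacterial subset at the null rate.
* Null calibration: per-taxon shuffling keeps the q ≤ 0.001 discovery rate
  within 3 SE of nominal; exchangeable samples keep the omission flag rate
  near 5% with near-uniform p; Mantel p is KS-uniform under independence.
* The published random-network reference columns are recomputed as 100
  uniform G(n, m) graphs per published size — ensembles of a few hundred
  nodes, seconds per ensemble. Two of the published GD values (the
  (250, 704) and (223, 380) rows) sit systematically above the harmonic
  GD of uniform G(n, m) and instead match the *arithmetic* mean path
  length over reachable pairs; the package reports the harmonic value its
  own definition prescribes and the corresponding checks are expected to
  exceed the strictest printed-SD band (they remain within ~5–9%
  relative).

## Numerical choices and limitations

* All randomness flows through `numpy.random.default_rng` with explicit
  per-stage seeds; identical configs reproduce byte-identical artifacts.
* Spearman p values use the t approximation (scipy); at n = 66 this is
  accurate far beyond the q = 0.001 regime used here.
* The NNSD chi-square binning (equal-probability bins, α = 0.05) is one of
  several defensible conventions; the recorded scan table makes any
  alternative decision rule recomputable after the fact.
* Greedy agglomeration can merge small modules below the resolution limit;
  the leading-eigenvector option gives an independent partition when that
  matters. Reported modularity differences between algorithms are ~0.01–0.02
  on the graph sizes used here.
* The omission-score p compares |OS| magnitudes; the OS/|ρ| ratio is also
  recorded per row so a ratio-based rule can be applied without
  recomputation.
* 16S counts and array-derived signal abundances are analysed jointly
  without cross-rescaling: Spearman correlation and GS are rank- and
  affine-invariant per taxon, so a joint rescaling would not change any
  reported statistic.
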