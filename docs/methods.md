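# Methods

This note documents the models, parameter choices and numerical
conventions behind `aqasm`, and what the synthetic-data generator does
and does not emulate.

## Fraction merging

A water sample filtered sequentially through 0.2 µm and 0.1 µm membranes
yields two sequenced communities whose relative abundances say nothing
about their relative biomass. We weight each fraction by its share of 16S
rRNA gene copies from qPCR: `w_f = copies_f / (copies_F01 + copies_F02)`
and merge per OTU as `w01·relF01 + w02·relF02`. Merging is linear, so
aggregating merged OTU abundances to any taxonomic rank equals merging
rank-aggregated profiles; we merge at OTU level because it preserves
maximal information. qPCR copies are used as-is, with no 16S operon
copy-number correction — ultra-small taxa typically carry a single operon
while common heterotrophs carry one to four, so taxon partitioning
estimates are conservative for the ultra-small fraction. When only one
fraction exists for a sample it is passed through as bulk with a logged
warning, never silently merged.

## Rarefaction

Subsampling to a common depth (default 7876 reads) draws reads without
replacement (multivariate hypergeometric), so rarefied counts never
exceed the originals and a sample whose total equals the depth is
returned unchanged. Samples below the depth are dropped and logged,
not padded. Rarefaction is a single seeded draw; repeated-rarefaction
averaging is deliberately not performed (single-draw matches the common
"subsampled to N reads" convention, and the seed makes it reproducible).

## Assembly null models

βMNTD uses the abundance-weighted form
`½[Σ_i p_k(i)·min_{j∈m} d(i,j) + Σ_j p_m(j)·min_{i∈k} d(j,i)]`,
with patristic distances from the OTU phylogeny; an OTU shared by both
communities contributes a nearest-taxon distance of zero. The βNTI null
shuffles the OTU↔tip assignment across the full OTU pool of the analyzed
table (not just the pair), recomputing βMNTD each time; the standardized
effect size uses the sample standard deviation (n−1). A degenerate null
(sd = 0, e.g. identical supports or a star phylogeny) yields NaN and the
pair is classified `undefined` rather than ±∞.

RC_bray nulls preserve each observed sample's richness and read total.
Membership is drawn without replacement with probability proportional to
each OTU's occurrence frequency across the metacommunity; each member
receives one read and the remainder are assigned multinomially with
probability proportional to metacommunity relative abundance. The
metacommunity is the full analyzed table after rarefaction and merging —
all samples, not only the compared pair — matching the pooled-dataset
convention of this null-model family and keeping the null informative
when the compared communities are themselves homogeneous. Ties between
null and observed Bray–Curtis count half; `P = (#less + ½·#ties)/reps`
and `RC = 2(P − ½) ∈ [−1, 1]`. Null randomizations are regenerated per
pair from independent substreams of the run seed (an alternative would
share one null set across pairs; per-pair regeneration is simpler and
unbiased). Pairs are unordered and reported once in lexicographic order.

Because qPCR-weighted merging produces non-integer profiles while the
Raup–Crick null operates on counts, merged profiles are re-discretized by
a seeded multinomial draw at the rarefaction depth. βMNTD uses the merged
relative abundances directly.

Classification follows the two-threshold scheme: βNTI > 2 variable
selection, βNTI < −2 homogeneous selection; otherwise RC > 0.95 dispersal
limitation, RC < −0.95 homogenizing dispersal, else undominated.

## Hydrochemical correlation

Spearman coefficients use midranks for ties. Two-sided p-values are exact
(full enumeration of rank permutations) for n ≤ 9 and t-approximated
above. No multiple-testing correction is applied by default, matching the
plain p < 0.05 significance convention of exploratory correlation
heatmaps; a Benjamini–Hochberg option exists (`fit(fdr=True)`).
Profile clustering is average-linkage (UPGMA) on Euclidean distances
between rows of coefficients, delegated to scipy's deterministic
implementation; undefined cells are zero-imputed with a log message. PCA
of "significant correlations" needs a complete matrix, so nonsignificant
cells are set to 0 (encoding "no detected association"), columns are
mean-centered, and components come from an SVD truncated to numerical
rank; explained-variance fractions sum to 1 over retained components.

## Co-occurrence network

OTUs are kept when they have ≥ 100 reads in total and appear in at least
⌈30% of samples⌉ (ceiling, "at least 30%"). The CLR transform uses a
pseudocount of 1 on counts. Neighborhood selection runs one lasso per
node over a shared log-spaced path of 20 lambdas from lambda_max (the
smallest penalty selecting nothing anywhere) down to lambda_max/100.
Directed selections are symmetrized by union ("or" rule) and the edge
coefficient is the mean of the available directed coefficients. StARS
draws 50 subsamples without replacement of size
`min(⌊10√n⌋, ⌊0.8n⌋)` — the cited selection scheme's own small-n default,
since ⌊10√n⌋ exceeds n below n = 100 — refits the path on each, and
defines per-edge confidence as the selection frequency at the selected
lambda. The selected lambda is the densest one whose monotonized mean
edge instability `2θ(1−θ)` stays ≤ 0.05. "Edge confidence" as selection
frequency at the selected lambda is our documented interpretation of the
stability values the original tooling reports. The final graph keeps
edges that are selected on the full data, have a positive coefficient,
and confidence strictly > 0.5. Clustering is greedy modularity
maximization (networkx); isolated nodes become singleton clusters.
The neighbor-composition test compares, between two node groups, the
per-node fraction of first-degree neighbors carrying a taxonomic label,
by Mann–Whitney U (exact for combined n ≤ 20 without ties, otherwise
normal approximation with tie correction).

## Synthetic-data generator

The generator emulates a hillslope observatory: forest-soil communities
feed seepage, seepage seeds a series of groundwater wells, and every
water sample is split into two filter fractions.

* **Metacommunity.** Log-normal species-abundance distribution
  (log-sd 1.5 by default), a standard baseline producing realistic
  rank-abundance curves. OTUs are partitioned into phylogenetically
  coherent clades by average-linkage clustering of patristic distances.
* **Mobilization.** One clade (the ultra-small, Patescibacteria-like
  clade) is rare in soil (soil abundance × 0.05) and carries a 100×
  seepage-transfer multiplier, reproducing preferential mobilization of
  rare soil taxa; ground truth records the expected enrichment ordering.
* **Fraction partitioning.** Biomass splits by a per-clade probability of
  passing the 0.2 µm filter (0.25 for the ultra-small clade, 0.02
  baseline). Each fraction is then sequenced to full depth — sequencing
  depth is unrelated to biomass — while qPCR totals carry the biomass
  shares, so qPCR-weighted merging recovers the true community and the
  passage probability is identifiable. The recorded bulk table is the sum
  of the two fraction tables by construction.
* **Assembly regimes.** Wells form under one of six regimes:
  `neutral` (log-normal noise on the seepage pool), `dispersal_limitation`
  (each OTU establishes in one primary well, with immigration probability
  0.08·exp(−distance/2 km)), `homogenizing_dispersal` (all wells share
  one realized colonization field per time point), `disjoint` (strict
  partition), and two niche regimes. Niche optima evolve by early-burst
  Brownian motion (rate ∝ exp(−4·depth/height)), concentrating trait
  variance on deep branches so clades are strongly niche-conserved — the
  premise the phylogenetic null models rest on. Well environments sit on
  real clade optima (the most isolated clade's optimum for
  `homogeneous_selection`; the two extreme clades' optima alternating
  along the transect for `selection`), and a truncated Gaussian filter
  (breadth 0.2–0.25 in trait units, weights < 1% zeroed) plus a 60%
  establishment probability give each sample a clade-coherent community
  with membership turnover. The niche presets use 300 OTUs and a flatter
  metacommunity (log-sd 0.8) so filtered communities retain enough
  members for a stable standardized effect size.
* **Planted associations.** Positive co-occurrence is planted as modules:
  members of a module share one log-normal latent factor per sample
  (amplitude 2.0 log units). A single factor per module yields an exact
  clique-structured inverse covariance, so the conditional-dependence
  graph the network stage estimates is precisely the set of
  within-module pairs. (Per-edge factors were rejected: they induce a
  dense inverse covariance whose chords are genuine conditional
  dependencies, making "planted edge" ill-defined.)
* **Hydrochemistry and qPCR.** The niche parameter (dissolved oxygen by
  default) tracks each well's environment with noise 0.2; other
  parameters get well-graded baselines with noise 0.5. qPCR totals are
  drawn uniformly from 1.2×10⁷–8.6×10⁸ copies L⁻¹.

What the generator does **not** emulate: hydrological transport dynamics,
temporal autocorrelation, strain-level microdiversity, chimeras or other
sequencing artifacts, and 16S copy-number variation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative assumptions, not robustness to all failure modes of
real amplicon data.

## Problem sizes and tolerances

The verification suite and `scripts/acceptance.py` use four wells at one
time point, 150–300 OTUs, 20 000-read samples rarefied to 7876, 199
randomizations per pair for regime-recovery runs (999 for single-pair
checks and null calibration), and a 60-OTU / 50-sample planted network —
sizes chosen so a full verification completes in about a minute on one
CPU while keeping Monte-Carlo error well below the decision thresholds
(RC granularity 1/199 ≈ 0.005 against a ±0.95 threshold). Oracle
comparisons use 1e-12 absolute tolerance; conservation checks use 1e-9
(merged sums) and 1e-12 (CLR row sums).

## Known limitations

* βNTI on pairs with near-identical supports is ill-defined (degenerate
  null); such pairs are reported `undefined` rather than forced into a
  class.
* The Raup–Crick null depends on the metacommunity definition; with very
  few, very similar samples it loses power. Including all samples of the
  dataset (as done here) is a convention, not a theorem.
* Neighborhood selection on CLR data inherits compositional closure
  effects; very strong positive associations in a small OTU pool can
  induce weak spurious structure elsewhere. The stability filter
  suppresses but cannot eliminate systematic artifacts.
* Enrichment factors with a zero source mean are reported as censored
  lower bounds (`target_mean / detection_floor`), not infinities.
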