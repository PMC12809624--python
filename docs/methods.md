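# Methods

This note records the models implemented in `microtempo`, the defaults
and why, the numerical choices, and what the synthetic data generator
does and does not emulate.

## Assembly-process inference

**βMNTD / βNTI.** Phylogenetic turnover between two communities is the
abundance-weighted β-mean nearest taxon distance on cophenetic
(patristic) distances; a taxon shared by both communities contributes
zero, since its nearest relative in the other community is itself. The
null model permutes taxa labels jointly over the rows and columns of
the full cophenetic matrix — a *regional-pool* null in which one
permutation per replicate is shared by all sample pairs, so the null
ensemble reflects "the same phylogeny, randomly relabelled" rather than
an independent relabelling per pair. (`bnti(per_pair=True)` provides
the per-pair variant for sensitivity analysis.) βNTI is the z-score of
the observation against the replicate ensemble; the null sd uses the
n−1 normalisation. Default 999 replicates, configurable; a reduced 199
is the package's demo fidelity. βNTI is invariant to uniform rescaling
of branch lengths, which the suite asserts.

*Degenerate nulls.* When every permutation leaves βMNTD unchanged
(star-like phylogenies, identical communities) the null sd is 0; these
pairs are assigned βNTI = 0 with a `degenerate` flag rather than NaN.
Since |βNTI| ≤ 2 is the semantically right branch when the phylogeny
carries no usable signal, classification then falls through to the
taxonomic (Raup–Crick) criterion, and the flag is propagated so such
pairs can be reported separately.

**RC_bray.** Each null community preserves its sample's observed
richness and total count: richness taxa are drawn without replacement
with probability proportional to occurrence frequency, each receives
one individual, and the remaining individuals are assigned
multinomially proportional to dataset-wide mean relative abundance
restricted to the drawn taxa. The observed Bray–Curtis value is ranked
in the null ensemble with half weight on ties —
RC = 2·[(#below + ½·#ties)/n_null] − 1 — which makes the extreme cases
exact (+1 when the observation beats every null, −1 for an identical
pair when every null differs). Null ensembles are generated per sample
per replicate and replicate *r* of sample *j* is paired with replicate
*r* of sample *k*; because samples' nulls are mutually independent this
is distributionally identical to regenerating the ensemble per pair and
reduces the cost from O(pairs · n_null) to O(samples · n_null)
community draws. The null pool (occurrence frequencies and mean
relative abundances) defaults to the analysed table — i.e. per
site × size-fraction group when run through `assembly_analysis` — and
can be overridden with pool arrays computed on a wider sample set.

**Classification and fractions.** Thresholds: |βNTI| > 2 for selection
(sign separates heterogeneous from homogeneous), then RC_bray against
±0.95, else ecological drift. Pairwise analyses are restricted to
within-group (site × size-fraction) pairs; process fractions are
reported per group and sum to one. Integer (rarefied) counts are
required for RC_bray; βNTI likewise runs on the rarefied table by
default.

## PERMANOVA

Distance-based variance partitioning in the McArdle–Anderson form: the
squared distance matrix is Gower-centred and its total sum of squares
partitioned sequentially over the user-supplied term order (Type-I-like,
matching the behaviour of the standard distance-based MANOVA
implementations); single-term runs are order-free. p-values come from
free permutation of sample labels, p = (#{F* ≥ F} + 1)/(n_perm + 1);
for small n an exhaustive mode enumerates all n! permutations and
reports the exact tail fraction with the identity included. A residual
sum of squares below 1e−10 of the total (perfectly separated groups) is
treated as exactly zero so the pseudo-F becomes +∞ consistently for the
observation and its equivalent permutations, rather than a
floating-point-noise ratio. Sequential R² plus the residual R² sum to
one exactly.

## Seasonality

The Lomb–Scargle periodogram in the classical per-frequency-offset form,
normalised by the centred sum of squares so power lies in [0, 1] and the
peak (PN) reads as the fraction of variance explained by the best
sinusoid. This equals scipy's `lombscargle(..., normalize=True)` (the
suite cross-checks it); the in-package implementation exists because the
permutation test evaluates many permuted series against one shared time
grid, which vectorises as a few matrix products per frequency. The time
axis is decimal months since the first sample (mean Julian month,
30.436875 days), so unevenly spaced or missing months need no
imputation. Period grid: 2 months (the monthly Nyquist limit) to half
the span, 4× frequency oversampling. Significance: values permuted over
fixed times, p = (#{PN* ≥ PN} + 1)/(n_perm + 1). Seasonal call:
PN > 0.2 ∧ p < 0.01 ∧ peak period in the annual window, operationalised
as [10, 14] months (configurable; "about one year" needs a concrete
tolerance). Note the p < 0.01 criterion is attainable only when
n_perm ≥ 100, and the annual window only when the series spans > 20
months — short runs therefore cannot produce seasonal calls by design.
ASVs must be detected in at least ⌈10% of samples⌉; series are relative
abundances from the rarefied table. Peak month is the calendar month
with maximal mean abundance across years, ties to the earlier month.

## ASV categories

Occurrence is the fraction of a site's samples with count > 0 on the
rarefied table, computed per size-fraction. "Common" requires strictly
more than 50% occurrence at *both* sites. IndVal.g is the
group-equalised indicator value: specificity A normalises each group's
mean abundance by the sum of per-group means (so unequal group sizes do
not bias it), fidelity B is within-group occupancy, stat = max over
groups of √(A·B); significance by permuting sample-to-group labels.
Indicator requires stat > 0.7 and p < 0.01. The headline label uses the
priority common > indicator > exclusive > background, but all flags are
retained — an exclusive ASV that also tests as an indicator is reported
as indicator with its exclusive flag set, and the overlap counts
reconcile in the output.

## Networks

The static association network is an *input* (network inference and
indirect-edge filtering are upstream concerns); for self-contained
synthetic runs the package supplies a deliberately simple baseline —
thresholded Pearson correlation of CLR profiles — plus a planted
random-network generator. The co-occurrence score of an edge is the
fraction of samples in which both endpoints are detected (> 0); edges
below 0.5 are removed, then isolated nodes. Monthly subnetworks keep a
node iff it is detected in that calendar month's sample(s) of its own
size-fraction, and an edge iff both endpoints survive; subnetworks are
therefore always node- and edge-subsets of the static network, and
months with supersets of detected nodes carry supersets of edges.
Metrics per (sub)network: node and edge counts, edge density m/(n(n−1)/2),
global transitivity (closed/all triplets), average shortest-path length
over *connected* ordered pairs (signs and weights ignored; the
disconnected-pair count is logged), degree assortativity, categorical
(domain, size-fraction) assortativity, and mean positive strength
averaged over positive *edges*. Metrics without a defined value (single
category, edgeless graph, no positive edges) are NaN with a reason
where the interface allows. Metric–environment association uses
Spearman correlation on pairwise-complete observations (≥ 4 pairs) with
Holm step-down adjustment across the whole metric × variable family.

## Synthetic scenario

The generator emulates two observatories sampled monthly for 41 months:
a Yule phylogeny (unit birth rate, tips extended to the present, so the
tree is ultrametric), Brownian-motion environmental optima along its
branches (variance σ_BM² per unit branch length — phylogenetically
close taxa prefer similar environments, the signal βNTI presupposes),
sinusoidal forcing E(t) with a 12-month period, and a discrete
generation process

w_i(t) ∝ [(1−m)·x_i(t−1)/N + m·π_i] · exp(−(E(t) − μ_i)²/(2σ_sel²)),
x(t) ~ Multinomial(N, w/Σw),

i.e. drift (multinomial resampling), immigration from a regional pool
π (uniform by default, log-series optional) and Gaussian environmental
filtering of width σ_sel. Defaults: 150 taxa, N = 2000 reads, m = 0.1,
σ_sel = 0.5, amplitude 3 (temperate) vs 0 (tropical, with σ_sel
inflated 100× so the filter is inert), σ_BM = 1. The demo pipeline runs
a reduced 100-taxa / N = 1000 scenario with 199 null/permutation
replicates — sizes chosen so a complete two-site analysis finishes in
well under a minute on a laptop while leaving every qualitative
contrast intact. Sample dates sit on the 15th of consecutive months.

What it does *not* emulate: taxonomies, biogeochemistry, cross-fraction
coupling (two size-fractions are independent draws from the same latent
weights), interaction-driven dynamics (planted networks are structural
fixtures), read-depth artefacts beyond optional uniform depth variation
(±20%, off by default), or the fat-tailed abundance distributions of
real amplicon surveys. Passing recovery tests on this scenario shows
the estimators respond correctly to known selection/drift regimes; it
does not certify performance on real data, where compositional noise,
undetected taxa and tree misspecification are harsher.

## Determinism and provenance

Every stochastic operation takes an explicit seed; pipeline stages
derive per-ASV/per-group seeds from the run seed through a
`numpy.random.default_rng` stream, so reruns are byte-identical. Stage
manifests record the analysis-parameter hash (file locations excluded),
seed, package version and output row counts.

## Known limitations

- The regional-pool βNTI null assumes all analysed taxa form one pool;
  strong within-group structure (e.g. habitat sub-pools) would call for
  stratified permutations, which are not implemented.
- RC_bray's occurrence-weighted, abundance-restricted null is one of
  several conventions in circulation; results are sensitive to the pool
  definition, which is why the pool is both per-group by default and
  overridable.
- The sequential PERMANOVA reports marginal variance only through term
  ordering; a dedicated marginal (Type-III-like) mode is not provided —
  run single-term models for marginal R².
- IndVal is two-group (site) oriented; multi-level site-combination
  analyses are out of scope.
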