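# Methods

This note documents the models, estimators, defaults and numerical choices
behind `edgepop`, and what the synthetic-data tests do and do not establish.

## Data model

Alleles are stored as integer repeat counts; fragment sizes in bp are
converted at ingest using the locus motif length and a per-locus offset
estimated as *min observed size mod motif length* (the flanking-sequence
contribution), making the bp ↔ repeat-unit map a bijection given the locus
metadata. Off-ladder sizes are rounded to the nearest repeat unit and the
rounding recorded in the ingest report. Missing data are whole-genotype
(half-calls rejected) and every statistic excludes missing genotypes
locus-wise.

## Diversity estimators

* Gene diversity uses Nei's unbiased correction, GD = n(1 − Σp²)/(n − 1)
  with n the number of gene copies. The plug-in He = 1 − Σp² (no
  correction) is used inside PIC and the null-allele formulas, matching the
  conventions of the tools those statistics come from; both variants are
  exposed.
* Allelic richness is rarefaction to g gene copies,
  AR(g) = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)], computed with log-gamma terms for
  stability; g defaults to the smallest per-stratum gene count.
* F<sub>IS</sub> is the Weir–Cockerham variance-components estimator,
  per-allele components summed within and across loci. For a single
  (pooled) population the among-population terms vanish and the estimator
  reduces to 1 − c/(b + c), which is well defined. Significance comes from
  re-pairing the observed gene copies at random among individuals *within*
  populations — this preserves allele frequencies while destroying any
  departure from random mating — with the (k + 1)/(B + 1) two-sided
  p-value estimator. Permutation counts default to 10 000 with explicit
  seeds.
* The exact Hardy–Weinberg test uses Levene's conditional distribution of
  genotype tables given allele counts. Tables are fully enumerated while
  the state space stays below a cap (10⁵ tables; the p-value is then exact,
  the sum of probabilities ≤ the observed table's). Above the cap the
  p-value is Monte-Carlo: gene copies are re-paired at random, which samples
  the Levene null i.i.d. — we prefer this to a Markov-chain sampler because
  it has no mixing or burn-in concerns at these sample sizes.
* Null-allele frequency: Chakraborty r = (He − Ho)/(He + Ho) and
  Brookfield-1 r = (He − Ho)/(1 + He); negative values (heterozygote
  excess) are reported as computed. Exact agreement with
  parentage-software null-allele columns is not expected, as those
  implement an iterative maximum-likelihood variant.
* Genotypic linkage disequilibrium: the log-likelihood-ratio G statistic of
  the two-locus genotype table, summed over populations, with a
  within-population permutation null. When every multilocus genotype in a
  sample is unique, any permutation produces an equally "perfect" table and
  the test has no power — a known degeneracy of this class of test, worth
  remembering for very small samples at hypervariable loci.

## Plastid analyses

Haplotypes are equivalence classes of sequences identical at all retained
sites; columns containing a gap or N are excluded completely before
comparison (pairwise deletion available). Including gap columns can only
split haplotype classes, never merge them. Haplotype diversity uses the
unbiased n/(n − 1) estimator with Nei's sampling variance; nucleotide
diversity is the mean pairwise per-site difference with the standard
sampling-variance formula (both a stochastic and a sampling component).
Haplotype ids are assigned in decreasing frequency, ties broken
lexicographically.

## AMOVA and DAPC

The AMOVA is the two-level decomposition of squared inter-individual
distances: δ² between two diploid genotypes is the number of allele
differences under best matching (0, 1 or 2), an F<sub>ST</sub>-style
distance; squared repeat-count differences (R<sub>ST</sub>-style) are a
flag away. Sums of squares within and among sites give variance components
by the usual unequal-sample-size moments; negative components are retained
as computed; Φ<sub>ST</sub> is the summed-component ratio across loci.
Significance permutes whole individuals across sites. Sites with a single
individual are excluded with a warning. Pairwise F<sub>ST</sub> values are
two-site AMOVAs, optionally Bonferroni-adjusted.

DAPC encodes individuals as centred allele-dosage vectors (missing
genotypes imputed at the column mean), retains enough principal components
for 90 % of variance by default, and — when no site labels are supplied —
chooses the number of groups by the BIC of a k-means-initialized
full-covariance Gaussian mixture on the retained scores. We use the mixture
BIC rather than a within-sum-of-squares k-means score because the latter
keeps splitting a single panmictic cloud at these sample sizes (n ≈ 40),
whereas the mixture criterion correctly returns k = 1 there and still finds
genuinely separated clusters. Group ordination and assignment probabilities
come from linear discriminant analysis on the retained components.

## Coalescent simulator with generalized stepwise mutation

Genealogies follow the continuous-time Kingman coalescent with
piecewise-constant diploid size N(t): each pair of lineages coalesces at
rate 1/(2N) per generation, with exact exponential rescaling across epoch
boundaries. The continuous-time approximation is appropriate here because
every size prior keeps N far above the sample size.

The four demographic scenarios are: constant Ne; ongoing bottleneck
(current Ne2, ancestral Na2 > Ne2 before generation t); expansion
(current Ne3 > Na3 before t); transitory bottleneck (Ne4 now, Nb between
t1 < t2, Na4 before t2, Nb below both). Times are in generations with a
one-year generation (annual herbs).

Mutation: events are Poisson along branches. Each event moves the allele
by ±(1 + G) repeat units with G ~ Geometric(P) on {0, 1, 2, …} and
equiprobable sign, so every mutation moves at least one unit and P → 1 is
the strict stepwise model. Per-locus rates are hierarchical: a dataset-level
mean rate uniform on [10⁻⁴, 10⁻²], per-locus rates Gamma(shape 2, mean =
that rate) truncated to [10⁻⁵, 10⁻²] by rejection. The step-size parameter
P is drawn per locus from Uniform(0.1, 0.3), the usual empirical band for
microsatellite step-size fits and the default of the standard ABC software
for this model; the bounds are configurable.

Allele sizes are bounded by each locus's empirical allele range. The
default boundary is reflecting (clamping is available): reflection avoids
the absorbing pile-up at the edges that truncation creates. The root allele
starts at the range midpoint — arbitrary, but symmetric under reflection.
Implementation: because each mutation's sign is equiprobable, the
event-by-event reflected walk equals, in joint distribution across the
tree, the triangular-wave fold of the *free* walk; the simulator therefore
draws only each branch's net displacement (a difference of negative
binomials, since a sum of geometric steps is negative binomial) and folds
node values once — O(1) per branch instead of O(mutations), exact, and
verified distributionally against the event-level walk. The summed-step
shortcut does not apply to clamping, which keeps the per-event loop.

Summary statistics (means across loci at the gene-copy level): number of
alleles, unbiased gene diversity, allele-size variance (denominator n), and
Garza–Williamson M = k/(r + 1) with r the observed size range. "Allele
size" enters as its variance, the single-sample statistic of the standard
catalogue.

Hot loops are numba-jitted with a pure-Python fallback; identical seeds
give bit-identical outputs in single-process runs.

## ABC workflow

* Reference table: equal rows per scenario, chunked generation, explicit
  seed; per-statistic median and MAD recorded for standardization
  (statistics with zero MAD are dropped from distances with a warning).
  Distances are Euclidean on the standardized statistics.
* Prior defaults (configurable; chosen once as broad, weakly informative
  ranges for long-lived plant metapopulations of this kind): every
  effective size uniform on [10, 5 × 10⁵] individuals; event times uniform
  on [10, 5 × 10⁴] generations; ordering constraints (Ne2 < Na2, Ne3 > Na3,
  Nb < Ne4 and Nb < Na4, t1 < t2) enforced by rejection.
* Model choice: the direct (rejection) estimate is the scenario composition
  of the k closest rows (default 500); the logistic estimate is a
  multinomial logistic regression of scenario on standardized statistics
  over the k closest rows (default 40 000), evaluated at the observation,
  with delta-method 95 % CIs from the asymptotic covariance. On separation
  or non-convergence an L2-regularized fit is substituted and flagged. In
  scaled-down experiments both k values are held at the same acceptance
  *fractions* as the full-scale defaults.
* Parameter estimation: local-linear (Beaumont) adjustment on the k closest
  rows of the winning scenario (default 20 000), Epanechnikov weights,
  parameters logit-transformed to their prior bounds, weighted least
  squares on the standardized statistic offsets, residual-adjusted to the
  observation and back-transformed. Point summaries: weighted 5 %/95 %
  quantiles and a mode from a weighted Gaussian KDE (Silverman bandwidth)
  on the natural scale. A singular design falls back to the unadjusted
  rejection posterior, flagged.
* Predictive error: pseudo-observed datasets cycle through the scenarios,
  parameters drawn from the priors (the prior-based confidence measure) or
  fixed at supplied values (the posterior-conditioned variant); the error
  is the fraction misclassified by the chosen method.
* Posterior model checking: datasets simulated from posterior draws;
  per-statistic tail probabilities P(sim ≤ obs), flagged outside
  (0.025, 0.975).

Known limitation: with only four summary statistics and broad priors, the
bottleneck-time parameter t is weakly identified — the mutation-rate ×
size × time ridge lets the marginal t interval drift away from a true
recent value even in the plain rejection posterior. Current and ancestral
sizes are much better behaved. Credible intervals for t should be read as
joint, not marginal, statements.

## Synthetic data generator

Two profiles emulate the study designs the pipeline targets. Multi-site
allele frequencies follow the Balding–Nichols model: site frequencies are
Dirichlet(p(1 − F)/F) around ancestral frequencies p, so F is the expected
F<sub>ST</sub> and is recorded as ground truth (a diverged site simply gets
a larger F). Partial selfing is imposed at the pairing stage — with
probability s/(2 − s) an individual's two gene copies are identical by
descent — which yields the classical equilibrium F<sub>IS</sub> exactly in
expectation. We chose this over a structured-coalescent generator because
it gives exact, analytically known targets for the recovery tests
(F<sub>ST</sub> band, F<sub>IS</sub> = s/(2 − s)); single-population
demographic truths for ABC experiments use the coalescent simulator itself.

What the generator does *not* emulate: null alleles and genotyping error,
isolation-by-distance, linked loci, and real mutation-model misfit. Tests
passing on these data validate the estimators and the inference machinery
under their own assumptions; they do not certify behaviour on data
violating them.

Profile defaults: 7 sites of 4–8 individuals totalling 38 with 12 loci (10
polymorphic), F = 0.08, no selfing, one plastid haplotype over 471 + 650 bp
regions; and 4 sites (30/10/21/20) totalling 81 with 14 loci (5
polymorphic), selfing 0.58, one strongly diverged small site (F = 0.65 vs
0.06), two plastid haplotypes at 79:2 over 445 + 746 bp. Base composition
of plastid sequences is drawn at ≈29 % GC, typical of these intergenic
spacers.

## Problem sizes used in the shipped experiments

The shipped acceptance experiments run the ABC at 50 000 rows per scenario
(200 000-row tables) with k = 25 (direct), 1 000 (logistic) and 500
(estimation) — the same acceptance fractions as the full-scale defaults —
and 5–50 pseudo-observed datasets per question; `scripts/acceptance.py`
uses 10 000 rows per scenario. These sizes were chosen so a complete run is
a matter of minutes on one CPU while keeping Monte-Carlo error well inside
the asserted tolerances; all are parameters, not constants.

## Seeds and reproducibility

Every stochastic step takes an explicit seed. The pipeline expands its
single run seed into independent per-stage streams by spawn-key (stage
index), so toggling one stage never shifts another's randomness; rerunning
a configuration reproduces byte-identical tables.
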