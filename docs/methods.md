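# Methods

This note documents the models, numerical choices and known limitations of
`ptgut`. It is the companion to the API docstrings; nothing here reports a
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

The pipeline starts from a genus-level sample × taxon integer count table
(TSV), a per-sample metadata table (infant id, corrected gestational age =
GA at birth + postnatal age, weight, antibiotic and ventilation flags,
weekly milk volumes for mother's own milk / donor human milk / formula,
fortifier in use) and a per-infant table of perinatal covariates. Taxon
labels are opaque strings (genus names contain spaces), so tables are
strictly tab-delimited. Empty metadata cells are missing values and are
excluded listwise by each analysis; `corrected_ga` is revalidated against
`ga_birth + postnatal_age` to 1e-6 weeks on read. A rooted Newick tree
over the taxa supplies UniFrac branch lengths; multifurcations are
resolved internally with zero-length branches, which leaves both UniFrac
variants unchanged while fixing a root for branch enumeration.

## Diversity

Rarefaction draws without replacement (multivariate hypergeometric), so
expected post-rarefaction proportions equal the input proportions; samples
under the target depth are dropped and logged. The cohort-scale default
depth is 23,098 reads; synthetic-cohort analyses use 5,000 for speed (the
generator's median library is 30,000, so essentially nothing is dropped at
either depth). One rarefied table feeds both alpha and beta diversity; the
choice is recorded in the run manifest. Shannon entropy defaults to base 2
(the convention of the upstream QIIME2-style stack), natural log
selectable. The arcsine-square-root transform asin(√p) is applied before
linear modelling as a variance stabiliser for proportions.

## Distances and PERMANOVA

The Jensen–Shannon distance is computed as √(H(m) − ½H(a) − ½H(b)) with
natural-log entropies and the 0·log 0 := 0 convention — algebraically the
symmetrised-KL form, but numerically stable for sparse profiles; it is a
metric bounded by √ln 2. Unweighted UniFrac delegates to scikit-bio.
Weighted UniFrac is computed in-package as a branch-mass tally on float
proportions (the scikit-bio driver casts inputs to integer counts, which
would zero a relative-abundance matrix); the raw form is a length-weighted
L1 distance and hence a metric, while the normalized form (default) is
bounded by 1 but need not satisfy the triangle inequality.

PERMANOVA follows the `adonis` convention: Gower-centred −½d² matrix,
sequential (Type-I) sums of squares in the user's term order via nested
hat-matrix projections, pseudo-F against the residual mean square, and
free permutation of sample labels with the +1 small-sample correction.
Repeated measures per infant are *not* restricted in the permutation
scheme (matching the upstream analysis); p-values for time-varying
covariates are therefore anticonservative in principle and should be read
as descriptive. Permutations are evaluated in vectorised blocks capped at
~20 M floats to bound memory.

## Enterotyping

PAM is the classic BUILD + SWAP: greedy seeding minimising total
point-to-nearest-medoid distance, then best-improvement swaps until no
swap lowers total cost; all ties break toward the lowest sample index, so
the fit is deterministic for a given distance matrix. The Calinski–Harabasz
index is formulated on the distance matrix alone (the JSD space has no
coordinates): within-dispersion W = Σ_c Σ_i d(i, medoid_c)², between-
dispersion B = Σ_c n_c·d(medoid_c, g)² with g the sample minimising total
squared distance; CH = (B/(k−1))/(W/(n−k)). k is scanned over 2–10 by
default with argmax-CH selection and ties toward smaller k; a mean
silhouette below 0.25 at the chosen k raises a weak-structure flag (this
is what a single-state cohort produces). Clusters are renumbered by
decreasing size; for k = 2 the cluster with the higher mean
*Escherichia-Shigella* abundance is named enterotype A. Transition
analysis orders each infant's samples by corrected GA and emits one record
per consecutive pair with differing labels. Because the "changed
enterotype" sample count can be read two ways, the comparison table
reports both: samples that immediately precede a switch, and all samples
of changer infants, each labelled.

## Differential abundance

The LefSe-style screen keeps taxa with two-class Kruskal–Wallis p < 0.05,
then scores each survivor as log₁₀ of the bootstrap-averaged absolute
class-mean difference of abundance × 10⁶ (for one feature the 1-D Fisher
discriminant projection reduces to the scaled mean difference), reporting
scores ≥ 2.0. The original tool's subclass (Wilcoxon) stage is omitted:
the two-enterotype design has no subclass structure. Bootstrap streams are
keyed by each class's sample-membership mask, making the scores exactly
invariant under class relabelling.

Per-taxon mixed models fit asin(√p) on the requested fixed effects with a
per-infant random intercept by REML, Wald z-tests per coefficient, and
Benjamini–Hochberg correction across taxa within each term (the FDR family
matching per-panel q-values). The six-level feeding factor is
treatment-coded against "Human milk - none". Numeric covariates are
standardised internally for optimizer conditioning and coefficients are
reported back on original units. Zero-variance taxa and fits without
finite standard errors are flagged and excluded from the FDR family rather
than failing the run; the optimizer cascade is lbfgs → bfgs → powell → cg,
accepting the first fit with finite estimates.

## Feeding categories and growth

A sample-week maps to the human-milk branch iff (MOM + DHM) volume is a
strict majority of the week's intake (MOM and DHM are pooled); the
category is completed by the fortifier flag, and HMF with formula
predominance is rejected as inconsistent (human-milk fortifier is added to
human milk). Weight-gain velocity is the consecutive-pair difference
Δweight/Δdays; the recorded birth weight anchors a week-0 observation, so
each infant contributes one interval more than their weighing count, which
substantially stabilises per-infant slopes on short stays. Each interval
inherits the fortifier of its closing week, so fortifier strata are
defined at sample-week resolution.

The growth model is a *linear* mixed model (the structure — fixed
intercept and slope, random intercept and slope per infant — is linear
even though the upstream description says "non-linear mixed-effects"):
velocity on corrected GA, REML, with the random intercept and random slope
as independent variance components. The uncorrelated parameterisation
mirrors the stated model ("variance of the intercept and the slope") and
is far better conditioned than a full 2×2 covariance on 3–8 observations
per infant. Corrected GA is centred at the sample mean; centring shifts
only the intercept. If the data lie exactly on one common line (zero
residual variance) REML degenerates at the boundary and the fit falls back
to ordinary least squares, which is then exact.

## The synthetic cohort generator

The generator emulates the study conditions and returns the ground truth
needed for recovery testing. Per infant: GA at birth ~ truncated normal
28.9 ± 2.45 wk on [23, 33]; perinatal covariates Bernoulli at the cohort
prevalences (chorioamnionitis 0.186, PROM 0.155, female 0.629, C-section
0.783, black maternal race 0.268); discharge at 35 ± 1.91 wk corrected GA;
weekly stools from postnatal week 1 to discharge. One master seed fans out
to per-infant streams by CRC-32 of the infant id, so outputs are invariant
to iteration order; identical (config, seed) is byte-identical.

**Community states.** Each sample carries a latent enterotype evolving as
a two-state weekly Markov chain: initial P(A) = 0.33, transition matrix
((0.85, 0.15), (0.075, 0.925)). The stationary law is exactly (1/3, 2/3),
matching the observed ~33%/67% sample split, and the persistence level
makes roughly 40–45% of infants switch at least once over a ~6-week stay
(the observed changer share). State A's Dirichlet mean is
*Escherichia-Shigella*-dominated (45.4%, with *Bacteroides* and
*Staphylococcus* co-enriched); state B has *Escherichia-Shigella* at 1.47%
and is enriched in uncharacterised *Enterobacteriaceae* (27.9%),
*Clostridium sensu stricto 1* (28.7%), *Klebsiella* and *Veillonella* —
the planted between-state contrasts of ~26–27 percentage points for the
two leading genera. Proportions are Dirichlet(mean × 40) and counts
multinomial at a log-normal library (median 30,000, log-sd 0.5), i.e.
Dirichlet-multinomial overdispersion. Antibiotic exposure is a per-sample
Bernoulli(0.08) that halves the *Clostridium sensu stricto 1* mean before
the draw — an effect direction taken from the cohort narrative, with a
free effect size.

**Feeding.** The fortification protocol is deterministic: infants born
<28 wk get HMF until 32 wk corrected GA (a one-week "both" overlap, then
BMF); infants born 28–34 wk get BMF; after 34 wk corrected GA formula
replaces unavailable HM, and after 35 wk fortification is weaned so
available HM is fed unfortified ahead of discharge — this wean supplies
the "Human milk - none" reference level at a realistic share of weeks.
Donor milk stands in when MOM is unavailable (per-infant probability
0.15), and MOM/DHM are treated identically throughout, as the upstream
analysis pooled them. From 30 wk corrected GA, weeks on BMF or no
fortifier may be mixed-fed with an HM fraction ~ Beta(5, 2), creating the
formula-predominant categories.

**Growth.** Weekly velocity follows a cumulative trend: it integrates the
fortifier-specific weekly increment (0.25 on HMF weeks, 0.43 on BMF weeks,
their mean on "both" weeks, 0.52 on unfortified weeks), anchored so the
trend passes the base velocity of 15 g/d near 32 wk corrected GA, plus a
per-infant random intercept (sd 8 g/d) and slope (sd 0.05), plus Gaussian
noise (sd 1.5 g/d, the scale of weekly weighing error). The cumulative
form means the local slope within any fortifier window is exactly the
configured increment — no kinks at switches — and the implied cohort-level
increment under the protocol-driven mix of weeks reproduces the reported
overall 0.39 g/d per week; the unfortified-week value of 0.52 (late
catch-up weeks near term-equivalent age) is the free parameter that closes
that identity. Velocities integrate to weights from a GA-dependent birth
weight (1273 g at 28.9 wk, 170 g/wk, sd 180 g).

**What the generator does not emulate.** Real abundance data are sparser
and more zero-inflated than a 21-genus Dirichlet-multinomial; there is no
bi-weekly sampling irregularity, no DNA-extraction or sequencing batch
structure, no NICU environmental covariates, and covariates other than
antibiotics/fortifier have no planted effect on composition — so passing
recovery tests demonstrates estimator correctness under the assumed model,
not robustness to real-data artefacts.

## Problem sizes used in validation

Recovery experiments are sized to finish in minutes: enterotype recovery
uses 40 cohorts of 60 infants at rarefaction depth 5,000; PERMANOVA
type-I calibration uses 500 null datasets of 30 samples with 999
permutations; mixed-model recovery uses 50 panels of 60 infants × 6
samples (planted effect +0.1 on the transformed scale) and 200 null panels
for p-value calibration; growth-slope recovery uses 50 replicate cohorts
of 150 infants — at the 97-infant study size the per-stratum intervals
still cover the planted increments, but the BMF > HMF ordering reproduces
only ~90–94% of the time, a power limitation of stratified fits on short
stays rather than an estimator defect.

## Known limitations

- PERMANOVA permutes freely across repeated measures (see above).
- The CH index on distances uses medoid-based dispersion; its absolute
  values are not comparable to the coordinate-based CH of other packages,
  only its profile over k matters.
- LDA effect sizes from the simplified (subclass-free) screen track the
  reference tool's scores only approximately; the ranking and the ≥2
  reporting behaviour are the validated properties.
- Mixed-model Wald tests use the normal approximation; with few infants
  per level, p-values for small groups are approximate.
- Fisher tests are exact but two-sided by the probability-mass rule; other
  two-sided conventions (doubling) give different values.
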