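# ptgut

Longitudinal analysis of the preterm-infant gut microbiota during NICU
hospitalisation: enterotype discovery and transition analysis, alpha/beta
diversity, differential-abundance screening, feeding-category assignment,
and growth-velocity modelling — together with a synthetic cohort generator
that plants known community states, feeding protocols and growth
parameters so every estimator can be validated by parameter recovery.

The package is aimed at microbiome researchers working with genus-level
16S count tables from longitudinal infant cohorts: weekly stools from
very-preterm infants (born ≤33 wk gestation), each sample annotated with
corrected gestational age (GA at birth + postnatal age), weight, milk
volumes by source (mother's own milk, donor human milk, formula) and the
fortifier in use (human-milk-based HMF, bovine-milk-based BMF).

## Methods at the core

**Enterotypes.** Samples are compared with the Jensen–Shannon distance

d(a, b) = √JS(a, b),  JS(a, b) = ½ KL(a‖m) + ½ KL(b‖m),  m = (a + b)/2

(natural logarithms; d ≤ √ln 2), clustered with Partitioning Around
Medoids (classic BUILD + SWAP, deterministic), and the number of clusters
k is chosen by maximising a Calinski–Harabasz index formulated directly on
the distance matrix: CH = [B/(k−1)] / [W/(n−k)], with W the summed squared
distances to cluster medoids and B the size-weighted squared distances
from cluster medoids to the pseudo-global medoid. The chosen k is
validated with the mean silhouette width s(i) = (b−a)/max(a,b). Each
infant's labelled samples, ordered by corrected GA, classify the infant as
exclusively one enterotype or a "changer", with covariates tabulated
before/after each switch (Fisher exact / Kruskal–Wallis comparisons).

**Diversity.** Counts are rarefied to an even depth (multivariate
hypergeometric), alpha diversity is observed richness and Shannon
H = −Σ pᵢ log₂ pᵢ; beta diversity is JSD plus unweighted and weighted
UniFrac on a rooted genus tree; covariate effects on distance matrices use
PERMANOVA with sequential (Type-I) sums of squares and free label
permutation, p = (1 + #{F* ≥ F}) / (1 + n_perm).

**Differential abundance.** A LefSe-style two-stage screen (per-taxon
Kruskal–Wallis, then a bootstrap-averaged one-dimensional linear
discriminant effect size on the log₁₀ scale, reported at ≥ 2.0), and
per-taxon linear mixed models of arcsine-√ abundance on perinatal,
anthropometric and dietary fixed effects with a per-infant random
intercept (REML, Wald tests), Benjamini–Hochberg FDR across taxa within
each term.

**Growth.** Weight-gain velocity (g/d) between consecutive weighings is
modelled as velocity = β₀ + β₁·correctedGA + b₀ᵢ + b₁ᵢ·correctedGA + ε
with per-infant random intercept and slope (uncorrelated variance
components, REML), overall and restricted to weeks on a given fortifier;
Spearman correlations link velocity to taxon abundances within fortifier
strata.

## Worked example

```python
from ptgut import (SynthConfig, generate_cohort, rarefy, relative_abundance,
                   fit_enterotypes, detect_transitions, velocity_table,
                   fit_growth_model)
from ptgut.enterotyping import transition_summary

config = SynthConfig(n_infants=60)
counts, meta, tree, truth = generate_cohort(config, seed=1)
relab = relative_abundance(rarefy(counts, depth=5000, seed=1))

fit = fit_enterotypes(relab, k_range=range(2, 11), seed=1)
print(f"samples: {len(relab.sample_ids)}, selected k = {fit.k}")
print(f"CH profile: k=2: {fit.ch_profile[2]:.0f}, k=3: {fit.ch_profile[3]:.0f}, "
      f"k=4: {fit.ch_profile[4]:.0f}")
named = {fit.names[c]: n for c, n in fit.cluster_sizes().items()}
total = sum(named.values())
print(f"enterotype A: {named['A']} samples ({100*named['A']/total:.1f}%), "
      f"B: {named['B']} ({100*named['B']/total:.1f}%)")
es = {fit.names[c]: v
      for c, v in fit.cluster_profiles["Escherichia-Shigella"].items()}
print(f"Escherichia-Shigella mean abundance: A {100*es['A']:.1f}%, "
      f"B {100*es['B']:.2f}%")

transitions, classes = detect_transitions(fit, meta)
s = transition_summary(transitions, classes)
print(f"infant classes: {s['class_counts']}, "
      f"changer share {100*s['changer_share']:.1f}%")

vel = velocity_table(meta)
for stratum in (None, "HMF", "BMF"):
    gf = fit_growth_model(vel, stratum=stratum)
    print(f"growth slope [{gf.stratum}]: {gf.slope:.3f} g/d per week "
          f"(95% CI {gf.slope_ci[0]:.3f} to {gf.slope_ci[1]:.3f})")
```

prints:

```
samples: 352, selected k = 2
CH profile: k=2: 975, k=3: 554, k=4: 418
enterotype A: 135 samples (38.4%), B: 217 (61.6%)
Escherichia-Shigella mean abundance: A 45.0%, B 1.38%
infant classes: {'exclusively-B': 27, 'changer': 20, 'exclusively-A': 13}, changer share 33.3%
growth slope [overall]: 0.432 g/d per week (95% CI 0.342 to 0.521)
growth slope [HMF]: 0.244 g/d per week (95% CI -0.295 to 0.783)
growth slope [BMF]: 0.389 g/d per week (95% CI -0.052 to 0.830)
```

The Calinski–Harabasz profile peaks sharply at k = 2 and the two fitted
clusters reproduce the planted community contrast (an
*Escherichia-Shigella*-dominated state A at ~45% mean abundance versus
~1.4% in state B). A third of infants start in state A, a third of the
cohort switches state during the stay, and the stratified growth fits
recover the planted fortifier-specific velocity increments (0.25 on HMF
weeks, 0.43 on BMF weeks) within their confidence intervals — at 60
infants the per-stratum intervals are wide; they tighten at the full
cohort size.

## Command line

```bash
ptgut simulate --n-infants 97 --seed 1 --out-dir cohort/
ptgut enterotype cohort/counts.tsv --depth 5000 --seed 1 \
      --sample-metadata cohort/samples.tsv --infant-metadata cohort/infants.tsv
ptgut growth cohort/samples.tsv cohort/infants.tsv --stratify-by fortifier
ptgut run --config pipeline.yaml --seed 1       # full pipeline, TSV bundle
```

Every output TSV carries a `# ptgut <version> seed=<seed>` provenance
header, and `run` writes a JSON manifest with per-stage seeds and content
checksums; reruns with the same config and seed are byte-identical.

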