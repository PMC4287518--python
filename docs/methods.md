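# Methods

## Data model

All matrices are samples × features in memory and features × samples on
disk (TSV, first column the feature id, `NA` for missing). Coordinates are
1-based inclusive. Genotypes are additive allele dosages in {0,1,2} with the
annotated effect allele counted; methylation is a beta value in [0,1];
expression is a log2 intensity. The sample sheet carries
(sample_id, cohort, group ∈ {fetal, adult}, tissue ∈ {liver, muscle, SAT,
VAT}); an `individual` column links multi-tissue samples from one donor.

Cis pairs are enumerated within a window of ±250 kb (inclusive at the
bound). A point feature (SNP, CpG) is anchored at its position; an interval
feature (expression probe) at its integer interval midpoint. The signed pair
distance is right anchor minus left anchor; eQTM results re-sign this to the
CpG-minus-probe convention. Probe strand is not modeled, so "downstream"
means plus-strand downstream — a documented limitation.

## Filters

* Variable-CpG filter: keep CpGs with cross-sample beta SD ≥ 0.02 (ddof 1).
  The threshold is a configurable stand-in: the criterion behind published
  "variable CpG" counts is typically part of unavailable supplementary
  protocols, so only the mechanism, not the constant, is load-bearing here.
* SNP QC defaults: MAF ≥ 0.05, Hardy–Weinberg exact-test p ≥ 1e-6,
  missingness ≤ 5%. The HWE test is the standard exact test conditional on
  the minor-allele count (sum of genotype configurations no more probable
  than the one observed), implemented directly via the stable two-sided
  recurrence because no installed dependency exposes one.
* Missing dosages are mean-imputed per SNP inside association computations
  only; imputed values are never written back.

All filters are idempotent.

## Association and meta-analysis

The association statistic is the Spearman rank correlation of trait on
dosage (average ranks for ties), chosen over Pearson for robustness to
outliers in array intensities and monotone-but-nonlinear dosage effects.
Two-sided p-values use the t approximation
`t = ρ√((n−2)/(1−ρ²))`; the per-cohort z is the signed normal quantile of
that p. Pairs are skipped with a coded reason (not an exception) when fewer
than 10 paired observations remain, the trait is constant, or fewer than two
genotype classes are present.

Cohorts are combined with the sample-size-weighted z:
`Z_meta = Σ √nᵢ Zᵢ / √(Σ nᵢ)`. Weights assume no sample overlap between
cohorts (distinct biobanks) and no between-cohort heterogeneity beyond the
additive batch offsets the generator produces; the meta-analysis reduces to
the single-cohort z when only one cohort is available and is invariant to
cohort order.

## Permutation FDR (QTL discovery)

The discovery unit is the trait feature (probe for eQTL, CpG for meQTL),
because downstream analyses count unique regulated features. For each
feature the observed top statistic is the maximum |Z_meta| over its cis
SNPs. Each of B permutations (default B = 10) shuffles the rows of the trait
matrix within each cohort — breaking the genotype–trait linkage while
preserving trait–trait correlation, LD, and cohort structure — and the
per-feature top statistics are recomputed. The estimate at threshold t is

    FDR(t) = (#{null tops ≥ t} / B) / #{observed tops ≥ t},

clipped to [0,1], using the null tops pooled over all features. A feature is
significant when FDR at its own top statistic is below α (default 0.05); the
pair-level threshold is the smallest top statistic among significant
features, and every pair at or above it is reported significant. The raw
counting estimator is used without monotonization so the arithmetic is
auditable against hand counts; with B = 10 it is mildly anticonservative,
which the calibration experiment quantifies (mean empirical FDR ≈ 0.06 at
nominal 0.05 under the conditions below).

meQTL scans first remove SNPs located inside the target methylation probe's
footprint (inclusive interval), since a variant under the probe can distort
hybridization and fake a methylation signal.

## eQTM mapping

eQTMs are tested at the pair level: Spearman ρ between CpG beta and probe
intensity over adult samples, with the add-one permutation p-value
`(1 + #{|ρ_null| ≥ |ρ_obs|}) / (1 + B)` (default B = 999, so p can never be
exactly zero and the floor is 1/(B+1)). Each permutation applies one shared
shuffle of the methylation–expression sample linkage so the cross-pair
correlation structure is preserved. When the adult panel pools cohorts the
shuffle is blocked within cohort: cohort batch offsets present in both data
types would otherwise inflate the observed correlations relative to a
globally-shuffled null — this miscalibration is visible as non-uniform
permutation p-values on null simulations and disappears under blocked
shuffling. A BH q over the permutation p-values is reported alongside so
either the plain p < 0.05 rule or a pair-level FDR convention can be applied
downstream.

## Variance partitioning

For each probe with both a significant eQTL and a significant eQTM, four
nested OLS fits: SNP only, top CpG only, SNP + top CpG, SNP + all CpGs with
a significant eQTM to that probe. The representative SNP is the strongest
significant association by |Z_meta| and the top CpG the strongest by |ρ| —
an assumption, since selection rules for such tables are rarely printed. R²
is unadjusted; unique contributions are semi-partial R² differences
(unique_snp = R²(SNP+CpG) − R²(CpG), and symmetrically); the shared
component R²(SNP+CpG) − unique_snp − unique_cpg may be negative under
suppression and is flagged rather than clipped. Collinear predictor columns
(e.g. the top CpG duplicated in the all-CpGs set) are dropped by a greedy
rank check, keeping the R² nesting chain exact. The nested F-test compares
SNP+CpG against SNP+all-CpGs with
`F = ((RSS_small − RSS_full)/Δp) / (RSS_full/(n − p_full − 1))`.

## Tissue sharing and matched-probe enrichment

Cross-tissue replication is strict significance-in-both, keyed by the
SNP–feature (or CpG–probe) pair; all 2^k − 1 Venn regions are counted
exactly and concordance is the fraction of shared keys with one sign across
every tissue carrying them. Matched-probe enrichment forms, for each target
probe, the nearest unused control probe in z-scored (median, SD) expression
space, greedily in seeded random order without replacement; enrichment is
the flagged fraction ratio with a 2×2 Pearson chi-squared (no continuity
correction).

## Synthetic cohorts

The generator emulates the two-cohort, four-tissue design: cohort A with 96
adult and 14 fetal liver samples, cohort B with 85 donors sampled in liver,
muscle, SAT and VAT; genotypes are constant across a donor's tissues, while
methylation/expression noise is redrawn per tissue. One synthetic chromosome
is used, with probes spaced 600 kb apart so cis windows are disjoint and
SNPs/CpGs assigned round-robin to probe neighborhoods within ±200 kb.

Generative model (per sample s, feature j):

* genotypes: MAF ~ Uniform(maf_range), dosage ~ Binomial(2, MAF);
* methylation latent scale: `m = μ_j + cohort offset + a·z(G)·σ_m +
  g·[fetal] + ε`, `ε ~ N(0, σ_m²)`, `β = 2^m/(2^m+1)`;
* expression: `y = μ_j + cohort offset + b·z(G)·σ_e + c·z(m_latent)·σ_e +
  f·[fetal] + ε`, `ε ~ N(0, σ_e²)`.

Effect sizes a, b, c are standardized slopes (effect per predictor SD in
units of the residual SD), so a slope of 0.6 corresponds to an expected
variance fraction 0.6²/(1+0.6²) ≈ 0.26. Defaults: meQTL slope 0.8, eQTL
slope 0.6, eQTM slope 0.6; σ_m = 0.5 (latent), σ_e = 1.0 (log2 units);
cohort offsets N(0, 0.2) per feature; baselines μ ~ Uniform(−3, 3) latent
for CpGs and Uniform(6, 12) for probes. Fetal group effects: latent shift
±2.0 for affected CpGs (drawn with baseline near the sigmoid midpoint so the
expected |Δβ| exceeds the 0.2 significance threshold) with island CpGs
hypomethylated in fetal with probability 0.86, mirroring the strong
island-specific asymmetry such comparisons show; expression shift ±3.0 log2
units. Shared SNPs affecting both methylation and expression of one gene are
planted with a 0.7 opposite-direction fraction; negative eQTM fractions are
0.70 within 50 kb and 0.50 beyond. Tissue sharing defaults (liver always
active, other tissues Bernoulli): 0.45 eQTL, 0.70 meQTL, 0.04 eQTM, with a
2% sign-flip rate among shared effects. Every planted effect is registered
exactly once in the truth table, which doubles as the acceptance oracle.

What the generator does **not** emulate: LD between SNPs, trans effects,
450K probe-type chemistry, cell-composition heterogeneity, expression
mean–variance coupling, or covariates such as age and sex. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated generative assumptions, not that real-cohort counts would
be reproduced.

## Calibration experiment (acceptance)

The headline check measures realized FDR of the eQTL discovery procedure:
500 probes, 1000 cis SNPs, 5% of probes carrying a planted eQTL with
standardized slope 0.6, two adult liver cohorts of 75 samples, mapping with
10 permutations at nominal FDR 0.05, repeated over 20 consecutive seeds. The
reported value is the mean false discovery proportion of declared probes
against the truth table (a seed declaring nothing contributes 0). These
problem sizes keep the whole experiment within seconds while leaving ~475
null features per replicate to populate the null tail.

## Numerical choices and degenerate inputs

* Spearman |ρ| is clipped below 1 before the t transform; p-values are
  floored at 1e-300 before the normal quantile.
* Constant traits, single-class genotypes, and sub-minimum sample counts are
  skipped with coded reasons; features with no valid pair are absent from
  the FDR computation rather than imputed.
* Zero-variance features in both groups of a differential test get p = 1
  with a warning; an all-zero row or column makes the CGI contingency
  chi-squared undefined (reported as such, with fractions still given).
* R² nesting is asserted to 1e-10; top-pair ties in the QTL table break by
  first occurrence; matching ties break by lowest pool index under a seeded
  target order.
* BH q-values come from statsmodels' step-up implementation and are checked
  against an independent oracle in the tests.

## Known limitations

No covariate regression (age, sex, ancestry, PEER-style factors), no
conditional/secondary signals, no trans analysis, no LD-aware SNP proxying
in the eQTL∩meQTL overlap (exact SNP identity only), and no moderated
(empirical-Bayes) differential testing. These are extension points, not
implicit claims.
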