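# Methods

## Study design emulated by the simulator

The package models a matched-tissue methylation study: one cohort of
colorectal-cancer cases, each contributing PBMC, normal colorectal mucosa
and tumour DNA, genotyped at the *MLH1* promoter SNP rs1800734 (GG, GA,
AA). The quantity of interest is the percent-methylated-reference (PMR)
score of the *MLH1* CpG shore, a percent on [0, 100].

Defaults in `SimulationConfig` encode the published cohort structure:

| parameter | default | notes |
|---|---|---|
| genotype counts | 211 GG / 119 GA / 19 AA | cohort margins |
| PBMC PMR mean (SD) | 30.1 (4.8) / 28.3 (3.6) / 22.6 (3.0) | by GG/GA/AA |
| normal colon | 32.8 (6.5) / 27.3 (4.5) / 24.0 (3.2) | |
| tumour | 33.3 (7.4) / 32.8 (7.0) / 37.0 (7.3) | |
| stage-IV tumour | 20.8 (3.6) | replaces the genotype mean |
| MSI-H rate | 30/211, 24/119, 8/19 | per genotype |
| stage margins | 22/81/208/21/17 over I/II/III/IV/unavailable | |
| island methylated | 34/349 | subject-level boolean |
| age | Normal(61.9, 8.8) truncated to [20, 74] | recruitment window |
| sex | P(female) = 163/349 | |
| clones | 15–27 per sample, 6 CpGs | amplicon 232 bp |
| qPCR | efficiency 2.0, Ct noise SD 0.2 cycles | duplicates per well group |

Per-tissue true methylation is drawn from a normal truncated to [0, 100]
by redrawing (PMR is a percent, and at these means/SDs the truncation
mass is negligible, so means are preserved to well under 0.1 points).
Stage-IV subjects' tumour methylation is drawn from the stage-IV
parameters *instead of* the genotype parameters — the stage effect
replaces, rather than shifts, the genotype mean, matching the reported
stage-IV hypomethylation irrespective of genotype. Each sub-simulation
(cohort, qPCR, clones, MSI markers) uses its own RNG stream derived from
the single config seed by a fixed offset, so stages are independently
reproducible and the whole pipeline is byte-deterministic for a fixed
config.

One caveat worth stating: the parenthetical dispersion values the
defaults adopt are treated as group SDs. Read that way, some printed
group comparisons are far more significant in simulation than the
p-values reported for the real cohort (and the tumour genotype ANOVA,
non-significant in the real data, can reach significance at the printed
tumour means). The simulator makes no attempt to reconcile this; tests
assert only directions and bounds, not specific p-values.

## qPCR model

A well's relative quantity is E^(−Ct) with amplification efficiency
E ∈ (1, 2], default 2 (perfect doubling; no standard-curve data exist to
fit anything better). The simulator inverts the PMR formula to place the
shore Ct so that the noiseless round trip is exact: PMR computed from
noise-free wells equals the subject's true methylation to machine
precision. Gaussian noise (SD 0.2 cycles) is added per replicate well.
True methylation of exactly 0 produces "Undetermined" shore wells, which
quantify as PMR 0 with a NO_AMPLIFICATION flag — below detection, not
missing. Each 96-well plate carries one duplicate pair of
fully-methylated reference wells for shore and *ALU-C4*; PMR uses the
plate's own calibrator ratio.

Replicates are aggregated as the arithmetic mean of Ct — the geometric
mean of quantities, which is the natural scale for an exponential assay —
and flagged REPLICATE_DISCORDANT above a ΔCt spread of 1.5 (configurable;
the handling of discordant duplicates and failed controls is an explicit
package choice, as no standard exists). Note the error budget: 0.2-cycle
noise on the four Ct means entering one PMR gives ≈ 0.4 cycles SD on
log2(PMR), i.e. roughly 20% relative measurement error and a small
(≈ 2–4%) upward bias from exponentiation; observed group SDs are
correspondingly wider than the generating truth.

## Bisulfite clone model and calling

The reference amplicon is a deterministic synthetic 232-bp sequence with
six CpGs and realistic non-CpG cytosine density (the real amplicon
sequence is not redistributable); CpG dinucleotides occur only at the six
designated sites, numbered 1–6 in the 5′→3′ direction. Clones are
bisulfite images of the top strand: non-CpG C → T except with the
conversion-failure rate (default 0.005), CpG C kept iff methylated, plus
per-base random substitutions at the sequencing-error rate (default
0.001). Sites are independent Bernoulli(p) per (tissue, genotype) by
default; an optional `fully_methylated_fraction` mixes in fully
methylated molecules to emulate correlated patterns, since no correlation
model is published. The default per-CpG probabilities (normal colon
0.42/0.25/0.10 for GG/GA/AA; tumour 0.42/0.40/0.45) were chosen once to
echo the reported pattern — genotype-dependent methylation in normal
tissue, genotype-independent in tumour — and are not fitted to anything.

Calling aligns each clone globally (Needleman–Wunsch via Biopython's
PairwiseAligner) under an asymmetric substitution matrix in which
reference C vs read T scores as a match; both orientations are tried and
the higher-identity one kept (reverse-complement clones are common in
TA cloning). Identity is bisulfite-equivalent matches over alignment
columns; below a hard floor of 0.6 the clone is rejected as non-target
(random sequence aligns far below this). QC thresholds, both
configurable: conversion efficiency ≥ 0.95 over covered non-CpG
cytosines, identity ≥ 0.90. An ambiguous base or gap at a CpG is
*missing* and excluded from denominators, never counted as unmethylated.
Lowering either threshold can only grow the retained clone set
(monotone QC, property-tested).

Genotype comparison uses, per CpG site, the 2×G table of pooled
methylated/unmethylated counts and Pearson chi-square without continuity
correction; a zero-margin table is reported as not computable rather
than patched. A clone-level contingency of methylated-CpG sums per clone
against genotype is also provided with configurable sum bins, because the
published description of that table's construction is ambiguous.

## Statistics

- Chi-square: Σ(O−E)²/E with margin-product expectations,
  df = (r−1)(c−1) (scipy backend; tests verify against a direct-formula
  oracle to 1e-10).
- Independent t-tests: Welch by default (the reported group SDs are
  unequal), pooled variant available; the F = t² identity for two groups
  is property-tested against the pooled variant.
- ANOVA: one-way fixed effects; all-identical input returns F = 0, p = 1.
- Regression: OLS with intercept; genotype coded additively by A-allele
  dose (GG = 0, GA = 1, AA = 2), tissue as treatment dummies with PBMC
  reference, stage binarized I–III vs IV (stage-unavailable subjects are
  dropped only from analyses that use stage). Because a per-variable
  "correlation" reported next to a multivariable model is ambiguous, both
  the OLS coefficients and the marginal Pearson r of each predictor with
  the outcome are reported, labelled distinctly. A rank-deficient design
  raises an error naming the collinear columns.
- Matched-tissue comparison: linear mixed model with a random intercept
  per subject (compound symmetry), fitted by maximum likelihood
  (statsmodels MixedLM); contrasts tumour−normal, tumour−PBMC,
  normal−PBMC are Wald z-tests on the fixed effects. No random slopes —
  with one observation per tissue per subject there is no information to
  identify them. For balanced complete data the contrast estimates equal
  tissue-mean differences (tested to 1e-6), and with zero between-subject
  variance the model collapses to the one-way ANOVA comparison.
- All p-values are two-sided; no multiple-testing adjustment is applied
  anywhere in the package.

MSI classification compares the unstable fraction as an exact rational
(`Fraction`), so 3 unstable of 10 is MSI-H and 29 of 100 is MSI-L with no
floating-point edge behaviour. Marker names are not restricted to the
default panel, since marker subsets are permitted provided ≥ 4 are
evaluable.

## What the simulations do and do not show

Passing round-trip and recovery tests demonstrates that the pipeline's
algebra is correct (PMR inversion exact at zero noise; clone calls exact
at zero error rates) and that the statistical layer detects the designed
effects at the designed sample sizes. They do not validate the biology of
real cohorts: the generator draws independent Gaussian methylation per
tissue (no within-subject correlation between tissues beyond the means,
while real matched tissues are correlated — the mixed model's subject
variance in simulated data comes mostly from measurement noise),
independent Bernoulli CpGs (real clones show spatial correlation), and no
batch, plate-position or extraction-quality effects.

## Problem sizes

Default simulated analyses use the full 349-subject design (1047 tissue
samples, ~70 plates) and complete in seconds; Monte-Carlo checks use 100
seeded replicates. Clone sequencing is simulated for two subjects per
genotype in tumour and matched normal tissue — the design of the
confirmation experiment — at 15–27 clones each; tests that need tighter
binomial precision raise the clone count instead of the sample count.
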