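# shoremeth

Analysis toolkit for CpG-**shore** DNA methylation studies of the *MLH1*
promoter region in colorectal cancer, built around four stages that are
usually welded together in ad-hoc scripts:

1. **MethyLight quantification** — real-time PCR Ct values from duplicate
   wells are converted to relative quantities and to the
   *percent methylated reference* (PMR) score,

   PMR = 100 × ([shore/*ALU-C4*]_sample) / ([shore/*ALU-C4*]_fully-methylated reference),

   with replicate-discordance and no-amplification QC and the standard
   CpG-island call (methylated iff PMR ≥ 10%).
2. **Bisulfite clone calling** — Sanger-sequenced clones are globally
   aligned to the reference amplicon with bisulfite-aware scoring
   (reference C vs read T counts as a match), methylation is called at
   each CpG (C = methylated, T = unmethylated, anything else = missing),
   clones are QC-gated on conversion efficiency over non-CpG cytosines,
   and per-site methylated counts are compared across rs1800734
   genotypes by Pearson chi-square. Text lollipop diagrams are rendered.
3. **MSI classification** — the NCI fraction rule over a ≥ 4-marker
   microsatellite panel: MSI-H iff ≥ 30% of evaluable markers unstable,
   MSS iff 0%, MSI-L otherwise (exact rational arithmetic at the
   boundary).
4. **Association statistics** — Table-1-style cohort summaries, one-way
   ANOVA and Welch t-tests of PMR across genotypes and clinical strata,
   multiple linear regression of PMR on tissue / genotype (additive
   A-allele dose) / age / sex / stage (I–III vs IV) / MSI / island
   status with marginal Pearson correlations reported alongside the OLS
   coefficients, and a random-intercept linear mixed model comparing
   matched PBMC, normal-colon and tumour DNA from the same subjects.

Because registry cohort data cannot be redistributed, the package ships a
first-class **synthetic cohort generator** that reproduces the study's
statistical structure — 211 GG / 119 GA / 19 AA cases, genotype- and
tissue-stratified PMR means and SDs, genotype-dependent MSI-H rates,
stage-IV tumour hypomethylation, 15–27 bisulfite clones per sample over a
232-bp six-CpG amplicon, and duplicate-well qPCR noise — so the whole
pipeline is testable end-to-end.

## Worked example

```python
from shoremeth import SimulationConfig
from shoremeth.io import run_pipeline

report = run_pipeline(SimulationConfig(seed=42), "demo_out")
print(open("demo_out/association_summary.txt").read())
```

runs the full pipeline (simulate → PMR → clones → MSI → associate) on the
default 349-subject cohort and prints, among other sections:

```
Matched-tissue mixed model (n=1047 obs, 349 subjects; ML, random intercept)
  subject var 11.584, residual var 65.217
  normal_colon - PBMC          est   +1.47 se 0.61  p 0.016
  tumour - PBMC                est   +4.75 se 0.61  p 8.16e-15
  tumour - normal_colon        est   +3.27 se 0.61  p 8.52e-08
normal_colon: mean PMR (SD) by genotype: GG 32.0 (8.8), GA 28.9 (7.0), AA 28.7 (7.4)
  ANOVA F=5.87 df=(2, 346) p=0.0031
Stage I-III vs IV (tumour): t=+9.06 df=22.9 p=4.91e-09
```

The mixed-model contrasts say tumour DNA is hypermethylated at the shore
relative to both normal colon (+3.3 PMR points) and PBMCs (+4.8 points);
the normal-colon ANOVA detects the genotype-dependent hypomethylation of
variant-allele carriers; the stage contrast shows the strong
hypomethylation of stage-IV tumours. Estimates differ from the generating
means by the simulated qPCR measurement noise.

The same stages are available from the shell:

```bash
shoremeth run --seed 42 --outdir demo_out
shoremeth pmr --wells demo_out/qpcr_wells.csv --out pmr.tsv
shoremeth clones --ref demo_out/reference.fasta --cpg demo_out/cpg_sites.bed \
    --fasta demo_out/clones/S0001_tumour.fasta --out clone_out
shoremeth msi --markers demo_out/msi_markers.tsv --out msi.tsv
```

Programmatic users can go through the model object directly:

```python
from shoremeth import ShoreAssociationModel
results = ShoreAssociationModel.from_dataframe(subjects_df, pmr_df).fit()
print(results.summary())
results.to_dict()  # JSON-ready report
```

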