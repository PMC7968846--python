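# mthet

Mitochondrial heteroplasmy from genotyping-array intensities: QC, phenotype
derivation, nuclear GWAS, and NUMT-artifact elimination.

## The problem

Mitochondrial DNA is present in hundreds of copies per cell, and sequence
variants can coexist with the reference molecule within one person — a
state called **heteroplasmy (MtHz)**. Genotyping arrays measure, at each
mtDNA probe, a B-allele frequency (BAF) in [0, 1]; because the labelling of
the two alleles is arbitrary, per-position heteroplasmy is the lesser-allele
intensity fraction

    h = min(BAF, 1 − BAF),   0 ≤ h ≤ 0.5,

and a person's phenotype is the mean of *h* over assayed positions,
winsorized at 99.5% and natural-log transformed for modelling. `mthet` is
for statistical geneticists who want to run — or audit — this analysis:

* an mtDNA variant/sample **QC cascade** (MAF/call-rate pruning, BAF-group
  split at 0.5, a pooled-SD LRR low-intensity filter, a cluster-quality
  filter, hypervariable-region exclusion, sample missingness);
* **phenotypes and noise covariates** (mean MtHz, log autosomal variance
  from 220 random high-quality autosomal SNPs, relative mtDNA copy number
  from mean LRR);
* a statsmodels-style modelling core: `HeteroplasmyNullModel` (covariate
  OLS: age, sex, PC1–5, log autosomal variance, optional haplogroup dummies
  vs reference H) and `HeteroplasmyGwas` (per-variant additive dosage term,
  1-df likelihood-ratio p-values, genomic control, distance-based locus
  clumping, single-imputed-locus rule, sensitivity refits);
* a **NUMT guard**: nuclear insertions of mtDNA sequence cross-hybridize
  with mitochondrial probes, inflate apparent MtHz in carriers inside the
  homology interval only, and — through LD with nearby nuclear SNPs —
  manufacture false GWAS hits. Interval masking and a three-subregion scan
  identify and remove them;
* **mother–offspring duo** concordance (stratified Spearman correlation);
* a seeded **synthetic-cohort generator** reproducing the statistical
  structure the analysis assumes, so the whole pipeline is testable with no
  data download.

## Worked example

```python
from mthet import (SimConfig, simulate_cohort, run_mt_qc, apply_qc,
                   build_phenotypes, fit_null_model, gwas,
                   NumtAnnotation, numt_retest)

cfg = SimConfig(n_samples=2000, seed=7)          # default study conditions
manifest, panel, samples, truth = simulate_cohort(cfg)

kept, kept_samples, report = run_mt_qc(panel, manifest)
clean = apply_qc(panel, kept, kept_samples, report)
pheno = build_phenotypes(clean, manifest, kept, seed=7)
pheno = pheno.join(samples.set_index("sample_id"))

null = fit_null_model(pheno)                     # covariate-only model
res = gwas(clean.dosage.loc[pheno.index], pheno, manifest=manifest)
lam = res.apply_genomic_control()
loci = res.clump()
```

printing, at seed 7:

```
QC kept 328 of 400 mtDNA variants, 1974 of 2000 samples
mean MtHz: 0.00795 (IQR 0.0057-0.0097)
lambda_GC = 1.194
loci: [('tag_numt474', 3.91e-89)]
```

QC removes the planted assay failures and hypervariable positions, leaving
a phenotype on the scale array cohorts actually show (mean MtHz ≈ 0.008).
The genomic inflation (λ = 1.19) and the single genome-wide significant
locus are both driven by the simulated polymorphic NUMT on chromosome 14 —
its tag SNP is in LD with an insertion whose carriers have inflated
apparent MtHz at positions mt.5583–6606. The guard exposes it:

```python
ann = NumtAnnotation("numt474", (5583, 6606), "14", 33_290_000)
numt_retest("tag_numt474", ann, clean, kept, manifest, pheno,
            clean.dosage.loc[pheno.index])
```

```
{'lead': 'tag_numt474', 'baseline_p': 5.07e-106, 'masked_p': 0.641,
 'verdict': 'numt_masked'}
```

Recomputing the phenotype without the homology interval annihilates the
association (p 5e-106 → 0.64): the "locus" measured the insertion, not any
influence on heteroplasmy. The three-subregion scan reaches the same
verdict without needing the annotation (`region_dependent`: significant in
the subregions containing the interval, p = 0.62 in the third).

The same flow runs end to end from the command line:

```bash
mthet all --config run.yaml            # or: simulate/qc/phenotype/gwas/numt-scan/duos
```

writing the QC report, phenotype table, null-model coefficients, GWAS
summary statistics, initial and final locus tables, NUMT scan reports and
the duo correlation table as tab-separated text under `out_dir`,
bit-identical across reruns at a fixed seed.

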