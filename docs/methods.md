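# Methods

`mthet` quantifies mitochondrial heteroplasmy (MtHz) from genotyping-array
intensity data and tests which nuclear loci influence it. This note records
the models, the synthetic-cohort generator the test suite runs against, and
the numerical choices a maintainer should know about.

## The heteroplasmy measure

At a biallelic mtDNA probe the B-allele frequency (BAF) estimates the
fraction of B-allele signal in [0, 1]. Because the labelling of the two
alleles is arbitrary, per-position heteroplasmy is the lesser-allele
fraction

    h(b) = min(b, 1 - b),  0 <= h <= 0.5,

with 0 meaning homoplasmy and 0.5 a perfectly balanced mixture. A sample's
phenotype is the arithmetic mean of h over its non-missing, QC-passing
positions. For modelling, the mean is winsorized at the upper 99.5%
quantile and natural-log transformed. Winsorization precedes the log: the
mean-MtHz distribution is right-skewed and bounded below, so only the upper
tail carries leverage-dominating outliers. Quantiles use the
linear-interpolation convention (numpy default); winsorized values depend on
it, which is why it is stated here. Under that convention re-winsorizing a
capped vector can lower the cap by the interpolation fraction of the top
gap; values below the cap are never touched.

## QC cascade

Variant and sample QC on the mtDNA panel proceeds, per pass, in the order:

1. **Prune** — keep biallelic variants with minor-allele frequency
   (from genotype calls) strictly above 0.001 and call rate strictly above
   99%.
2. **BAF groups** — split each variant's samples at BAF 0.5 (low group:
   BAF <= 0.5). Both alleles segregate in a population, so the two
   homoplasmic clusters are arbitrary labels of the same assay.
3. **LRR low-intensity filter** — within each group, remove calls whose
   log2 R ratio lies below the group mean minus 3 pooled SDs (SD pooled
   across the two groups, so small noisy groups do not calibrate their own
   threshold). The trim is iterated on the surviving calls until no further
   call falls below the recomputed threshold; a variant fails when the
   cumulative removed fraction reaches 1% in either group.
4. **Cluster-quality filter** — a variant is removed when, in either BAF
   group, at least 10 samples **and** at least 10% of the group show
   apparent heteroplasmy >= 0.20: such probes cannot discriminate the
   alleles.
5. **Hypervariable filter** — positions 57–372, 438–574 and 16024–16383
   (1-based inclusive, rCRS) are excluded for hybridization reliability.
6. **Sample missingness** — samples missing strictly more than 5% of the
   surviving variants are removed.

Because removing samples or calls shifts per-variant statistics, the pass
is repeated on the surviving panel until a pass removes nothing new
(typically two or three passes). The converged state is a fixed point, so
running QC on its own output changes nothing — a property the test suite
asserts. Within the first pass the filters apply in the order above to the
full input, and the reported per-variant statistics are first-pass values;
later passes recompute all statistics on survivors, so a variant whose
surviving call rate dips under the bar after call removal is dropped.
Exact monotonicity ("tighter thresholds keep fewer") holds per filter on
fixed input; at cascade level, feedback through sample removal can rescue a
variant, and the tests assert the per-filter form.

## Covariates

* **Autosomal variance** — per sample, the mean absolute BAF deviation from
  the expected 0 (AA) or 1 (BB) at homozygous calls over a seeded random
  panel of 10 high-quality autosomal SNPs per autosome (220 total; MAF >=
  0.1, call rate > 99.98%). It is the autosomal analogue of the MtHz
  measure and absorbs per-sample intensity noise. Whether the source
  construction averaged absolute or squared deviations is not documented;
  the absolute form mirrors the MtHz mean and is the default, with the
  squared form behind `squared=True`. The covariate enters models as
  ln(autosomal variance + 1e-6); the offset exists because a noise-free
  sample has variance exactly 0.
* **Relative mtDNA copy number** — the mean mtDNA LRR over kept positions
  after low-intensity call removal. Used only in sensitivity refits.

## Models

The null (covariate-only) model is ordinary least squares of the winsorized
log mean MtHz on age, sex (female indicator), principal components 1–5 and
log autosomal variance, optionally plus haplogroup dummies against
reference H and copy number. The GWAS adds an additive per-B-allele dosage
term per nuclear variant; its p-value is a 1-df likelihood-ratio test
(for OLS, LRT = n·ln(RSS0/RSS1)), with Wald statistics reported alongside.
Residualizing phenotype and dosages on the covariates once
(Frisch–Waugh–Lovell) reduces the scan to matrix products; columns with
missing dosages fall back to per-variant complete-case fits. Male
X-chromosome genotypes are coded homozygous diploid {0, 2}
(`male_x_dosage`). Zero-variance or covariate-collinear dosages are flagged
untested rather than raising.

Genomic control is the standard median form: lambda = median chi-square /
0.45494 (the 1-df null median); when lambda > 1 every statistic is divided
by lambda and p-values recomputed. Loci are clumped greedily by distance
(most significant unassigned variant leads; significant variants within
±500 kb on the same chromosome join it) — distance rather than LD because
the package carries no LD panel. Loci whose only genome-wide-significant
member is a single imputed variant are dropped as poorly supported.

**Measurement attenuation.** Apparent mean MtHz is latent heteroplasmy plus
a noise floor proportional to the sample's intensity noise. On the log
scale every covariate and genotype effect is therefore attenuated toward
zero by roughly the latent share of the apparent mean (~0.8 at the default
noise settings). This is a property of the measurement, not of the
estimator; the log-autosomal-variance covariate absorbs between-sample
noise differences but not the multiplicative attenuation. Parameter-recovery
tests either use the default (small) effects, where the bias is well under
one standard error, or a low-noise assay configuration.

## NUMT guard

Nuclear insertions of mitochondrial sequence (NUMTs) cross-hybridize with
mtDNA probes and inflate apparent heteroplasmy in carriers — but only at
positions inside the insertion's homology interval — and, being in LD with
nearby nuclear SNPs, manufacture false associations. Two guards:

* **Interval masking** — recompute the phenotype excluding the annotated
  interval (1-based inclusive) and re-test the lead; verdict `numt_masked`
  when a genome-wide-significant baseline association loses significance.
* **Subregion scan** — split kept positions into k = 3 contiguous
  coordinate groups of near-equal count (the whole-genome mean is exactly
  the count-weighted mean of the group means), recompute the phenotype per
  group and re-test each lead. The default verdict rule is heterogeneity:
  `region_dependent` when at least one subregion loses genome-wide
  significance while at least one retains it. The literal rule — flag on
  any non-significant subregion — also removes genuine loci that merely
  lose power on a third of the positions, so it is opt-in
  (`literal_rule=True` / `--literal-subregion-rule`); both readings are
  reported. Leads not significant at baseline are excluded from the scan.

## Mother–offspring duos

Each (pair, variant) point with maternal heteroplasmy strictly above 5%
contributes maternal vs offspring BAF, stratified by the maternal BAF side
of 0.5 (exactly 0.5 goes to the low stratum, consistent with the QC
grouping). Spearman rank correlation (midranks, t-approximation) is
computed per stratum; positive correlation in both strata is the signature
of germline transmission. Points with heteroplasmic offspring but
sub-threshold mothers are excluded — the maternal threshold defines the
point set. No per-pair aggregation is performed; the correlation is over
points.

## Synthetic cohort generator

The generator emulates the statistical structure of a large saliva-array
cohort; every draw flows from one integer seed through named sub-streams.

* **Latent phenotype.** ln(latent mean MtHz) = baseline + age·age_effect +
  sex_effect·I(female) + haplogroup effect + Σ causal-β·dosage + N(0,
  latent_sd). Defaults: age −0.000246/yr, female −0.0407, haplogroup
  shifts for the 19 common European haplogroups plus a pooled remainder
  (reference H), one genotyped causal locus of +0.035 per allele,
  latent_sd 0.35. Haplogroup frequencies follow the composition of a
  ~1M-sample European-ancestry cohort.
* **Per-position heteroplasmy.** h ~ Gamma(k = 0.3, mean = latent mean),
  clipped to 0.5: most positions near-homoplasmic with occasional high
  heteroplasmy, as arrays observe.
* **Intensities.** Each variant has a population B-allele frequency; each
  sample a homoplasmic base allele, so BAF = h or 1 − h plus N(0, σ_s)
  noise, clipped to [0, 1]. σ_s ~ Gamma(9, rate 6000) (mean 0.0015) is
  shared between mtDNA probes and autosomal homozygote BAF — exactly the
  coupling that makes autosomal variance a noise covariate. With these
  defaults the apparent cohort mean MtHz is ≈ 0.0074 with an
  interquartile spread matching the 0.0046–0.012 scale of real saliva
  arrays; the baseline and noise scale were fixed once from that target.
  LRR = per-sample copy-number term N(0, 0.15) + N(0, 0.12) probe noise.
* **NUMTs.** An insertion segregating at frequency f adds
  `baf_offset_per_copy` per copy to apparent heteroplasmy (toward BAF 0.5)
  at every position inside its homology interval, and is tagged by a
  genotyped nuclear SNP with haplotype-level LD achieving the configured
  r². The default spec mirrors a known chromosome-14 NUMT homologous to
  mt.5583–6606 (f = 0.14, r² = 0.8, offset 0.05): a 0.05 offset over the
  ~6% of positions in the interval shifts ln mean MtHz by ≈ 0.3 per copy,
  which an a-priori non-centrality calculation puts far beyond genome-wide
  significance at n ≥ 1500 — the guard tests operate in that regime.
* **Transmission.** A configurable fraction of the cohort forms
  mother–offspring duos (mothers drawn from females; offspring inherit the
  maternal base allele). Offspring heteroplasmy is Beta-distributed around
  the maternal value with concentration 50 (a germline-bottleneck model);
  infinite concentration copies the maternal value.
* **Assay failures.** 5% of mtDNA probes acquire low-intensity dropouts
  (LRR −1.5 for a per-probe failure rate drawn in [0.2%, 3%], so some but
  not all fail the 1% rule) and 3% lose allele discrimination (BAF
  compressed toward 0.5, triggering the cluster filter). A 0.2% baseline
  no-call rate and a 0.5% fraction of high-missingness samples exercise
  call-rate and sample filters.

**What the generator does not emulate:** realistic LD beyond the one
tag-SNP construction, haplogroup phylogeny (labels are sampled from a
frequency table), read-level error, mega-NUMTs spanning the whole mtDNA,
or platform batch structure. Passing tests therefore demonstrate the
pipeline's operating characteristics under this noise model, not
performance on any particular array product.

## Problem sizes and numerics

The test suite runs cohorts of 800–5000 samples and 120–400 mtDNA
variants; null calibration uses 5000 independent test SNPs at n = 2000, and
the NUMT-guard operating characteristics use 20 replicates per arm at
n = 1500. Rank deficiency in a design matrix raises an error naming the
collinear columns (pivoted QR); the genomic-control adjustment is skipped
when lambda exceeds 1 by less than 1e-9 to avoid quantile round-trip noise;
residual sums of squares are floored at 1e-300 before the log-ratio. Locus
clumping breaks p-value ties by chromosome then position, making results
independent of input order. All writers emit tab-separated text with a
stable column order and `%.10g` floats, so repeated runs at a fixed seed
are bit-identical.

## Known limitations

* Distance-based clumping can merge distinct signals within 500 kb and
  split a long LD block.
* The subregion scan's heterogeneity rule has reduced power against NUMTs
  whose homology interval straddles a partition boundary; annotation-based
  masking is the stronger guard when the interval is known.
* Effects estimated on the apparent (noisy) phenotype are attenuated
  relative to latent effects, as described above.
* The duo analysis treats points as independent although a pair
  contributes many positions; p-values for transmission are therefore
  anti-conservative and the package reports them as descriptive.
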