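"""Seeded synthetic cohorts of array intensities for heteroplasmy analysis.

The generator emulates the statistical structure of a large direct-to-consumer
genotyping cohort: per-sample intensity noise that inflates both autosomal
homozygote BAF deviation and apparent mitochondrial heteroplasmy (MtHz),
age/sex/haplogroup shifts of the latent mean heteroplasmy, additive nuclear
causal loci acting on the log latent mean, polymorphic NUMT insertions that
inflate apparent MtHz only inside their mtDNA homology interval (and are
tagged by a nuclear SNP in LD), maternal transmission of heteroplasmy through
a germline bottleneck, and the two assay failure modes the QC cascade is
designed to remove (low-intensity dropouts, poorly clustering probes).

Every draw flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MT_CHROM, MT_LENGTH, IntensityPanel

__all__ = ["NumtSpec", "SimConfig", "TruthSet", "simulate_cohort", "simulate_duos",
           "DEFAULT_HAPLOGROUP_FREQS", "DEFAULT_HAPLOGROUP_EFFECTS"]

# Haplogroup composition of a large European-ancestry cohort (counts of the
# 19 haplogroups with >= ~1% frequency plus a pooled remainder), normalised
# to frequencies at construction time.
_HAPLOGROUP_COUNTS = {
    "H": 72363, "H1": 203003, "H2": 31389, "H3": 28107, "H4": 15052,
    "H5": 37219, "H6": 20240, "HV": 23855, "J1": 76312, "J2": 17812,
    "K1": 71844, "K2": 18034, "T1": 21921, "T2": 76650, "U2": 12438,
    "U4": 23358, "U5": 84439, "V": 17675, "X2": 14869, "Other": 115492,
}
_total = float(sum(_HAPLOGROUP_COUNTS.values()))
DEFAULT_HAPLOGROUP_FREQS: dict[str, float] = {
    k: v / _total for k, v in _HAPLOGROUP_COUNTS.items()
}

# Baseline shifts of ln mean MtHz per haplogroup, relative to reference H.
DEFAULT_HAPLOGROUP_EFFECTS: dict[str, float] = {
    "H": 0.0, "H1": 0.000753, "H2": 0.017434, "H3": 0.082418, "H4": 0.047945,
    "H5": 0.018601, "H6": 0.040591, "HV": 0.021313, "J1": 0.092318,
    "J2": 0.113978, "K1": 0.134303, "K2": 0.134744, "T1": 0.148079,
    "T2": 0.118618, "U2": 0.134402, "U4": 0.122405, "U5": 0.120046,
    "V": 0.009295, "X2": 0.049903, "Other": 0.079721,
}


@dataclass(frozen=True)
class NumtSpec:
    """A polymorphic nuclear insertion of mitochondrial sequence.

    Carriers gain an additive apparent-heteroplasmy offset (``baf_offset_per_copy``
    per insertion copy, applied toward BAF 0.5) at every assayed mtDNA position
    inside ``mt_interval`` (1-based inclusive, rCRS).  The insertion segregates
    at ``insertion_frequency`` and is tagged by a genotyped nuclear SNP at
    (``nuclear_chrom``, ``nuclear_pos``) with haplotype LD achieving ``tag_r2``.
    """

    mt_interval: tuple[int, int]
    nuclear_chrom: str
    nuclear_pos: int
    insertion_frequency: float
    tag_r2: float
    baf_offset_per_copy: float
    name: str = "numt"

    def __post_init__(self):
        s, e = self.mt_interval
        if not (1 <= s <= e <= MT_LENGTH):
            raise ValueError(
                f"mt_interval: need 1 <= start <= end <= {MT_LENGTH}, got {self.mt_interval}")
        if not 0 < self.insertion_frequency < 1:
            raise ValueError(f"insertion_frequency must be in (0,1), got {self.insertion_frequency}")
        if not 0 <= self.tag_r2 <= 1:
            raise ValueError(f"tag_r2 must be in [0,1], got {self.tag_r2}")
        if self.baf_offset_per_copy <= 0:
            raise ValueError(f"baf_offset_per_copy must be > 0, got {self.baf_offset_per_copy}")


def _default_numts() -> list[NumtSpec]:
    # Mirrors a known polymorphic NUMT homologous to mt.5583-6606 tagged by a
    # chromosome-14 SNP.
    return [NumtSpec(mt_interval=(5583, 6606), nuclear_chrom="14",
                     nuclear_pos=33_290_000, insertion_frequency=0.14,
                     tag_r2=0.8, baf_offset_per_copy=0.05, name="numt474")]


@dataclass
class SimConfig:
    """Cohort generator settings.

    Defaults reproduce the study conditions of a saliva-array heteroplasmy
    cohort at desk scale: apparent mean MtHz near 0.0074 with IQR-scale
    dispersion, small negative age and female effects on ln mean MtHz,
    haplogroup baseline shifts relative to H, one TFAM-scale causal nuclear
    locus and one polymorphic NUMT.
    """

    n_samples: int = 2000
    n_mt_variants: int = 400
    n_autosomes: int = 22
    n_auto_snps_per_chr: int = 25
    n_nuclear_test_snps: int = 200
    #: (shape, rate) of the Gamma distribution of per-sample BAF noise sigma_s.
    #: shape 0 disables noise entirely (sigma_s = 0 for every sample).
    noise_scale_distribution: tuple[float, float] = (9.0, 6000.0)
    baseline_log_mthz: float = float(np.log(0.006))
    age_effect: float = -0.000246
    sex_effect: float = -0.040726
    haplogroup_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_EFFECTS))
    haplogroup_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS))
    causal_loci: list[tuple[int, float]] = field(default_factory=lambda: [(0, 0.035)])
    numts: list[NumtSpec] = field(default_factory=_default_numts)
    duo_fraction: float = 0.2
    transmission_concentration: float = 50.0
    #: (low_intensity_fraction, poor_cluster_fraction) of mtDNA probes.
    assay_failure: tuple[float, float] = (0.05, 0.03)
    seed: int = 0

    # Generator noise-model knobs not tied to a single operation.
    latent_sd: float = 0.35          # residual SD of ln latent mean MtHz
    position_dispersion: float = 0.3  # Gamma shape of per-position heteroplasmy
    lrr_noise_sd: float = 0.12
    copy_number_sd: float = 0.15
    nocall_rate: float = 0.002       # baseline mtDNA probe no-call rate
    bad_sample_fraction: float = 0.005  # samples with grossly elevated no-call
    mono_mt_fraction: float = 0.08   # mtDNA variants essentially monomorphic

    def validate(self) -> None:
        for name in ("n_samples", "n_mt_variants", "n_autosomes",
                     "n_auto_snps_per_chr", "n_nuclear_test_snps"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        shape, rate = self.noise_scale_distribution
        if shape < 0 or (shape > 0 and rate <= 0):
            raise ValueError(
                f"noise_scale_distribution must have shape >= 0 and rate > 0, "
                f"got {self.noise_scale_distribution}")
        for name in ("duo_fraction", "bad_sample_fraction", "nocall_rate",
                     "mono_mt_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not self.transmission_concentration > 0:
            raise ValueError(
                f"transmission_concentration must be > 0, got {self.transmission_concentration}")
        lo, pc = self.assay_failure
        if not (0 <= lo <= 1 and 0 <= pc <= 1):
            raise ValueError(f"assay_failure fractions must be in [0,1], got {self.assay_failure}")
        for idx, beta in self.causal_loci:
            if not 0 <= idx < self.n_nuclear_test_snps:
                raise ValueError(
                    f"causal_loci index {idx} outside [0, {self.n_nuclear_test_snps})")
        freqs = np.array(list(self.haplogroup_freqs.values()), dtype=float)
        if freqs.size == 0 or (freqs < 0).any() or freqs.sum() <= 0:
            raise ValueError("haplogroup_freqs must be non-negative and sum > 0")
        for hap in self.haplogroup_effects:
            if hap not in self.haplogroup_freqs:
                raise ValueError(f"haplogroup_effects refers to unknown label {hap!r}")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated cohort."""

    true_heteroplasmy: pd.DataFrame          # samples x mt variants, in [0, 0.5]
    numt_copies: pd.DataFrame                # samples x numts, integer {0,1,2}
    per_sample_noise: pd.Series              # sigma_s
    causal_betas: list[tuple[str, float]]    # (variant_id, per-allele effect)
    duo_pairs: list[tuple[str, str]]         # (mother_id, offspring_id)
    latent_mean: pd.Series = None            # latent mean MtHz per sample
    base_allele: pd.DataFrame = None         # per-sample major allele (0=A, 1=B)
    copy_number_term: pd.Series = None       # per-sample mtDNA LRR shift


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _hwe_genotypes(rng, freq: np.ndarray, n: int) -> np.ndarray:
    """n x m genotype counts under Hardy-Weinberg at B-allele frequencies freq."""
    return (rng.random((n, freq.size)) < freq).astype(np.int8) + \
           (rng.random((n, freq.size)) < freq).astype(np.int8)


def _ld_pair(rng, q: float, r2: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes at an (insertion, tag) SNP pair with equal frequency q and LD r2.

    Haplotype frequencies are set so the squared haplotype correlation equals
    r2 exactly; individuals are two independent haplotype draws.
    """
    d = np.sqrt(r2) * q * (1 - q)
    probs = np.array([
        (1 - q) * (1 - q) + d,   # 00
        (1 - q) * q - d,         # 0 tag
        q * (1 - q) - d,         # ins 0
        q * q + d,               # ins tag
    ])
    haps = rng.choice(4, size=(n, 2), p=probs / probs.sum())
    ins = (haps >= 2).sum(axis=1).astype(np.int8)
    tag = (haps % 2).sum(axis=1).astype(np.int8)
    return ins, tag


def simulate_duos(config: SimConfig, truth: TruthSet,
                  rng: np.random.Generator | None = None,
                  female_mask: np.ndarray | None = None) -> TruthSet:
    """Overwrite offspring heteroplasmy with maternally transmitted values.

    ``duo_fraction`` of the cohort is paired into mother-offspring duos.  At
    every shared mtDNA position the offspring heteroplasmy is drawn from a
    Beta distribution centred on the maternal value with concentration
    ``transmission_concentration`` (a germline-bottleneck model); infinite
    concentration copies the maternal value exactly.  Unpaired samples keep
    their independent draws.  When ``female_mask`` is given, mothers are
    drawn from female samples only.  Returns the same TruthSet, modified in
    place with ``duo_pairs`` filled in.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(9)[-1])
    samples = truth.true_heteroplasmy.index
    n = len(samples)
    n_paired = int(round(n * config.duo_fraction))
    n_pairs = n_paired // 2
    truth.duo_pairs = []
    if n_pairs == 0:
        return truth
    pool = np.arange(n) if female_mask is None else np.flatnonzero(female_mask)
    if n_pairs > pool.size:
        raise ValueError(
            f"duo_fraction: need {n_pairs} eligible mothers, have {pool.size}")
    mothers = rng.choice(pool, size=n_pairs, replace=False)
    rest = np.setdiff1d(np.arange(n), mothers)
    offspring = rng.choice(rest, size=n_pairs, replace=False)
    kappa = config.transmission_concentration
    h = truth.true_heteroplasmy.to_numpy()
    h_mat = h[mothers]
    if np.isinf(kappa):
        h_off = h_mat.copy()
    else:
        x = np.clip(h_mat / 0.5, 1e-9, 1 - 1e-9)
        h_off = 0.5 * rng.beta(kappa * x + 1e-3, kappa * (1 - x) + 1e-3)
    h[offspring] = h_off
    truth.true_heteroplasmy.iloc[:, :] = h
    truth.duo_pairs = [(samples[m], samples[o]) for m, o in zip(mothers, offspring)]
    return truth


def simulate_cohort(config: SimConfig):
    """Generate a full cohort.

    Returns
    -------
    (manifest, panel, samples, truth) :
        ``manifest`` — variant table (variant_id, chrom, pos, allele_A,
        allele_B, source); ``panel`` — :class:`IntensityPanel` over all
        mtDNA + nuclear-test (+NUMT tag) + autosomal-QC variants;
        ``samples`` — sample metadata table; ``truth`` — :class:`TruthSet`.
    """
    config.validate()
    rngs = _rngs(config.seed, [
        "meta", "noise", "mt_layout", "nuclear", "auto", "heteroplasmy",
        "intensity", "failures", "duos"])
    n = config.n_samples
    sample_ids = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")

    # ---- sample metadata -------------------------------------------------
    rng = rngs["meta"]
    age = np.clip(rng.normal(50, 15, n), 18, 95).round(1)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    hap_labels = list(config.haplogroup_freqs)
    hap_p = np.array([config.haplogroup_freqs[h] for h in hap_labels], dtype=float)
    haplogroup = rng.choice(hap_labels, size=n, p=hap_p / hap_p.sum())
    pcs = rng.normal(0.0, 1.0, (n, 5))

    # ---- per-sample noise ------------------------------------------------
    shape, rate = config.noise_scale_distribution
    if shape == 0:
        sigma = np.zeros(n)
    else:
        sigma = rngs["noise"].gamma(shape, 1.0 / rate, n)

    # ---- mtDNA variant layout -------------------------------------------
    rng = rngs["mt_layout"]
    mt_pos = np.sort(rng.choice(np.arange(1, MT_LENGTH + 1),
                                size=config.n_mt_variants, replace=False))
    mt_ids = [f"mt{p}" for p in mt_pos]
    # population B-allele frequency of the major (homoplasmic) allele
    mono = rng.random(config.n_mt_variants) < config.mono_mt_fraction
    mt_freq = np.where(mono, 0.0005, rng.uniform(0.02, 0.5, config.n_mt_variants))

    # ---- nuclear test SNPs (plus NUMT tags) ------------------------------
    rng = rngs["nuclear"]
    m_nuc = config.n_nuclear_test_snps
    nuc_freq = rng.uniform(0.05, 0.5, m_nuc)
    nuc_chrom = [str(1 + i % config.n_autosomes) for i in range(m_nuc)]
    nuc_pos = [1_000_000 + (i // config.n_autosomes) * 500_000 for i in range(m_nuc)]
    nuc_ids = [f"snp_c{c}_{p}" for c, p in zip(nuc_chrom, nuc_pos)]
    nuc_geno = _hwe_genotypes(rng, nuc_freq, n).astype(float)
    imputed = rng.random(m_nuc) < 0.3
    for idx, _ in config.causal_loci:
        imputed[idx] = False  # causal loci are genotyped
    dosage = nuc_geno.copy()
    if imputed.any():
        dosage[:, imputed] = np.clip(
            nuc_geno[:, imputed] + rng.normal(0, 0.12, (n, int(imputed.sum()))), 0, 2)

    numt_copies = np.zeros((n, len(config.numts)), dtype=np.int8)
    tag_ids, tag_chrom, tag_pos, tag_dosage = [], [], [], []
    for j, spec in enumerate(config.numts):
        ins, tag = _ld_pair(rng, spec.insertion_frequency, spec.tag_r2, n)
        numt_copies[:, j] = ins
        tag_ids.append(f"tag_{spec.name}")
        tag_chrom.append(str(spec.nuclear_chrom))
        tag_pos.append(int(spec.nuclear_pos))
        tag_dosage.append(tag.astype(float))

    # ---- autosomal QC SNP candidates ------------------------------------
    rng = rngs["auto"]
    m_auto = config.n_autosomes * config.n_auto_snps_per_chr
    low_maf = rng.random(m_auto) < 0.2
    auto_freq = np.where(low_maf, rng.uniform(0.01, 0.08, m_auto),
                         rng.uniform(0.12, 0.5, m_auto))
    auto_chrom = [str(1 + i // config.n_auto_snps_per_chr) for i in range(m_auto)]
    auto_pos = [50_000_000 + (i % config.n_auto_snps_per_chr) * 100_000
                for i in range(m_auto)]
    auto_ids = [f"qc_c{c}_{p}" for c, p in zip(auto_chrom, auto_pos)]
    auto_geno = _hwe_genotypes(rng, auto_freq, n)
    # a subset of probes genotype imperfectly, failing the strict call-rate bar
    auto_lowcall = rng.random(m_auto) < 0.1
    auto_nocall = (rng.random((n, m_auto)) < 0.002) & auto_lowcall[None, :]

    # ---- latent mean heteroplasmy ---------------------------------------
    hap_eff = np.array([config.haplogroup_effects.get(h, 0.0) for h in haplogroup])
    ln_m = (config.baseline_log_mthz
            + config.age_effect * age
            + config.sex_effect * (sex == "female")
            + hap_eff)
    for idx, beta in config.causal_loci:
        ln_m = ln_m + beta * nuc_geno[:, idx]
    rng = rngs["heteroplasmy"]
    if config.latent_sd > 0:
        ln_m = ln_m + rng.normal(0, config.latent_sd, n)
    latent_mean = np.clip(np.exp(ln_m), 1e-8, 0.45)

    k = config.position_dispersion
    h = np.clip(rng.gamma(k, latent_mean[:, None] / k,
                          (n, config.n_mt_variants)), 0.0, 0.5)
    base = (rng.random((n, config.n_mt_variants)) < mt_freq[None, :]).astype(np.int8)

    truth = TruthSet(
        true_heteroplasmy=pd.DataFrame(h, index=sample_ids, columns=mt_ids),
        numt_copies=pd.DataFrame(numt_copies, index=sample_ids,
                                 columns=[s.name for s in config.numts]),
        per_sample_noise=pd.Series(sigma, index=sample_ids, name="sigma"),
        causal_betas=[(nuc_ids[i], b) for i, b in config.causal_loci],
        duo_pairs=[],
        latent_mean=pd.Series(latent_mean, index=sample_ids, name="latent_mean"),
        base_allele=pd.DataFrame(base, index=sample_ids, columns=mt_ids),
        copy_number_term=None,
    )
    if config.duo_fraction > 0:
        truth = simulate_duos(config, truth, rngs["duos"],
                              female_mask=(sex == "female"))
        # the mitochondrial genome is maternally inherited: offspring carry
        # the maternal homoplasmic base allele at every position
        pos_of = {sid: i for i, sid in enumerate(sample_ids)}
        for mom, kid in truth.duo_pairs:
            base[pos_of[kid]] = base[pos_of[mom]]
        truth.base_allele.iloc[:, :] = base
    h = truth.true_heteroplasmy.to_numpy()

    # ---- mtDNA intensities ----------------------------------------------
    # Apparent heteroplasmy: truth plus NUMT cross-hybridization inside the
    # homology interval (offset per insertion copy, pushing BAF toward 0.5).
    h_app = h.copy()
    for j, spec in enumerate(config.numts):
        s, e = spec.mt_interval
        in_interval = (mt_pos >= s) & (mt_pos <= e)
        if in_interval.any():
            h_app[:, in_interval] = np.clip(
                h_app[:, in_interval]
                + spec.baf_offset_per_copy * numt_copies[:, j:j + 1], 0.0, 0.5)

    rng = rngs["intensity"]
    mt_baf = np.where(base == 1, 1.0 - h_app, h_app)
    if sigma.max() > 0:
        mt_baf = mt_baf + rng.normal(0, 1, mt_baf.shape) * sigma[:, None]
    mt_baf = np.clip(mt_baf, 0.0, 1.0)

    cn = rng.normal(0, config.copy_number_sd, n)
    truth.copy_number_term = pd.Series(cn, index=sample_ids, name="copy_number_term")
    mt_lrr = cn[:, None] + rng.normal(0, config.lrr_noise_sd, mt_baf.shape)

    # ---- assay failure modes --------------------------------------------
    rng = rngs["failures"]
    low_frac, poor_frac = config.assay_failure
    n_low = int(np.floor(low_frac * config.n_mt_variants))
    n_poor = int(np.floor(poor_frac * config.n_mt_variants))
    failed = rng.choice(config.n_mt_variants, size=n_low + n_poor, replace=False)
    low_probes, poor_probes = failed[:n_low], failed[n_low:]
    for v in low_probes:
        fail_rate = rng.uniform(0.002, 0.03)
        hit = rng.random(n) < fail_rate
        mt_lrr[hit, v] -= 1.5
    # poorly clustering probes: allele discrimination collapses toward BAF 0.5
    if n_poor:
        mt_baf[:, poor_probes] = 0.5 + (mt_baf[:, poor_probes] - 0.5) * 0.45

    # ---- genotype calls and missingness ----------------------------------
    mt_calls = np.where(mt_baf < 0.25, "AA", np.where(mt_baf > 0.75, "BB", "AB"))
    nocall_p = np.full(n, config.nocall_rate)
    if config.bad_sample_fraction > 0:
        n_bad = int(np.floor(config.bad_sample_fraction * n))
        bad = rng.choice(n, size=n_bad, replace=False)
        nocall_p[bad] = 0.08
    mt_missing = rng.random(mt_baf.shape) < nocall_p[:, None]
    mt_baf = np.where(mt_missing, np.nan, mt_baf)
    mt_lrr = np.where(mt_missing, np.nan, mt_lrr)
    mt_calls = np.where(mt_missing, None, mt_calls)

    # ---- autosomal QC SNP intensities ------------------------------------
    rng = rngs["intensity"]  # continue the intensity stream
    auto_baf = auto_geno / 2.0
    if sigma.max() > 0:
        het = auto_geno == 1
        noise = rng.normal(0, 1, auto_baf.shape) * sigma[:, None]
        auto_baf = auto_baf + np.where(het, 1.2 * noise, noise)
    auto_baf = np.clip(auto_baf, 0.0, 1.0)
    auto_lrr = rng.normal(0, config.lrr_noise_sd, auto_baf.shape)
    auto_calls = np.select([auto_geno == 0, auto_geno == 1], ["AA", "AB"], "BB")
    auto_baf = np.where(auto_nocall, np.nan, auto_baf)
    auto_calls = np.where(auto_nocall, None, auto_calls)

    # ---- nuclear test SNP intensities ------------------------------------
    nuc_baf = np.clip(nuc_geno / 2.0 + rng.normal(0, 0.02, nuc_geno.shape), 0, 1)
    nuc_lrr = rng.normal(0, config.lrr_noise_sd, nuc_geno.shape)
    nuc_calls = np.select([nuc_geno == 0, nuc_geno == 1], ["AA", "AB"], "BB")
    tag_mats = []
    for tdos in tag_dosage:
        tag_mats.append((
            np.clip(tdos / 2.0 + rng.normal(0, 0.02, n), 0, 1),
            rng.normal(0, config.lrr_noise_sd, n),
            np.select([tdos == 0, tdos == 1], ["AA", "AB"], "BB"),
        ))

    # ---- assemble ---------------------------------------------------------
    alleles = ["A", "C", "G", "T"]
    rng = rngs["mt_layout"]

    def _alleles(m):
        a = rng.integers(0, 4, m)
        b = (a + rng.integers(1, 4, m)) % 4
        return [alleles[i] for i in a], [alleles[i] for i in b]

    mt_a, mt_b = _alleles(config.n_mt_variants)
    nuc_a, nuc_b = _alleles(m_nuc)
    tag_a, tag_b = _alleles(len(tag_ids))
    auto_a, auto_b = _alleles(m_auto)

    manifest = pd.DataFrame({
        "variant_id": mt_ids + nuc_ids + tag_ids + auto_ids,
        "chrom": [MT_CHROM] * config.n_mt_variants + nuc_chrom + tag_chrom + auto_chrom,
        "pos": list(mt_pos) + nuc_pos + tag_pos + auto_pos,
        "allele_A": mt_a + nuc_a + tag_a + auto_a,
        "allele_B": mt_b + nuc_b + tag_b + auto_b,
        "source": (["genotyped"] * config.n_mt_variants
                   + ["imputed" if f else "genotyped" for f in imputed]
                   + ["genotyped"] * len(tag_ids)
                   + ["genotyped"] * m_auto),
    })

    all_ids = manifest["variant_id"].tolist()
    baf = np.column_stack([mt_baf, nuc_baf] + [t[0][:, None] for t in tag_mats]
                          + [auto_baf]) if tag_mats else \
        np.column_stack([mt_baf, nuc_baf, auto_baf])
    lrr = np.column_stack([mt_lrr, nuc_lrr] + [t[1][:, None] for t in tag_mats]
                          + [auto_lrr]) if tag_mats else \
        np.column_stack([mt_lrr, nuc_lrr, auto_lrr])
    calls = np.column_stack([mt_calls, nuc_calls] + [t[2][:, None] for t in tag_mats]
                            + [auto_calls]) if tag_mats else \
        np.column_stack([mt_calls, nuc_calls, auto_calls])

    dos = pd.DataFrame(np.column_stack([dosage] + [t[:, None] for t in tag_dosage])
                       if tag_dosage else dosage,
                       index=sample_ids, columns=nuc_ids + tag_ids)

    panel = IntensityPanel(
        baf=pd.DataFrame(baf, index=sample_ids, columns=all_ids, dtype=float),
        lrr=pd.DataFrame(lrr, index=sample_ids, columns=all_ids, dtype=float),
        calls=pd.DataFrame(calls, index=sample_ids, columns=all_ids),
        dosage=dos,
    )

    mother_id = pd.Series([None] * n, index=sample_ids, dtype=object)
    for mom, kid in truth.duo_pairs:
        mother_id.loc[kid] = mom

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "sex": sex,
        "haplogroup": haplogroup,
        "mother_id": mother_id.to_numpy(),
        **{f"pc{i + 1}": pcs[:, i] for i in range(5)},
    }).reset_index(drop=True)

    return manifest, panel, samples, truth
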