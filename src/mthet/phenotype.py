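"""Per-sample phenotypes and noise covariates.

The central quantity is per-position heteroplasmy, the lesser-allele
fraction min(BAF, 1 - BAF), bounded by 0.5.  A sample's phenotype is the
arithmetic mean over its non-missing QC-passing mtDNA positions; for
modelling, the mean is winsorized at an upper quantile (default 99.5%) and
natural-log transformed.  Two technical covariates accompany it: the
"autosomal variance" — mean absolute BAF deviation from the expected 0/1 at
homozygous calls over a seeded random panel of high-quality autosomal SNPs —
which absorbs per-sample intensity noise, and relative mtDNA copy number,
quantified as the mean mtDNA LRR after low-intensity call removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MT_CHROM, IntensityPanel

__all__ = ["per_position_heteroplasmy", "mean_mthz", "winsorize_upper",
           "ln_phenotype", "SnpSelectionCriteria", "select_autosomal_snps",
           "autosomal_variance", "mt_copy_number", "build_phenotypes",
           "AUTOSOMAL_VARIANCE_OFFSET"]

#: Offset added before log-transforming autosomal variance (its minimum is 0).
AUTOSOMAL_VARIANCE_OFFSET = 1e-6


def per_position_heteroplasmy(baf):
    """Lesser-allele intensity fraction min(b, 1-b); maximum 0.5 at b = 0.5.

    Accepts a scalar or array; raises ValueError outside [0, 1].
    """
    b = np.asarray(baf, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("BAF outside [0,1]")
    out = np.minimum(b, 1.0 - b)
    return float(out) if np.isscalar(baf) else out


def mean_mthz(panel: IntensityPanel, kept_mt_variants) -> pd.DataFrame:
    """Per-sample mean heteroplasmy over non-missing kept positions.

    Returns a DataFrame with columns ``mean_mthz`` and ``n_positions_used``;
    samples with zero usable positions get NaN.
    """
    baf = panel.baf[list(kept_mt_variants)].to_numpy(dtype=float)
    hz = np.minimum(baf, 1.0 - baf)
    n_used = (~np.isnan(hz)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(hz, axis=1) / n_used
    mean[n_used == 0] = np.nan
    return pd.DataFrame({"mean_mthz": mean, "n_positions_used": n_used},
                        index=panel.samples)


def winsorize_upper(values, q: float = 0.995) -> np.ndarray:
    """Cap values above the q-quantile (linear-interpolation convention).

    The lower tail is untouched; NaN entries pass through.  Idempotent and
    order-preserving below the cap.
    """
    if not 0 < q < 1:
        raise ValueError(f"winsorization quantile must be in (0,1), got {q}")
    v = np.asarray(values, dtype=float).copy()
    finite = ~np.isnan(v)
    if finite.sum() < 2:
        raise ValueError("winsorize_upper needs at least 2 finite values")
    cap = np.quantile(v[finite], q)  # method='linear'
    v[finite & (v > cap)] = cap
    return v


def ln_phenotype(mean_mthz_values, q: float = 0.995):
    """Natural log of the winsorized mean-heteroplasmy vector.

    Non-positive entries cannot be log-transformed; they are returned as NaN
    and their count reported.  Returns (ln values, n_excluded).
    """
    v = np.asarray(mean_mthz_values, dtype=float).copy()
    nonpos = ~np.isnan(v) & (v <= 0)
    v[nonpos] = np.nan
    w = winsorize_upper(v, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(w)
    return out, int(nonpos.sum())


@dataclass(frozen=True)
class SnpSelectionCriteria:
    maf_min: float = 0.1        # inclusive
    callrate_min: float = 0.9998  # strict
    per_chrom: int = 10


def select_autosomal_snps(manifest: pd.DataFrame, panel: IntensityPanel,
                          criteria: SnpSelectionCriteria | None = None,
                          seed: int = 0) -> list[str]:
    """Randomly sample ``per_chrom`` eligible SNPs per autosome, seeded.

    Eligibility: MAF >= maf_min (from genotype calls) and call rate >
    callrate_min.  Raises ValueError naming any autosome with too few
    eligible SNPs.  22 autosomes at the default 10 per chromosome give the
    standard 220-SNP panel.
    """
    criteria = criteria or SnpSelectionCriteria()
    autosomes = [str(c) for c in range(1, 23)]
    auto = manifest[manifest["chrom"].astype(str).isin(autosomes)]
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for chrom in autosomes:
        ids = auto.loc[auto["chrom"].astype(str) == chrom, "variant_id"]
        ids = [v for v in ids if v in panel.calls.columns]
        if not ids:
            continue
        eligible = []
        for vid in ids:
            calls = panel.calls[vid]
            obs = calls.dropna()
            call_rate = len(obs) / len(calls)
            if call_rate <= criteria.callrate_min or len(obs) == 0:
                continue
            counts = obs.value_counts()
            p = (2 * counts.get("BB", 0) + counts.get("AB", 0)) / (2 * len(obs))
            if min(p, 1 - p) >= criteria.maf_min:
                eligible.append(vid)
        if len(eligible) < criteria.per_chrom:
            raise ValueError(
                f"chromosome {chrom}: only {len(eligible)} eligible autosomal "
                f"SNPs, need {criteria.per_chrom}")
        pick = rng.choice(len(eligible), size=criteria.per_chrom, replace=False)
        selected.extend(eligible[i] for i in sorted(pick))
    return selected


def autosomal_variance(panel: IntensityPanel, snp_ids,
                       squared: bool = False) -> pd.Series:
    """Mean BAF deviation from the expected 0/1 at homozygous calls.

    For each sample, averages |BAF - expected| (expected 0 for AA, 1 for BB)
    across the selected SNPs at which it has a homozygous call; heterozygous
    and missing calls are excluded.  ``squared=True`` averages squared
    deviations instead.  Samples with no homozygous call get NaN.
    """
    calls = panel.calls[list(snp_ids)].to_numpy()
    baf = panel.baf[list(snp_ids)].to_numpy(dtype=float)
    expected = np.where(calls == "AA", 0.0, np.where(calls == "BB", 1.0, np.nan))
    dev = np.abs(baf - expected)
    if squared:
        dev = dev ** 2
    n_hom = (~np.isnan(dev)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.nansum(dev, axis=1) / n_hom
    out[n_hom == 0] = np.nan
    return pd.Series(out, index=panel.samples, name="autosomal_variance")


def mt_copy_number(panel: IntensityPanel, kept_mt_variants) -> pd.Series:
    """Relative mtDNA copy number: mean LRR over kept mtDNA positions.

    Assumes low-intensity outlier calls were already blanked by the QC
    cascade; samples with no surviving LRR value get NaN.
    """
    lrr = panel.lrr[list(kept_mt_variants)].to_numpy(dtype=float)
    n = (~np.isnan(lrr)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.nansum(lrr, axis=1) / n
    out[n == 0] = np.nan
    return pd.Series(out, index=panel.samples, name="mt_copy_number")


def build_phenotypes(panel: IntensityPanel, manifest: pd.DataFrame,
                     kept_mt_variants, winsor_q: float = 0.995,
                     snp_criteria: SnpSelectionCriteria | None = None,
                     seed: int = 0,
                     squared_deviation: bool = False) -> pd.DataFrame:
    """Assemble the per-sample phenotype table.

    Columns: mean_mthz, ln_mean_mthz_w, autosomal_variance,
    ln_autosomal_variance, mt_copy_number, n_positions_used.
    """
    pheno = mean_mthz(panel, kept_mt_variants)
    pheno["ln_mean_mthz_w"], _ = ln_phenotype(pheno["mean_mthz"].to_numpy(), winsor_q)
    snps = select_autosomal_snps(manifest, panel, snp_criteria, seed=seed)
    av = autosomal_variance(panel, snps, squared=squared_deviation)
    pheno["autosomal_variance"] = av
    pheno["ln_autosomal_variance"] = np.log(av + AUTOSOMAL_VARIANCE_OFFSET)
    pheno["mt_copy_number"] = mt_copy_number(panel, kept_mt_variants)
    return pheno
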