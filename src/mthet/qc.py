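"""mtDNA variant and sample QC cascade for array intensity panels.

The cascade mirrors standard practice for quantifying heteroplasmy from
genotyping arrays.  Variants are first pruned on minor-allele frequency,
biallelism and call rate; each surviving variant is then split into low/high
BAF groups (low = BAF <= 0.5, accounting for the arbitrary labelling of the
two alleles); within groups, low-intensity calls are removed at three pooled
SDs below the group LRR mean and variants failing that filter in >= 1% of
either group are dropped; poorly clustering probes (excess apparent
heteroplasmy in >= 10% of a group, minimum 10 samples) are dropped; variants
in the hypervariable control-region segments are dropped; finally samples
missing more than 5% of the surviving variants are removed.

Every removal is recorded with its reason in a :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MT_CHROM, MT_LENGTH, IntensityPanel

__all__ = ["QCParams", "QCReport", "prune_mt_variants", "split_baf_groups",
           "lrr_low_intensity_filter", "cluster_quality_filter",
           "hypervariable_filter", "sample_missingness_filter",
           "run_mt_qc", "apply_qc"]

#: Hypervariable control-region segments (1-based inclusive, rCRS).
HYPERVARIABLE_RANGES = [(57, 372), (438, 574), (16024, 16383)]


@dataclass(frozen=True)
class QCParams:
    maf_min: float = 0.001
    variant_callrate_min: float = 0.99
    lrr_sd_multiplier: float = 3.0
    lrr_variant_fail_max: float = 0.01
    hz_threshold: float = 0.20
    hz_sample_fraction: float = 0.10
    min_group_size: int = 10
    hypervariable_ranges: tuple = tuple(HYPERVARIABLE_RANGES)
    sample_missing_max: float = 0.05

    def __post_init__(self):
        for name in ("maf_min", "variant_callrate_min", "lrr_variant_fail_max",
                     "hz_sample_fraction", "sample_missing_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for s, e in self.hypervariable_ranges:
            if not (1 <= s <= e <= MT_LENGTH):
                raise ValueError(f"hypervariable range {(s, e)} outside [1,{MT_LENGTH}]")


@dataclass
class QCReport:
    """Machine-readable account of every QC removal."""

    removed_variants: list = field(default_factory=list)   # (variant_id, reason)
    removed_samples: list = field(default_factory=list)    # (sample_id, reason)
    per_variant_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_call_removals: list = field(default_factory=list)  # (sample_id, variant_id)
    log: list = field(default_factory=list)

    def removal_reasons(self) -> dict:
        return dict(self.removed_variants)


def _b_allele_freq(calls: pd.Series) -> tuple[float, float]:
    """(minor allele frequency, call rate) from AA/AB/BB genotype calls."""
    obs = calls.dropna()
    call_rate = len(obs) / len(calls) if len(calls) else 0.0
    if len(obs) == 0:
        return 0.0, call_rate
    counts = obs.value_counts()
    n_b = 2 * counts.get("BB", 0) + counts.get("AB", 0)
    p = n_b / (2 * len(obs))
    return min(p, 1 - p), call_rate


def prune_mt_variants(panel: IntensityPanel, manifest: pd.DataFrame,
                      params: QCParams):
    """Keep biallelic mtDNA variants with MAF and call rate above threshold.

    Both inequalities are strict (MAF > maf_min, call rate >
    variant_callrate_min); MAF is computed from genotype calls.  Returns
    (kept variant ids, removals as (id, reason) list, stats DataFrame).
    """
    mt = manifest[manifest["chrom"].astype(str) == MT_CHROM]
    mt = mt[mt["variant_id"].isin(panel.calls.columns)]
    kept, removed, stats = [], [], []
    for _, row in mt.iterrows():
        vid = row["variant_id"]
        biallelic = (
            isinstance(row["allele_A"], str) and isinstance(row["allele_B"], str)
            and len(row["allele_A"]) == 1 and len(row["allele_B"]) == 1
            and row["allele_A"] != row["allele_B"]
        )
        maf, call_rate = _b_allele_freq(panel.calls[vid])
        stats.append({"variant_id": vid, "maf": maf, "call_rate": call_rate})
        if not biallelic:
            removed.append((vid, "multiallelic"))
        elif call_rate <= params.variant_callrate_min:
            removed.append((vid, "callrate"))
        elif maf <= params.maf_min:
            removed.append((vid, "maf"))
        else:
            kept.append(vid)
    return kept, removed, pd.DataFrame(stats).set_index("variant_id")


def split_baf_groups(baf: pd.Series):
    """Split samples into low (BAF <= 0.5) and high (BAF > 0.5) groups.

    Missing BAF belongs to neither group.
    """
    obs = baf.dropna()
    low = obs.index[obs <= 0.5]
    high = obs.index[obs > 0.5]
    return low, high


def _pooled_sd(groups: list[np.ndarray]) -> float:
    """Pooled SD over groups; groups with <2 values contribute nothing."""
    num = 0.0
    dof = 0
    for g in groups:
        g = g[~np.isnan(g)]
        if g.size >= 2:
            num += (g.size - 1) * g.var(ddof=1)
            dof += g.size - 1
    if dof == 0:
        return np.nan
    return float(np.sqrt(num / dof))


def lrr_low_intensity_filter(panel: IntensityPanel, variant: str,
                             params: QCParams, max_rounds: int = 10):
    """Remove low-intensity calls at a variant; flag the variant if too many fail.

    Within each BAF group a call is removed when its LRR lies strictly below
    the group mean minus ``lrr_sd_multiplier`` pooled SDs (SD pooled across
    both groups).  The trim is iterated on the surviving calls until no
    further call falls below the recomputed threshold (cap ``max_rounds``),
    so the filter output is a fixed point and the QC cascade is idempotent.
    The variant fails when the cumulative removed fraction reaches
    ``lrr_variant_fail_max`` in either group.  Returns
    (removed sample ids, variant_failed, stats dict); the reported group
    means and pooled SD are the first-round statistics.
    """
    low, high = split_baf_groups(panel.baf[variant])
    lrr = panel.lrr[variant]
    g_low = lrr.loc[low].to_numpy(dtype=float).copy()
    g_high = lrr.loc[high].to_numpy(dtype=float).copy()
    sp0 = _pooled_sd([g_low, g_high])
    stats = {
        "lrr_mean_low": float(np.nanmean(g_low)) if np.isfinite(g_low).any() else np.nan,
        "lrr_mean_high": float(np.nanmean(g_high)) if np.isfinite(g_high).any() else np.nan,
        "lrr_pooled_sd": sp0,
    }
    if not np.isfinite(sp0):
        # both groups degenerate: nothing to calibrate the threshold on
        return [], False, {**stats, "skipped": True}
    n0 = {id(low): max(int(np.isfinite(g_low).sum()), 1),
          id(high): max(int(np.isfinite(g_high).sum()), 1)}
    removed: list = []
    n_removed = {id(low): 0, id(high): 0}
    for _ in range(max_rounds):
        sp = _pooled_sd([g_low, g_high])
        if not np.isfinite(sp):
            break
        any_hit = False
        for idx, g in ((low, g_low), (high, g_high)):
            finite = ~np.isnan(g)
            if not finite.any():
                continue
            cut = g[finite].mean() - params.lrr_sd_multiplier * sp
            hit = finite & (g < cut)
            if hit.any():
                any_hit = True
                removed.extend(idx[hit])
                n_removed[id(idx)] += int(hit.sum())
                g[hit] = np.nan
        if not any_hit:
            break
    failed = any(n_removed[k] / n0[k] >= params.lrr_variant_fail_max
                 for k in n_removed)
    return removed, failed, stats


def cluster_quality_filter(panel: IntensityPanel, variant: str,
                           params: QCParams):
    """Flag a variant whose homoplasmic clusters are poorly separated.

    Within either BAF group, if at least ``min_group_size`` samples AND at
    least ``hz_sample_fraction`` of the group show apparent heteroplasmy
    >= ``hz_threshold``, the probe cannot discriminate the alleles and the
    variant is removed.  Returns (removed flag, stats dict).
    """
    low, high = split_baf_groups(panel.baf[variant])
    stats = {}
    removed = False
    for label, idx in (("low", low), ("high", high)):
        vals = panel.baf.loc[idx, variant].to_numpy(dtype=float)
        hz = np.minimum(vals, 1 - vals)
        n_hz = int((hz >= params.hz_threshold).sum())
        frac = n_hz / vals.size if vals.size else 0.0
        stats[f"hz_frac_{label}"] = frac
        if vals.size and n_hz >= params.min_group_size and frac >= params.hz_sample_fraction:
            removed = True
    return removed, stats


def hypervariable_filter(manifest: pd.DataFrame, params: QCParams,
                         variants=None) -> list[str]:
    """Drop mtDNA variants inside any hypervariable range (inclusive ends)."""
    mt = manifest[manifest["chrom"].astype(str) == MT_CHROM]
    if variants is not None:
        mt = mt[mt["variant_id"].isin(set(variants))]
    kept = []
    for vid, pos in zip(mt["variant_id"], mt["pos"]):
        inside = any(s <= pos <= e for s, e in params.hypervariable_ranges)
        if not inside:
            kept.append(vid)
    return kept


def sample_missingness_filter(panel: IntensityPanel, params: QCParams,
                              variants=None) -> list:
    """Keep samples missing at most ``sample_missing_max`` of the kept variants.

    Strictly-greater missingness removes the sample; call removals applied by
    earlier filters count as missing.
    """
    cols = panel.baf.columns if variants is None else list(variants)
    frac = panel.baf[cols].isna().mean(axis=1)
    return list(panel.samples[frac.to_numpy() <= params.sample_missing_max])


def _qc_pass(work: IntensityPanel, manifest: pd.DataFrame, params: QCParams,
             report: QCReport):
    """One cascade pass over the working panel; mutates ``work`` and ``report``.

    Returns (kept_variants, kept_samples, per-variant stats DataFrame).
    """
    kept, removed, stats = prune_mt_variants(work, manifest, params)
    report.removed_variants.extend(removed)
    report.log.append(
        f"prune: kept {len(kept)} of {len(kept) + len(removed)} mtDNA variants")

    extra_stats = {}
    still = []
    n_calls = 0
    for vid in kept:
        removed_calls, failed, vstats = lrr_low_intensity_filter(work, vid, params)
        extra_stats[vid] = vstats
        n_calls += len(removed_calls)
        for sid in removed_calls:
            report.per_call_removals.append((sid, vid))
            work.baf.loc[sid, vid] = np.nan
            work.lrr.loc[sid, vid] = np.nan
            work.calls.loc[sid, vid] = None
        if failed:
            report.removed_variants.append((vid, "lrr_fail"))
        else:
            still.append(vid)
    report.log.append(f"lrr filter: removed {n_calls} calls, "
                      f"{len(kept) - len(still)} variants failed")
    kept = still

    still = []
    for vid in kept:
        removed_flag, vstats = cluster_quality_filter(work, vid, params)
        extra_stats[vid].update(vstats)
        if removed_flag:
            report.removed_variants.append((vid, "poor_cluster"))
        else:
            still.append(vid)
    report.log.append(f"cluster filter: {len(kept) - len(still)} variants removed")
    kept = still

    still = hypervariable_filter(manifest, params, variants=kept)
    gone = set(kept) - set(still)
    report.removed_variants.extend((vid, "hypervariable") for vid in kept
                                   if vid in gone)
    report.log.append(f"hypervariable filter: {len(gone)} variants removed")
    kept = still

    kept_samples = sample_missingness_filter(work, params, variants=kept) \
        if kept else []
    dropped = set(work.samples) - set(kept_samples)
    report.removed_samples.extend((sid, "missingness") for sid in sorted(dropped))
    report.log.append(f"sample filter: {len(dropped)} samples removed")
    return kept, kept_samples, stats.join(
        pd.DataFrame.from_dict(extra_stats, orient="index"))


def run_mt_qc(panel: IntensityPanel, manifest: pd.DataFrame,
              params: QCParams | None = None, max_passes: int = 5):
    """Run the full mtDNA QC cascade to a fixed point.

    Each pass applies, in order: MAF/biallelic/call-rate prune -> per-variant
    BAF split -> LRR low-intensity filter -> cluster-quality filter ->
    hypervariable-region filter -> sample missingness.  Removing samples or
    calls shifts the per-variant statistics, so the pass is repeated on the
    surviving panel until a pass removes nothing new (almost always two or
    three passes).  The converged state is a fixed point of the pass, which
    makes the cascade exactly idempotent in kept variants and samples.
    Returns (kept_variants, kept_samples, QCReport); the per-variant stats
    are those of the first pass over the full input.  Raises ValueError if
    no variant survives.
    """
    params = params or QCParams()
    report = QCReport()

    mt_all = set(manifest.loc[manifest["chrom"].astype(str) == MT_CHROM,
                              "variant_id"])
    work = panel.subset()
    first_stats: pd.DataFrame | None = None
    kept: list = []
    kept_samples: list = []
    for i in range(max_passes):
        before = (len(report.removed_variants), len(report.removed_samples),
                  len(report.per_call_removals))
        kept, kept_samples, stats = _qc_pass(work, manifest, params, report)
        if first_stats is None:
            first_stats = stats
        if not kept:
            raise ValueError("mtDNA QC removed every variant")
        after = (len(report.removed_variants), len(report.removed_samples),
                 len(report.per_call_removals))
        if after == before:
            break
        cols = [v for v in work.variants if v not in mt_all or v in set(kept)]
        work = work.subset(samples=kept_samples, variants=cols)
        report.log.append(f"pass {i + 1} complete; re-checking survivors")

    report.per_variant_stats = first_stats
    return kept, kept_samples, report


def apply_qc(panel: IntensityPanel, kept_variants, kept_samples,
             report: QCReport, keep_other_variants: bool = True) -> IntensityPanel:
    """Materialise QC results: subset the panel and blank removed calls.

    Non-mtDNA variants are carried through untouched when
    ``keep_other_variants`` is set.
    """
    if keep_other_variants:
        mt_all = {v for v in panel.variants if v.startswith("mt")}
        cols = [v for v in panel.variants
                if v in set(kept_variants) or v not in mt_all]
    else:
        cols = list(kept_variants)
    out = panel.subset(samples=kept_samples, variants=cols)
    for sid, vid in report.per_call_removals:
        if sid in out.baf.index and vid in out.baf.columns:
            out.baf.loc[sid, vid] = np.nan
            out.lrr.loc[sid, vid] = np.nan
            out.calls.loc[sid, vid] = None
    return out
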