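"""Elimination of spurious associations driven by nuclear mtDNA segments.

NUMTs — nuclear insertions of mitochondrial sequence — cross-hybridize with
ostensibly mitochondrial probes and inflate apparent heteroplasmy in
carriers, but only at positions inside the insertion's homology interval.
Because insertions are in LD with nearby nuclear SNPs, they manufacture
false nuclear associations with the mean-heteroplasmy phenotype.  Two
complementary guards are implemented:

* interval masking — recompute the phenotype excluding the annotated
  homology interval and re-test the lead variant; a true NUMT artifact loses
  genome-wide significance;
* subregion scan — partition the assayed positions into k (default 3)
  contiguous groups of near-equal size, recompute the phenotype per group
  and re-test; an artifact is driven by the group(s) containing the NUMT
  while a genuine trans-acting locus affects every group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GENOME_WIDE_P, ModelSpec, gwas
from .containers import MT_CHROM, MT_LENGTH, IntensityPanel
from .phenotype import ln_phenotype, mean_mthz

__all__ = ["NumtAnnotation", "masked_phenotype", "numt_retest",
           "subregion_partition", "subregion_scan"]


@dataclass(frozen=True)
class NumtAnnotation:
    """A known NUMT: mtDNA homology interval paired with its nuclear locus."""

    name: str
    mt_interval: tuple[int, int]   # 1-based inclusive on the mtDNA circle
    nuclear_chrom: str
    nuclear_pos: int
    identity_fraction: float | None = None

    def __post_init__(self):
        s, e = self.mt_interval
        if not (1 <= s <= e <= MT_LENGTH):
            raise ValueError(f"mt_interval {self.mt_interval} outside [1, {MT_LENGTH}]")


def _positions(manifest: pd.DataFrame, variants) -> pd.Series:
    mt = manifest[manifest["chrom"].astype(str) == MT_CHROM]
    pos = mt.set_index("variant_id")["pos"]
    return pos.loc[list(variants)]


def masked_phenotype(panel: IntensityPanel, kept_mt_variants,
                     interval: tuple[int, int], manifest: pd.DataFrame,
                     winsor_q: float = 0.995) -> pd.DataFrame:
    """Mean heteroplasmy excluding positions inside ``interval`` (inclusive).

    Winsorization and the log transform are reapplied on the reduced
    position set.  Raises ValueError if masking removes every position.
    """
    pos = _positions(manifest, kept_mt_variants)
    s, e = interval
    keep = pos.index[(pos < s) | (pos > e)].tolist()
    if not keep:
        raise ValueError(f"masking interval {interval} removes every kept position")
    out = mean_mthz(panel, keep)
    out["ln_mean_mthz_w"], _ = ln_phenotype(out["mean_mthz"].to_numpy(), winsor_q)
    return out


def _retest_p(lead: str, response: pd.Series, dosages: pd.DataFrame,
              phenotypes: pd.DataFrame, spec: ModelSpec) -> float:
    pheno = phenotypes.copy()
    pheno[spec.response] = response
    res = gwas(dosages[[lead]], pheno, spec).table
    return float(res["p_lrt"].iloc[0])


def numt_retest(lead: str, annotation: NumtAnnotation, panel: IntensityPanel,
                kept_mt_variants, manifest: pd.DataFrame,
                phenotypes: pd.DataFrame, dosages: pd.DataFrame,
                spec: ModelSpec | None = None,
                threshold: float = GENOME_WIDE_P,
                baseline_p: float | None = None,
                winsor_q: float = 0.995) -> dict:
    """Re-test a lead variant against the interval-masked phenotype.

    Verdict ``numt_masked`` when the baseline association is genome-wide
    significant but the masked one is not; otherwise ``clean``.
    """
    spec = spec or ModelSpec()
    if baseline_p is None:
        baseline_p = _retest_p(lead, phenotypes[spec.response], dosages,
                               phenotypes, spec)
    masked = masked_phenotype(panel, kept_mt_variants, annotation.mt_interval,
                              manifest, winsor_q)
    masked_p = _retest_p(lead, masked["ln_mean_mthz_w"], dosages, phenotypes, spec)
    verdict = ("numt_masked"
               if baseline_p <= threshold and masked_p > threshold else "clean")
    return {"lead": lead, "numt": annotation.name, "baseline_p": baseline_p,
            "masked_p": masked_p, "verdict": verdict}


def subregion_partition(kept_mt_variants, manifest: pd.DataFrame,
                        k: int = 3) -> list[list[str]]:
    """Split kept positions into k contiguous coordinate groups.

    Positions are sorted by mtDNA coordinate and divided into k groups whose
    sizes differ by at most one (326 positions -> 109/109/108).
    """
    pos = _positions(manifest, kept_mt_variants).sort_values()
    if len(pos) < k:
        raise ValueError(f"need at least {k} positions, have {len(pos)}")
    return [list(chunk) for chunk in np.array_split(pos.index.to_numpy(), k)]


def subregion_scan(lead_ids, panel: IntensityPanel, kept_mt_variants,
                   manifest: pd.DataFrame, phenotypes: pd.DataFrame,
                   dosages: pd.DataFrame, spec: ModelSpec | None = None,
                   k: int = 3, threshold: float = GENOME_WIDE_P,
                   literal_rule: bool = False,
                   winsor_q: float = 0.995) -> pd.DataFrame:
    """Re-test lead variants against per-subregion phenotypes.

    Default (heterogeneity) rule: ``region_dependent`` when at least one
    subregion loses genome-wide significance while at least one other
    retains it.  The literal rule flags any lead with at least one
    non-significant subregion; it also removes genuine loci that merely lose
    power on a third of the positions, so it is opt-in.  Leads whose
    baseline p exceeds the threshold are excluded from the scan.
    """
    spec = spec or ModelSpec()
    groups = subregion_partition(kept_mt_variants, manifest, k)
    sub_resp = []
    for g in groups:
        sub = mean_mthz(panel, g)
        resp, _ = ln_phenotype(sub["mean_mthz"].to_numpy(), winsor_q)
        sub_resp.append(pd.Series(resp, index=sub.index))

    rows = []
    for lead in lead_ids:
        baseline_p = _retest_p(lead, phenotypes[spec.response], dosages,
                               phenotypes, spec)
        if baseline_p > threshold:
            continue
        sub_p = [_retest_p(lead, r, dosages, phenotypes, spec) for r in sub_resp]
        lost = [p > threshold for p in sub_p]
        if literal_rule:
            dependent = any(lost)
        else:
            dependent = any(lost) and not all(lost)
        rows.append({
            "lead": lead, "baseline_p": baseline_p,
            **{f"subregion_{i + 1}_p": p for i, p in enumerate(sub_p)},
            "verdict": "region_dependent" if dependent else "clean",
        })
    return pd.DataFrame(rows)
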