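"""In-memory containers for array-intensity cohorts.

An :class:`IntensityPanel` holds the three sample × variant matrices a
genotyping array produces per probe — B-allele frequency (BAF), log2 R ratio
(LRR) and the discrete genotype call — plus, for nuclear test variants,
an allele-dosage matrix (fractional for imputed variants).  The variant
manifest and sample table are plain pandas DataFrames with documented
columns; all coordinates are 1-based inclusive (rCRS for mtDNA, GRCh37-style
for nuclear positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: rCRS mitochondrial genome length (bp).
MT_LENGTH = 16569

#: Chromosome label used for mitochondrial variants throughout.
MT_CHROM = "MT"

MANIFEST_COLUMNS = ["variant_id", "chrom", "pos", "allele_A", "allele_B", "source"]
SAMPLE_COLUMNS = ["sample_id", "age", "sex", "haplogroup", "mother_id",
                  "pc1", "pc2", "pc3", "pc4", "pc5"]

GENOTYPE_CODES = ("AA", "AB", "BB")


@dataclass
class IntensityPanel:
    """Sample × variant intensity matrices.

    Attributes
    ----------
    baf, lrr : DataFrame
        Float matrices indexed by sample_id with variant_id columns; NaN
        marks a missing (or QC-removed) call.
    calls : DataFrame
        Genotype calls as ``"AA"``/``"AB"``/``"BB"`` strings, NaN = no-call.
    dosage : DataFrame
        B-allele dosage in [0, 2] for nuclear test variants only (a column
        subset of the manifest); fractional values for imputed variants.
    """

    baf: pd.DataFrame
    lrr: pd.DataFrame
    calls: pd.DataFrame
    dosage: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> pd.Index:
        return self.baf.index

    @property
    def variants(self) -> pd.Index:
        return self.baf.columns

    def validate(self) -> None:
        """Check index alignment and value ranges; raise ValueError on defect."""
        for name, frame in (("lrr", self.lrr), ("calls", self.calls)):
            if not frame.index.equals(self.baf.index):
                raise ValueError(f"{name} rows do not match baf rows")
            if not frame.columns.equals(self.baf.columns):
                raise ValueError(f"{name} columns do not match baf columns")
        if self.baf.index.has_duplicates:
            dups = self.baf.index[self.baf.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.baf.columns.has_duplicates:
            dups = self.baf.columns[self.baf.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        vals = self.baf.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"BAF outside [0,1] at sample {self.baf.index[i]!r}, "
                f"variant {self.baf.columns[j]!r}: {vals[i, j]}"
            )
        if not self.dosage.empty:
            if not self.dosage.index.equals(self.baf.index):
                raise ValueError("dosage rows do not match baf rows")
            d = self.dosage.to_numpy(dtype=float)
            bad = (d < 0) | (d > 2)
            if np.any(bad & ~np.isnan(d)):
                i, j = np.argwhere(bad & ~np.isnan(d))[0]
                raise ValueError(
                    f"dosage outside [0,2] at sample {self.dosage.index[i]!r}, "
                    f"variant {self.dosage.columns[j]!r}: {d[i, j]}"
                )

    def subset(self, samples=None, variants=None) -> "IntensityPanel":
        """Return a panel restricted to the given samples and/or variants."""
        idx = self.baf.index if samples is None else pd.Index(samples)
        cols = self.baf.columns if variants is None else pd.Index(variants)
        dos_cols = self.dosage.columns.intersection(cols) if not self.dosage.empty else []
        return IntensityPanel(
            baf=self.baf.loc[idx, cols].copy(),
            lrr=self.lrr.loc[idx, cols].copy(),
            calls=self.calls.loc[idx, cols].copy(),
            dosage=self.dosage.loc[idx, dos_cols].copy() if not self.dosage.empty
            else pd.DataFrame(index=idx),
        )


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest["variant_id"].duplicated().any():
        dups = manifest.loc[manifest["variant_id"].duplicated(), "variant_id"]
        raise ValueError(f"duplicate variant_id in manifest: {dups.iloc[0]!r}")
    bad = ~manifest["source"].isin(["genotyped", "imputed"])
    if bad.any():
        row = manifest.index[bad][0]
        raise ValueError(f"manifest row {row}: source must be genotyped/imputed")
    mt = manifest["chrom"].astype(str) == MT_CHROM
    pos = manifest.loc[mt, "pos"]
    if ((pos < 1) | (pos > MT_LENGTH)).any():
        raise ValueError(f"mtDNA position outside [1, {MT_LENGTH}]")


def mt_variant_ids(manifest: pd.DataFrame) -> list[str]:
    """Variant ids on the mitochondrial genome, in manifest order."""
    return manifest.loc[manifest["chrom"].astype(str) == MT_CHROM, "variant_id"].tolist()
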