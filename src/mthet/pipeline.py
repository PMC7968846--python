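"""File formats, run configuration and the end-to-end pipeline.

All tables are tab-separated text with a header line and stable column
order; matrices (BAF, LRR, calls, dosage) are wide, rows = samples.
Coordinates are 1-based inclusive everywhere, including the NUMT annotation
table (documented deliberately, since BED files are 0-based half-open).
Missing values are empty fields.

Stages communicate exclusively through files under ``out_dir``, so the CLI
subcommands (simulate, qc, phenotype, gwas, numt-scan, duos) compose to
exactly the same artifacts as :func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, duos as duos_mod, numt as numt_mod, phenotype as pheno_mod, qc as qc_mod
from .containers import IntensityPanel, validate_manifest
from .simulate import NumtSpec, SimConfig, simulate_cohort

__all__ = ["RunConfig", "read_panel", "read_long_panel", "write_cohort",
           "read_numt_annotations", "run_pipeline",
           "stage_simulate", "stage_qc", "stage_phenotype", "stage_gwas",
           "stage_numt", "stage_duos"]

log = logging.getLogger("mthet")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Settings for a full pipeline run (YAML-serialisable)."""

    seed: int = 0
    out_dir: str = "mthet_out"
    simulate: dict | None = None          # SimConfig overrides; None = use inputs
    inputs: dict | None = None            # paths: manifest, samples, baf, lrr, calls, dosage
    qc: dict = field(default_factory=dict)          # QCParams overrides
    model: dict = field(default_factory=dict)       # ModelSpec overrides
    snp_criteria: dict = field(default_factory=dict)
    numt_annotations: list = field(default_factory=list)  # dicts or a TSV path
    threshold: float = association.GENOME_WIDE_P
    subregions: int = 3
    winsor_q: float = 0.995
    literal_subregion_rule: bool = False
    duo_hz_min: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate or {})
        numts = kwargs.pop("numts", None)
        if numts is not None:
            kwargs["numts"] = [NumtSpec(**{**n, "mt_interval": tuple(n["mt_interval"])})
                               if isinstance(n, dict) else n for n in numts]
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def qc_params(self) -> qc_mod.QCParams:
        kwargs = dict(self.qc)
        if "hypervariable_ranges" in kwargs:
            kwargs["hypervariable_ranges"] = tuple(
                tuple(r) for r in kwargs["hypervariable_ranges"])
        return qc_mod.QCParams(**kwargs)

    def model_spec(self) -> association.ModelSpec:
        kwargs = dict(self.model)
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return association.ModelSpec(**kwargs)

    def annotations(self) -> list[numt_mod.NumtAnnotation]:
        if isinstance(self.numt_annotations, (str, Path)):
            return read_numt_annotations(self.numt_annotations)
        return [numt_mod.NumtAnnotation(
            name=a["name"], mt_interval=tuple(a["mt_interval"]),
            nuclear_chrom=str(a["nuclear_chrom"]), nuclear_pos=int(a["nuclear_pos"]),
            identity_fraction=a.get("identity_fraction"))
            for a in self.numt_annotations]


# ---------------------------------------------------------------------------
# readers / writers


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="")


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def write_cohort(out_dir, manifest: pd.DataFrame, panel: IntensityPanel,
                 samples: pd.DataFrame, truth=None) -> None:
    """Write a cohort as the documented TSV bundle under ``out_dir``."""
    out = Path(out_dir)
    _write(manifest, out / "manifest.tsv")
    _write(samples, out / "samples.tsv")
    _write(panel.baf, out / "baf.tsv", index=True)
    _write(panel.lrr, out / "lrr.tsv", index=True)
    _write(panel.calls, out / "calls.tsv", index=True)
    _write(panel.dosage, out / "dosage.tsv", index=True)
    if truth is not None:
        _write(truth.true_heteroplasmy, out / "truth_heteroplasmy.tsv", index=True)
        _write(truth.numt_copies, out / "truth_numt_copies.tsv", index=True)
        _write(truth.per_sample_noise.to_frame(), out / "truth_noise.tsv", index=True)
        _write(pd.DataFrame(truth.causal_betas, columns=["variant_id", "beta"]),
               out / "truth_causal.tsv")
        _write(pd.DataFrame(truth.duo_pairs, columns=["mother_id", "offspring_id"]),
               out / "truth_duos.tsv")


def read_panel(cohort_dir):
    """Read a cohort TSV bundle; validates ids, ranges and alignment.

    Returns (manifest, panel, samples).
    """
    d = Path(cohort_dir)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t",
                           dtype={"chrom": str, "variant_id": str})
    validate_manifest(manifest)
    samples = pd.read_csv(d / "samples.tsv", sep="\t",
                          dtype={"sample_id": str, "mother_id": str, "sex": str})
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    bad_sex = ~samples["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(
            f"samples row {samples.index[bad_sex][0]}: sex must be male/female")
    dosage_path = d / "dosage.tsv"
    panel = IntensityPanel(
        baf=_read_matrix(d / "baf.tsv"),
        lrr=_read_matrix(d / "lrr.tsv"),
        calls=_read_matrix(d / "calls.tsv"),
        dosage=_read_matrix(dosage_path) if dosage_path.exists() else pd.DataFrame(),
    )
    panel.validate()
    missing = set(panel.variants) - set(manifest["variant_id"])
    if missing:
        raise ValueError(f"panel variants absent from manifest: {sorted(missing)[:5]}")
    return manifest, panel, samples


def read_long_panel(path) -> IntensityPanel:
    """Read a long-format per-call TSV (sample_id, variant_id, baf, lrr, call)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_id": str})
    need = {"sample_id", "variant_id", "baf", "lrr", "call"}
    if not need.issubset(df.columns):
        raise ValueError(f"long panel needs columns {sorted(need)}")
    if df.duplicated(["sample_id", "variant_id"]).any():
        raise ValueError("duplicate (sample_id, variant_id) entries")
    panel = IntensityPanel(
        baf=df.pivot(index="sample_id", columns="variant_id", values="baf"),
        lrr=df.pivot(index="sample_id", columns="variant_id", values="lrr"),
        calls=df.pivot(index="sample_id", columns="variant_id", values="call"),
    )
    panel.validate()
    return panel


NUMT_COLUMNS = ["name", "mt_start", "mt_end", "nuclear_chrom", "nuclear_pos",
                "identity"]


def read_numt_annotations(path) -> list[numt_mod.NumtAnnotation]:
    """Read the BED-like NUMT table (1-based inclusive mtDNA intervals)."""
    df = pd.read_csv(path, sep="\t", dtype={"nuclear_chrom": str})
    missing = [c for c in NUMT_COLUMNS if c not in df.columns and c != "identity"]
    if missing:
        raise ValueError(f"NUMT annotation file missing columns: {missing}")
    return [numt_mod.NumtAnnotation(
        name=str(r["name"]), mt_interval=(int(r["mt_start"]), int(r["mt_end"])),
        nuclear_chrom=str(r["nuclear_chrom"]), nuclear_pos=int(r["nuclear_pos"]),
        identity_fraction=float(r["identity"]) if "identity" in df.columns
        and pd.notna(r.get("identity")) else None)
        for _, r in df.iterrows()]


def write_numt_annotations(annotations, path) -> None:
    df = pd.DataFrame([{
        "name": a.name, "mt_start": a.mt_interval[0], "mt_end": a.mt_interval[1],
        "nuclear_chrom": a.nuclear_chrom, "nuclear_pos": a.nuclear_pos,
        "identity": a.identity_fraction,
    } for a in annotations], columns=NUMT_COLUMNS)
    _write(df, Path(path))


# ---------------------------------------------------------------------------
# pipeline stages (file-to-file)


def _cohort_dir(cfg: RunConfig) -> Path:
    if cfg.simulate is not None or cfg.inputs is None:
        return Path(cfg.out_dir) / "cohort"
    return Path(cfg.inputs["cohort_dir"])


def stage_simulate(cfg: RunConfig) -> None:
    sim = cfg.sim_config()
    manifest, panel, samples, truth = simulate_cohort(sim)
    out = Path(cfg.out_dir) / "cohort"
    write_cohort(out, manifest, panel, samples, truth)
    # default NUMT annotations follow the simulated truth unless overridden
    if not cfg.numt_annotations:
        write_numt_annotations(
            [numt_mod.NumtAnnotation(s.name, s.mt_interval, str(s.nuclear_chrom),
                                     int(s.nuclear_pos)) for s in sim.numts],
            out / "numt_annotations.tsv")
    log.info("simulate: %d samples x %d variants", len(samples), len(manifest))


def _load_qc(cfg: RunConfig):
    d = Path(cfg.out_dir) / "qc"
    kept_variants = pd.read_csv(d / "kept_variants.tsv", sep="\t")["variant_id"].tolist()
    kept_samples = pd.read_csv(d / "kept_samples.tsv", sep="\t",
                               dtype=str)["sample_id"].tolist()
    removals = pd.read_csv(d / "per_call_removals.tsv", sep="\t", dtype=str)
    report = qc_mod.QCReport(
        per_call_removals=list(removals.itertuples(index=False, name=None)))
    return kept_variants, kept_samples, report


def stage_qc(cfg: RunConfig) -> None:
    manifest, panel, _ = read_panel(_cohort_dir(cfg))
    params = cfg.qc_params()
    kept, kept_samples, report = qc_mod.run_mt_qc(panel, manifest, params)
    d = Path(cfg.out_dir) / "qc"
    _write(pd.DataFrame({"variant_id": kept}), d / "kept_variants.tsv")
    _write(pd.DataFrame({"sample_id": kept_samples}), d / "kept_samples.tsv")
    removed = pd.DataFrame(report.removed_variants, columns=["id", "reason"])
    removed["kind"] = "variant"
    removed_s = pd.DataFrame(report.removed_samples, columns=["id", "reason"])
    removed_s["kind"] = "sample"
    _write(pd.concat([removed, removed_s], ignore_index=True), d / "removed.tsv")
    _write(pd.DataFrame(report.per_call_removals,
                        columns=["sample_id", "variant_id"]),
           d / "per_call_removals.tsv")
    _write(report.per_variant_stats.reset_index(), d / "per_variant_stats.tsv")
    for line in report.log:
        log.info("qc: %s", line)


def stage_phenotype(cfg: RunConfig) -> None:
    manifest, panel, samples = read_panel(_cohort_dir(cfg))
    kept, kept_samples, report = _load_qc(cfg)
    clean = qc_mod.apply_qc(panel, kept, kept_samples, report)
    crit = pheno_mod.SnpSelectionCriteria(**cfg.snp_criteria) \
        if cfg.snp_criteria else None
    pheno = pheno_mod.build_phenotypes(clean, manifest, kept,
                                       winsor_q=cfg.winsor_q,
                                       snp_criteria=crit, seed=cfg.seed)
    pheno = pheno.join(samples.set_index("sample_id"))
    _write(pheno.reset_index().rename(columns={"index": "sample_id"}),
           Path(cfg.out_dir) / "phenotypes.tsv")
    log.info("phenotype: %d samples, %d positions used (median)",
             len(pheno), int(pheno["n_positions_used"].median()))


def _load_phenotypes(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(Path(cfg.out_dir) / "phenotypes.tsv", sep="\t",
                       index_col="sample_id",
                       dtype={"sex": str, "haplogroup": str, "mother_id": str})


def _nuclear_dosages(cfg: RunConfig, pheno_index) -> tuple[pd.DataFrame, pd.DataFrame]:
    manifest, panel, _ = read_panel(_cohort_dir(cfg))
    dos = panel.dosage.loc[pheno_index]
    return dos, manifest


def stage_gwas(cfg: RunConfig) -> None:
    pheno = _load_phenotypes(cfg)
    spec = cfg.model_spec()
    null_res = association.fit_null_model(pheno, spec)
    _write(null_res.coef_table().reset_index().rename(columns={"index": "term"}),
           Path(cfg.out_dir) / "null_model.tsv")

    dosages, manifest = _nuclear_dosages(cfg, pheno.index)
    res = association.gwas(dosages, pheno, spec, manifest)
    lam = res.apply_genomic_control()
    log.info("gwas: %d variants tested, lambda = %.4f",
             int(res.table["tested"].sum()), lam)

    tab = res.table.copy()
    tab["baf_freq"] = dosages.mean(axis=0).to_numpy() / 2.0
    cols = ["variant_id", "chrom", "pos", "allele_A", "allele_B", "baf_freq",
            "beta", "se", "p_lrt", "p_adjusted", "n", "tested"]
    tab = tab[cols].rename(columns={"tested": "tested_flag"})
    _write(tab, Path(cfg.out_dir) / "summary_stats.tsv")

    loci = res.clump(threshold=cfg.threshold)
    _write(loci.to_frame(), Path(cfg.out_dir) / "loci_initial.tsv")
    with open(Path(cfg.out_dir) / "gwas_meta.json", "w") as fh:
        json.dump({"lambda_gc": lam, "n": res.nobs}, fh)


def stage_numt(cfg: RunConfig) -> None:
    pheno = _load_phenotypes(cfg)
    spec = cfg.model_spec()
    manifest, panel, _ = read_panel(_cohort_dir(cfg))
    kept, kept_samples, report = _load_qc(cfg)
    clean = qc_mod.apply_qc(panel, kept, kept_samples, report)
    dosages = clean.dosage.loc[pheno.index]

    loci_path = Path(cfg.out_dir) / "loci_initial.tsv"
    loci = pd.read_csv(loci_path, sep="\t") if loci_path.stat().st_size else \
        pd.DataFrame(columns=["lead"])
    leads = loci["lead"].tolist() if "lead" in loci.columns else []

    annotations = cfg.annotations()
    if not annotations:
        default = _cohort_dir(cfg) / "numt_annotations.tsv"
        if default.exists():
            annotations = read_numt_annotations(default)

    reports = []
    lead_pos = manifest.set_index("variant_id")
    for lead in leads:
        for ann in annotations:
            # mask-retest only where the lead is plausibly LD-linked: same chromosome
            if str(lead_pos.loc[lead, "chrom"]) != str(ann.nuclear_chrom):
                continue
            reports.append(numt_mod.numt_retest(
                lead, ann, clean, kept, manifest, pheno, dosages, spec,
                threshold=cfg.threshold, winsor_q=cfg.winsor_q))
    retest = pd.DataFrame(reports, columns=["lead", "numt", "baseline_p",
                                            "masked_p", "verdict"])
    scan = numt_mod.subregion_scan(
        leads, clean, kept, manifest, pheno, dosages, spec,
        k=cfg.subregions, threshold=cfg.threshold,
        literal_rule=cfg.literal_subregion_rule, winsor_q=cfg.winsor_q)
    _write(retest, Path(cfg.out_dir) / "numt_retest.tsv")
    _write(scan, Path(cfg.out_dir) / "numt_scan.tsv")

    flagged = set(retest.loc[retest["verdict"] == "numt_masked", "lead"]) | \
        set(scan.loc[scan["verdict"] == "region_dependent", "lead"]
            if not scan.empty else [])
    log.info("numt: %d of %d leads flagged", len(flagged), len(leads))

    if not loci.empty:
        loci["numt_dependent"] = loci["lead"].isin(flagged)
        surviving = loci[~loci["numt_dependent"]].copy()
        # poorly supported loci: a single significant member that is imputed
        src = manifest.set_index("variant_id")["source"]
        surviving["single_imputed_only"] = (
            (surviving["n_significant"] == 1)
            & (surviving["lead"].map(src) == "imputed"))
        final = surviving[~surviving["single_imputed_only"]]
    else:
        final = loci
    _write(final, Path(cfg.out_dir) / "loci_final.tsv")

    refits = []
    for extra in ("haplogroup", "mt_copy_number"):
        if final.empty:
            break
        refits.append(association.sensitivity_refit(
            final["lead"].tolist(), dosages, pheno, extra, spec, manifest))
    _write(pd.concat(refits, ignore_index=True) if refits else
           pd.DataFrame(columns=["variant_id", "extra"]),
           Path(cfg.out_dir) / "sensitivity.tsv")


def stage_duos(cfg: RunConfig) -> None:
    manifest, panel, samples = read_panel(_cohort_dir(cfg))
    kept, kept_samples, report = _load_qc(cfg)
    clean = qc_mod.apply_qc(panel, kept, kept_samples, report)
    linked = samples.dropna(subset=["mother_id"])
    keep = set(kept_samples)
    pairs = [(m, s) for m, s in zip(linked["mother_id"], linked["sample_id"])
             if m in keep and s in keep]
    points = duos_mod.collect_duo_points(clean, pairs, kept, hz_min=cfg.duo_hz_min)
    stats = duos_mod.duo_spearman(points)
    _write(points, Path(cfg.out_dir) / "duo_points.tsv")
    _write(stats, Path(cfg.out_dir) / "duo_report.tsv")
    log.info("duos: %d pairs, %d points", len(pairs), len(points))


_STAGES = [
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("phenotype", stage_phenotype),
    ("gwas", stage_gwas),
    ("numt", stage_numt),
    ("duos", stage_duos),
]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and return the artifact paths.

    A stage failure aborts the run with the stage name; artifacts written so
    far are preserved and a ``status.json`` flags the run incomplete.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done = []
    stages = _STAGES if cfg.inputs is None else _STAGES[1:]
    try:
        for name, fn in stages:
            fn(cfg)
            done.append(name)
    except Exception as exc:
        with open(out / "status.json", "w") as fh:
            json.dump({"complete": False, "failed_stage": name,
                       "stages_done": done, "error": str(exc)}, fh, indent=1)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    with open(out / "status.json", "w") as fh:
        json.dump({"complete": True, "stages_done": done}, fh, indent=1)
    return {
        "qc_report": out / "qc" / "removed.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "null_model": out / "null_model.tsv",
        "summary_stats": out / "summary_stats.tsv",
        "loci": out / "loci_final.tsv",
        "numt_scan": out / "numt_scan.tsv",
        "duo_report": out / "duo_report.tsv",
    }
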