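import numpy as np
import pandas as pd
import pytest

from mthet import SimConfig, apply_qc, build_phenotypes, run_mt_qc, simulate_cohort


def noise_free_config(**overrides) -> SimConfig:
    """A cohort with every noise and failure channel switched off."""
    base = dict(
        n_samples=120, n_mt_variants=60, n_auto_snps_per_chr=12,
        n_nuclear_test_snps=20, noise_scale_distribution=(0.0, 1.0),
        numts=[], causal_loci=[], assay_failure=(0.0, 0.0),
        nocall_rate=0.0, bad_sample_fraction=0.0, duo_fraction=0.0,
        latent_sd=0.3, seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under the default study conditions."""
    cfg = SimConfig(n_samples=800, n_mt_variants=250, seed=11)
    manifest, panel, samples, truth = simulate_cohort(cfg)
    return cfg, manifest, panel, samples, truth


@pytest.fixture(scope="session")
def qc_cohort(default_cohort):
    """The default cohort after QC, with the phenotype table attached."""
    cfg, manifest, panel, samples, truth = default_cohort
    kept, kept_samples, report = run_mt_qc(panel, manifest)
    clean = apply_qc(panel, kept, kept_samples, report)
    pheno = build_phenotypes(clean, manifest, kept, seed=cfg.seed)
    pheno = pheno.join(samples.set_index("sample_id"))
    return {
        "config": cfg, "manifest": manifest, "panel": panel,
        "samples": samples, "truth": truth, "kept": kept,
        "kept_samples": kept_samples, "report": report, "clean": clean,
        "phenotypes": pheno,
    }


def analyze(cfg: SimConfig):
    """simulate -> QC -> phenotypes; returns the pieces downstream tests need."""
    manifest, panel, samples, truth = simulate_cohort(cfg)
    kept, kept_samples, report = run_mt_qc(panel, manifest)
    clean = apply_qc(panel, kept, kept_samples, report)
    pheno = build_phenotypes(clean, manifest, kept, seed=cfg.seed)
    pheno = pheno.join(samples.set_index("sample_id"))
    dosages = clean.dosage.loc[pheno.index]
    return {"manifest": manifest, "panel": panel, "clean": clean,
            "samples": samples, "truth": truth, "kept": kept,
            "phenotypes": pheno, "dosages": dosages}


def tiny_panel(baf: np.ndarray, lrr: np.ndarray = None, calls=None,
               variant_ids=None, sample_ids=None):
    """Hand-built IntensityPanel from raw matrices."""
    from mthet import IntensityPanel
    n, m = baf.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    variant_ids = variant_ids or [f"v{j}" for j in range(m)]
    if lrr is None:
        lrr = np.zeros_like(baf, dtype=float)
    if calls is None:
        calls = np.where(np.isnan(baf), None,
                         np.where(baf < 0.25, "AA",
                                  np.where(baf > 0.75, "BB", "AB")))
    return IntensityPanel(
        baf=pd.DataFrame(baf, index=sample_ids, columns=variant_ids, dtype=float),
        lrr=pd.DataFrame(lrr, index=sample_ids, columns=variant_ids, dtype=float),
        calls=pd.DataFrame(calls, index=sample_ids, columns=variant_ids),
    )


def mt_manifest(positions, prefix="v"):
    """Manifest of mtDNA variants at the given 1-based positions."""
    return pd.DataFrame({
        "variant_id": [f"{prefix}{i}" for i in range(len(positions))],
        "chrom": "MT",
        "pos": list(positions),
        "allele_A": "A",
        "allele_B": "G",
        "source": "genotyped",
    })
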