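"""Covariate model and GWAS: estimation, LRT, genomic control, clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from mthet import (HeteroplasmyGwas, HeteroplasmyNullModel, ModelSpec,
                   clump_loci, drop_single_imputed_loci, fit_null_model,
                   genomic_control, gwas, male_x_dosage, sensitivity_refit)
from mthet.association import CHI2_1_MEDIAN, design_matrix
from conftest import noise_free_config


def _covariate_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(50, 12, n).round(1),
        "sex": rng.choice(["male", "female"], n),
        **{f"pc{i}": rng.normal(0, 1, n) for i in range(1, 6)},
        "ln_autosomal_variance": rng.normal(-6, 0.3, n),
    }, index=[f"s{i}" for i in range(n)])


def _linear_cohort(rng, n, m, beta=0.0, maf=0.2, sigma=0.1):
    """Phenotype built directly from the linear model (no intensity layer)."""
    data = _covariate_frame(rng, n)
    g = rng.binomial(2, maf, (n, m)).astype(float)
    y = (0.5 - 0.002 * data["age"].to_numpy()
         - 0.05 * (data["sex"] == "female").to_numpy()
         + 0.3 * data["ln_autosomal_variance"].to_numpy()
         + beta * g[:, 0]
         + rng.normal(0, sigma, n))
    data["ln_mean_mthz_w"] = y
    dosages = pd.DataFrame(g, index=data.index,
                           columns=[f"g{j}" for j in range(m)])
    return data, dosages


# ------------------------------------------------------------- null model

def test_null_model_recovers_boosted_effects():
    """Sign and 3-SE recovery of planted age/sex effects on the log scale.

    Uses a low-noise assay so the apparent phenotype tracks the latent mean
    (heavier intensity noise attenuates log-scale effects toward zero by the
    noise-floor share -- a measurement property, not an estimator defect)."""
    from mthet import build_phenotypes, run_mt_qc, apply_qc, simulate_cohort
    cfg = noise_free_config(n_samples=3000, n_mt_variants=120,
                            n_auto_snps_per_chr=25,
                            noise_scale_distribution=(9.0, 60000.0),
                            age_effect=-0.01, sex_effect=-0.3,
                            latent_sd=0.3, assay_failure=(0.0, 0.0),
                            nocall_rate=0.002, seed=31)
    manifest, panel, samples, _ = simulate_cohort(cfg)
    kept, ks, rep = run_mt_qc(panel, manifest)
    clean = apply_qc(panel, kept, ks, rep)
    pheno = build_phenotypes(clean, manifest, kept, seed=31)
    pheno = pheno.join(samples.set_index("sample_id"))
    res = fit_null_model(pheno)
    tab = res.coef_table()
    for term, truth in (("age", -0.01), ("sex_female", -0.3)):
        est, se = tab.loc[term, "estimate"], tab.loc[term, "se"]
        assert est < 0
        assert abs(est - truth) < 3 * se


def test_identity_response_gives_unit_coefficient():
    rng = np.random.default_rng(0)
    data = _covariate_frame(rng, 200)
    data["ln_mean_mthz_w"] = data["age"]
    spec = ModelSpec(covariates=("age",))
    res = HeteroplasmyNullModel(data, spec).fit()
    assert res.params["age"] == pytest.approx(1.0, abs=1e-10)
    assert res.params["const"] == pytest.approx(0.0, abs=1e-8)
    assert res._res.ssr == pytest.approx(0.0, abs=1e-12)


def test_null_model_rank_deficiency_names_columns():
    rng = np.random.default_rng(1)
    data = _covariate_frame(rng, 100)
    data["pc2"] = data["pc1"]  # exact collinearity
    data["ln_mean_mthz_w"] = rng.normal(0, 1, 100)
    with pytest.raises(ValueError, match="pc"):
        HeteroplasmyNullModel(data).fit()


def test_permuted_response_pvalues_are_uniform():
    """Covariate p-values under permutation pass a KS test at alpha=0.01."""
    rng = np.random.default_rng(7)
    data = _covariate_frame(rng, 150)
    y = 0.4 * data["pc1"].to_numpy() + rng.normal(0, 1, 150)
    pvals = []
    spec = ModelSpec(covariates=("age", "pc1"))
    for _ in range(200):
        data["ln_mean_mthz_w"] = rng.permutation(y)
        res = HeteroplasmyNullModel(data, spec).fit()
        pvals.append(res.pvalues["pc1"])
    _, p_ks = stats.kstest(pvals, "uniform")
    assert p_ks > 0.01


def test_haplogroup_dummies_reference_h():
    rng = np.random.default_rng(3)
    data = _covariate_frame(rng, 300)
    data["haplogroup"] = rng.choice(["H", "J1", "K1"], 300)
    data["ln_mean_mthz_w"] = rng.normal(0, 1, 300)
    X = design_matrix(data, ModelSpec(covariates=("age", "haplogroup")))
    assert "hap_J1" in X.columns and "hap_K1" in X.columns
    assert "hap_H" not in X.columns


# -------------------------------------------------------------------- GWAS

def test_gwas_recovers_planted_beta_and_significance():
    rng = np.random.default_rng(11)
    data, dosages = _linear_cohort(rng, 5000, 5, beta=0.03, maf=0.2)
    res = gwas(dosages, data).table.set_index("variant_id")
    row = res.loc["g0"]
    assert abs(row["beta"] - 0.03) < 3 * row["se"]
    assert row["p_lrt"] < 5e-8
    assert (res.loc["g1":, "p_lrt"] > 1e-4).all()


def test_gwas_zero_variance_dosage_flagged_untested():
    rng = np.random.default_rng(2)
    data, dosages = _linear_cohort(rng, 300, 3)
    dosages["g1"] = 1.0  # constant column
    res = gwas(dosages, data).table.set_index("variant_id")
    assert not res.loc["g1", "tested"]
    assert np.isnan(res.loc["g1", "beta"])
    assert res.loc["g0", "tested"] and res.loc["g2", "tested"]


def test_gwas_handles_missing_dosages_per_column():
    rng = np.random.default_rng(8)
    data, dosages = _linear_cohort(rng, 800, 3, beta=0.5, sigma=0.1)
    dosages.iloc[rng.choice(800, 100, replace=False), 0] = np.nan
    res = gwas(dosages, data).table.set_index("variant_id")
    assert res.loc["g0", "n"] == 700
    assert res.loc["g0", "p_lrt"] < 1e-10
    assert res.loc["g1", "n"] == 800


def test_gwas_matches_statsmodels_oracle():
    """Dual route: FWL sweep vs an explicit statsmodels OLS + LR test."""
    rng = np.random.default_rng(5)
    data, dosages = _linear_cohort(rng, 400, 3, beta=0.05)
    res = gwas(dosages, data).table.set_index("variant_id")
    X0 = design_matrix(data, ModelSpec())
    y = data["ln_mean_mthz_w"]
    for vid in dosages.columns:
        X1 = X0.copy()
        X1["g"] = dosages[vid]
        full = sm.OLS(y, X1).fit()
        reduced = sm.OLS(y, X0).fit()
        lr, p_lr, _ = full.compare_lr_test(reduced)
        assert res.loc[vid, "beta"] == pytest.approx(full.params["g"], rel=1e-9)
        assert res.loc[vid, "se"] == pytest.approx(full.bse["g"], rel=1e-9)
        assert res.loc[vid, "p_lrt"] == pytest.approx(p_lr, rel=1e-6)


def test_lrt_and_wald_pvalues_agree_on_well_conditioned_fits():
    rng = np.random.default_rng(13)
    data, dosages = _linear_cohort(rng, 2000, 200)
    res = gwas(dosages, data).table
    mod = res[res["p_lrt"].between(1e-6, 0.999)]
    rel = np.abs(mod["p_lrt"] - mod["p_wald"]) / mod["p_wald"]
    assert rel.max() < 0.10


def test_ci_coverage_over_replicates():
    """95% CI for a planted beta covers truth at the nominal rate."""
    rng = np.random.default_rng(17)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        data, dosages = _linear_cohort(rng, 500, 1, beta=0.08)
        row = gwas(dosages[["g0"]], data).table.iloc[0]
        t975 = stats.t.ppf(0.975, 500 - 10 - 1)
        lo, hi = row["beta"] - t975 * row["se"], row["beta"] + t975 * row["se"]
        hits += lo <= 0.08 <= hi
    # binomial 99.9% bounds around 0.95 for 100 draws
    assert 87 <= hits <= 100


def test_male_x_dosage_coding():
    d = male_x_dosage([0, 1, 1, 2, 0], [True, True, False, False, False])
    np.testing.assert_array_equal(d, [0, 2, 1, 2, 0])
    with pytest.raises(ValueError, match="male X"):
        male_x_dosage([2], [True])


# --------------------------------------------------------- genomic control

def test_genomic_control_null_and_doubled_chi2():
    p_half = np.full(500, 0.5)
    lam, p_adj = genomic_control(p_half)
    assert lam == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_array_equal(p_adj, p_half)
    # doubling every chi-square doubles lambda; adjustment restores the median
    u = np.linspace(0.001, 0.999, 999)
    chi = stats.chi2.isf(u, 1)
    p_doubled = stats.chi2.sf(2 * chi, 1)
    lam2, p_adj2 = genomic_control(p_doubled)
    assert lam2 == pytest.approx(2.0, rel=1e-6)
    adj_chi = stats.chi2.isf(p_adj2, 1)
    assert np.median(adj_chi) == pytest.approx(CHI2_1_MEDIAN, rel=1e-6)


def test_genomic_control_below_one_leaves_pvalues():
    p = np.linspace(0.2, 0.99, 200)  # deflated statistics
    lam, p_adj = genomic_control(p)
    assert lam < 1
    np.testing.assert_array_equal(p_adj, p)


# ----------------------------------------------------------------- clumping

def _res_table(rows):
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "beta",
                                     "p_lrt"])
    df["se"] = 0.01
    df["tested"] = True
    return df


def test_clump_hand_cases():
    tab = _res_table([("a", "1", 100_000, 0.1, 1e-10),
                      ("b", "1", 400_000, 0.1, 1e-9)])
    loci = clump_loci(tab)
    assert len(loci) == 1
    assert loci[0].lead == "a" and set(loci[0].members) == {"a", "b"}

    tab = _res_table([("a", "1", 100_000, 0.1, 1e-10),
                      ("b", "2", 100_000, 0.1, 1e-9)])
    assert len(clump_loci(tab)) == 2

    tab = _res_table([("a", "1", 100_000, 0.1, 1e-10),
                      ("b", "1", 700_000, 0.1, 1e-9)])  # outside +-500kb
    assert len(clump_loci(tab)) == 2

    assert clump_loci(_res_table([])) == []
    # sub-threshold variants never form loci
    assert clump_loci(_res_table([("a", "1", 1, 0.1, 1e-7)])) == []


def test_clump_invariant_to_input_order():
    rng = np.random.default_rng(23)
    rows = [(f"v{i}", str(rng.integers(1, 5)), int(rng.integers(1, 5_000_000)),
             0.1, float(10 ** -rng.uniform(6, 30))) for i in range(60)]
    tab = _res_table(rows)
    base = clump_loci(tab)
    shuffled = clump_loci(tab.sample(frac=1, random_state=1))
    assert [(l.lead, sorted(l.members)) for l in base] == \
        [(l.lead, sorted(l.members)) for l in shuffled]
    # the lead carries the locus minimum p
    for locus in base:
        member_p = tab.set_index("variant_id").loc[locus.members, "p_lrt"]
        assert locus.lead_p == member_p.min()


def test_drop_single_imputed_loci():
    manifest = pd.DataFrame({
        "variant_id": ["a", "b", "c", "d"],
        "chrom": "1", "pos": [1, 2, 3, 4],
        "allele_A": "A", "allele_B": "G",
        "source": ["imputed", "genotyped", "imputed", "imputed"],
    })
    tab = _res_table([("a", "1", 100_000, 0.1, 1e-10),      # single imputed
                      ("b", "2", 100_000, 0.1, 1e-9),       # single genotyped
                      ("c", "3", 100_000, 0.1, 1e-12),      # two imputed
                      ("d", "3", 150_000, 0.1, 1e-9)])
    loci = clump_loci(tab)
    kept = drop_single_imputed_loci(loci, manifest)
    assert [l.lead for l in kept] == ["c", "b"]
    assert all(l.flags["single_imputed_only"] is False for l in kept)


# -------------------------------------------------------------- sensitivity

def test_sensitivity_refit_stable_and_collinear_flag():
    rng = np.random.default_rng(29)
    data, dosages = _linear_cohort(rng, 2000, 2, beta=0.08)
    data["haplogroup"] = rng.choice(["H", "J1", "K1"], 2000)
    data["mt_copy_number"] = rng.normal(0, 0.15, 2000)
    out = sensitivity_refit(["g0"], dosages, data, "haplogroup").iloc[0]
    assert abs(out["beta_adj"] - out["beta_base"]) < out["se_base"]
    assert not out["collinear"]
    out = sensitivity_refit(["g0"], dosages, data, "mt_copy_number").iloc[0]
    assert abs(np.log10(out["p_adj"]) - np.log10(out["p_base"])) < 1.0
    # covariate identical to the dosage: genotype term untestable
    data["mt_copy_number"] = dosages["g0"]
    out = sensitivity_refit(["g0"], dosages, data, "mt_copy_number").iloc[0]
    assert out["collinear"]
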