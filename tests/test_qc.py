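"""QC cascade: hand-enumerated fixtures, boundary rules, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from mthet import QCParams, apply_qc, run_mt_qc
from mthet.qc import (cluster_quality_filter, hypervariable_filter,
                      lrr_low_intensity_filter, prune_mt_variants,
                      sample_missingness_filter, split_baf_groups, _pooled_sd)
from conftest import mt_manifest, tiny_panel
from _qc_oracle import oracle_run_qc


# ---------------------------------------------------------------------- prune

def test_prune_hand_enumerated_panel():
    # 5 variants x 10 samples with hand-set genotype calls
    calls = np.array([
        # v0: MAF 0.3, full calls -> kept
        ["AA", "AA", "AA", "AA", "BB", "BB", "BB", "AA", "AA", "AA"],
        # v1: monomorphic (MAF 0) -> removed (maf)
        ["AA"] * 10,
        # v2: call rate 0.9 -> removed (callrate)
        ["AA", "AA", "BB", "BB", "AA", "AA", "BB", "AA", "AA", None],
        # v3: MAF 0.05 > 0.001, full calls -> kept
        ["AB", "AA", "AA", "AA", "AA", "AA", "AA", "AA", "AA", "AA"],
        # v4: zero calls -> removed (callrate)
        [None] * 10,
    ], dtype=object).T
    baf = np.where(calls == "AA", 0.01, np.where(calls == "BB", 0.99,
                   np.where(calls == "AB", 0.5, np.nan))).astype(float)
    panel = tiny_panel(baf, calls=calls)
    manifest = mt_manifest([1000, 2000, 3000, 4000, 5000])
    kept, removed, stats = prune_mt_variants(panel, manifest, QCParams())
    assert kept == ["v0", "v3"]
    assert dict(removed) == {"v1": "maf", "v2": "callrate", "v4": "callrate"}
    assert stats.loc["v0", "maf"] == pytest.approx(0.3)


def test_prune_boundaries_are_strict():
    # MAF exactly 0.001: 1 B allele among 1000 haploid-equivalent calls
    n = 500
    calls = np.full((n, 2), "AA", dtype=object)
    calls[0, 0] = "AB"          # v0: MAF = 1/1000 exactly -> removed
    calls[:, 1] = "AA"
    calls[:150, 1] = "BB"       # v1: MAF 0.3, call rate 1 -> kept
    baf = np.where(calls == "BB", 0.99, np.where(calls == "AB", 0.5, 0.01)).astype(float)
    panel = tiny_panel(baf, calls=calls)
    manifest = mt_manifest([700, 800])
    kept, removed, _ = prune_mt_variants(panel, manifest, QCParams())
    assert kept == ["v1"]
    assert ("v0", "maf") in removed


def test_prune_multiallelic_removed():
    calls = np.array([["AA", "BB", "AA", "BB"]], dtype=object).T
    panel = tiny_panel(np.array([[0.0], [1.0], [0.0], [1.0]]), calls=calls)
    manifest = mt_manifest([1500])
    manifest.loc[0, "allele_B"] = "A"  # not biallelic
    kept, removed, _ = prune_mt_variants(panel, manifest, QCParams())
    assert kept == []
    assert removed == [("v0", "multiallelic")]


# ----------------------------------------------------------------- BAF groups

def test_split_baf_groups_boundary_and_missing():
    s = pd.Series([0.1, 0.6, np.nan, 0.5, 0.0], index=list("abcde"))
    low, high = split_baf_groups(s)
    assert set(low) == {"a", "d", "e"}   # 0.5 goes to the low group
    assert set(high) == {"b"}
    all_zero = pd.Series([0.0, 0.0], index=["x", "y"])
    low, high = split_baf_groups(all_zero)
    assert len(high) == 0 and set(low) == {"x", "y"}


# ----------------------------------------------------------------- LRR filter

def test_pooled_sd_hand_value():
    sp = _pooled_sd([np.array([-1.0, 1.0]), np.array([-2.0, 2.0])])
    assert sp == pytest.approx(math.sqrt(5), abs=1e-12)
    # a group with <2 samples contributes nothing
    sp = _pooled_sd([np.array([-1.0, 1.0]), np.array([7.0])])
    assert sp == pytest.approx(math.sqrt(2), abs=1e-12)
    assert math.isnan(_pooled_sd([np.array([1.0]), np.array([])]))


def test_lrr_filter_identical_values_remove_nothing():
    baf = np.concatenate([np.full(20, 0.01), np.full(20, 0.99)])[:, None]
    lrr = np.zeros((40, 1))
    panel = tiny_panel(baf, lrr)
    removed, failed, stats = lrr_low_intensity_filter(panel, "v0", QCParams())
    assert removed == [] and not failed
    assert stats["lrr_pooled_sd"] == 0.0


def test_lrr_filter_planted_outlier_removed():
    # tight +-0.1 clusters in both groups; one planted outlier far below the
    # mean - 3*pooled SD cut; after its removal the trim is at a fixed point
    n = 200
    baf = np.concatenate([np.full(n // 2, 0.01), np.full(n // 2, 0.99)])[:, None]
    lrr = np.tile([0.1, -0.1], n // 2)[:, None].astype(float)
    lrr[5, 0] = -0.9  # ~9 pooled SDs below the low-group mean
    panel = tiny_panel(baf, lrr)
    removed, failed, _ = lrr_low_intensity_filter(panel, "v0", QCParams())
    assert removed == ["s5"]
    assert failed  # 1/100 >= 1% in the low group


def test_lrr_filter_degenerate_groups_skipped():
    baf = np.array([[0.2], [0.9]])
    lrr = np.array([[0.0], [0.0]])
    panel = tiny_panel(baf, lrr)
    removed, failed, stats = lrr_low_intensity_filter(panel, "v0", QCParams())
    assert removed == [] and not failed and stats.get("skipped")


# ------------------------------------------------------------- cluster filter

def _group_panel(n_hz, n_total=100):
    baf = np.full(n_total, 0.02)
    baf[:n_hz] = 0.25
    return tiny_panel(baf[:, None])


def test_cluster_filter_count_and_fraction_rule():
    removed, _ = cluster_quality_filter(_group_panel(12), "v0", QCParams())
    assert removed  # 12 >= 10 and 12% >= 10%
    removed, _ = cluster_quality_filter(_group_panel(9), "v0", QCParams())
    assert not removed  # fails the minimum-count arm
    # 10% fraction but group of 2000 -> removal needs both arms; 15 of 2000 < 10%
    removed, _ = cluster_quality_filter(_group_panel(15, 2000), "v0", QCParams())
    assert not removed


def test_cluster_filter_homoplasmic_kept():
    baf = np.concatenate([np.zeros(60), np.ones(40)])[:, None]
    removed, _ = cluster_quality_filter(tiny_panel(baf), "v0", QCParams())
    assert not removed


# ------------------------------------------------------- positions & samples

def test_hypervariable_boundaries_inclusive():
    manifest = mt_manifest([57, 372, 373, 100, 16000, 16024, 437, 438])
    kept = hypervariable_filter(manifest, QCParams())
    kept_pos = sorted(manifest.set_index("variant_id").loc[kept, "pos"])
    assert kept_pos == [373, 437, 16000]


def test_sample_missingness_strictly_greater():
    baf = np.zeros((3, 100))
    baf[0, :6] = np.nan   # 6% missing -> removed
    baf[1, :5] = np.nan   # exactly 5% -> kept
    panel = tiny_panel(baf)
    kept = sample_missingness_filter(panel, QCParams())
    assert kept == ["s1", "s2"]


# ------------------------------------------------------------------- cascade

def test_run_mt_qc_planted_failures_each_reason(default_cohort):
    _, manifest, panel, _, _ = default_cohort
    _, _, report = run_mt_qc(panel, manifest)
    reasons = {r for _, r in report.removed_variants}
    # the default generator plants every failure class
    assert {"maf", "lrr_fail", "poor_cluster", "hypervariable"} <= reasons
    assert len(report.per_call_removals) > 0
    assert any(r == "missingness" for _, r in report.removed_samples)


def test_run_mt_qc_idempotent_in_kept_sets(default_cohort):
    _, manifest, panel, _, _ = default_cohort
    kept1, samples1, report1 = run_mt_qc(panel, manifest)
    clean = apply_qc(panel, kept1, samples1, report1, keep_other_variants=False)
    kept2, samples2, _ = run_mt_qc(clean, manifest)
    assert kept2 == kept1
    assert samples2 == samples1


def test_tightening_thresholds_shrinks_kept_set(default_cohort):
    """Monotonicity, asserted where it holds exactly: per filter on fixed
    input, and for the variant set of a single pass under one threshold."""
    _, manifest, panel, _, _ = default_cohort

    # prune: stricter MAF and call-rate bars keep a subset
    k1, _, _ = prune_mt_variants(panel, manifest, QCParams())
    k2, _, _ = prune_mt_variants(panel, manifest, QCParams(maf_min=0.05))
    k3, _, _ = prune_mt_variants(panel, manifest,
                                 QCParams(variant_callrate_min=0.995))
    assert set(k2) <= set(k1) and set(k3) <= set(k1)

    # sample missingness: stricter bound keeps a subset (fixed variant set)
    s1 = sample_missingness_filter(panel, QCParams(), variants=k1)
    s2 = sample_missingness_filter(panel, QCParams(sample_missing_max=0.01),
                                   variants=k1)
    assert set(s2) <= set(s1)

    # cluster filter: lowering both arms can only add removals
    loose = QCParams()
    tight = QCParams(hz_sample_fraction=0.05, min_group_size=5)
    for vid in k1[:50]:
        removed_loose, _ = cluster_quality_filter(panel, vid, loose)
        removed_tight, _ = cluster_quality_filter(panel, vid, tight)
        assert removed_tight or not removed_loose

    # single-pass cascade, one variant-level threshold tightened
    kept_l, _, _ = run_mt_qc(panel, manifest, QCParams(), max_passes=1)
    kept_t, _, _ = run_mt_qc(panel, manifest, QCParams(maf_min=0.05),
                             max_passes=1)
    assert set(kept_t) <= set(kept_l)


def test_qc_all_variants_removed_raises():
    baf = np.full((20, 2), 0.01)
    panel = tiny_panel(baf)
    manifest = mt_manifest([1000, 2000])
    with pytest.raises(ValueError, match="every variant"):
        run_mt_qc(panel, manifest)  # both monomorphic -> nothing survives


def _random_small_panel(rng):
    n = rng.integers(20, 51)
    m = rng.integers(3, 11)
    kind = rng.random(m)
    baf = np.empty((n, m))
    for j in range(m):
        freq = rng.uniform(0.0, 0.5)
        base = rng.random(n) < freq
        h = rng.gamma(0.4, 0.02, n)
        col = np.clip(np.where(base, 1 - h, h) + rng.normal(0, 0.02, n), 0, 1)
        if kind[j] < 0.2:
            col = 0.5 + (col - 0.5) * rng.uniform(0.3, 0.6)  # poor clustering
        baf[:, j] = col
    lrr = rng.normal(0, 0.12, (n, m))
    lrr[rng.random((n, m)) < 0.03] -= rng.uniform(0.5, 2.0)
    baf[rng.random((n, m)) < 0.05] = np.nan
    lrr[np.isnan(baf)] = np.nan
    positions = sorted(rng.choice(np.arange(1, 16570), size=m, replace=False))
    return tiny_panel(baf, lrr), mt_manifest(positions)


def test_cascade_matches_bruteforce_oracle_randomized():
    """Randomized small panels: kept sets equal an independent loop oracle."""
    rng = np.random.default_rng(123)
    params = QCParams(min_group_size=3)
    n_checked = 0
    for _ in range(60):
        panel, manifest = _random_small_panel(rng)
        expect_kept, expect_samples = oracle_run_qc(panel, manifest, params)
        if not expect_kept:
            with pytest.raises(ValueError):
                run_mt_qc(panel, manifest, params)
            continue
        kept, samples, _ = run_mt_qc(panel, manifest, params)
        assert kept == expect_kept
        assert samples == expect_samples
        n_checked += 1
    assert n_checked >= 20
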