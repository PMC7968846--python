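"""Brute-force reimplementation of the QC cascade, for oracle tests.

Deliberately written with plain Python loops and explicit formulas,
independent of the package's vectorised implementation.
"""

import math


def oracle_maf_callrate(calls):
    """calls: list of 'AA'/'AB'/'BB'/None."""
    obs = [c for c in calls if c is not None]
    if not calls:
        return 0.0, 0.0
    call_rate = len(obs) / len(calls)
    if not obs:
        return 0.0, call_rate
    n_b = sum({"AA": 0, "AB": 1, "BB": 2}[c] for c in obs)
    p = n_b / (2 * len(obs))
    return min(p, 1 - p), call_rate


def oracle_prune(calls_by_variant, biallelic_by_variant, maf_min, callrate_min):
    kept = []
    for vid, calls in calls_by_variant.items():
        maf, cr = oracle_maf_callrate(calls)
        if biallelic_by_variant[vid] and cr > callrate_min and maf > maf_min:
            kept.append(vid)
    return kept


def oracle_groups(baf_by_sample):
    low, high = [], []
    for sid, b in baf_by_sample.items():
        if b is None or (isinstance(b, float) and math.isnan(b)):
            continue
        (low if b <= 0.5 else high).append(sid)
    return low, high


def oracle_pooled_sd(values_a, values_b):
    num, dof = 0.0, 0
    for vals in (values_a, values_b):
        vals = [v for v in vals if not math.isnan(v)]
        if len(vals) >= 2:
            mean = sum(vals) / len(vals)
            num += sum((v - mean) ** 2 for v in vals)
            dof += len(vals) - 1
    if dof == 0:
        return float("nan")
    return math.sqrt(num / dof)


def oracle_lrr_filter(baf_by_sample, lrr_by_sample, multiplier, fail_max):
    """Iterated trim to a fixed point; cumulative fraction drives failure."""
    low, high = oracle_groups(baf_by_sample)
    values = {s: v for s, v in lrr_by_sample.items() if not math.isnan(v)}
    first_sp = oracle_pooled_sd([values[s] for s in low if s in values],
                                [values[s] for s in high if s in values])
    if math.isnan(first_sp):
        return [], False
    n0 = {0: max(sum(1 for s in low if s in values), 1),
          1: max(sum(1 for s in high if s in values), 1)}
    removed_by_group = {0: [], 1: []}
    for _ in range(10):
        sp = oracle_pooled_sd([values[s] for s in low if s in values],
                              [values[s] for s in high if s in values])
        if math.isnan(sp):
            break
        any_hit = False
        for gi, group in enumerate((low, high)):
            present = [s for s in group if s in values]
            if not present:
                continue
            mean = sum(values[s] for s in present) / len(present)
            cut = mean - multiplier * sp
            hit = [s for s in present if values[s] < cut]
            for s in hit:
                del values[s]
            removed_by_group[gi].extend(hit)
            any_hit = any_hit or bool(hit)
        if not any_hit:
            break
    removed = removed_by_group[0] + removed_by_group[1]
    failed = any(len(removed_by_group[g]) / n0[g] >= fail_max for g in (0, 1))
    return removed, failed


def oracle_cluster_filter(baf_by_sample, hz_threshold, hz_fraction, min_count):
    low, high = oracle_groups(baf_by_sample)
    for group in (low, high):
        if not group:
            continue
        hz = [min(baf_by_sample[s], 1 - baf_by_sample[s]) for s in group]
        n_hz = sum(1 for h in hz if h >= hz_threshold)
        if n_hz >= min_count and n_hz / len(group) >= hz_fraction:
            return True
    return False


def oracle_hypervariable(pos_by_variant, ranges):
    return [vid for vid, pos in pos_by_variant.items()
            if not any(s <= pos <= e for s, e in ranges)]


def oracle_sample_filter(baf_rows, missing_max):
    """baf_rows: {sample: list of values (None/nan = missing)} over kept variants."""
    kept = []
    for sid, row in baf_rows.items():
        miss = sum(1 for v in row
                   if v is None or (isinstance(v, float) and math.isnan(v)))
        if row and miss / len(row) <= missing_max:
            kept.append(sid)
    return kept


def oracle_run_qc(panel, manifest, params):
    """Full cascade on an IntensityPanel, loops only; mirrors the stated order."""
    mt = manifest[manifest["chrom"].astype(str) == "MT"]
    calls_by_variant, biallelic, pos_by_variant = {}, {}, {}
    for _, row in mt.iterrows():
        vid = row["variant_id"]
        calls_by_variant[vid] = [
            c if isinstance(c, str) else None for c in panel.calls[vid]]
        a, b = row["allele_A"], row["allele_B"]
        biallelic[vid] = (isinstance(a, str) and isinstance(b, str)
                          and len(a) == 1 and len(b) == 1 and a != b)
        pos_by_variant[vid] = row["pos"]

    kept = oracle_prune(calls_by_variant, biallelic,
                        params.maf_min, params.variant_callrate_min)

    baf = {vid: dict(panel.baf[vid]) for vid in kept}
    lrr = {vid: dict(panel.lrr[vid]) for vid in kept}
    still = []
    for vid in kept:
        removed, failed = oracle_lrr_filter(
            baf[vid], lrr[vid], params.lrr_sd_multiplier,
            params.lrr_variant_fail_max)
        for sid in removed:
            baf[vid][sid] = float("nan")
            lrr[vid][sid] = float("nan")
        if not failed:
            still.append(vid)
    kept = still

    kept = [vid for vid in kept if not oracle_cluster_filter(
        baf[vid], params.hz_threshold, params.hz_sample_fraction,
        params.min_group_size)]

    kept = oracle_hypervariable({v: pos_by_variant[v] for v in kept},
                                params.hypervariable_ranges)

    rows = {sid: [baf[vid][sid] for vid in kept] for sid in panel.samples}
    kept_samples = oracle_sample_filter(rows, params.sample_missing_max)
    return kept, kept_samples
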