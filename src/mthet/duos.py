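"""Mother-offspring concordance of heteroplasmy.

Each (pair, variant) combination where the mother is appreciably
heteroplasmic (min(BAF, 1-BAF) > 5% by default) contributes one point of
maternal vs offspring BAF.  Points are stratified by the maternal BAF side
of 0.5 — the two homoplasmic clusters are arbitrary labellings of the same
biology — and Spearman rank correlation is computed per stratum.  Positive
correlation in both strata is the signature of germline transmission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityPanel

__all__ = ["collect_duo_points", "duo_spearman"]


def collect_duo_points(panel: IntensityPanel, pairs, variants,
                       hz_min: float = 0.05) -> pd.DataFrame:
    """Collect stratified maternal/offspring BAF points.

    Keeps (pair, variant) points with maternal heteroplasmy strictly above
    ``hz_min``; maternal BAF <= 0.5 goes to the ``low`` stratum (consistent
    with the QC grouping convention), > 0.5 to ``high``.  Points where
    either BAF is missing are dropped.
    """
    variants = list(variants)
    baf = panel.baf[variants]
    rows = []
    for mother, offspring in pairs:
        if mother not in baf.index or offspring not in baf.index:
            continue
        mb = baf.loc[mother].to_numpy(dtype=float)
        ob = baf.loc[offspring].to_numpy(dtype=float)
        ok = ~np.isnan(mb) & ~np.isnan(ob)
        hz = np.minimum(mb, 1 - mb)
        ok &= hz > hz_min
        for v, m, o in zip(np.asarray(variants)[ok], mb[ok], ob[ok]):
            rows.append({
                "mother_id": mother, "offspring_id": offspring,
                "variant_id": v, "maternal_baf": m, "offspring_baf": o,
                "stratum": "low" if m <= 0.5 else "high",
            })
    return pd.DataFrame(rows, columns=["mother_id", "offspring_id", "variant_id",
                                       "maternal_baf", "offspring_baf", "stratum"])


def duo_spearman(points: pd.DataFrame, min_points: int = 10) -> pd.DataFrame:
    """Spearman correlation of maternal vs offspring BAF per stratum.

    Uses midranks for ties and the t-approximation for the p-value.  Strata
    with fewer than ``min_points`` points or a constant coordinate are
    flagged undefined (NaN statistics).
    """
    rows = []
    for stratum, grp in points.groupby("stratum"):
        n = len(grp)
        x = grp["maternal_baf"].to_numpy()
        y = grp["offspring_baf"].to_numpy()
        defined = (n >= min_points
                   and np.unique(x).size > 1 and np.unique(y).size > 1)
        if defined:
            rho, p = stats.spearmanr(x, y)
        else:
            rho, p = np.nan, np.nan
        rows.append({"stratum": stratum, "n": n, "rho": rho, "p": p,
                     "defined": bool(defined)})
    return pd.DataFrame(rows, columns=["stratum", "n", "rho", "p", "defined"])
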