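"""Covariate modelling and nuclear GWAS of the heteroplasmy phenotype.

Two model objects follow the statsmodels convention of a model built from
data whose ``fit()`` returns a results object:

* :class:`HeteroplasmyNullModel` — ordinary least squares of the winsorized
  log mean-heteroplasmy phenotype on the covariate set (age, sex, principal
  components 1-5, log autosomal variance, optionally haplogroup dummies
  against reference H and relative mtDNA copy number).
* :class:`HeteroplasmyGwas` — per-variant OLS adding an additive allele-dosage
  term to the null covariates.  The genotype term's p-value comes from a
  1-df likelihood-ratio test; Wald statistics are reported alongside.
  Residualizing phenotype and dosages on the covariates once
  (Frisch-Waugh-Lovell) makes the scan a handful of matrix products.

Post-processing implements standard genomic control (median-chi-square
inflation factor, statistics divided by lambda when it exceeds 1),
distance-based locus clumping, and the poorly-supported-locus rule that
drops loci whose only genome-wide-significant member is a single imputed
variant.  Sensitivity refits re-test lead variants with an extra covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import MT_CHROM

__all__ = ["ModelSpec", "HeteroplasmyNullModel", "NullModelResults",
           "HeteroplasmyGwas", "GwasResults", "fit_null_model", "gwas",
           "genomic_control", "Locus", "clump_loci", "drop_single_imputed_loci",
           "sensitivity_refit", "male_x_dosage", "GENOME_WIDE_P", "CHI2_1_MEDIAN"]

#: Genome-wide significance threshold.
GENOME_WIDE_P = 5e-8

#: Median of the 1-df chi-square distribution (the genomic-control null median).
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

DEFAULT_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5",
                      "ln_autosomal_variance")


@dataclass(frozen=True)
class ModelSpec:
    """Response and ordered covariate set for the phenotype models.

    ``"sex"`` expands to a female-vs-male indicator and ``"haplogroup"`` to
    dummies against ``haplogroup_reference``; all other names must be numeric
    phenotype columns.
    """

    response: str = "ln_mean_mthz_w"
    covariates: tuple = DEFAULT_COVARIATES
    haplogroup_reference: str = "H"

    def with_extra(self, extra: str) -> "ModelSpec":
        if extra in self.covariates:
            return self
        return ModelSpec(self.response, tuple(self.covariates) + (extra,),
                         self.haplogroup_reference)


def design_matrix(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Expand the covariate list into a numeric design matrix with intercept."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for cov in spec.covariates:
        if cov == "sex":
            sex = data["sex"].astype(str)
            bad = ~sex.isin(["male", "female"])
            if bad.any():
                raise ValueError(f"sex must be male/female, got {sex[bad].iloc[0]!r}")
            cols["sex_female"] = (sex == "female").to_numpy(dtype=float)
        elif cov == "haplogroup":
            hap = data["haplogroup"].astype(str)
            ref = spec.haplogroup_reference
            for level in sorted(hap.unique()):
                if level != ref:
                    cols[f"hap_{level}"] = (hap == level).to_numpy(dtype=float)
        else:
            if cov not in data.columns:
                raise ValueError(f"covariate {cov!r} not in phenotype table")
            cols[cov] = data[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


class NullModelResults:
    """OLS results for the covariate-only model.

    Thin wrapper around the statsmodels RegressionResults with the
    coefficient table exposed as a DataFrame.
    """

    def __init__(self, sm_results, n_dropped: int):
        self._res = sm_results
        self.n_dropped = n_dropped
        self.nobs = int(sm_results.nobs)

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self._res.params,
            "se": self._res.bse,
            "t": self._res.tvalues,
            "p": self._res.pvalues,
        })

    def summary(self):
        return self._res.summary()


class HeteroplasmyNullModel:
    """Covariate-only model of the log mean-heteroplasmy phenotype."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        X = design_matrix(data, self.spec)
        y = data[self.spec.response].astype(float)
        complete = y.notna() & X.notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.y = y[complete]
        self.X = X.loc[complete]
        _check_full_rank(self.X)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec | None = None):
        return cls(data, spec)

    def fit(self) -> NullModelResults:
        res = sm.OLS(self.y, self.X).fit()
        return NullModelResults(res, self.n_dropped)


def fit_null_model(phenotypes: pd.DataFrame,
                   spec: ModelSpec | None = None) -> NullModelResults:
    """Convenience wrapper: build and fit the covariate-only model."""
    return HeteroplasmyNullModel(phenotypes, spec).fit()


def male_x_dosage(allele_count, is_male):
    """Code male X-chromosome genotypes as homozygous diploid {0, 2}.

    Males carry one X allele; the observed allele count in {0, 1} is doubled
    so effect sizes are on the same per-allele scale as females.
    """
    a = np.asarray(allele_count, dtype=float)
    m = np.asarray(is_male, dtype=bool)
    bad = m & ~np.isnan(a) & ~np.isin(a, (0.0, 1.0))
    if bad.any():
        raise ValueError("male X allele count must be 0 or 1")
    return np.where(m, 2 * a, a)


@dataclass
class Locus:
    lead: str
    chrom: str
    start: int
    end: int
    members: list            # genome-wide significant variant ids
    lead_p: float
    lead_beta: float
    flags: dict = field(default_factory=dict)


class LocusSet(list):
    """Loci ordered by lead p-value; plain list with a table view."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "lead": l.lead, "chrom": l.chrom, "start": l.start, "end": l.end,
            "n_significant": len(l.members), "lead_p": l.lead_p,
            "lead_beta": l.lead_beta,
            **{k: v for k, v in l.flags.items()},
        } for l in self])


class GwasResults:
    """Per-variant association results with post-processing methods."""

    def __init__(self, table: pd.DataFrame, model: "HeteroplasmyGwas"):
        self.table = table
        self.model = model
        self.lambda_gc: float | None = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def apply_genomic_control(self) -> float:
        """Compute lambda from tested variants and store adjusted p-values."""
        tested = self.table["tested"].to_numpy()
        lam, p_adj = genomic_control(self.table.loc[tested, "p_lrt"].to_numpy())
        self.lambda_gc = lam
        self.table["p_adjusted"] = np.nan
        self.table.loc[tested, "p_adjusted"] = p_adj
        return lam

    def clump(self, threshold: float = GENOME_WIDE_P,
              window_kb: float = 500.0) -> LocusSet:
        return clump_loci(self.table, threshold=threshold, window_kb=window_kb)

    def summary(self) -> pd.DataFrame:
        cols = ["variant_id", "chrom", "pos", "beta", "se", "p_lrt",
                "p_adjusted", "n", "tested"]
        have = [c for c in cols if c in self.table.columns]
        return self.table[have].sort_values("p_lrt").reset_index(drop=True)

    def manhattan_plot(self, ax=None, threshold: float = GENOME_WIDE_P):
        """Optional diagnostic -log10(p) scatter by chromosome."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        tab = self.table[self.table["tested"]]
        p = tab["p_adjusted"] if "p_adjusted" in tab else tab["p_lrt"]
        chroms = sorted(tab["chrom"].unique(), key=lambda c: (len(str(c)), str(c)))
        offset = 0
        for i, c in enumerate(chroms):
            sub = tab[tab["chrom"] == c]
            ax.scatter(offset + sub["pos"].to_numpy(), -np.log10(p[sub.index]),
                       s=4, color="C0" if i % 2 == 0 else "C1")
            offset += sub["pos"].max() + 1
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
        ax.set_xlabel("genomic position")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax


class HeteroplasmyGwas:
    """Additive per-variant association scan of the heteroplasmy phenotype.

    Parameters
    ----------
    dosages : DataFrame
        Samples x variants B-allele dosage in [0, 2]; fractional values are
        allowed for imputed variants.  Male X-chromosome genotypes must
        already be coded {0, 2} (see :func:`male_x_dosage`).
    phenotypes : DataFrame
        Phenotype/covariate table indexed like ``dosages``.
    manifest : DataFrame, optional
        Supplies chrom/pos/source columns for the result table.
    """

    def __init__(self, dosages: pd.DataFrame, phenotypes: pd.DataFrame,
                 spec: ModelSpec | None = None,
                 manifest: pd.DataFrame | None = None):
        self.spec = spec or ModelSpec()
        if not dosages.index.equals(phenotypes.index):
            dosages = dosages.loc[phenotypes.index]
        X = design_matrix(phenotypes, self.spec)
        y = phenotypes[self.spec.response].astype(float)
        complete = y.notna() & X.notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.y = y[complete].to_numpy()
        self.X = X.loc[complete]
        _check_full_rank(self.X)
        self.dosages = dosages.loc[complete.index[complete]]
        self.manifest = manifest
        self.nobs = len(self.y)

    def fit(self) -> GwasResults:
        Xa = self.X.to_numpy(dtype=float)
        n, p0 = Xa.shape
        Q, _ = np.linalg.qr(Xa)
        y_r = self.y - Q @ (Q.T @ self.y)
        rss0 = float(y_r @ y_r)

        G = self.dosages.to_numpy(dtype=float)
        m = G.shape[1]
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p_wald = np.full(m, np.nan)
        p_lrt = np.full(m, np.nan)
        lrt = np.full(m, np.nan)
        nvec = np.full(m, n)
        tested = np.zeros(m, dtype=bool)

        nan_cols = np.isnan(G).any(axis=0)
        df = n - p0 - 1

        def _column_stats(g_r, yy_r, rss_null, nn, dof):
            gg = float(g_r @ g_r)
            if gg <= 1e-12 * nn or dof <= 0:
                return None
            gy = float(g_r @ yy_r)
            b = gy / gg
            rss1 = max(rss_null - gy * gy / gg, 1e-300)
            sigma2 = rss1 / dof
            s = np.sqrt(sigma2 / gg)
            t = b / s
            stat = nn * np.log(rss_null / rss1)
            return b, s, 2 * stats.t.sf(abs(t), dof), stat, stats.chi2.sf(stat, 1)

        # complete-dosage columns in one sweep
        idx = np.flatnonzero(~nan_cols)
        if idx.size:
            Gc = G[:, idx]
            G_r = Gc - Q @ (Q.T @ Gc)
            gg = np.einsum("ij,ij->j", G_r, G_r)
            gy = G_r.T @ y_r
            ok = gg > 1e-12 * n
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(ok, gy / gg, np.nan)
                rss1 = np.maximum(rss0 - np.where(ok, gy * gy / gg, 0.0), 1e-300)
                s = np.sqrt(rss1 / df / np.where(ok, gg, np.nan))
                t = b / s
                stat = n * np.log(rss0 / rss1)
            beta[idx] = b
            se[idx] = s
            p_wald[idx] = 2 * stats.t.sf(np.abs(t), df)
            lrt[idx] = np.where(ok, stat, np.nan)
            p_lrt[idx] = np.where(ok, stats.chi2.sf(stat, 1), np.nan)
            tested[idx] = ok

        # columns with missing dosages: per-column complete-case fit
        for j in np.flatnonzero(nan_cols):
            g = G[:, j]
            mask = ~np.isnan(g)
            nn = int(mask.sum())
            if nn <= p0 + 1:
                continue
            Xm = Xa[mask]
            Qm, _ = np.linalg.qr(Xm)
            ym = self.y[mask]
            ym_r = ym - Qm @ (Qm.T @ ym)
            rssm = float(ym_r @ ym_r)
            gm = g[mask]
            gm_r = gm - Qm @ (Qm.T @ gm)
            out = _column_stats(gm_r, ym_r, rssm, nn, nn - p0 - 1)
            nvec[j] = nn
            if out is not None:
                beta[j], se[j], p_wald[j], lrt[j], p_lrt[j] = out
                tested[j] = True

        table = pd.DataFrame({
            "variant_id": self.dosages.columns,
            "beta": beta, "se": se, "lrt": lrt,
            "p_wald": p_wald, "p_lrt": p_lrt,
            "n": nvec, "tested": tested,
        })
        if self.manifest is not None:
            meta = self.manifest.set_index("variant_id")[["chrom", "pos", "source",
                                                          "allele_A", "allele_B"]]
            table = table.join(meta, on="variant_id")
        return GwasResults(table, self)


def gwas(dosages: pd.DataFrame, phenotypes: pd.DataFrame,
         spec: ModelSpec | None = None,
         manifest: pd.DataFrame | None = None) -> GwasResults:
    """Convenience wrapper: build and fit the per-variant scan."""
    return HeteroplasmyGwas(dosages, phenotypes, spec, manifest).fit()


def genomic_control(p_values) -> tuple[float, np.ndarray]:
    """Median-based genomic control.

    lambda = median of the 1-df chi-square statistics implied by the p-values
    divided by the null median (~0.4549).  When lambda > 1 every statistic is
    divided by lambda and the p-values recomputed; otherwise they are
    returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    chi = np.full_like(p, np.nan)
    chi[finite] = stats.chi2.isf(p[finite], 1)
    lam = float(np.median(chi[finite]) / CHI2_1_MEDIAN)
    # guard against quantile round-trip noise at an exactly-null median
    if lam > 1 + 1e-9:
        p_adj = np.where(finite, stats.chi2.sf(chi / lam, 1), np.nan)
    else:
        p_adj = p.copy()
    return lam, p_adj


def _pcol(table: pd.DataFrame) -> str:
    return "p_adjusted" if "p_adjusted" in table.columns else "p_lrt"


def clump_loci(table: pd.DataFrame, threshold: float = GENOME_WIDE_P,
               window_kb: float = 500.0) -> LocusSet:
    """Greedy distance-based clumping of genome-wide significant variants.

    Repeatedly takes the most significant unassigned variant as a locus lead
    and assigns every significant variant within +-window_kb on the same
    chromosome to it.  Output is independent of input row order (ties broken
    by chromosome then position).
    """
    pcol = _pcol(table)
    sig = table[table["tested"] & (table[pcol] <= threshold)].copy()
    loci = LocusSet()
    if sig.empty:
        return loci
    sig = sig.sort_values([pcol, "chrom", "pos"], kind="mergesort")
    window = window_kb * 1000.0
    unassigned = sig.copy()
    while not unassigned.empty:
        lead = unassigned.iloc[0]
        near = unassigned[
            (unassigned["chrom"] == lead["chrom"])
            & (np.abs(unassigned["pos"] - lead["pos"]) <= window)]
        loci.append(Locus(
            lead=lead["variant_id"], chrom=str(lead["chrom"]),
            start=int(near["pos"].min()), end=int(near["pos"].max()),
            members=near["variant_id"].tolist(),
            lead_p=float(lead[pcol]), lead_beta=float(lead["beta"]),
        ))
        unassigned = unassigned.drop(near.index)
    return loci


def drop_single_imputed_loci(loci: LocusSet, manifest: pd.DataFrame) -> LocusSet:
    """Drop loci whose only significant member is a single imputed variant."""
    source = manifest.set_index("variant_id")["source"]
    out = LocusSet()
    for locus in loci:
        single_imputed = (len(locus.members) == 1
                          and source.get(locus.members[0]) == "imputed")
        locus.flags["single_imputed_only"] = single_imputed
        if not single_imputed:
            out.append(locus)
    return out


def sensitivity_refit(lead_ids, dosages: pd.DataFrame, phenotypes: pd.DataFrame,
                      extra: str, spec: ModelSpec | None = None,
                      manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Re-test lead variants with an extra covariate (haplogroup or copy number).

    Returns a table of beta/se/p before and after inclusion; a lead whose
    dosage becomes collinear with the extended covariate set is flagged.
    """
    spec = spec or ModelSpec()
    base = gwas(dosages[list(lead_ids)], phenotypes, spec, manifest).table
    ext_spec = spec.with_extra(extra)
    ext = gwas(dosages[list(lead_ids)], phenotypes, ext_spec, manifest).table
    out = base[["variant_id", "beta", "se", "p_lrt"]].rename(
        columns={"beta": "beta_base", "se": "se_base", "p_lrt": "p_base"})
    out = out.merge(
        ext[["variant_id", "beta", "se", "p_lrt", "tested"]].rename(
            columns={"beta": "beta_adj", "se": "se_adj", "p_lrt": "p_adj",
                     "tested": "tested_adj"}),
        on="variant_id")
    out["collinear"] = ~out["tested_adj"]
    out["extra"] = extra
    return out
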