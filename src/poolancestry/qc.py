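"""SNP quality-control filters for pooled array genotyping.

Four filters, applied per SNP:

* **FLD-filter** -- separation of the individual genotype clusters,
  scored as the minimum Fisher's linear discriminant over the adjacent
  cluster pairs (AA-AB, AB-BB); poorly separated clusters make the
  polar transform unreliable.
* **r-filter** -- the ratio r/r' of the pooled replicate's radial
  distance from the origin O to the radius expected of an average
  individual sample at the same allele frequency; a pass requires a
  configurable fraction of replicates (over all pools) at or above the
  ratio cut-off.
* **MAF-filter** -- panel-wide (pool-size-weighted) minor allele
  frequency cut-off; SNPs whose estimated MAF is negative in any pool
  (estimate outside [0, 1]) are hard-dropped.
* **hist-filter** -- on a training panel with individual genotypes, the
  variance across pools of (pooled AF - individual AF); its verdict
  list is portable to other panels typed on the same array.

Plus the two tuning metrics used to choose cut-offs: the proportion of
false positives (PFP) among top-ranked SNPs, and the genomic-control
inflation factor lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import ClusterGeometry, PoolAfTable

__all__ = [
    "QcConfig",
    "QcVerdict",
    "fld_score",
    "fld_filter",
    "r_filter",
    "maf_filter",
    "hist_filter",
    "apply_qc",
    "proportion_false_positives",
    "gc_lambda",
    "sweep_filter_cutoffs",
    "rank_snps_by_chi2_discrepancy",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.45493...


@dataclass(frozen=True)
class QcConfig:
    """Filter cut-offs.

    ``r_ratio_min`` / ``r_pass_fraction`` follow the published tuning
    (cut-off 0.8 with an 80% pass rate, i.e. 11 of 13 replicates).
    ``fld_min`` and ``hist_var_max`` have no published values; the
    defaults here were fixed once by the packaged tuning utilities
    (:func:`sweep_filter_cutoffs`) on a synthetic calibration panel.
    """

    fld_min: float = 10.0
    r_ratio_min: float = 0.8
    r_pass_fraction: float = 0.8
    maf_min: float = 0.05
    hist_var_max: float = 2e-3

    def __post_init__(self):
        if not 0 <= self.r_pass_fraction <= 1:
            raise ValueError("r_pass_fraction must lie in [0, 1]")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.fld_min < 0 or self.r_ratio_min < 0 or self.hist_var_max < 0:
            raise ValueError("cut-offs must be non-negative")


@dataclass
class QcVerdict:
    """Per-SNP pass/fail table; overall pass iff all applied filters pass."""

    table: pd.DataFrame  # snp_id, fld, fld_pass, r_pass_count, n_replicates,
    # r_pass, maf, maf_pass, hard_drop, hist_var, hist_pass, qc_pass, reasons
    config: QcConfig

    @property
    def passing_snps(self) -> np.ndarray:
        return self.table.loc[self.table["qc_pass"], "snp_id"].to_numpy()


def _fld_pair(mu1, cov1, mu2, cov2):
    """Vectorized 2-D Fisher's linear discriminant between cluster pairs.

    FLD = dmu^T (S1 + S2)^-1 dmu, the maximum over projection directions
    of (projected mean separation)^2 / (sum of projected variances).
    Covariances are given as (n, 3) [cxx, cxy, cyy] triples.
    """
    d = np.asarray(mu2, float) - np.asarray(mu1, float)
    s = np.asarray(cov1, float) + np.asarray(cov2, float)
    det = s[:, 0] * s[:, 2] - s[:, 1] ** 2
    det = np.where(det <= 0, np.nan, det)
    # (S^-1 d) via the 2x2 adjugate.
    ix = (s[:, 2] * d[:, 0] - s[:, 1] * d[:, 1]) / det
    iy = (-s[:, 1] * d[:, 0] + s[:, 0] * d[:, 1]) / det
    return d[:, 0] * ix + d[:, 1] * iy


def fld_score(geometry: ClusterGeometry) -> np.ndarray:
    """Minimum FLD over the adjacent genotype-cluster pairs, per SNP."""
    aa, ab, bb = (geometry.centroids[:, g, :] for g in range(3))
    c_aa, c_ab, c_bb = (geometry.covariances[:, g, :] for g in range(3))
    f1 = _fld_pair(aa, c_aa, ab, c_ab)
    f2 = _fld_pair(ab, c_ab, bb, c_bb)
    return np.fmin(f1, f2)  # fmin: a missing pair falls back to the other


def fld_filter(geometry: ClusterGeometry, fld_min: float):
    """FLD scores and pass flags (score >= cut-off)."""
    score = fld_score(geometry)
    return score, np.nan_to_num(score, nan=-1.0) >= fld_min


def r_filter(r_ratios, r_ratio_min: float = 0.8, r_pass_fraction: float = 0.8) -> bool:
    """Pass iff >= ceil(fraction * n) replicates have r/r' >= cut-off.

    ``r_ratios`` pools together every replicate of every pool for one
    SNP; with 13 replicates at the default fraction, 11 must pass.
    """
    rr = np.asarray(r_ratios, dtype=float)
    if rr.size == 0:
        raise ValueError("no replicates")
    need = math.ceil(r_pass_fraction * rr.size)
    return int(np.sum(rr >= r_ratio_min)) >= need


def maf_filter(pool_afs, pool_sizes, maf_min: float = 0.05):
    """Panel-wide MAF cut-off with a hard drop for negative estimates.

    ``pool_afs`` is an (n_snps, n_pools) array of per-pool AF estimates,
    ``pool_sizes`` the per-pool individual counts.  Returns
    ``(maf, passed, hard_drop)``; a SNP whose estimate leaves [0, 1] in
    any pool (negative MAF) is hard-dropped regardless of the cut-off.
    """
    afs = np.atleast_2d(np.asarray(pool_afs, dtype=float))
    w = np.asarray(pool_sizes, dtype=float)
    w = w / w.sum()
    total = afs @ w
    maf = np.minimum(total, 1.0 - total)
    per_pool_maf = np.minimum(afs, 1.0 - afs)
    hard_drop = np.any(per_pool_maf < 0, axis=1) | np.any(np.isnan(afs), axis=1)
    passed = (maf >= maf_min) & ~hard_drop
    return maf, passed, hard_drop


def hist_filter(pooled_afs, individual_afs, hist_var_max: float):
    """Consistency of pooled AF against individual-genotype AF.

    Both inputs are (n_snps, n_pools) on a training panel with >= 2
    pools.  The score is the variance across pools of
    (pooled AF - individual AF); small variance means the pooled
    estimate tracks the truth consistently.  Returns (score, passed).
    """
    pooled = np.atleast_2d(np.asarray(pooled_afs, dtype=float))
    indiv = np.atleast_2d(np.asarray(individual_afs, dtype=float))
    if pooled.shape != indiv.shape:
        raise ValueError("pooled and individual AF tables must align")
    if pooled.shape[1] < 2:
        raise ValueError("hist-filter needs >= 2 pools")
    diff = pooled - indiv
    score = np.var(diff, axis=1, ddof=1)
    return score, np.nan_to_num(score, nan=np.inf) <= hist_var_max


def apply_qc(
    geometry: ClusterGeometry,
    pool_af: PoolAfTable,
    pool_sizes: dict,
    config: QcConfig = QcConfig(),
    individual_afs: pd.DataFrame | None = None,
    hist_verdict: pd.Series | None = None,
) -> QcVerdict:
    """Run every applicable filter and combine verdicts.

    ``individual_afs`` (SNP x pool, training panel) enables the
    hist-filter; alternatively a portable ``hist_verdict`` (bool Series
    indexed by snp_id, trained elsewhere) may be supplied.  SNPs with
    unusable cluster geometry fail QC outright.
    """
    af_mat = pool_af.af_matrix()
    snp_ids = af_mat.index.to_numpy()
    idx = geometry.indexer(snp_ids)
    fld, fld_pass = fld_filter(geometry, config.fld_min)
    fld, fld_pass = fld[idx], fld_pass[idx]

    rr = pool_af.replicates.groupby("snp_id", sort=True)["r_ratio"]
    r_count = rr.apply(lambda a: int(np.sum(np.asarray(a) >= config.r_ratio_min)))
    n_rep = rr.size()
    need = np.ceil(config.r_pass_fraction * n_rep.to_numpy()).astype(int)
    r_pass = pd.Series(r_count.to_numpy() >= need, index=r_count.index).reindex(
        snp_ids, fill_value=False
    )
    r_count = r_count.reindex(snp_ids, fill_value=0)
    n_rep = n_rep.reindex(snp_ids, fill_value=0)

    sizes = np.array([pool_sizes[p] for p in af_mat.columns])
    maf, maf_pass, hard_drop = maf_filter(af_mat.to_numpy(), sizes, config.maf_min)

    if individual_afs is not None:
        indiv = individual_afs.reindex(index=af_mat.index, columns=af_mat.columns)
        hist_var, hist_pass = hist_filter(af_mat.to_numpy(), indiv.to_numpy(), config.hist_var_max)
    elif hist_verdict is not None:
        hist_var = np.full(len(snp_ids), np.nan)
        hist_pass = hist_verdict.reindex(snp_ids, fill_value=True).to_numpy(dtype=bool)
    else:
        hist_var = np.full(len(snp_ids), np.nan)
        hist_pass = np.ones(len(snp_ids), dtype=bool)

    geom_ok = geometry.ok[idx]
    overall = fld_pass & r_pass.to_numpy() & maf_pass & ~hard_drop & hist_pass & geom_ok
    reasons = []
    for i in range(len(snp_ids)):
        r = []
        if not geom_ok[i]:
            r.append(f"geometry:{geometry.reason[idx[i]]}")
        if not fld_pass[i]:
            r.append("fld")
        if not r_pass.iloc[i]:
            r.append("r-ratio")
        if hard_drop[i]:
            r.append("negative-maf")
        elif not maf_pass[i]:
            r.append("maf")
        if not hist_pass[i]:
            r.append("hist")
        reasons.append(";".join(r))
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "fld": fld,
            "fld_pass": fld_pass,
            "r_pass_count": r_count.to_numpy(),
            "n_replicates": n_rep.to_numpy(),
            "r_pass": r_pass.to_numpy(),
            "maf": maf,
            "maf_pass": maf_pass,
            "hard_drop": hard_drop,
            "hist_var": hist_var,
            "hist_pass": hist_pass,
            "qc_pass": overall,
            "reasons": reasons,
        }
    )
    return QcVerdict(table=table, config=config)


def proportion_false_positives(pooled_p, expected_p, top_fraction: float = 0.0005) -> float:
    """Share of top-ranked pooled-test SNPs that are expected-null.

    The top set is the ``top_fraction`` of SNPs with the smallest
    pooled P-values; a member counts as a false positive when its
    expected (individual-genotyping) P-value exceeds 0.05.
    """
    pooled_p = np.asarray(pooled_p, dtype=float)
    expected_p = np.asarray(expected_p, dtype=float)
    if pooled_p.shape != expected_p.shape:
        raise ValueError("P-value vectors must align on the same SNPs")
    k = int(len(pooled_p) * top_fraction)
    if k < 1:
        raise ValueError("top set is empty; increase top_fraction or the SNP count")
    top = np.argsort(pooled_p, kind="stable")[:k]
    return float(np.mean(expected_p[top] > 0.05))


def gc_lambda(chi2_stats) -> float:
    """Genomic-control inflation factor: median chi^2 over the chi^2_1 median."""
    x = np.asarray(chi2_stats, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no test statistics")
    return float(np.median(x) / CHI2_1_MEDIAN)


def sweep_filter_cutoffs(values, cutoffs, metric, higher_passes=True) -> pd.DataFrame:
    """Tuning sweep: retained count and a quality metric per cut-off.

    ``metric`` maps a boolean keep-mask to a scalar (e.g. a PFP or a GC
    lambda computed on the retained SNPs).  ``higher_passes`` selects the
    pass direction (>= cut-off for FLD/MAF, <= for the hist-filter).
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for c in cutoffs:
        keep = values >= c if higher_passes else values <= c
        rows.append({"cutoff": c, "n_retained": int(keep.sum()), "metric": metric(keep)})
    return pd.DataFrame(rows)


def rank_snps_by_chi2_discrepancy(chi2_pooled, chi2_individual, n: int = 200) -> dict:
    """Diagnostic: worst/best SNP sets by pooled-vs-individual chi^2 gap.

    "Worst" are the ``n`` SNPs with the largest |pooled - individual|
    corrected-statistic difference; "best" are the ``n`` with the
    smallest gap among the most significant individual statistics.
    Used to choose filter families during training, not as a filter.
    """
    cp = np.asarray(chi2_pooled, dtype=float)
    ci = np.asarray(chi2_individual, dtype=float)
    gap = np.abs(cp - ci)
    worst = np.argsort(-gap, kind="stable")[:n]
    strong = np.argsort(-ci, kind="stable")[: max(n * 5, n)]
    best = strong[np.argsort(gap[strong], kind="stable")[:n]]
    return {"worst": worst, "best": best}
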