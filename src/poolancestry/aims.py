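"""Ancestry-informative-marker discovery with a pooling-deflated chi-square.

A pooled panel ("case") is compared per SNP against its
pseudopopulation or another reference ("control").  Because pooled
allele counts are *estimated*, the naive allele-count chi-square is
inflated by the pooling error; the statistic is deflated by the ratio
of the binomial sampling variance V to the total variance:

    chi2_corrected = chi2_naive * V / (V + var(e_case) + var(e_control))

where V = p_case(1-p_case)/(2 n_case) + p_control(1-p_control)/(2 n_control)
and the var(e) terms are the squared standard errors of the pooled AF
estimates (zero for a pseudopopulation by construction).  Genomic
control rescales the corrected statistics by the inflation factor
lambda (floored at 1) before converting to P-values.

Downstream of the test: LD-based categorization of each SNP by the
P-values of its neighbors (encouraging / inconclusive / discouraging),
a corrected allele-frequency difference read back from the deflated
statistic, distance-based pruning to an independent marker panel, and
the two candidate selection lists used for validation genotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import gc_lambda

__all__ = [
    "VarianceComponents",
    "sampling_variance",
    "pooled_error_variance",
    "weighted_pool_af",
    "corrected_chi2",
    "gc_correct",
    "corrected_af_difference",
    "ld_neighbors",
    "categorize",
    "prune_by_distance",
    "select_candidates",
    "aim_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    """Variance budget of one case/control AF comparison (AF^2 units)."""

    v: float  # binomial sampling variance, case + control
    var_e_case: float
    var_e_control: float
    n_case: int
    n_control: int

    def __post_init__(self):
        if min(self.v, self.var_e_case, self.var_e_control) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def total(self) -> float:
        return self.v + self.var_e_case + self.var_e_control

    @property
    def deflation(self) -> float:
        return self.v / self.total if self.total > 0 else 1.0


def sampling_variance(p_case, n_case, p_control, n_control):
    """Binomial sampling variance V of the case-control AF difference.

    V = p_case q_case / (2 n_case) + p_control q_control / (2 n_control),
    with n counted in individuals (2n chromosomes).  AFs are clipped to
    [0, 1] here; negative-MAF exclusion happens in the test itself.
    """
    if np.any(np.asarray(n_case) <= 0) or np.any(np.asarray(n_control) <= 0):
        raise ValueError("pool sizes must be positive")
    pc = np.clip(np.asarray(p_case, dtype=float), 0.0, 1.0)
    pt = np.clip(np.asarray(p_control, dtype=float), 0.0, 1.0)
    return pc * (1 - pc) / (2 * np.asarray(n_case)) + pt * (1 - pt) / (2 * np.asarray(n_control))


def weighted_pool_af(pool_afs, pool_sizes):
    """Total AF over pools: average weighted by individuals per pool."""
    afs = np.atleast_2d(np.asarray(pool_afs, dtype=float))
    w = np.asarray(pool_sizes, dtype=float)
    w = w / w.sum()
    return afs @ w


def pooled_error_variance(pool_ses, pool_sizes):
    """Pooling error variance of the weighted-mean AF across pools.

    var(e_tot) = sum_i w_i^2 SE_i^2 with w_i = n_i / sum(n); SE_i is the
    replicate standard error of pool i.  ``pool_ses`` may be a vector
    (one SNP) or an (n_snps, n_pools) array.  A pseudopopulation has no
    pooling error; pass var 0 downstream instead of calling this.
    """
    ses = np.atleast_2d(np.asarray(pool_ses, dtype=float))
    if np.any(np.isnan(ses)):
        raise ValueError("missing replicate SE (single-replicate pool?)")
    w = np.asarray(pool_sizes, dtype=float)
    w = w / w.sum()
    out = (ses**2) @ (w**2)
    return out if out.size > 1 else float(out[0])


def _naive_chi2(p_case, p_control, n_case, n_control):
    """Pearson chi-square of the 2x2 estimated allele-count table (1 df)."""
    m_case = 2.0 * np.asarray(n_case, dtype=float)
    m_ctrl = 2.0 * np.asarray(n_control, dtype=float)
    pc = np.asarray(p_case, dtype=float)
    pt = np.asarray(p_control, dtype=float)
    pbar = (m_case * pc + m_ctrl * pt) / (m_case + m_ctrl)
    denom = pbar * (1 - pbar) * (1.0 / m_case + 1.0 / m_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (pc - pt) ** 2 / denom
    return np.where(pc == pt, 0.0, chi2)


def corrected_chi2(p_case, p_control, n_case, n_control, var_e_case=0.0, var_e_control=0.0):
    """Naive and pooling-deflated chi-square statistics, vectorized.

    Returns ``(naive, corrected, excluded)`` where ``excluded`` marks
    SNPs with an estimated MAF below 0 in either group (AF outside
    [0, 1]); their statistics are NaN and the reason is "negative-MAF".
    The deflation factor V / (V + var_e_case + var_e_control) never
    exceeds 1, so corrected <= naive everywhere.
    """
    pc = np.asarray(p_case, dtype=float)
    pt = np.asarray(p_control, dtype=float)
    excluded = (np.minimum(pc, 1 - pc) < 0) | (np.minimum(pt, 1 - pt) < 0)
    excluded |= np.isnan(pc) | np.isnan(pt)
    naive = _naive_chi2(np.clip(pc, 0, 1), np.clip(pt, 0, 1), n_case, n_control)
    v = sampling_variance(pc, n_case, pt, n_control)
    total = v + np.asarray(var_e_case, dtype=float) + np.asarray(var_e_control, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        deflation = np.where(total > 0, v / total, 1.0)
    corrected = naive * deflation
    naive = np.where(excluded, np.nan, naive)
    corrected = np.where(excluded, np.nan, corrected)
    return naive, corrected, excluded


def gc_correct(chi2_stats, lam: float | None = None):
    """Genomic-control P-values: upper tail of chi2_1 at statistic / lambda.

    ``lam`` defaults to the inflation factor of the supplied vector and
    is floored at 1 so the correction is never anti-conservative.
    Returns ``(p_values, lambda_used)``.
    """
    x = np.asarray(chi2_stats, dtype=float)
    if lam is None:
        lam = gc_lambda(x)
    lam = max(float(lam), 1.0)
    return stats.chi2.sf(x / lam, df=1), lam


def corrected_af_difference(corrected, v, raw_diff):
    """Signed AF difference implied by the deflated statistic.

    |dAF| = sqrt(chi2_corrected * V), signed by the raw pooled-minus-
    control difference and capped at |raw| so the correction only ever
    shrinks the estimate.  This fixes the control (pseudopopulation) AF
    and moves the pooled AF in the observed direction by the amount the
    deflated evidence supports.
    """
    corrected = np.asarray(corrected, dtype=float)
    raw = np.asarray(raw_diff, dtype=float)
    mag = np.sqrt(np.maximum(corrected, 0.0) * np.asarray(v, dtype=float))
    return np.sign(raw) * np.minimum(mag, np.abs(raw))


def ld_neighbors(
    genotypes,
    snp_ids,
    chrom,
    pos,
    window: int = 20_000_000,
    r2_min: float = 0.5,
) -> dict:
    """Per-SNP LD neighbor lists from a reference genotype matrix.

    ``genotypes`` is (n_individuals, n_snps) dosage 0/1/2 aligned with
    ``snp_ids``/``chrom``/``pos``.  Neighbors are other SNPs on the same
    chromosome within ``window`` bp (boundary included) whose squared
    genotype correlation exceeds ``r2_min``.  Monomorphic SNPs have
    undefined r2 and never qualify.
    """
    g = np.asarray(genotypes, dtype=float)
    snp_ids = np.asarray(snp_ids)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(snp_ids)
    sd = g.std(axis=0)
    gc = g - g.mean(axis=0)
    out = {s: [] for s in snp_ids}
    order = np.lexsort((pos, chrom))
    for a_i in range(n):
        i = order[a_i]
        for a_j in range(a_i + 1, n):
            j = order[a_j]
            if chrom[j] != chrom[i] or pos[j] - pos[i] > window:
                break
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.dot(gc[:, i], gc[:, j]) / (len(g) * sd[i] * sd[j])
            if r * r > r2_min:
                out[snp_ids[i]].append(snp_ids[j])
                out[snp_ids[j]].append(snp_ids[i])
    return out


def categorize(neighbor_p_values) -> str:
    """LD-support category of a SNP from its neighbors' GC-corrected P.

    encouraging: at least one neighbor with P < 0.05 AND at least half
    of the neighbors with P < 0.1; discouraging: no neighbor with
    P < 0.1; inconclusive otherwise, including SNPs with no neighbors.
    """
    p = np.asarray(neighbor_p_values, dtype=float)
    if p.size == 0:
        return "inconclusive"
    if np.any(p < 0.05) and np.sum(p < 0.1) >= p.size / 2.0:
        return "encouraging"
    if not np.any(p < 0.1):
        return "discouraging"
    return "inconclusive"


def prune_by_distance(records: pd.DataFrame, min_separation: int = 4_000_000) -> pd.DataFrame:
    """Greedy distance pruning to an independent AIM panel.

    Only non-discouraging SNPs enter.  Repeatedly keep the SNP with the
    smallest GC-corrected P and drop any other SNP on the same
    chromosome closer than ``min_separation`` bp.  Returns the records
    with a boolean ``kept`` column (False for discouraging SNPs too).
    """
    rec = records.reset_index(drop=True).copy()
    chrom = rec["chrom"].to_numpy()
    pos = rec["pos"].to_numpy()
    eligible = (rec["category"] != "discouraging").to_numpy()
    order = rec[eligible].sort_values(["gc_p", "snp_id"], kind="stable").index.to_numpy()
    kept = np.zeros(len(rec), dtype=bool)
    removed = np.zeros(len(rec), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        kept[i] = True
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) < min_separation)
        near[i] = False
        removed |= near
    rec["kept"] = kept
    return rec


def select_candidates(
    records: pd.DataFrame,
    ld_p_filtered: dict,
    ld_p_unfiltered: dict,
    list_size: int = 25,
    p_threshold: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two candidate AIM lists used for validation genotyping.

    List 1: the ``list_size`` smallest GC-corrected P-values among SNPs
    not categorized discouraging under either the filtered or the
    unfiltered LD set.  List 2: SNPs with P < ``p_threshold``, at least
    two unfiltered LD neighbors, and an encouraging categorization
    under both LD sets, ranked by the number of LD neighbors with
    P < 0.05 (ties broken by smaller P, then snp_id).  ``ld_p_*`` map
    snp_id -> array of neighbor GC-corrected P-values.  Shorter lists
    than requested are returned (and logged) when few SNPs qualify.
    """
    rec = records.copy()
    empty = np.array([])
    cat_f = {s: categorize(ld_p_filtered.get(s, empty)) for s in rec["snp_id"]}
    cat_u = {s: categorize(ld_p_unfiltered.get(s, empty)) for s in rec["snp_id"]}
    not_disc = rec["snp_id"].map(
        lambda s: cat_f[s] != "discouraging" and cat_u[s] != "discouraging"
    )
    list1 = (
        rec.loc[not_disc]
        .sort_values(["gc_p", "snp_id"], kind="stable")
        .head(list_size)
        .copy()
    )
    if len(list1) < list_size:
        logger.info("candidate list 1 short: %d of %d", len(list1), list_size)

    n_neighbors = rec["snp_id"].map(lambda s: len(ld_p_unfiltered.get(s, empty)))
    n_sig = rec["snp_id"].map(
        lambda s: int(np.sum(np.asarray(ld_p_unfiltered.get(s, empty)) < 0.05))
    )
    both_enc = rec["snp_id"].map(
        lambda s: cat_f[s] == "encouraging" and cat_u[s] == "encouraging"
    )
    eligible = (rec["gc_p"] < p_threshold) & (n_neighbors >= 2) & both_enc
    list2 = rec.loc[eligible].copy()
    list2["n_ld_significant"] = n_sig[eligible]
    list2 = (
        list2.sort_values(
            ["n_ld_significant", "gc_p", "snp_id"],
            ascending=[False, True, True],
            kind="stable",
        )
        .head(list_size)
    )
    if len(list2) < list_size:
        logger.info("candidate list 2 short: %d of %d", len(list2), list_size)
    return list1, list2


def aim_scan(
    snp_table: pd.DataFrame,
    p_case,
    n_case,
    p_control,
    n_control,
    var_e_case=0.0,
    var_e_control=0.0,
    ld_neighbor_map: dict | None = None,
    prune: bool = True,
    min_separation: int = 4_000_000,
) -> pd.DataFrame:
    """Full per-SNP AIM scan; returns the AIM record table.

    ``snp_table`` needs snp_id, chrom, pos aligned with the AF vectors.
    Produces naive/corrected chi2, GC-corrected P, category (from
    ``ld_neighbor_map``, inconclusive when absent), the corrected signed
    AF difference, and the pruning ``kept`` flag (all True when
    ``prune`` is off -- the reuse-existing-genotypes exception).
    """
    pc = np.asarray(p_case, dtype=float)
    pt = np.asarray(p_control, dtype=float)
    naive, corrected, excluded = corrected_chi2(
        pc, pt, n_case, n_control, var_e_case, var_e_control
    )
    if excluded.any():
        logger.info("aim_scan: %d SNPs dropped for negative MAF", int(excluded.sum()))
    rec = snp_table[["snp_id", "chrom", "pos"]].copy().reset_index(drop=True)
    rec["p_case"] = pc
    rec["p_control"] = pt
    rec["naive_chi2"] = naive
    rec["corrected_chi2"] = corrected
    rec["excluded"] = excluded
    ok = ~excluded
    gc_p = np.full(len(rec), np.nan)
    gc_p[ok], lam = gc_correct(corrected[ok])
    rec["gc_p"] = gc_p
    rec.attrs["gc_lambda"] = lam
    v = sampling_variance(pc, n_case, pt, n_control)
    rec["corrected_af_diff"] = corrected_af_difference(corrected, v, pc - pt)
    if ld_neighbor_map is not None:
        pmap = dict(zip(rec["snp_id"], gc_p))
        rec["category"] = [
            categorize([pmap[n] for n in ld_neighbor_map.get(s, []) if n in pmap])
            for s in rec["snp_id"]
        ]
    else:
        rec["category"] = "inconclusive"
    rec.loc[excluded, "category"] = "discouraging"  # never select excluded SNPs
    rec = rec[~rec["gc_p"].isna() | excluded]
    if prune:
        rec = prune_by_distance(rec, min_separation=min_separation)
    else:
        rec["kept"] = rec["category"] != "discouraging"
    return rec.reset_index(drop=True)
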