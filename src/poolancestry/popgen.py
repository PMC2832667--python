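"""Panel and population evaluation: F_ST, PCA, and the null AF-difference bound.

Utilities for judging how well a pooled panel matches its
pseudopopulation and how informative a selected AIM panel is:

* multi-locus F_ST between allele-frequency vectors (Hudson
  ratio-of-averages by default, naive Wright as an option);
* PCA of genotype matrices with Patterson normalization and iterative
  outlier removal, the standard stratification workflow;
* correlation of a small-panel ancestry axis with the genome-wide
  ("true") axis;
* the null simulation bounding how large a sample-vs-expected AF
  deviation pure sampling noise can produce across a genome-wide SNP
  set -- the yardstick separating real AIMs from noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PcaResult",
    "fst",
    "pca_with_outlier_removal",
    "axis_correlation",
    "null_max_afdiff_sim",
]


def fst(af_a, af_b, n_a=None, n_b=None, method: str = "hudson") -> float:
    """Multi-locus F_ST between two allele-frequency vectors.

    ``method="hudson"`` (default) is the ratio-of-averages estimator:
    mean over loci of (p1-p2)^2 minus within-population sampling terms
    (when haploid sample sizes ``n_a``/``n_b`` are given), over the mean
    of p1(1-p2) + p2(1-p1).  ``method="wright"`` is the naive
    1 - mean(H_S)/mean(H_T).  Tiny negative estimates are clamped to 0.
    """
    p1 = np.asarray(af_a, dtype=float)
    p2 = np.asarray(af_b, dtype=float)
    if p1.size == 0 or p1.shape != p2.shape:
        raise ValueError("need two aligned, non-empty AF vectors")
    if method == "hudson":
        num = (p1 - p2) ** 2
        if n_a is not None:
            num = num - p1 * (1 - p1) / (n_a - 1)
        if n_b is not None:
            num = num - p2 * (1 - p2) / (n_b - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if np.mean(den) == 0:
            return 0.0
        f = float(np.mean(num) / np.mean(den))
    elif method == "wright":
        hs = p1 * (1 - p1) + p2 * (1 - p2)
        pbar = 0.5 * (p1 + p2)
        ht = 2 * pbar * (1 - pbar)
        if np.mean(ht) == 0:
            return 0.0
        f = 1.0 - float(np.mean(hs) / np.mean(ht))
    else:
        raise ValueError(f"unknown F_ST method {method!r}")
    return float(np.clip(f, 0.0, 1.0))


@dataclass
class PcaResult:
    """Principal components of a genotype matrix after outlier removal."""

    coords: np.ndarray  # (n_kept, k) individual coordinates
    eigenvalues: np.ndarray  # length k, non-increasing
    kept: np.ndarray  # indices into the original individuals
    removed_per_iteration: list  # original indices removed at each pass


def _patterson_pca(g: np.ndarray, k: int):
    """Top-k PCA of 0/1/2 genotypes with Patterson normalization."""
    p = g.mean(axis=0) / 2.0
    var = p * (1 - p)
    keep = var > 0
    z = (g[:, keep] - 2 * p[keep]) / np.sqrt(var[keep])
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(k, len(s))
    coords = u[:, :k] * s[:k]
    eigvals = s[:k] ** 2 / max(g.shape[0] - 1, 1)
    return coords, eigvals


def pca_with_outlier_removal(
    genotypes, k: int = 10, sd_threshold: float = 6.0, max_iter: int = 5
) -> PcaResult:
    """PCA with iterative removal of individuals extreme on any top axis.

    Individuals more than ``sd_threshold`` standard deviations from the
    mean along any of the top ``k`` axes are removed and the
    decomposition recomputed, up to ``max_iter`` times or until stable.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] <= k:
        k = max(1, g.shape[0] - 1)
    kept = np.arange(g.shape[0])
    removed_log = []
    coords = eigvals = None
    for _ in range(max_iter + 1):
        coords, eigvals = _patterson_pca(g[kept], k)
        z = (coords - coords.mean(axis=0)) / coords.std(axis=0, ddof=0)
        outlier = np.any(np.abs(z) > sd_threshold, axis=1)
        if not outlier.any():
            break
        removed_log.append(kept[outlier])
        kept = kept[~outlier]
    return PcaResult(
        coords=coords, eigenvalues=eigvals, kept=kept, removed_per_iteration=removed_log
    )


def axis_correlation(axis_a, axis_b) -> float:
    """|Pearson r| between two ancestry axes (eigenvector sign is arbitrary)."""
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("axes must cover the same individuals")
    return float(abs(stats.pearsonr(a, b).statistic))


def null_max_afdiff_sim(
    n_snps,
    n_individuals,
    proportions,
    seed,
    reference_afs=None,
    af_range=(0.05, 0.95),
) -> float:
    """Largest sample-vs-expected AF deviation under pure sampling noise.

    Per SNP the mixture AF is sum_j beta_j p_j over the reference
    populations; a cohort of ``n_individuals`` diploids contributes an
    allele count ~ Binomial(2n, mixture AF).  Returns the maximum over
    SNPs of |sample AF - mixture AF|.  ``reference_afs`` may supply an
    (n_snps, n_pops) matrix; otherwise per-population AFs are drawn
    uniformly on ``af_range``.
    """
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if reference_afs is None:
        reference_afs = rng.uniform(af_range[0], af_range[1], size=(n_snps, len(props)))
    mix = np.asarray(reference_afs, dtype=float) @ props
    m = 2 * n_individuals
    counts = rng.binomial(m, mix)
    return float(np.max(np.abs(counts / m - mix)))
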