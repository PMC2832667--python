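"""Synthetic data with known ground truth for the pooled-ancestry pipeline.

Generates every input the pipeline consumes:

* reference-panel allele frequencies drifted from shared ancestral
  frequencies under the Balding-Nichols Beta model;
* admixed diploid genotypes, each allele copy drawn from a source
  population chosen with the admixture proportions;
* per-SNP bivariate intensity-cluster models (AA/AB/BB centroids and
  covariances) with configurable rotation and allelic-intensity
  imbalance, constructed so that the polar transform recovers the
  simulated allele frequency exactly at zero noise;
* noisy pooled replicate intensity points, with an optional corrupt-SNP
  mode (collapsed clusters, off-radius hybridization, inconsistent
  replicates) to exercise the QC filters.

An optional "missing ancestry" population contributes the shortfall
1 - sum(admixture_proportions).  Its ancestral frequencies are drawn
independently of the reference populations' shared ancestral draw, so
that the unexplained component is orthogonal to the reference panels
and surfaces as a reduced summed admixture proportion plus an intercept
of about half its weight in the regression stage.

All randomness flows from ``SimConfig.seed`` through spawned
``numpy.random`` generators; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intensity import ClusterGeometry

__all__ = [
    "SimConfig",
    "SimStudy",
    "simulate_reference_afs",
    "simulate_admixed_genotypes",
    "simulate_cluster_models",
    "simulate_cluster_model",
    "simulate_pool_replicates",
    "simulate_ld_blocks",
    "simulate_study",
]

CORRUPT_MODES = ("collapsed", "low-radius", "noisy")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: pools of
    a few hundred individuals hybridized in triplicate, a two-way
    African/European-like admixture of 0.82/0.18, reference panels of 60
    individuals drifted at F = 0.15 from a shared ancestral population,
    and per-replicate allele-frequency noise of 0.02.
    """

    n_snps: int = 20_000
    n_individuals: int = 250  # per pool
    n_pools: int = 2
    n_replicates: int = 3  # per pool
    admixture_proportions: tuple[float, ...] = (0.82, 0.18)
    drift_fst: tuple[float, ...] = (0.15, 0.15)
    missing_drift_fst: float = 0.15
    ref_sample_sizes: tuple[int, ...] = (60, 60)
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    pool_noise_sd: float = 0.02  # AF-scale, per replicate
    radial_noise_sd: float = 0.03  # relative radius, per replicate
    intensity_noise: float = 1.0  # scales cluster covariances
    allelic_imbalance_range: tuple[float, float] = (0.8, 1.25)
    corrupt_fraction: float = 0.0
    n_chromosomes: int = 22
    chrom_length: int = 135_000_000
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.admixture_proportions, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or p.sum() > 1 + 1e-12:
            raise ValueError("admixture proportions must lie in [0,1] and sum to <= 1")
        f = np.asarray(self.drift_fst, dtype=float)
        if len(f) != len(p):
            raise ValueError("drift_fst must match admixture_proportions in length")
        if np.any(f < 0) or np.any(f >= 1) or not 0 <= self.missing_drift_fst < 1:
            raise ValueError("drift F values must lie in [0, 1)")
        lo, hi = self.ancestral_af_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_af_range must be an interval within (0, 1)")
        if len(self.ref_sample_sizes) != len(p):
            raise ValueError("ref_sample_sizes must match admixture_proportions")
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must lie in [0, 1]")
        if self.n_replicates < 1 or self.n_pools < 1 or self.n_snps < 1:
            raise ValueError("counts must be positive")

    @property
    def missing_weight(self) -> float:
        return float(1.0 - sum(self.admixture_proportions))

    def rng_streams(self, n: int):
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def _balding_nichols(ancestral: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Population AFs drifted from ancestral frequencies at fixation index f."""
    if f == 0:
        return ancestral.copy()
    scale = (1.0 - f) / f
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def _positions(n_snps: int, n_chrom: int, chrom_length: int, rng: np.random.Generator):
    """Assign SNPs to chromosomes with roughly even spacing plus jitter."""
    chrom = np.repeat(np.arange(1, n_chrom + 1), int(np.ceil(n_snps / n_chrom)))[:n_snps]
    pos = np.empty(n_snps, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        m = chrom == c
        k = int(m.sum())
        if k == 0:
            continue
        spacing = chrom_length / (k + 1)
        base = spacing * (1 + np.arange(k))
        jitter = rng.uniform(-0.4, 0.4, size=k) * spacing
        pos[m] = np.maximum(1, (base + jitter).astype(np.int64))
    return chrom, pos


def simulate_reference_afs(config: SimConfig):
    """Draw ancestral + drifted per-population AFs and the truth table.

    Returns ``(afs, truth)`` where ``afs`` is an (n_snps, n_pops) array
    of reference-population allele frequencies (missing-ancestry
    population last when configured) and ``truth`` is a DataFrame with
    ancestral AF, per-population AF, and the true admixed AF
    ``sum_j beta_j * AF_j`` including any missing-ancestry component.
    """
    rng_anc, rng_drift, rng_pos = config.rng_streams(3)
    lo, hi = config.ancestral_af_range
    ancestral = rng_anc.uniform(lo, hi, size=config.n_snps)
    cols = {}
    afs = []
    for j, f in enumerate(config.drift_fst):
        aj = _balding_nichols(ancestral, f, rng_drift)
        afs.append(aj)
        cols[f"af_pop{j + 1}"] = aj
    props = list(config.admixture_proportions)
    if config.missing_weight > 1e-12:
        # Independent ancestral draw: the unexplained component must not be
        # predictable from the reference panels (see module docstring).
        anc_miss = rng_anc.uniform(lo, hi, size=config.n_snps)
        a_miss = _balding_nichols(anc_miss, config.missing_drift_fst, rng_drift)
        afs.append(a_miss)
        cols["af_missing"] = a_miss
        props.append(config.missing_weight)
    af_mat = np.column_stack(afs)
    true_admixed = af_mat @ np.asarray(props)
    chrom, pos = _positions(config.n_snps, config.n_chromosomes, config.chrom_length, rng_pos)
    truth = pd.DataFrame(
        {
            "snp_id": [f"snp{i:07d}" for i in range(config.n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ancestral_af": ancestral,
            **cols,
            "true_admixed_af": true_admixed,
        }
    )
    return af_mat, truth


def simulate_admixed_genotypes(afs, proportions, n_individuals, rng, chunk=200_000_000):
    """Diploid genotypes (copies of allele A) for an admixed cohort.

    Each of the two allele copies of each individual at each SNP
    independently selects a source population with the given
    proportions (which must sum to 1) and is then a Bernoulli draw at
    that population's allele frequency.  Returns an
    (n_individuals, n_snps) int8 matrix with entries in {0, 1, 2}.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    afs = np.atleast_2d(np.asarray(afs, dtype=float))
    if afs.shape[0] == 1 and afs.shape[1] == len(proportions):
        pass  # single SNP given as a row
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1 (include the missing-ancestry term)")
    n_snps = afs.shape[0]
    geno = np.zeros((n_individuals, n_snps), dtype=np.int8)
    if n_individuals == 0:
        return geno
    cum = np.cumsum(props)
    # Chunk over SNPs to bound memory on large panels.
    step = max(1, int(chunk // max(1, 2 * n_individuals)))
    for start in range(0, n_snps, step):
        sl = slice(start, min(start + step, n_snps))
        block_afs = afs[sl]  # (m, k)
        for _copy in range(2):
            src = np.searchsorted(cum, rng.random((n_individuals, sl.stop - sl.start)))
            src = np.minimum(src, len(props) - 1)
            p = block_afs[np.arange(block_afs.shape[0])[None, :], src]
            geno[:, sl] += (rng.random(src.shape) < p).astype(np.int8)
    return geno


def _rot_cov(theta_deg, sd_major, sd_minor):
    """(n, 3) [cxx, cxy, cyy] with major axis at theta_deg."""
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    a, b = sd_major**2, sd_minor**2
    cxx = a * c**2 + b * s**2
    cyy = a * s**2 + b * c**2
    cxy = (a - b) * c * s
    return np.column_stack([cxx, cxy, cyy])


def simulate_cluster_models(
    n_snps,
    rng,
    intensity_noise=1.0,
    allelic_imbalance_range=(0.8, 1.25),
    snp_ids=None,
    collapsed_mask=None,
) -> ClusterGeometry:
    """Per-SNP genotype-cluster geometry (centroids + covariances).

    AA clusters lie toward the A-probe axis, BB toward the B-probe axis
    and AB between them; covariance major axes point along the
    centroid-origin direction so the derived cluster angles match the
    construction exactly.  A per-SNP allelic-imbalance factor rescales
    the A-probe coordinate (moving the AB centroid off the 45-degree
    diagonal) to exercise the NF correction.  ``collapsed_mask`` marks
    SNPs whose covariances are inflated 25x ("collapsed" corrupt mode,
    poorly separated clusters).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if snp_ids is None:
        snp_ids = np.array([f"snp{i:07d}" for i in range(n_snps)])
    origin = rng.uniform(30.0, 90.0, size=(n_snps, 2))
    a_aa = rng.uniform(6.0, 22.0, size=n_snps)  # degrees, toward A axis
    a_bb = rng.uniform(68.0, 84.0, size=n_snps)
    r_aa = rng.uniform(1500.0, 2600.0, size=n_snps)
    r_bb = rng.uniform(1500.0, 2600.0, size=n_snps)
    r_ab = rng.uniform(0.85, 1.0, size=n_snps) * 0.5 * (r_aa + r_bb)
    imb = rng.uniform(*allelic_imbalance_range, size=n_snps)

    def _dir(theta_deg):
        t = np.radians(theta_deg)
        return np.stack([np.cos(t), np.sin(t)], axis=1)

    d_aa, d_bb = _dir(a_aa), _dir(a_bb)
    d_ab = d_aa + d_bb
    d_ab /= np.linalg.norm(d_ab, axis=1, keepdims=True)
    cents = np.stack(
        [
            origin + r_aa[:, None] * d_aa,
            origin + r_ab[:, None] * d_ab,
            origin + r_bb[:, None] * d_bb,
        ],
        axis=1,
    )
    # Allelic imbalance: rescale the A-probe (x) coordinate of everything.
    scale = np.stack([imb, np.ones(n_snps)], axis=1)
    cents *= scale[:, None, :]
    radii = np.stack([r_aa, r_ab, r_bb], axis=1)
    covs = np.empty((n_snps, 3, 3))
    sd_scale = np.full(n_snps, float(intensity_noise))
    if collapsed_mask is not None:
        sd_scale = sd_scale * np.where(collapsed_mask, 5.0, 1.0)
    for g in range(3):
        d_g = cents[:, g, :] - origin * scale
        theta_g = np.degrees(np.arctan2(d_g[:, 1], d_g[:, 0]))
        covs[:, g, :] = _rot_cov(
            theta_g,
            0.11 * radii[:, g] * sd_scale,
            0.045 * radii[:, g] * sd_scale,
        )
    return ClusterGeometry(np.asarray(snp_ids), cents, covs)


def simulate_cluster_model(snp_params: dict, seed=0) -> ClusterGeometry:
    """Single-SNP convenience wrapper around :func:`simulate_cluster_models`."""
    return simulate_cluster_models(1, np.random.default_rng(seed), **snp_params)


def _place_points(geometry: ClusterGeometry, idx, af, radius_factor):
    """Intensity points at the angular position of ``af`` for each SNP row."""
    theta = np.radians((1.0 - np.clip(af, -0.2, 1.2)) * 90.0)
    w = (
        np.cos(theta)[:, None] * geometry.xhat[idx]
        + (geometry.nf[idx] * np.sin(theta))[:, None] * geometry.yhat[idx]
    )
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    r = geometry.expected_radius(geometry.snp_id[idx], np.clip(af, 0.0, 1.0))
    return geometry.origin[idx] + (r * radius_factor)[:, None] * w


def simulate_pool_replicates(
    true_af,
    geometry: ClusterGeometry,
    n_replicates,
    noise=0.0,
    seed=0,
    pool_id="pool1",
    radial_noise=0.0,
    corrupt_modes=None,
) -> pd.DataFrame:
    """Replicate intensity points for one pool.

    Each replicate lies at the angular position of ``true_af`` plus
    AF-scale Gaussian noise (sd ``noise``), at the radius an average
    individual sample would show, times ``1 + N(0, radial_noise)``.
    ``corrupt_modes`` is an optional per-SNP array over
    ``{"", "collapsed", "low-radius", "noisy"}``: "low-radius" shrinks
    the radius to 40%, "noisy" adds a shared per-pool AF bias (sd 0.12)
    plus large per-replicate scatter (sd 0.08) so replicates disagree.

    Returns a DataFrame (snp_id, pool_id, replicate_id, x, y).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_af = np.asarray(true_af, dtype=float)
    n = len(true_af)
    if len(geometry) != n:
        raise ValueError("true_af must align with geometry rows")
    idx = np.arange(n)
    modes = np.asarray(corrupt_modes) if corrupt_modes is not None else np.full(n, "")
    noisy = modes == "noisy"
    pool_bias = np.where(noisy, rng.normal(0.0, 0.12, size=n), 0.0)
    radius_base = np.where(modes == "low-radius", 0.4, 1.0)
    frames = []
    for rep in range(n_replicates):
        af = true_af + pool_bias
        if noise > 0:
            af = af + rng.normal(0.0, noise, size=n)
        af = af + np.where(noisy, rng.normal(0.0, 0.08, size=n), 0.0)
        rf = radius_base.copy()
        if radial_noise > 0:
            rf = rf * (1.0 + rng.normal(0.0, radial_noise, size=n))
        pts = _place_points(geometry, idx, af, np.maximum(rf, 0.05))
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": geometry.snp_id,
                    "pool_id": pool_id,
                    "replicate_id": f"rep{rep + 1}",
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ld_blocks(afs, n_individuals, block_size, rho, rng):
    """Genotypes with block-correlation structure for LD-categorization tests.

    SNPs are grouped into consecutive blocks of ``block_size``.  Within a
    block every SNP shares the block anchor's allele frequency, and each
    allele copy is, with probability ``rho``, a copy of the anchor's
    corresponding allele and otherwise an independent Bernoulli draw.
    Pairwise genotype correlation is ~rho^2 between non-anchor SNPs.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    afs = np.asarray(afs, dtype=float)
    n_snps = len(afs)
    geno = np.zeros((n_individuals, n_snps), dtype=np.int8)
    block_af = afs.copy()
    for start in range(0, n_snps, block_size):
        block_af[start : start + block_size] = afs[start]
    for _copy in range(2):
        anchor = rng.random((n_individuals, n_snps)) < block_af[None, :]
        for start in range(0, n_snps, block_size):
            sl = slice(start, min(start + block_size, n_snps))
            anchor[:, sl] = anchor[:, [start]] | np.zeros((1, sl.stop - start), bool)
        fresh = rng.random((n_individuals, n_snps)) < block_af[None, :]
        copy_mask = rng.random((n_individuals, n_snps)) < rho
        geno += np.where(copy_mask, anchor, fresh).astype(np.int8)
    return geno, block_af


@dataclass
class SimStudy:
    """Everything the pipeline consumes, plus ground truth."""

    config: SimConfig
    truth: pd.DataFrame  # per SNP: ancestral/per-pop/true admixed AF, pool sample AFs
    reference_panels: dict  # name -> DataFrame in ReferencePanel layout
    pool_sizes: dict  # pool_id -> n individuals
    geometry: ClusterGeometry
    replicate_points: pd.DataFrame
    corrupt_modes: pd.Series  # per SNP: "" or a CORRUPT_MODES entry
    genotypes: dict = field(default_factory=dict)  # pool_id -> (n_ind, n_snps) int8

    @property
    def pool_ids(self) -> list:
        return sorted(self.pool_sizes)

    def true_pool_af(self, pool_id) -> np.ndarray:
        return self.truth[f"sample_af_{pool_id}"].to_numpy()


def simulate_study(config: SimConfig, keep_genotypes: bool = False) -> SimStudy:
    """Run the full generative model and return every pipeline input.

    Pools are independent samples of ``n_individuals`` admixed diploids;
    each pool's true AF is its sample allele frequency, and replicates
    are placed around it with the configured noise.  A
    ``corrupt_fraction`` of SNPs is assigned one of the corrupt modes
    uniformly at random.
    """
    af_mat, truth = simulate_reference_afs(config)
    streams = config.rng_streams(8)
    rng_geno, rng_clusters, rng_reps, rng_corrupt = streams[3:7]
    props = list(config.admixture_proportions)
    if config.missing_weight > 1e-12:
        props.append(config.missing_weight)
    n = config.n_snps
    modes = np.full(n, "", dtype=object)
    if config.corrupt_fraction > 0:
        bad = rng_corrupt.random(n) < config.corrupt_fraction
        modes[bad] = rng_corrupt.choice(CORRUPT_MODES, size=int(bad.sum()))
    geometry = simulate_cluster_models(
        n,
        rng_clusters,
        intensity_noise=config.intensity_noise,
        allelic_imbalance_range=config.allelic_imbalance_range,
        snp_ids=truth["snp_id"].to_numpy(),
        collapsed_mask=(modes == "collapsed"),
    )
    pool_sizes = {}
    genotypes = {}
    rep_frames = []
    for p in range(config.n_pools):
        pool_id = f"pool{p + 1}"
        geno = simulate_admixed_genotypes(af_mat, props, config.n_individuals, rng_geno)
        sample_af = geno.mean(axis=0) / 2.0
        truth[f"sample_af_{pool_id}"] = sample_af
        pool_sizes[pool_id] = config.n_individuals
        if keep_genotypes:
            genotypes[pool_id] = geno
        rep_frames.append(
            simulate_pool_replicates(
                sample_af,
                geometry,
                config.n_replicates,
                noise=config.pool_noise_sd,
                seed=rng_reps,
                pool_id=pool_id,
                radial_noise=config.radial_noise_sd,
                corrupt_modes=modes,
            )
        )
    panels = {}
    for j, (f, nn) in enumerate(zip(config.drift_fst, config.ref_sample_sizes)):
        panels[f"pop{j + 1}"] = pd.DataFrame(
            {
                "snp_id": truth["snp_id"],
                "chrom": truth["chrom"],
                "pos": truth["pos"],
                "allele_a": "A",
                "allele_b": "B",
                "af": af_mat[:, j],
                "call_rate": 1.0,
                "n": nn,
            }
        )
    return SimStudy(
        config=config,
        truth=truth,
        reference_panels=panels,
        pool_sizes=pool_sizes,
        geometry=geometry,
        replicate_points=pd.concat(rep_frames, ignore_index=True),
        corrupt_modes=pd.Series(modes, index=truth["snp_id"], name="corrupt_mode"),
        genotypes=genotypes,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
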