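"""Pooled allele-frequency estimation by polar transformation of raw intensities.

On a two-allele SNP array each SNP yields a bivariate intensity point
(A-probe signal, B-probe signal).  Individual samples form three genotype
clusters (AA, AB, BB); a pooled sample falls between the homozygote
clusters at an angular position proportional to its allele frequency.
This module turns per-SNP genotype-cluster summaries (centroid + 2x2
covariance per class) into the geometry needed to read an allele
frequency off a pooled intensity point:

* ``cluster_angle`` -- orientation of a cluster's major axis, the
  "degree of rotation" of the genotype cluster with respect to the
  A-probe axis;
* the origin ``O`` -- intersection of the lines through the AA and BB
  centroids angled at theta_AA and theta_BB, defining oblique axes x'
  (toward AA) and y' (toward BB);
* ``NF`` -- a k-correction style normalization factor computed from the
  AB centroid so that the heterozygote cluster maps to AF exactly 0.5;
* the AF conversion -- linear in NF-corrected angle, pinned by the
  three-point contract AF(AA direction)=1, AF(AB centroid)=0.5,
  AF(BB direction)=0.

Estimates slightly outside [0, 1] are retained (not clipped); negative
minor-allele-frequency handling is a downstream concern.

All kernels are vectorized over SNPs; ``ClusterGeometry`` is the
per-panel container and the single-SNP functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterGeometry",
    "PoolAfTable",
    "cluster_angle",
    "cluster_angles",
    "compute_origin",
    "normalization_factor",
    "estimate_replicate_af",
    "aggregate_replicates",
    "estimate_pool_afs",
    "r_ratio",
]

_PARALLEL_TOL_DEG = 1e-6

GENOTYPE_CLASSES = ("AA", "AB", "BB")


def cluster_angles(cxx, cxy, cyy):
    """Major-axis orientation of 2x2 covariance matrices, in degrees.

    Returns ``(theta, isotropic)`` where ``theta`` lies in [0, 90] (the
    intensity quadrant; orientations outside it are reflected in) and
    ``isotropic`` marks matrices with no defined orientation
    (``cxy == 0`` and ``cxx == cyy``), for which 0 is returned.

    Raises ``ValueError`` on negative variances or a matrix that is not
    positive-semidefinite.
    """
    cxx = np.asarray(cxx, dtype=float)
    cxy = np.asarray(cxy, dtype=float)
    cyy = np.asarray(cyy, dtype=float)
    if np.any(cxx < 0) or np.any(cyy < 0):
        raise ValueError("negative variance in covariance matrix")
    det = cxx * cyy - cxy**2
    if np.any(det < -1e-9 * np.maximum(cxx * cyy, 1.0)):
        raise ValueError("covariance matrix not positive-semidefinite")
    theta = 0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy))
    theta = np.mod(theta, 180.0)
    theta = np.where(theta > 90.0, 180.0 - theta, theta)
    isotropic = (cxy == 0) & (cxx == cyy)
    theta = np.where(isotropic, 0.0, theta)
    return theta, isotropic


def cluster_angle(cov) -> float:
    """Orientation (degrees in [0, 90]) of one cluster's major axis."""
    cov = np.asarray(cov, dtype=float)
    theta, _ = cluster_angles(cov[0, 0], cov[0, 1], cov[1, 1])
    return float(theta)


def _unit(theta_deg):
    t = np.radians(np.asarray(theta_deg, dtype=float))
    return np.stack([np.cos(t), np.sin(t)], axis=-1)


def compute_origin(aa_centroid, theta_aa, bb_centroid, theta_bb):
    """Intersection O of the homozygote cluster lines, plus oblique axes.

    The line through the AA centroid at angle ``theta_aa`` and the line
    through the BB centroid at ``theta_bb`` meet at the origin O.  The
    x' axis is the unit direction from O toward the AA centroid, y' the
    direction toward the BB centroid.

    Returns ``(O, xhat, yhat)``.  Raises ``ValueError`` when the lines
    are (near-)parallel; such SNPs are flagged and excluded downstream.
    """
    o, xhat, yhat, ok = _origin_axes(
        np.atleast_2d(np.asarray(aa_centroid, float)),
        np.atleast_1d(float(theta_aa)),
        np.atleast_2d(np.asarray(bb_centroid, float)),
        np.atleast_1d(float(theta_bb)),
    )
    if not ok[0]:
        raise ValueError("homozygote cluster lines are parallel; origin undefined")
    return o[0], xhat[0], yhat[0]


def _origin_axes(aa_c, theta_aa, bb_c, theta_bb):
    """Vectorized origin + oblique axes; returns (O, xhat, yhat, ok)."""
    u = _unit(theta_aa)
    w = _unit(theta_bb)
    # AA + t*u = BB + s*w  ->  [u, -w] @ [t, s] = BB - AA
    rhs = bb_c - aa_c
    det = -u[..., 0] * w[..., 1] + w[..., 0] * u[..., 1]  # = -sin(taa - tbb)
    ok = np.abs(np.sin(np.radians(theta_aa - theta_bb))) > np.sin(
        np.radians(_PARALLEL_TOL_DEG)
    )
    safe_det = np.where(ok, det, 1.0)
    t = (rhs[..., 0] * (-w[..., 1]) - (-w[..., 0]) * rhs[..., 1]) / safe_det
    o = aa_c + t[..., None] * u
    # x' points from O toward the AA centroid, y' toward BB.
    xhat = np.where(t[..., None] > 0, -u, u)
    s = (u[..., 0] * rhs[..., 1] - u[..., 1] * rhs[..., 0]) / safe_det
    yhat = np.where(s[..., None] > 0, -w, w)
    # Degenerate t == 0 (origin at centroid) keeps +u; harmless, flagged later.
    return o, xhat, yhat, ok


def _oblique_coords(points, origin, xhat, yhat):
    """Coordinates (a, b) of points in the oblique frame O + a*xhat + b*yhat."""
    d = points - origin
    det = xhat[..., 0] * yhat[..., 1] - yhat[..., 0] * xhat[..., 1]
    a = (d[..., 0] * yhat[..., 1] - yhat[..., 0] * d[..., 1]) / det
    b = (xhat[..., 0] * d[..., 1] - d[..., 0] * xhat[..., 1]) / det
    return a, b


def normalization_factor(ab_oblique) -> float:
    """NF from the AB centroid's oblique coordinates (x'_AB, y'_AB).

    NF = y'_AB / x'_AB, so that the NF-corrected angle of the AB
    centroid, atan(y' / (NF x')), equals 45 degrees and converts to AF
    0.5.  Requires the centroid strictly inside the quadrant; a centroid
    on (or beyond) an axis means a collapsed heterozygote cluster.
    """
    a, b = float(ab_oblique[0]), float(ab_oblique[1])
    if a <= 0 or b <= 0:
        raise ValueError("AB centroid on or outside the oblique axes (collapsed cluster)")
    return b / a


def _af_from_oblique(a, b, nf):
    """AF via the NF-corrected angle; AA direction -> 1, BB direction -> 0."""
    theta = np.degrees(np.arctan2(b, nf * a))
    return 1.0 - theta / 90.0


@dataclass
class ClusterGeometry:
    """Derived polar-transform geometry for a panel of SNPs.

    Arrays are aligned on ``snp_id``.  ``ok`` marks SNPs with a usable
    geometry; ``reason`` holds the failure label for the rest
    ("parallel-lines", "collapsed-AB", "isotropic-AA", ...).
    """

    snp_id: np.ndarray
    centroids: np.ndarray  # (n, 3, 2) in AA, AB, BB order
    covariances: np.ndarray  # (n, 3, 3) columns cxx, cxy, cyy
    theta: np.ndarray = field(init=False)  # (n, 3) degrees
    origin: np.ndarray = field(init=False)  # (n, 2)
    xhat: np.ndarray = field(init=False)
    yhat: np.ndarray = field(init=False)
    nf: np.ndarray = field(init=False)
    ok: np.ndarray = field(init=False)
    reason: np.ndarray = field(init=False)

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        n = len(self.snp_id)
        theta = np.empty((n, 3))
        iso = np.empty((n, 3), dtype=bool)
        for g in range(3):
            theta[:, g], iso[:, g] = cluster_angles(
                self.covariances[:, g, 0],
                self.covariances[:, g, 1],
                self.covariances[:, g, 2],
            )
        # Isotropic homozygote clusters: orientation undefined -> convention
        # theta_AA = 0, theta_BB = 90, flagged low-confidence downstream.
        theta[:, 2] = np.where(iso[:, 2], 90.0, theta[:, 2])
        self.theta = theta
        o, xh, yh, ok = _origin_axes(
            self.centroids[:, 0], theta[:, 0], self.centroids[:, 2], theta[:, 2]
        )
        reason = np.full(n, "", dtype=object)
        reason[~ok] = "parallel-lines"
        a_ab, b_ab = _oblique_coords(self.centroids[:, 1], o, xh, yh)
        collapsed = ok & ((a_ab <= 0) | (b_ab <= 0))
        reason[collapsed] = "collapsed-AB"
        ok = ok & ~collapsed
        with np.errstate(divide="ignore", invalid="ignore"):
            nf = np.where(ok, b_ab / np.where(a_ab == 0, np.nan, a_ab), np.nan)
        lowconf = ok & (iso[:, 0] | iso[:, 2])
        reason[lowconf] = "isotropic-homozygote"
        self.origin, self.xhat, self.yhat = o, xh, yh
        self.nf = nf
        self.ok = ok
        self.reason = reason
        self._index = pd.Index(self.snp_id)

    def __len__(self) -> int:
        return len(self.snp_id)

    def indexer(self, snp_ids) -> np.ndarray:
        idx = self._index.get_indexer(np.asarray(snp_ids))
        if np.any(idx < 0):
            missing = np.asarray(snp_ids)[idx < 0][:3]
            raise KeyError(f"SNPs absent from cluster geometry: {list(missing)} ...")
        return idx

    def estimate_af(self, snp_ids, points) -> np.ndarray:
        """AF of intensity points, aligned to ``snp_ids`` (NaN where geometry bad)."""
        idx = self.indexer(snp_ids)
        pts = np.asarray(points, dtype=float)
        a, b = _oblique_coords(pts, self.origin[idx], self.xhat[idx], self.yhat[idx])
        at_origin = (a == 0) & (b == 0)
        af = _af_from_oblique(a, b, self.nf[idx])
        af = np.where(self.ok[idx] & ~at_origin, af, np.nan)
        return af

    def centroid_radii(self) -> np.ndarray:
        """(n, 3) distances from O to the AA, AB, BB centroids."""
        return np.linalg.norm(self.centroids - self.origin[:, None, :], axis=2)

    def expected_radius(self, snp_ids, af) -> np.ndarray:
        """r': expected individual-sample radius at a given AF.

        Linear interpolation of centroid radii in AF, through
        (0, r_BB), (0.5, r_AB), (1, r_AA); AF clipped to [0, 1].
        """
        idx = self.indexer(snp_ids)
        radii = self.centroid_radii()[idx]
        p = np.clip(np.asarray(af, dtype=float), 0.0, 1.0)
        upper = radii[:, 1] + (p - 0.5) / 0.5 * (radii[:, 0] - radii[:, 1])
        lower = radii[:, 2] + p / 0.5 * (radii[:, 1] - radii[:, 2])
        return np.where(p >= 0.5, upper, lower)

    def r_ratios(self, snp_ids, points, af) -> np.ndarray:
        """r/r' ratios of pool points at their estimated AFs."""
        idx = self.indexer(snp_ids)
        r = np.linalg.norm(np.asarray(points, float) - self.origin[idx], axis=-1)
        rp = self.expected_radius(snp_ids, af)
        if np.any(rp[self.ok[idx]] == 0):
            raise ValueError("degenerate cluster model: expected radius r' = 0")
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ok[idx], r / rp, np.nan)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterGeometry":
        """Build from long-format table (snp_id, class, x, y, cxx, cxy, cyy)."""
        need = {"snp_id", "class", "x", "y", "cxx", "cxy", "cyy"}
        if not need.issubset(df.columns):
            raise ValueError(f"cluster table missing columns {sorted(need - set(df.columns))}")
        wide = df.pivot(index="snp_id", columns="class")
        snp_ids = wide.index.to_numpy()
        cent = np.stack(
            [np.stack([wide[("x", g)], wide[("y", g)]], axis=1) for g in GENOTYPE_CLASSES],
            axis=1,
        )
        cov = np.stack(
            [
                np.stack([wide[("cxx", g)], wide[("cxy", g)], wide[("cyy", g)]], axis=1)
                for g in GENOTYPE_CLASSES
            ],
            axis=1,
        )
        return cls(snp_ids, cent, cov)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, name in enumerate(GENOTYPE_CLASSES):
            rows.append(
                pd.DataFrame(
                    {
                        "snp_id": self.snp_id,
                        "class": name,
                        "x": self.centroids[:, g, 0],
                        "y": self.centroids[:, g, 1],
                        "cxx": self.covariances[:, g, 0],
                        "cxy": self.covariances[:, g, 1],
                        "cyy": self.covariances[:, g, 2],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).sort_values(["snp_id", "class"], kind="stable")


def estimate_replicate_af(pool_point, geometry: ClusterGeometry, snp_id) -> float:
    """AF of a single pooled replicate intensity point at one SNP."""
    af = geometry.estimate_af([snp_id], np.asarray(pool_point, float)[None, :])
    return float(af[0])


def r_ratio(pool_point, geometry: ClusterGeometry, snp_id, estimated_af) -> float:
    """r/r' of a single pooled replicate point at its estimated AF."""
    out = geometry.r_ratios(
        [snp_id], np.asarray(pool_point, float)[None, :], np.asarray([estimated_af], float)
    )
    return float(out[0])


def aggregate_replicates(replicate_afs) -> tuple[float, float]:
    """Mean AF and standard error of the mean over a pool's replicates.

    With a single replicate the SE is undefined (NaN) and the SNP should
    be flagged by the caller.  Raises on an empty list.
    """
    afs = np.asarray(replicate_afs, dtype=float)
    if afs.size == 0:
        raise ValueError("no replicates to aggregate")
    mean = float(np.mean(afs))
    if afs.size == 1:
        return mean, float("nan")
    return mean, float(np.std(afs, ddof=1) / np.sqrt(afs.size))


@dataclass
class PoolAfTable:
    """Per-SNP, per-pool allele-frequency estimates with replicate detail.

    ``table`` columns: snp_id, pool_id, af_estimate, se, n_replicates,
    flag.  ``replicates`` columns: snp_id, pool_id, replicate_id, af,
    r_ratio.  ``af_estimate`` is the mean of the replicate AFs and may
    fall slightly outside [0, 1] -- by design.
    """

    table: pd.DataFrame
    replicates: pd.DataFrame

    def af_matrix(self) -> pd.DataFrame:
        """SNP x pool matrix of AF estimates."""
        return self.table.pivot(index="snp_id", columns="pool_id", values="af_estimate")

    def se_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="snp_id", columns="pool_id", values="se")


def estimate_pool_afs(geometry: ClusterGeometry, replicate_points: pd.DataFrame) -> PoolAfTable:
    """Estimate pooled AFs for every (SNP, pool) from replicate intensities.

    ``replicate_points`` columns: snp_id, pool_id, replicate_id, x, y.
    Replicates at SNPs with unusable geometry yield NaN AFs and a flag.
    """
    need = {"snp_id", "pool_id", "replicate_id", "x", "y"}
    if not need.issubset(replicate_points.columns):
        raise ValueError(
            f"replicate table missing columns {sorted(need - set(replicate_points.columns))}"
        )
    rep = replicate_points.copy()
    pts = rep[["x", "y"]].to_numpy(dtype=float)
    af = geometry.estimate_af(rep["snp_id"].to_numpy(), pts)
    rr = geometry.r_ratios(rep["snp_id"].to_numpy(), pts, af)
    rep["af"] = af
    rep["r_ratio"] = rr
    grouped = rep.groupby(["snp_id", "pool_id"], sort=True)["af"]
    summary = grouped.agg(
        af_estimate="mean",
        se=lambda a: np.std(a, ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan,
        n_replicates="size",
    ).reset_index()
    flags = np.full(len(summary), "", dtype=object)
    flags[summary["af_estimate"].isna().to_numpy()] = "bad-geometry"
    single = (summary["n_replicates"] == 1).to_numpy()
    flags[single & (flags == "")] = "single-replicate"
    summary["flag"] = flags
    cols = ["snp_id", "pool_id", "replicate_id", "af", "r_ratio"]
    return PoolAfTable(table=summary, replicates=rep[cols])
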