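"""Admixture-proportion estimation by regression on reference panels.

The pooled allele frequency P_u,i of the admixed panel at SNP i is
modeled as a linear combination of the reference-population allele
frequencies P_j,i:

    P_u,i = c + sum_j beta_j * P_j,i + e_i

fit by ordinary least squares over all SNPs passing QC with adequate
reference call rates.  Each coefficient beta_j estimates the
proportional contribution of population j; the coefficients are not
constrained to be non-negative or to sum to one -- a summed proportion
below 1 is informative, indicating ancestry the reference panels do not
model.  Because the array's allele-A assignment is independent of the
minor allele, E(P) ~ 0.5 in every panel, and the intercept c then
absorbs about half of the unexplained ancestry (reported as the ``2c``
diagnostic).

From a fit, a *pseudopopulation* is constructed: a weighted reference
panel with per-SNP AF = sum_j beta_j * P_j,i + c, an effective sample
size equal to the summed reference-panel sizes, and zero
pooling-specific variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AdmixtureFit",
    "Pseudopopulation",
    "select_regression_snps",
    "fit_admixture",
    "build_pseudopopulation",
    "combine_reference_panels",
    "check_allele_orientation",
    "ld_thin_snps",
]

logger = logging.getLogger(__name__)

CONDITION_WARN = 1e4


@dataclass
class AdmixtureFit:
    """OLS admixture estimates for one pooled panel."""

    populations: tuple[str, ...]
    beta: np.ndarray
    beta_se: np.ndarray
    intercept: float
    intercept_se: float
    n_snp: int
    snp_ids: np.ndarray
    condition_number: float
    collinearity_warning: bool

    @property
    def sum_beta(self) -> float:
        return float(np.sum(self.beta))

    @property
    def unexplained(self) -> float:
        """Ancestry not attributed to any reference population."""
        return 1.0 - self.sum_beta

    @property
    def two_c(self) -> float:
        """2 x intercept: matches the unexplained ancestry when mean AF ~ 0.5."""
        return 2.0 * self.intercept

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"term": pop, "estimate": b, "se": s}
            for pop, b, s in zip(self.populations, self.beta, self.beta_se)
        ]
        rows.append({"term": "intercept", "estimate": self.intercept, "se": self.intercept_se})
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [f"admixture fit on {self.n_snp} SNPs"]
        for pop, b, s in zip(self.populations, self.beta, self.beta_se):
            lines.append(f"  beta[{pop}] = {b:.4f} (se {s:.5f})")
        lines.append(f"  intercept  = {self.intercept:.5f} (se {self.intercept_se:.5f})")
        lines.append(f"  summed proportion = {self.sum_beta:.4f}")
        lines.append(f"  unexplained ancestry = {self.unexplained:.4f} (2c = {self.two_c:.4f})")
        if self.collinearity_warning:
            lines.append(f"  WARNING: collinear references (cond {self.condition_number:.3g})")
        return "\n".join(lines)


@dataclass
class Pseudopopulation:
    """Admixture-weighted reference panel standing in as a control pool."""

    af: pd.Series  # indexed by snp_id, clipped to [0, 1]
    n_effective: int  # summed reference sample sizes (individuals)
    pooling_variance: float  # 0 by construction
    n_clipped: int


def select_regression_snps(qc_verdicts: pd.DataFrame, reference_panels: dict, min_call_rate=0.8):
    """SNPs passing QC with call rate > ``min_call_rate`` in every reference.

    ``qc_verdicts`` needs columns snp_id and qc_pass; each panel is a
    DataFrame with snp_id and call_rate.  Raises if nothing qualifies.
    """
    keep = set(qc_verdicts.loc[qc_verdicts["qc_pass"], "snp_id"])
    for name, panel in reference_panels.items():
        ok = set(panel.loc[panel["call_rate"] > min_call_rate, "snp_id"])
        keep &= ok
    if not keep:
        raise ValueError("no SNPs pass QC and reference call-rate requirements")
    return np.array(sorted(keep))


def fit_admixture(pooled_afs: pd.Series, reference_panels: dict) -> AdmixtureFit:
    """OLS of pooled AFs on reference-panel AFs, with intercept.

    ``pooled_afs`` is indexed by snp_id; each reference panel supplies
    (snp_id, af).  Only SNPs present everywhere with finite values
    enter.  Collinear reference panels trigger a logged warning but the
    fit is still returned.
    """
    names = tuple(reference_panels)
    x = pd.DataFrame(
        {name: panel.set_index("snp_id")["af"] for name, panel in reference_panels.items()}
    )
    df = x.join(pooled_afs.rename("_pooled"), how="inner").dropna()
    if len(df) < len(names) + 1:
        raise ValueError(f"need more than {len(names)} SNPs to fit {len(names)} proportions")
    design = sm.add_constant(df[list(names)].to_numpy(), has_constant="add")
    res = sm.OLS(df["_pooled"].to_numpy(), design).fit()
    cond = float(np.linalg.cond(design))
    warn = cond > CONDITION_WARN
    if warn:
        logger.warning("reference panels nearly collinear (condition number %.3g)", cond)
    return AdmixtureFit(
        populations=names,
        beta=res.params[1:].copy(),
        beta_se=res.bse[1:].copy(),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        n_snp=int(len(df)),
        snp_ids=df.index.to_numpy(),
        condition_number=cond,
        collinearity_warning=warn,
    )


def build_pseudopopulation(fit: AdmixtureFit, reference_panels: dict) -> Pseudopopulation:
    """Weighted reference panel: AF_i = sum_j beta_j P_ji + c.

    The effective sample size is the sum of the reference panels'
    sample sizes (120 for two 60-individual panels, 210 when a combined
    90-individual panel joins).  Combined AFs falling outside [0, 1] are
    clipped, with the count logged.
    """
    x = pd.DataFrame(
        {name: panel.set_index("snp_id")["af"] for name, panel in reference_panels.items()}
    ).dropna()
    raw = x[list(fit.populations)].to_numpy() @ fit.beta + fit.intercept
    n_clipped = int(np.sum((raw < 0) | (raw > 1)))
    if n_clipped:
        logger.info("pseudopopulation: clipped %d combined AFs into [0, 1]", n_clipped)
    n_eff = int(sum(int(panel["n"].iloc[0]) for panel in reference_panels.values()))
    return Pseudopopulation(
        af=pd.Series(np.clip(raw, 0.0, 1.0), index=x.index, name="af"),
        n_effective=n_eff,
        pooling_variance=0.0,
        n_clipped=n_clipped,
    )


def combine_reference_panels(panel_a: pd.DataFrame, panel_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two reference panels by sample-size-weighted averaging.

    Useful when two closely related populations (for example the two
    East Asian HapMap panels) should act as a single reference.

    Requires a shared SNP set; SNPs with mismatched alleles are excluded
    with a log entry.  AF and call rate are weighted means, the sample
    size the sum.
    """
    a = panel_a.set_index("snp_id")
    b = panel_b.set_index("snp_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("panels share no SNPs")
    a, b = a.loc[common], b.loc[common]
    mismatch = (a["allele_a"] != b["allele_a"]) | (a["allele_b"] != b["allele_b"])
    if mismatch.any():
        logger.info("combine_reference_panels: excluding %d allele-mismatched SNPs",
                    int(mismatch.sum()))
        a, b = a.loc[~mismatch], b.loc[~mismatch]
    na, nb = a["n"].astype(float), b["n"].astype(float)
    tot = na + nb
    out = a.copy()
    out["af"] = (a["af"] * na + b["af"] * nb) / tot
    out["call_rate"] = (a["call_rate"] * na + b["call_rate"] * nb) / tot
    out["n"] = tot.astype(int)
    return out.reset_index()


def check_allele_orientation(afs, label="panel", tol: float = 0.05) -> bool:
    """Verify E(AF) ~ 0.5, the premise of the intercept diagnostic.

    Returns True when the mean AF is within ``tol`` of 0.5; otherwise
    logs a warning (allele-A orientation may be confounded with the
    minor allele) and returns False.
    """
    m = float(np.nanmean(np.asarray(afs, dtype=float)))
    if abs(m - 0.5) > tol:
        logger.warning("%s: mean AF %.3f deviates from 0.5; orientation suspect", label, m)
        return False
    return True


def ld_thin_snps(snp_table: pd.DataFrame, min_separation: int = 100_000) -> np.ndarray:
    """Thin SNPs by physical distance for an LD-robust refit.

    Keeps, per chromosome, a greedy left-to-right subset at least
    ``min_separation`` bp apart.  ``snp_table`` needs snp_id, chrom, pos.
    The OLS standard errors assume independent residuals; LD between
    neighboring SNPs deflates them, and refitting on a thinned set is
    the honesty check.
    """
    kept = []
    for _, sub in snp_table.sort_values(["chrom", "pos"]).groupby("chrom"):
        last = -np.inf
        for snp_id, pos in zip(sub["snp_id"], sub["pos"]):
            if pos - last >= min_separation:
                kept.append(snp_id)
                last = pos
    return np.array(kept)
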