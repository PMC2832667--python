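"""End-to-end orchestration of the pooled-ancestry workflow.

Stage order: AF estimation from intensities -> SNP QC -> admixture
regression -> pseudopopulation -> AIM scan -> evaluation.  Each stage
writes its table under the configured output directory, and a run log
records parameters and per-stage SNP counts so every input SNP is
accounted for (an output row or an exclusion reason).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .admixture import (
    AdmixtureFit,
    Pseudopopulation,
    build_pseudopopulation,
    check_allele_orientation,
    fit_admixture,
    select_regression_snps,
)
from .aims import aim_scan, pooled_error_variance, weighted_pool_af
from .intensity import PoolAfTable, estimate_pool_afs
from .io import RunConfig, ensure_dir, read_intensity_tables, read_reference_panel
from .popgen import fst
from .qc import QcConfig, QcVerdict, apply_qc

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Artifacts of one pipeline run."""

    pool_af: PoolAfTable
    qc: QcVerdict
    fit: AdmixtureFit
    pseudo: Pseudopopulation
    aims: pd.DataFrame
    evaluation: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage on the files named in ``config``.

    Deterministic given identical inputs and configuration.  Any stage
    failure propagates with the stage name prepended.
    """
    out = ensure_dir(config.output_dir)
    stage = "read-inputs"
    try:
        geometry, reps = read_intensity_tables(
            config.cluster_table, config.replicate_table, logger=logger
        )
        panels = {
            name: read_reference_panel(path)
            for name, path in config.reference_panels.items()
        }

        stage = "estimate-af"
        pool_af = estimate_pool_afs(geometry, reps)
        pool_af.table.to_csv(out / "pool_af.tsv", sep="\t", index=False)

        stage = "qc"
        indiv = None
        if config.individual_af_table is not None:
            indiv = pd.read_csv(config.individual_af_table, sep="\t").set_index("snp_id")
        qc_config = QcConfig(
            fld_min=config.fld_min,
            r_ratio_min=config.r_ratio_min,
            r_pass_fraction=config.r_pass_fraction,
            maf_min=config.maf_min,
            hist_var_max=config.hist_var_max,
        )
        verdict = apply_qc(
            geometry, pool_af, config.pool_sizes, qc_config, individual_afs=indiv
        )
        verdict.table.to_csv(out / "qc_verdicts.tsv", sep="\t", index=False)

        stage = "admixture"
        snps = select_regression_snps(verdict.table, panels, config.min_call_rate)
        af_mat = pool_af.af_matrix().loc[list(snps)]
        sizes = np.array([config.pool_sizes[p] for p in af_mat.columns])
        pooled = pd.Series(
            weighted_pool_af(af_mat.to_numpy(), sizes), index=af_mat.index, name="af"
        )
        check_allele_orientation(pooled, label="pooled panel")
        for name, panel in panels.items():
            check_allele_orientation(panel["af"], label=name)
        fit = fit_admixture(pooled, panels)
        (out / "admixture_report.txt").write_text(fit.report() + "\n")
        fit.summary_frame().to_csv(out / "admixture_fit.tsv", sep="\t", index=False)

        stage = "pseudopopulation"
        pseudo = build_pseudopopulation(fit, panels)

        stage = "find-aims"
        first = next(iter(panels.values())).set_index("snp_id")
        snp_table = first.loc[list(snps), ["chrom", "pos"]].reset_index()
        se_mat = pool_af.se_matrix().loc[list(snps)]
        var_e = pooled_error_variance(se_mat.to_numpy(), sizes)
        records = aim_scan(
            snp_table,
            p_case=pooled.to_numpy(),
            n_case=int(sizes.sum()),
            p_control=pseudo.af.reindex(pooled.index).to_numpy(),
            n_control=pseudo.n_effective,
            var_e_case=var_e,
            var_e_control=pseudo.pooling_variance,
            prune=config.prune,
            min_separation=config.prune_separation,
        )
        records.to_csv(out / "aims.tsv", sep="\t", index=False)

        stage = "evaluate"
        evaluation = {
            "gc_lambda": records.attrs.get("gc_lambda"),
            "fst_pool_vs_pseudo": fst(
                pooled.to_numpy(), pseudo.af.reindex(pooled.index).to_numpy()
            ),
            "n_snps_input": int(geometry.ok.size),
            "n_snps_post_qc": int(len(snps)),
            "n_aims_kept": int(records["kept"].sum()),
        }
        log = {
            "version": __version__,
            "stages": "estimate-af,qc,admixture,pseudopopulation,find-aims,evaluate",
            "config": {k: str(v) for k, v in vars(config).items()},
            **evaluation,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        return RunResult(
            pool_af=pool_af, qc=verdict, fit=fit, pseudo=pseudo, aims=records,
            evaluation=evaluation,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
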