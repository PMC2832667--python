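"""TSV readers/writers and run-configuration parsing.

Every table crossing the pipeline boundary is plain TSV:

* reference panel: snp_id, chrom, pos, allele_a, allele_b, af,
  call_rate, n (1-based positions);
* cluster model (long): snp_id, class, x, y, cxx, cxy, cyy;
* replicate intensities: snp_id, pool_id, replicate_id, x, y;
* pooled AF table, QC verdicts, AIM records: written as produced.

Readers validate eagerly and raise ``DataError`` (malformed values,
duplicate SNPs, AF out of range) with enough context to find the row.
Run configuration is a flat YAML mapping; unknown keys are rejected
(``ConfigError``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intensity import ClusterGeometry

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "read_reference_panel",
    "write_reference_panel",
    "read_intensity_tables",
    "read_pool_af_table",
    "load_run_config",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed input table (CLI exit code 3)."""


PANEL_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "af", "call_rate", "n"]


def read_reference_panel(path) -> pd.DataFrame:
    """Read and validate a reference-panel AF table."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate snp_id {dup.iloc[0]!r} (row {dup.index[0] + 2})")
    for col in ("pos", "af", "call_rate", "n"):
        bad = df[col].isna()
        if bad.any():
            raise DataError(f"{path}: malformed {col} at row {int(bad.idxmax()) + 2}")
    out_of_range = (df["af"] < 0) | (df["af"] > 1)
    if out_of_range.any():
        i = int(out_of_range.idxmax())
        raise DataError(f"{path}: af outside [0, 1] at row {i + 2} (snp {df['snp_id'][i]})")
    if (df["pos"] < 1).any():
        raise DataError(f"{path}: positions must be 1-based and positive")
    return df[PANEL_COLUMNS]


def write_reference_panel(df: pd.DataFrame, path) -> None:
    df[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intensity_tables(cluster_path, replicate_path, logger=None):
    """Read cluster-model + replicate-intensity TSVs joined on snp_id.

    SNPs present in only one table are skipped (logged when a logger is
    given).  Returns ``(ClusterGeometry, replicate_frame)``.
    """
    clusters = pd.read_csv(cluster_path, sep="\t", dtype={"snp_id": str})
    reps = pd.read_csv(replicate_path, sep="\t", dtype={"snp_id": str})
    need_c = {"snp_id", "class", "x", "y", "cxx", "cxy", "cyy"}
    need_r = {"snp_id", "pool_id", "replicate_id", "x", "y"}
    if not need_c.issubset(clusters.columns):
        raise DataError(f"{cluster_path}: missing columns {sorted(need_c - set(clusters.columns))}")
    if not need_r.issubset(reps.columns):
        raise DataError(f"{replicate_path}: missing columns {sorted(need_r - set(reps.columns))}")
    counts = clusters.groupby("snp_id")["class"].nunique()
    complete = set(counts[counts == 3].index)
    shared = complete & set(reps["snp_id"])
    dropped = (set(clusters["snp_id"]) | set(reps["snp_id"])) - shared
    if dropped and logger is not None:
        logger.info("read_intensity_tables: skipping %d SNPs missing from one side", len(dropped))
    clusters = clusters[clusters["snp_id"].isin(shared)]
    reps = reps[reps["snp_id"].isin(shared)].reset_index(drop=True)
    geometry = ClusterGeometry.from_frame(clusters)
    return geometry, reps


def read_pool_af_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "pool_id": str})
    need = {"snp_id", "pool_id", "af_estimate", "se", "n_replicates"}
    if not need.issubset(df.columns):
        raise DataError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return df


@dataclass
class RunConfig:
    """End-to-end run parameters (see ``load_run_config``)."""

    output_dir: str
    cluster_table: str | None = None
    replicate_table: str | None = None
    reference_panels: dict = field(default_factory=dict)  # name -> path
    pool_sizes: dict = field(default_factory=dict)  # pool_id -> individuals
    individual_af_table: str | None = None  # training panel, enables hist-filter
    seed: int = 0
    # QC cut-offs
    fld_min: float = 10.0
    r_ratio_min: float = 0.8
    r_pass_fraction: float = 0.8
    maf_min: float = 0.05
    hist_var_max: float = 2e-3
    # admixture / AIM parameters
    min_call_rate: float = 0.8
    ld_window: int = 20_000_000
    ld_r2_min: float = 0.5
    prune_separation: int = 4_000_000
    prune: bool = True
    candidate_list_size: int = 25
    candidate_p_threshold: float = 1e-3
    # simulate subcommand
    sim_n_snps: int = 20_000
    sim_n_individuals: int = 250
    sim_n_pools: int = 2
    sim_n_replicates: int = 3
    sim_proportions: tuple = (0.82, 0.18)
    sim_drift_fst: tuple = (0.15, 0.15)
    sim_pool_noise_sd: float = 0.02
    sim_corrupt_fraction: float = 0.0


def load_run_config(path) -> RunConfig:
    """Parse a flat YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of configuration keys")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
    if "output_dir" not in raw:
        raise ConfigError(f"{path}: output_dir is required")
    for tup_key in ("sim_proportions", "sim_drift_fst"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    cfg = RunConfig(**raw)
    for key in ("cluster_table", "replicate_table", "individual_af_table"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path}: {key} points to missing file {p}")
    for name, p in cfg.reference_panels.items():
        if not Path(p).exists():
            raise ConfigError(f"{path}: reference panel {name!r} missing file {p}")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
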