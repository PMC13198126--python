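"""CSV readers/writers, run configuration, and the end-to-end pipeline.

All tables are plain CSV: the workflow's contract starts at vendor-exported
peak areas and ends at analysis tables, so no raw-spectrum format is
involved.  Writers emit a schema-version comment line and a stable column
order; readers skip comment lines and accept their own output (round-trip).
Malformed rows are collected into a rejects table, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import load_is_map, load_panel
from .quantify import PEAK_AREA_COLUMNS, quantify_by_internal_standard
from .stats import exclusive_intersections, group_compare
from .synthdata import (
    LIPIDOME_IS,
    SimulationSpec,
    default_spec,
    quantify_lipidome_table,
    render_peak_areas,
    simulate_tissue,
)
from .tiers import (
    TIER_DERIVED,
    esterified_from_subtraction,
    partition_fractions,
    tg_carbon_bins,
)

logger = logging.getLogger("lipidtiers")

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a CSV with a schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# lipidtiers-schema: {kind} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_peak_area_csv(path, required=PEAK_AREA_COLUMNS) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a peak-area CSV; returns (accepted rows, rejected rows).

    A missing required column is a :class:`SchemaError` naming the column;
    rows with a non-numeric area are moved to the rejects table with a
    reason column.  An empty file (header only) returns an empty table with
    a logged warning.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: empty peak-area table", path)
        rejects = df.iloc[0:0].assign(reject_reason=pd.Series(dtype=str))
        return df, rejects
    area = pd.to_numeric(df["area"], errors="coerce")
    bad = area.isna() & df["area"].notna()
    rejects = df[bad].assign(reject_reason="non-numeric area")
    accepted = df[~bad].copy()
    accepted["area"] = area[~bad]
    return accepted, rejects


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (paths + parameters + seed)."""

    tier_a: Optional[str] = None
    tier_b: Optional[str] = None
    tier_c: Optional[str] = None
    panel: Optional[str] = None
    is_map: Optional[str] = None
    out_dir: str = "lipidtiers_out"
    alpha: float = 0.05
    r2_cutoff: float = 0.98
    injection_volume_ul: float = 2.0
    denominator_mode: str = TIER_DERIVED
    tg_boundary: int = 50
    partition_fas: tuple = ()
    reference_group: Optional[str] = None
    lipidome_is_pmol: float = 1000.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "partition_fas" in raw:
            raw["partition_fas"] = tuple(raw["partition_fas"])
        cfg = cls(**raw)
        for key in ("tier_a", "tier_b", "tier_c", "panel", "is_map"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise SchemaError(f"config {key}: file not found: {p}")
        if not (0 < cfg.alpha < 1):
            raise SchemaError("alpha must lie in (0, 1)")
        if not (0 < cfg.r2_cutoff <= 1):
            raise SchemaError("r2_cutoff must lie in (0, 1]")
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["partition_fas"] = list(d["partition_fas"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_simulation(spec: SimulationSpec, out_dir) -> Dict[str, Path]:
    """Simulate a study and write the three tier CSVs plus ground truth."""
    out = Path(out_dir)
    truth = simulate_tissue(spec)
    tables = render_peak_areas(truth, spec)
    paths = {}
    for tier, df in tables.items():
        p = out / f"tier_{tier}_peak_areas.csv"
        write_table(df, p, "peak_areas")
        paths[tier] = p
    gt = truth.free.assign(pool="free")
    gt = pd.concat(
        [
            gt,
            truth.total.assign(pool="total"),
            truth.esterified.assign(pool="esterified"),
            truth.species.rename(columns={"species": "analyte"}).assign(pool="species"),
        ],
        ignore_index=True,
    )
    p = out / "ground_truth.csv"
    write_table(gt, p, "ground_truth")
    paths["truth"] = p
    return paths


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute quantification -> ledger -> partitioning -> statistics.

    Writes amounts, ledger, partition, comparison and set-summary CSVs plus
    a machine-readable manifest; deterministic given inputs and seed.  Any
    stage failure removes partial outputs and re-raises with the stage
    name.  With no tier B the run degrades to branch-C-only mode (free
    amounts and statistics; no ledger or partitioning).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    panel = load_panel(config.panel)
    is_map = load_is_map(config.is_map)
    flags = []

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = "setup"
    try:
        stage = _stage("quantify")
        amounts = {}
        for tier, path in (("B", config.tier_b), ("C", config.tier_c)):
            if path is None:
                continue
            table, rejects = read_peak_area_csv(path)
            if len(rejects):
                flags.append(f"tier {tier}: {len(rejects)} rejected rows")
                write_table(rejects, out / f"tier_{tier}_rejects.csv", "rejects")
            amounts[tier] = quantify_by_internal_standard(table, panel, is_map)
            write_table(
                amounts[tier], out / f"amounts_tier_{tier}.csv", "amounts"
            )
            written[f"amounts_{tier}"] = out / f"amounts_tier_{tier}.csv"

        lipidome = None
        if config.tier_a is not None:
            table_a, rejects_a = read_peak_area_csv(config.tier_a)
            if len(rejects_a):
                flags.append(f"tier A: {len(rejects_a)} rejected rows")
                write_table(rejects_a, out / "tier_A_rejects.csv", "rejects")
            lipidome = quantify_lipidome_table(
                table_a, config.lipidome_is_pmol, LIPIDOME_IS
            )
            write_table(lipidome, out / "amounts_tier_A.csv", "amounts")
            written["amounts_A"] = out / "amounts_tier_A.csv"

        ledger = None
        if "B" in amounts and "C" in amounts:
            stage = _stage("tiers")
            ledger = esterified_from_subtraction(amounts["C"], amounts["B"])
            n_clamped = int(ledger["clamped"].sum())
            if n_clamped:
                flags.append(f"ledger: {n_clamped} clamped negative subtractions")
            write_table(ledger, out / "ledger.csv", "ledger")
            written["ledger"] = out / "ledger.csv"
        else:
            flags.append("branch-C-only mode: no ledger or partitioning")

        if ledger is not None and lipidome is not None and config.partition_fas:
            stage = _stage("partition")
            parts = []
            sinks = tg_carbon_bins(config.tg_boundary)
            for fa_name in config.partition_fas:
                parts.append(
                    partition_fractions(
                        lipidome,
                        ledger,
                        fa_name,
                        sinks=sinks,
                        denominator_mode=config.denominator_mode,
                    )
                )
            partition = pd.concat(parts, ignore_index=True)
            write_table(partition, out / "partition.csv", "partition")
            written["partition"] = out / "partition.csv"

        stage = _stage("compare")
        comparisons = {}
        for tier, amt in amounts.items():
            if "group" not in amt.columns or amt["group"].nunique() != 2:
                continue
            comp = group_compare(
                amt,
                reference=config.reference_group,
                alpha=config.alpha,
            )
            comparisons[tier] = comp
            write_table(comp, out / f"comparison_tier_{tier}.csv", "comparison")
            written[f"comparison_{tier}"] = out / f"comparison_tier_{tier}.csv"

        if comparisons:
            stage = _stage("set_summary")
            sig_sets = {
                tier: set(c.loc[c["significant"], "analyte"])
                for tier, c in comparisons.items()
            }
            summary = exclusive_intersections(sig_sets)
            rows = [
                {
                    "pattern": "&".join(sorted(p)) if p else "(none)",
                    "count": n,
                    "members": ";".join(sorted(map(str, summary.members[p]))),
                }
                for p, n in sorted(
                    summary.counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
                )
            ]
            write_table(pd.DataFrame(rows), out / "set_summary.csv", "set_summary")
            written["set_summary"] = out / "set_summary.csv"

        stage = _stage("manifest")
        manifest = {
            "package": "lipidtiers",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "qc_flags": flags,
            "outputs": {k: str(v) for k, v in written.items()},
        }
        mpath = out / "run_manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written["manifest"] = mpath
        return written
    except Exception as e:
        for p in written.values():
            if Path(p).exists():
                Path(p).unlink()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
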