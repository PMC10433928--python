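"""CSV interchange with unit-bearing headers.

The field data are instrument exports with no standard bioinformatics
container, so the interchange format is plain RFC-4180 CSV: one row per
timestamp x tree (or per anatomical sample), ISO-8601 timestamps, and
every quantitative column named with an explicit unit suffix
(``Js_cm_per_h``, ``D_kPa``, ...).  Parsing is strict — a missing
mandatory column or an unknown unit variant is an error naming the
column — but a small table of declared unit variants (e.g. flux in
mm h-1) is converted on read and logged.  Extra columns pass through
untouched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table",
           "write_campaign", "read_ground_truth"]


@dataclass(frozen=True)
class TableSchema:
    """Declared columns of one interchange table.

    ``required`` are canonical column names; ``conversions`` maps an
    accepted alternative header to ``(canonical_name, factor)`` applied
    multiplicatively on read.
    """

    name: str
    required: tuple[str, ...]
    timestamp_cols: tuple[str, ...] = ()
    conversions: dict = None

    def __post_init__(self):
        if self.conversions is None:
            object.__setattr__(self, "conversions", {})


SCHEMAS = {
    "microclimate": TableSchema(
        "microclimate",
        ("timestamp", "Tair_C", "Tleaf_C", "RH_frac", "D_kPa",
         "Rs_W_m2", "u_m_s"),
        timestamp_cols=("timestamp",),
        conversions={"RH_percent": ("RH_frac", 0.01)}),
    "sapflux": TableSchema(
        "sapflux", ("timestamp", "tree_id", "Js_cm_per_h"),
        timestamp_cols=("timestamp",),
        conversions={"Js_mm_per_h": ("Js_cm_per_h", 0.1)}),
    "gas_exchange": TableSchema(
        "gas_exchange",
        ("timestamp", "tree_id", "gs_mol_m2_s", "Tleaf_C"),
        timestamp_cols=("timestamp",),
        conversions={"gs_mmol_m2_s": ("gs_mol_m2_s", 1e-3)}),
    "vessels": TableSchema(
        "vessels",
        ("species", "sample_id", "transect_area_mm2", "diameter_um")),
    "stomata": TableSchema(
        "stomata",
        ("species", "sample_id", "density_mm2", "size_um2", "amax_um2")),
    "branches": TableSchema(
        "branches",
        ("species", "sample_id", "diameter_mm", "leaf_area_cm2"),
        conversions={"diameter_cm": ("diameter_mm", 10.0)}),
    "veins": TableSchema(
        "veins",
        ("species", "sample_id", "leaf_area_mm2", "vein_length_mm")),
    "water_potentials": TableSchema(
        "water_potentials",
        ("tree_id", "species", "day", "psi_pd_MPa", "psi_min_MPa",
         "gs_mol_m2_s", "D_kPa")),
    "tree_meta": TableSchema(
        "tree_meta", ("tree_id", "species", "sapwood_area_cm2")),
    "tree_branches": TableSchema(
        "tree_branches", ("tree_id", "diameter_mm")),
}


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read one interchange CSV, enforcing the schema.

    Unknown unit variants or missing mandatory columns raise
    ``ValueError`` naming the column and expected unit; declared
    variants are converted and logged; malformed timestamps raise with
    the offending line number.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path)
    for alt, (canon, factor) in schema.conversions.items():
        if alt in df.columns:
            if canon in df.columns:
                raise ValueError(
                    f"{schema.name}: both {alt!r} and {canon!r} present")
            df[canon] = df[alt] * factor
            df = df.drop(columns=[alt])
            logger.info("%s: converted %s -> %s (x%g)", schema.name, alt,
                        canon, factor)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{schema.name}: missing mandatory column(s) {missing}; "
            f"expected units as in {list(schema.required)}")
    for col in schema.timestamp_cols:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{schema.name}: malformed timestamp at line {line}: "
                f"{df.loc[bad.idxmax(), col]!r}")
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | str = None
                ) -> None:
    """Write a table as CSV with ISO-8601 timestamps, full precision."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    out = df.copy()
    ts_cols = schema.timestamp_cols if schema else ()
    for col in ts_cols:
        out[col] = pd.to_datetime(out[col]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


_CAMPAIGN_TABLES = (
    ("met", "microclimate", "microclimate.csv"),
    ("gas", "gas_exchange", "gas_exchange.csv"),
    ("flux", "sapflux", "sapflux.csv"),
    ("water_potentials", "water_potentials", "water_potentials.csv"),
    ("tree_meta", "tree_meta", "tree_meta.csv"),
    ("tree_branches", "tree_branches", "tree_branches.csv"),
)


def write_campaign(campaign, outdir) -> None:
    """Write every campaign table plus the ground-truth JSON sidecar."""
    from .synthetic import truth_to_json
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, schema, fname in _CAMPAIGN_TABLES:
        write_table(getattr(campaign, attr), outdir / fname, schema)
    for key, df in campaign.anatomy.items():
        write_table(df, outdir / f"{key}.csv", key)
    (outdir / "ground_truth.json").write_text(
        truth_to_json(campaign.truth))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
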