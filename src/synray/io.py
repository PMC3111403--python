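"""Readers and writers for the plain-text dialects the pipeline consumes.

Dose-response data travel as UTF-8 CSV with header
``compound,dose_um,replicate,response_pct``; feature tables as TSV with
header ``feature_id\tgene_id\tratio\tp_value``; a YAML manifest maps each
treatment to its three replicate files.  Malformed rows are reported with
their line numbers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dose_response import DoseResponseData
from .transcripts import FEATURE_COLUMNS, ReplicateSet

__all__ = [
    "RunConfig",
    "read_dose_response",
    "write_dose_response",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "read_replicate_sets",
    "write_matrix",
]

DOSE_COLUMNS = ["compound", "dose_um", "replicate", "response_pct"]


@dataclass
class RunConfig:
    """Thresholds and switches shared by the CLI subcommands."""

    fc: float = 2.0
    p: float = 0.01
    ci_level: float = 0.95
    effect_grid_step: float = 1.0
    seed: int = 0
    out_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self):
        if self.fc <= 0 or self.p <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("fc", "p", "ci_level", "effect_grid_step", "seed") if k in raw}
        if "out_dir" in raw:
            known["out_dir"] = Path(raw["out_dir"])
        return cls(**known)


def read_dose_response(path, compound: str | None = None) -> DoseResponseData:
    """Read a dose-response CSV; bad rows are reported with line numbers."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != DOSE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {','.join(DOSE_COLUMNS)}, got {reader.fieldnames}"
            )
        rows, bad = [], []
        for lineno, rec in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        rec["compound"],
                        float(rec["dose_um"]),
                        rec["replicate"],
                        float(rec["response_pct"]),
                    )
                )
            except (TypeError, ValueError):
                bad.append(lineno)
        if bad:
            raise ValueError(f"{path}: non-numeric dose/response on line(s) {bad}")
    df = pd.DataFrame(rows, columns=DOSE_COLUMNS)
    return DoseResponseData.from_frame(df, compound)


def write_dose_response(data: DoseResponseData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a per-replicate feature TSV (feature_id, gene_id, ratio, p_value)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("ratio", "p_value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            lines = [i + 2 for i in bad]
            raise ValueError(f"{path}: non-numeric {col} on line(s) {lines}")
        df[col] = vals
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{path}: duplicate feature_id rows: {dupes[:5]}")
    return df[FEATURE_COLUMNS]


def write_feature_table(df: pd.DataFrame, path) -> None:
    df[FEATURE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path) -> dict:
    """Read a YAML manifest mapping treatment -> list of 3 replicate paths."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: manifest must map treatments to replicate file lists")
    out = {}
    for treatment, files in raw.items():
        if not isinstance(files, list) or len(files) != 3:
            raise ValueError(
                f"{path}: treatment {treatment!r} must list exactly 3 replicate files"
            )
        out[str(treatment)] = [path.parent / f for f in files]
    return out


def read_replicate_sets(manifest_path) -> dict:
    """Load and validate all ReplicateSets named by a manifest."""
    manifest = read_manifest(manifest_path)
    return {
        t: ReplicateSet(t, tuple(read_feature_table(f) for f in files))
        for t, files in manifest.items()
    }


def write_matrix(matrix, out_dir, prefix: str = "response_matrix") -> tuple[Path, Path]:
    """Write a ResponseMatrix as value and significance-mask TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vpath = out_dir / f"{prefix}_log2.tsv"
    mpath = out_dir / f"{prefix}_significant.tsv"
    matrix.values.to_csv(vpath, sep="\t")
    matrix.significant.to_csv(mpath, sep="\t")
    return vpath, mpath
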