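"""Tab-separated readers and writers for tables, metadata and matrices.

All on-disk formats are plain text.  Count tables are samples-as-rows with
the first column holding sample identifiers and the header row holding OTU
identifiers.  Distance matrices are square TSV with identifier header row and
column.  Metadata is TSV with columns sample_id, substrate_bin, incubation,
is_control.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from .otu import OtuTable, RelativeAbundanceTable, SampleMetadata, ValidationError

METADATA_COLUMNS = ("sample_id", "substrate_bin", "incubation", "is_control")


class ParseError(ValidationError):
    """Raised when an input file violates its documented format."""


def read_otu_table(path) -> OtuTable:
    """Read a samples × OTUs count table from TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate OTU id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ParseError(
                f"{path}: non-numeric count at row {row!r}, column {col!r}"
            )
        if not np.all(np.mod(vals.to_numpy(dtype=float), 1) == 0):
            row = df.index[np.mod(vals.to_numpy(dtype=float), 1) != 0][0]
            raise ParseError(
                f"{path}: non-integer count at row {row!r}, column {col!r}"
            )
    return OtuTable(df.astype(np.int64))


def write_otu_table(table: OtuTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def write_relative_abundance(rel: RelativeAbundanceTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rel.values.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> list[SampleMetadata]:
    """Read per-sample metadata records from TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        inc = row["incubation"]
        incubation = None if pd.isna(inc) or inc in ("", "none", "NA") else int(inc)
        is_control = str(row["is_control"]).strip().lower() in ("true", "1", "yes")
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                substrate_bin=row["substrate_bin"],
                incubation=incubation,
                is_control=is_control,
            )
        )
    return records


def write_metadata(records: list[SampleMetadata], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "substrate_bin": [r.substrate_bin for r in records],
            "incubation": ["" if r.incubation is None else r.incubation for r in records],
            "is_control": [r.is_control for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column identifiers disagree")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_run_report(report: dict, path) -> None:
    """Machine-parseable key-value run report (YAML)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=False)


def read_run_report(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for clean serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_plain(obj), fh, indent=2)
        fh.write("\n")
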