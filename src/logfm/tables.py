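"""Descriptor-table I/O.

Tables are UTF-8, comma-separated CSV with a header row and "." decimals,
one row per compound. Incoming headers are matched case-insensitively
against a versioned alias map (ADMETLab-style exports spell the same field
several ways); unrecognised columns are preserved as pass-through metadata.
Blank cells in numeric columns are flagged as missing, never silently
zeroed — downstream model evaluation raises a missing-descriptor error
instead. Lines starting with ``#`` are comments (run provenance stamps).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .descriptors import NUMERIC_FIELDS, DescriptorVector
from .errors import TableFormatError

__all__ = ["load_alias_map", "read_descriptor_table", "write_descriptor_table",
           "records_to_frame", "frame_to_records"]

#: canonical column order for written tables
CANONICAL_ORDER = (
    "compound_id", "MW", "Vol", "Dense", "nHA", "nHD", "nRot", "nRing",
    "MaxRing", "nHet", "nRig", "Flex", "logS", "logP", "logD", "Fsp3",
    "TPSA", "caco2", "MDCK", "PAMPA", "logVDss", "PPB", "Fu", "Lipinski",
    "Hmax", "AATSC1c", "ZMIC1", "GI_absorption",
)

_NON_NUMERIC = {"compound_id", "GI_absorption", "SMILES"}


def load_alias_map() -> dict:
    """Load the versioned header alias map shipped with the package."""
    with resources.files("logfm.data").joinpath("aliases.json").open() as fh:
        return json.load(fh)


def _canonical_header(name: str, amap: dict) -> str | None:
    key = name.strip().lower()
    if key in amap["aliases"]:
        return amap["aliases"][key]
    for f in NUMERIC_FIELDS + ("GI_absorption", "logFM", "SMILES"):
        if key == f.lower():
            return f
    return None


def read_descriptor_table(path, alias_map: dict | None = None):
    """Read a descriptor CSV into ``[(compound_id, DescriptorVector), ...]``.

    Raises :class:`TableFormatError` on duplicate compound ids or on a
    non-numeric cell in a numeric column (reported with 1-based data row
    and column name). Extra columns (including logFM and SMILES) ride along
    in ``DescriptorVector.extra``.
    """
    amap = alias_map or load_alias_map()
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    if df.empty and not len(df.columns):
        raise TableFormatError(f"{path}: no header row")

    id_aliases = set(amap["id_aliases"])
    id_col = None
    colmap: dict[str, str] = {}
    for col in df.columns:
        low = col.strip().lower()
        if id_col is None and low in id_aliases:
            id_col = col
            continue
        canon = _canonical_header(col, amap)
        colmap[col] = canon if canon else col

    ids = (df[id_col].astype(str).str.strip() if id_col is not None
           else pd.Series([str(i + 1) for i in range(len(df))]))
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableFormatError(f"duplicate compound ids: {sorted(set(dup))}")

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        d = DescriptorVector(compound_id=ids.iloc[i])
        for col, canon in colmap.items():
            raw = row[col]
            blank = pd.isna(raw) or str(raw).strip() == ""
            if canon in NUMERIC_FIELDS or canon == "logFM":
                if blank:
                    value = None
                else:
                    try:
                        value = float(raw)
                    except ValueError:
                        raise TableFormatError(
                            f"non-numeric value {raw!r} in row {i + 1}, "
                            f"column {col!r}"
                        ) from None
                if canon == "logFM":
                    d.extra["logFM"] = value
                else:
                    setattr(d, canon, value)
            elif canon == "GI_absorption":
                d.GI_absorption = None if blank else str(raw).strip()
            else:
                d.extra[canon] = None if blank else str(raw).strip()
        records.append((d.compound_id, d))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Stack ``(id, DescriptorVector)`` pairs into a DataFrame in canonical
    column order, extras appended in first-seen order."""
    rows = []
    extra_cols: list[str] = []
    for cid, d in records:
        row = d.to_dict()
        row["compound_id"] = cid
        for k in row:
            if k not in CANONICAL_ORDER and k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    cols = [c for c in CANONICAL_ORDER] + extra_cols
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def frame_to_records(df: pd.DataFrame):
    """Inverse of :func:`records_to_frame` (numeric NaN → missing)."""
    records = []
    for _, row in df.iterrows():
        d = DescriptorVector(compound_id=str(row.get("compound_id", "")))
        for f in NUMERIC_FIELDS:
            if f in row.index:
                v = row[f]
                setattr(d, f, None if pd.isna(v) else float(v))
        if "GI_absorption" in row.index and not pd.isna(row["GI_absorption"]):
            d.GI_absorption = str(row["GI_absorption"])
        for col in row.index:
            if col not in NUMERIC_FIELDS and col not in ("compound_id", "GI_absorption"):
                if not pd.isna(row[col]):
                    d.extra[col] = row[col]
        records.append((d.compound_id, d))
    return records


def write_descriptor_table(records, path, stamp: str | None = None) -> None:
    """Write records as CSV in canonical column order.

    Floats are serialised with shortest round-trip repr so that a
    write/read cycle reproduces every numeric field bit-identically.
    ``stamp`` (e.g. a run config hash) is written as a leading ``#``
    comment line that :func:`read_descriptor_table` skips.
    """
    df = records_to_frame(records)
    with open(path, "w", newline="") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for v in row:
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write(",".join(cells) + "\n")
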