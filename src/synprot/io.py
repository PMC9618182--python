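"""Reading and writing protein quantification tables and related files.

A protein quantification table is a :class:`pandas.DataFrame` indexed by
UniProt-style accession with the columns ``symbol`` (gene symbol, may be
empty), ``unique_peptides`` (integer count) and one positive-intensity
column per experimental pool.  Zero and blank intensities both mean "not
detected" and are stored as NaN.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "read_protein_table",
    "validate_protein_table",
    "write_protein_table",
    "read_gmt",
    "read_id_list",
    "read_two_column_tsv",
]

META_COLUMNS = ("symbol", "unique_peptides")

#: Column-name mapping adapting a MaxQuant proteinGroups-style export.
MAXQUANT_COLUMN_MAP = {
    "Majority protein IDs": "accession",
    "Gene names": "symbol",
    "Unique peptides": "unique_peptides",
}


def _delimiter_for(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_protein_table(
    path: str,
    pool_ids: Sequence[str],
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a protein quantification table from TSV/CSV.

    Parameters
    ----------
    path
        File path; delimiter is comma for ``.csv``, tab otherwise.
    pool_ids
        Pool columns that must be present.
    column_map
        Optional raw-header -> canonical-name mapping (e.g. to adapt
        MaxQuant headers such as ``"Reporter intensity corrected 1"``).

    Returns
    -------
    pandas.DataFrame
        Accession-indexed table with ``symbol``, ``unique_peptides`` and
        one column per pool; zero/blank intensities are NaN.

    Raises
    ------
    SchemaError
        If a required column is missing or an accession is duplicated.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["accession", "unique_peptides", *pool_ids]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "symbol" not in df.columns:
        df["symbol"] = ""
    df = df.set_index("accession")
    return validate_protein_table(df, pool_ids)


def validate_protein_table(df: pd.DataFrame, pool_ids: Sequence[str]) -> pd.DataFrame:
    """Validate and canonicalize an in-memory quantification table.

    Enforces unique accessions, integer peptide counts and strictly
    positive intensities; zeros become NaN ("not detected").
    """
    missing = [c for c in ("unique_peptides", *pool_ids) if c not in df.columns]
    if missing:
        raise SchemaError(f"protein table missing column(s) {missing}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate accession(s): {dupes[:5]}")
    out = df.copy()
    out.index = out.index.astype(str)
    out.index.name = "accession"
    if "symbol" not in out.columns:
        out["symbol"] = ""
    out["symbol"] = out["symbol"].fillna("").astype(str)
    out["unique_peptides"] = (
        pd.to_numeric(out["unique_peptides"], errors="raise").fillna(0).astype(int)
    )
    for pool in pool_ids:
        vals = pd.to_numeric(out[pool], errors="coerce")
        vals = vals.where(vals > 0)  # zero or negative -> missing
        out[pool] = vals.astype(float)
    ordered = [*META_COLUMNS, *pool_ids]
    extra = [c for c in out.columns if c not in ordered]
    return out[ordered + extra]


def write_protein_table(df: pd.DataFrame, path: str) -> None:
    """Write a quantification table as UTF-8 TSV (NaN as empty cells)."""
    df.to_csv(path, sep="\t", na_rep="", encoding="utf-8")


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise SchemaError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    if not sets:
        raise SchemaError(f"{path}: no gene sets found")
    return sets


def read_id_list(path: str) -> set[str]:
    """Read a one-identifier-per-line text file (blank lines ignored)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_two_column_tsv(path: str) -> dict[str, str]:
    """Read a two-column TSV into an id -> value mapping."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(f"{path}:{lineno}: expected two tab-separated columns")
            out[fields[0].strip()] = fields[1].strip()
    return out
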