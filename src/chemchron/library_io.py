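"""Reading and writing compound tables and rectangular result tables.

Compound libraries arrive as ``.smi`` (whitespace-separated ``SMILES id``,
``#`` comments), CSV/TSV with configurable column names, or SDF (V2000).
Records whose SMILES fails to parse are retained, flagged ``parse-failed``
and excluded by downstream stages, so the row count out always equals the
data-row count in.
"""

from __future__ import annotations

import csv
import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import chem

#: Provenance flags attached to records as they move through the pipeline.
FLAG_PARSE_FAILED = "parse-failed"
FLAG_DESALTED = "desalted"
FLAG_NEUTRALIZED = "neutralized"
FLAG_ACYCLIC = "acyclic"

DEFAULT_YEAR_RANGE = (1700, 2100)


@dataclass
class CompoundRecord:
    """One library entry: identifier, structure, optional origin year.

    ``origin_year`` is the compound's earliest recorded year of appearance
    in the literature (absent when undated). ``mol_type_label`` carries the
    source database's record-type tag; unrecognized or absent labels are
    treated as small molecules downstream.
    """

    id: str
    smiles: str
    origin_year: int | None = None
    mol_type_label: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def parse_failed(self) -> bool:
        return FLAG_PARSE_FAILED in self.flags


def _validate_year(raw, record_id: str, year_range: tuple[int, int]) -> int | None:
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if not raw:
            return None
    if isinstance(raw, float) and pd.isna(raw):
        return None
    try:
        year = int(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"record {record_id!r}: year {raw!r} is not an integer") from exc
    lo, hi = year_range
    if not lo <= year <= hi:
        raise ValueError(f"record {record_id!r}: year {year} outside plausible range {lo}-{hi}")
    return year


def _check_ids(ids: Sequence[str]) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if not i:
            raise ValueError("empty record id")
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate record ids: {', '.join(dups)}")


def _flag_parse(records: list[CompoundRecord]) -> list[CompoundRecord]:
    for rec in records:
        if chem.parse_smiles(rec.smiles) is None:
            rec.flags.add(FLAG_PARSE_FAILED)
    return records


def read_compound_table(
    path: str | Path,
    format: str | None = None,
    id_col: str = "id",
    smiles_col: str = "smiles",
    year_col: str = "year",
    type_col: str = "mol_type",
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
    sdf_year_tag: str = "year",
) -> list[CompoundRecord]:
    """Read a compound table, preserving input order.

    ``format`` is one of ``smi``, ``csv``, ``tsv``, ``sdf``; inferred from
    the file suffix when omitted. Unparseable SMILES yield records flagged
    ``parse-failed`` rather than a fatal error; missing files, missing
    mandatory columns and duplicate ids are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound table not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"smi", "csv", "tsv", "sdf"}:
        raise ValueError(f"unsupported compound-table format: {fmt!r}")

    if fmt == "smi":
        records = _read_smi(path)
    elif fmt in {"csv", "tsv"}:
        records = _read_delimited(
            path, "," if fmt == "csv" else "\t",
            id_col, smiles_col, year_col, type_col, year_range,
        )
    else:
        records = _read_sdf(path, sdf_year_tag, year_range)

    _check_ids([r.id for r in records])
    return _flag_parse(records)


def _read_smi(path: Path) -> list[CompoundRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            rid = parts[1].strip() if len(parts) > 1 else f"mol{n}"
            records.append(CompoundRecord(id=rid, smiles=smiles))
    return records


def _read_delimited(path, sep, id_col, smiles_col, year_col, type_col, year_range):
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_col, smiles_col):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    records = []
    for _, row in df.iterrows():
        rid = str(row[id_col]).strip()
        year = _validate_year(row.get(year_col), rid, year_range) if year_col in df.columns else None
        label = row.get(type_col) or None
        records.append(
            CompoundRecord(id=rid, smiles=str(row[smiles_col]).strip(),
                           origin_year=year, mol_type_label=label)
        )
    return records


def _read_sdf(path, year_tag, year_range):
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for n, mol in enumerate(supplier, start=1):
        if mol is None:
            records.append(CompoundRecord(id=f"sdf{n}", smiles="", flags={FLAG_PARSE_FAILED}))
            continue
        rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") and mol.GetProp("_Name").strip() else f"sdf{n}"
        year = None
        if mol.HasProp(year_tag):
            year = _validate_year(mol.GetProp(year_tag), rid, year_range)
        records.append(CompoundRecord(id=rid, smiles=chem.canonical_smiles(mol), origin_year=year))
    return records


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of records (flags serialized as a ``;``-joined string)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "year": pd.array([r.origin_year for r in records], dtype="Int64"),
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )


_SCALAR_TYPES = (str, numbers.Number, type(None))


def write_table(rows, path: str | Path, format: str = "csv") -> None:
    """Write a rectangular results table as CSV (RFC 4180) or JSON.

    Round-trip safe: strings and integers survive bit-exactly, floats to 10
    significant digits. Cells must be scalars; nested structures are a
    schema violation.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        keys = list(rows[0].keys()) if rows else []
        for r in rows:
            if list(r.keys()) != keys:
                raise ValueError("rows do not share one schema")
        df = pd.DataFrame(rows, columns=keys)
    for col in df.columns:
        for v in df[col]:
            if isinstance(v, _SCALAR_TYPES):
                continue
            if pd.api.types.is_scalar(v) and pd.isna(v):
                continue
            raise ValueError(f"non-scalar cell in column {col!r}: {type(v).__name__}")
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.10g",
                  quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=_json_scalar)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported output format: {format!r}")


def _json_scalar(value):
    if isinstance(value, numbers.Integral):
        return int(value)
    if isinstance(value, numbers.Real):
        return float(value)
    raise TypeError(f"non-scalar cell: {type(value).__name__}")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (CSV)."""
    return pd.read_csv(path)
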