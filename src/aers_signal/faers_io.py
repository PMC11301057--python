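"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarterly extracts ship as seven ``$``-delimited text files — DEMO
(demographics and administration), DRUG, REAC (MedDRA-coded reactions),
OUTC (outcomes), RPSR (report sources), THER (therapy dates) and INDI
(indications).  The dialect has one header line naming the columns and no
quoting or escaping of any kind: a ``$`` can never occur inside a field, so
a line with the wrong number of ``$``-separated fields is corrupt and is
reported with its line number rather than silently repaired.

This layer is deliberately dumb: no field content (dates, ages, codes) is
interpreted here.  Type coercion and validation happen downstream so that a
malformed date can never cause a row to be dropped during parsing.

The PT→SOC mapping (MedDRA preferred term to system organ class) is read
from a user-supplied two-column delimited file, since the dictionary itself
is licensed and cannot ship with the package.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TABLE_IDS",
    "DELIMITER",
    "TableSchema",
    "RawRecord",
    "PtSocMap",
    "DEFAULT_SCHEMAS",
    "FaersIOError",
    "SchemaError",
    "DialectError",
    "MappingConflictError",
    "read_table",
    "write_table",
    "load_pt_soc_map",
    "normalize_term",
]

TABLE_IDS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")
DELIMITER = "$"
KEY_FIELDS = ("primaryid", "caseid")


class FaersIOError(Exception):
    """Base class for FAERS I/O failures."""


class SchemaError(FaersIOError):
    """Header does not satisfy the expected table schema."""


class DialectError(FaersIOError):
    """A line violates the ``$``-delimited dialect (wrong field count etc.)."""


class MappingConflictError(FaersIOError):
    """A preferred term maps to more than one system organ class."""


_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-insensitive key for a MedDRA term: strip, collapse internal
    whitespace, casefold.  FAERS REAC preferred terms vary in case between
    quarters, so all PT lookups and set semantics go through this."""
    return _WS.sub(" ", term.strip()).casefold()


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one of the seven FAERS tables.

    ``columns`` is the minimum ordered column set required downstream;
    actual files may carry extra columns (the column sets drift across
    quarters), which are preserved but ignored.
    """

    table_id: str
    columns: tuple[str, ...]
    key_fields: tuple[str, ...] = KEY_FIELDS

    def __post_init__(self) -> None:
        if self.table_id not in TABLE_IDS:
            raise SchemaError(f"unknown table_id {self.table_id!r}; expected one of {TABLE_IDS}")
        if not self.columns:
            raise SchemaError("schema column list must be non-empty")
        if len(set(self.columns)) != len(self.columns):
            raise SchemaError(f"duplicate columns in schema for {self.table_id}")
        missing = [k for k in self.key_fields if k not in self.columns]
        if missing:
            raise SchemaError(f"{self.table_id} schema lacks key fields {missing}")


DEFAULT_SCHEMAS: dict[str, TableSchema] = {
    "DEMO": TableSchema(
        "DEMO",
        ("primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
         "occp_cod", "reporter_country"),
    ),
    "DRUG": TableSchema("DRUG", ("primaryid", "caseid", "drug_seq", "role_cod", "drugname")),
    "REAC": TableSchema("REAC", ("primaryid", "caseid", "pt")),
    "OUTC": TableSchema("OUTC", ("primaryid", "caseid", "outc_cod")),
    "RPSR": TableSchema("RPSR", ("primaryid", "caseid", "rpsr_cod")),
    "THER": TableSchema("THER", ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt")),
    "INDI": TableSchema("INDI", ("primaryid", "caseid", "indi_drug_seq", "indi_pt")),
}


@dataclass(frozen=True)
class RawRecord:
    """One parsed line of a FAERS table, untyped and untrimmed."""

    table_id: str
    values: dict[str, str]
    source_file: str = ""
    line_no: int = 0

    def __post_init__(self) -> None:
        pid = self.values.get("primaryid", "")
        if not pid or not pid.isdigit():
            raise DialectError(
                f"{self.source_file or self.table_id}: line {self.line_no}: "
                f"primaryid must be a non-empty digit string, got {pid!r}"
            )

    def __getitem__(self, key: str) -> str:
        return self.values[key]

    def get(self, key: str, default: str = "") -> str:
        return self.values.get(key, default)


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_table(path: str | Path, schema: TableSchema) -> list[RawRecord]:
    """Parse one ``$``-delimited FAERS table.

    The header drives column order; it must contain every schema column
    (extras are kept in the record values).  A data line whose field count
    differs from the header raises :class:`DialectError` with its line
    number.  Records come back in file order with strictly increasing
    ``line_no``.
    """
    path = Path(path)
    text = _read_text(path)
    lines = text.split("\n")
    if not lines or not lines[0].strip():
        raise DialectError(f"{path}: empty file, expected a header line")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    missing = [c for c in schema.columns if c not in header]
    if missing:
        raise SchemaError(
            f"{path}: header {header} does not cover schema columns "
            f"{list(schema.columns)} (missing {missing})"
        )
    records: list[RawRecord] = []
    for i, line in enumerate(lines[1:], start=2):
        if line == "":
            continue  # trailing newline
        fields = line.split(DELIMITER)
        if len(fields) != len(header):
            raise DialectError(
                f"{path}: line {i}: expected {len(header)} fields, got {len(fields)}"
            )
        records.append(
            RawRecord(schema.table_id, dict(zip(header, fields)), str(path), i)
        )
    return records


def write_table(
    records: Sequence[RawRecord],
    path: str | Path,
    schema: TableSchema | None = None,
) -> Path:
    """Emit header + one ``$``-joined line per record, bit-stable.

    All records must share one table_id.  For an empty sequence a schema is
    required to know which header to write.
    """
    path = Path(path)
    if not records:
        if schema is None:
            raise ValueError("write_table of an empty sequence requires a schema")
        columns: Sequence[str] = schema.columns
        table_id = schema.table_id
    else:
        table_ids = {r.table_id for r in records}
        if len(table_ids) != 1:
            raise ValueError(f"mixed table_ids in write_table: {sorted(table_ids)}")
        table_id = records[0].table_id
        columns = list(records[0].values.keys())
    lines = [DELIMITER.join(columns)]
    for r in records:
        if list(r.values.keys()) != list(columns):
            raise SchemaError(
                f"record columns {list(r.values)} differ from header {list(columns)}"
            )
        for v in r.values.values():
            if DELIMITER in v:
                raise DialectError(
                    f"field value {v!r} contains the delimiter; the FAERS "
                    f"dialect has no escaping"
                )
        lines.append(DELIMITER.join(r.values[c] for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@dataclass(frozen=True)
class PtSocMap:
    """Preferred-term → system-organ-class mapping with normalized keys.

    Lookup of an unmapped PT returns ``None`` — callers tally such terms,
    they are never silently dropped.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def lookup(self, pt: str) -> str | None:
        return self.entries.get(normalize_term(pt))

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PtSocMap":
        entries: dict[str, str] = {}
        conflicts: list[str] = []
        for pt, soc in pairs:
            key = normalize_term(pt)
            soc = soc.strip()
            if key in entries and entries[key] != soc:
                conflicts.append(pt.strip())
            else:
                entries[key] = soc
        if conflicts:
            raise MappingConflictError(
                "preferred terms mapped to conflicting organ classes: "
                + ", ".join(sorted(set(conflicts)))
            )
        return cls(entries)


def load_pt_soc_map(path: str | Path) -> PtSocMap:
    """Read a two-column delimited PT,SOC file (header required).

    Comma- or tab-delimited; commas inside SOC names (common in MedDRA SOC
    labels) must be CSV-quoted.  Duplicate PT rows with conflicting SOCs
    raise :class:`MappingConflictError` naming the terms.
    """
    path = Path(path)
    text = _read_text(path)
    first = text.split("\n", 1)[0]
    delim = "\t" if "\t" in first else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    if not rows:
        raise FaersIOError(f"{path}: empty mapping file")
    body = rows[1:]  # header required but its names are free
    pairs = []
    for row in body:
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise FaersIOError(f"{path}: mapping row {row!r} has fewer than 2 columns")
        pairs.append((row[0], row[1]))
    return PtSocMap.from_pairs(pairs)
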