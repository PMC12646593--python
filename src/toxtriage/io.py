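"""Readers and writers: chemical tables (CSV/TSV) and JSON audit reports.

Tables are UTF-8 delimited text with a header row. A column mapping
(``TableDialect``) renames caller columns onto the canonical field names;
missing optional cells become ``None`` -- never silent zeros. Ionizable
groups travel as two semicolon-joined columns (``pka_acids``, ``pka_bases``);
set-valued annotation fields are semicolon-joined too. Floats are written
with ``repr`` so a write/read round trip is value-exact.
"""

from __future__ import annotations

import csv
import json
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError, SchemaError
from .registry import ACID, BASE, ChemicalRecord, IonizationProfile
from .triage import TriageResult

CANONICAL_COLUMNS = [
    "name", "cas", "dtxsid", "smiles", "inchikey",
    "log_kow", "log_kaw", "pka_acids", "pka_bases", "zwitterionic",
    "purity_pct", "cost_eur", "available", "restricted", "hazard_excluded",
    "stability_ok", "toxicity_groups", "use_categories", "moa_tags", "exposome",
    "reference_compound", "moa_exception",
]

_FLOAT_FIELDS = {"log_kow", "log_kaw", "purity_pct", "cost_eur"}
_BOOL_FIELDS = {
    "zwitterionic", "available", "restricted", "hazard_excluded",
    "stability_ok", "exposome", "reference_compound", "moa_exception",
}
_SET_FIELDS = {"toxicity_groups", "use_categories", "moa_tags"}
_LIST_SEP = ";"


@dataclass
class TableDialect:
    """Column mapping and parsing options for a chemical table.

    ``columns`` maps canonical field name -> column name in the file
    (identity for anything unmapped). ``mandatory`` lists canonical fields
    whose columns must exist. ``delimiter`` defaults to comma.
    """

    columns: dict[str, str] = field(default_factory=dict)
    mandatory: list[str] = field(default_factory=lambda: ["name"])
    delimiter: str = ","

    def source_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_json(cls, path: str | Path) -> "TableDialect":
        raw = json.loads(Path(path).read_text())
        return cls(
            columns=raw.get("columns", {}),
            mandatory=raw.get("mandatory", ["name"]),
            delimiter=raw.get("delimiter", ","),
        )


def _parse_bool(value: str):
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(value)


def _parse_pka_list(value: str) -> tuple[float, ...]:
    return tuple(float(p) for p in value.split(_LIST_SEP) if p.strip())


def read_chemical_table(
    source: str | Path | _io.TextIOBase, dialect: TableDialect | None = None
) -> list[ChemicalRecord]:
    """Parse one :class:`ChemicalRecord` per row of a delimited table."""
    dialect = dialect or TableDialect()
    if isinstance(source, (str, Path)):
        handle: _io.TextIOBase = open(source, newline="", encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    try:
        reader = csv.DictReader(handle, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [
            f for f in dialect.mandatory if dialect.source_column(f) not in header
        ]
        if missing:
            raise SchemaError(missing)
        records = []
        for i, row in enumerate(reader):
            records.append(_record_from_row(row, i, dialect))
        return records
    finally:
        if close:
            handle.close()


def _record_from_row(
    row: dict[str, str], index: int, dialect: TableDialect
) -> ChemicalRecord:
    vals: dict[str, object] = {}
    for canon in CANONICAL_COLUMNS:
        cell = row.get(dialect.source_column(canon))
        if cell is None or cell.strip() == "":
            continue
        cell = cell.strip()
        try:
            if canon in _FLOAT_FIELDS:
                vals[canon] = float(cell)
            elif canon in _BOOL_FIELDS:
                vals[canon] = _parse_bool(cell)
            elif canon in _SET_FIELDS:
                vals[canon] = frozenset(
                    t.strip() for t in cell.split(_LIST_SEP) if t.strip()
                )
            elif canon in ("pka_acids", "pka_bases"):
                vals[canon] = _parse_pka_list(cell)
            else:
                vals[canon] = cell
        except ValueError:
            raise ParseError(index, dialect.source_column(canon), cell) from None

    groups = [(p, ACID) for p in vals.pop("pka_acids", ())]
    groups += [(p, BASE) for p in vals.pop("pka_bases", ())]
    profile = IonizationProfile(
        groups=tuple(groups), zwitterionic=bool(vals.pop("zwitterionic", False))
    )
    return ChemicalRecord(ionization=profile, **vals)  # type: ignore[arg-type]


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, frozenset):
        return _LIST_SEP.join(sorted(value))
    return str(value)


def write_chemical_table(
    records: list[ChemicalRecord],
    target: str | Path | _io.TextIOBase,
    dialect: TableDialect | None = None,
) -> None:
    """Write records as a delimited table that round-trips losslessly."""
    dialect = dialect or TableDialect()
    if isinstance(target, (str, Path)):
        handle: _io.TextIOBase = open(target, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = target, False
    try:
        cols = [dialect.source_column(c) for c in CANONICAL_COLUMNS]
        writer = csv.writer(handle, delimiter=dialect.delimiter)
        writer.writerow(cols)
        for rec in records:
            row = []
            for canon in CANONICAL_COLUMNS:
                if canon == "pka_acids":
                    row.append(_LIST_SEP.join(repr(p) for p in rec.ionization.acids))
                elif canon == "pka_bases":
                    row.append(_LIST_SEP.join(repr(p) for p in rec.ionization.bases))
                elif canon == "zwitterionic":
                    row.append(_format_cell(rec.ionization.zwitterionic))
                else:
                    row.append(_format_cell(getattr(rec, canon)))
            writer.writerow(row)
    finally:
        if close:
            handle.close()


def audit_report_dict(result: TriageResult) -> dict:
    """Machine-readable audit structure for a triage result."""
    return {
        "totals": {
            "input": len(result.retained) + len(result.excluded),
            "retained": len(result.retained),
            "excluded": len(result.excluded),
        },
        "stage_counts": result.stage_counts,
        "retained": [r.identifier for r in result.retained],
        "decisions": [
            {
                "identifier": e.record.identifier,
                "stage": e.stage,
                "failed_criteria": list(e.reasons),
            }
            for e in result.excluded
        ],
        "flagged_exceptions": [
            {"identifier": r.identifier, "breached_criteria": list(reasons)}
            for r, reasons in result.flagged_exceptions
        ],
    }


def write_audit_report(result: TriageResult, path: str | Path) -> None:
    """Serialize the audit report as JSON (round-trips via ``json.load``)."""
    Path(path).write_text(json.dumps(audit_report_dict(result), indent=2))


def read_audit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
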