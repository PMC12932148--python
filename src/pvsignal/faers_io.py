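"""Reading and writing FAERS-style quarterly ASCII extracts.

FAERS quarters are distributed as a set of '$'-delimited text tables
(DEMO, DRUG, REAC, OUTC, THER, ...) keyed by PRIMARYID (one row per report
version) and CASEID (one safety case, possibly several versions), plus an
optional deleted-cases list. This module reads those tables into string
DataFrames with validated headers, checks referential integrity against
DEMO, and provides the field-level decoders (sex, reporter occupation,
age→age-group, partial dates) used downstream.

Dialect notes
-------------
The delimiter is a literal '$' with no quoting mechanism. On write an
embedded '$' in a value is rejected; on read, lines with too many fields
are truncated to the schema width and counted in the parse report rather
than aborting the load.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DELIMITER = "$"

#: canonical column layout per table (uppercase, FAERS naming)
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
        "AGE_COD", "OCCP_COD", "REPORTER_COUNTRY",
    ],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
}

ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}

MISSING = "missing"

SEX_LABELS = {"M": "M", "F": "F"}

#: FAERS OCCP_COD → the reporter categories of the descriptive table.
#: "health-professor" is retained verbatim as the label for code HP.
REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "health-professor",
    "OT": "Other health professional",
}

AGE_GROUPS = ("<18", "18-65", ">65", MISSING)

_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}


class FaersFormatError(ValueError):
    """Malformed FAERS table: wrong delimiter, header or missing file."""


class FaersSchemaError(FaersFormatError):
    """Header lacks a mandatory column."""


@dataclass
class ParseReport:
    """Per-quarter accounting of what was read, flagged and dropped."""

    line_counts: dict[str, int] = field(default_factory=dict)
    truncated_lines: dict[str, int] = field(default_factory=dict)
    orphans: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def total_records(self) -> int:
        return sum(self.line_counts.values())


@dataclass
class QuarterBundle:
    """One quarter's tables as string DataFrames plus the deletion list.

    ``truth`` is populated only by the synthetic generator (ground-truth
    record for testing); bundles read from disk carry ``None``.
    """

    label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    deleted: frozenset = frozenset()
    truth: object | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
            "OUTC": self.outc, "THER": self.ther,
        }

    def equals(self, other: "QuarterBundle") -> bool:
        if self.deleted != other.deleted:
            return False
        for name, df in self.tables().items():
            odf = other.tables()[name]
            if not df.reset_index(drop=True).equals(odf.reset_index(drop=True)):
                return False
        return True


# ---------------------------------------------------------------------------
# low-level table I/O

def read_table(path: str | Path, table: str) -> tuple[pd.DataFrame, dict]:
    """Read one '$'-delimited table into a string DataFrame.

    Returns ``(frame, report)`` where report counts data lines and lines
    that carried extra fields (truncated, not fatal). Raises
    FaersSchemaError when a mandatory column is absent and
    FaersFormatError when the header does not look '$'-delimited.
    """
    path = Path(path)
    schema = TABLE_SCHEMAS[table]
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file")
    header = [h.strip().upper() for h in lines[0].split(DELIMITER)]
    if len(header) == 1 and len(schema) > 1:
        raise FaersFormatError(
            f"{path}: header not '{DELIMITER}'-delimited (line 1: {lines[0]!r})"
        )
    missing_cols = [c for c in schema if c not in header]
    if "PRIMARYID" in missing_cols:
        raise FaersSchemaError(f"{path}: mandatory column PRIMARYID absent")
    if missing_cols:
        raise FaersSchemaError(f"{path}: missing columns {missing_cols}")
    idx = [header.index(c) for c in schema]
    width = len(header)
    rows: list[list[str]] = []
    truncated = 0
    for ln in lines[1:]:
        if ln == "":
            continue
        parts = ln.split(DELIMITER)
        if len(parts) > width:
            parts = parts[:width]
            truncated += 1
        elif len(parts) < width:
            parts = parts + [""] * (width - len(parts))
        rows.append([parts[i].strip() for i in idx])
    frame = pd.DataFrame(rows, columns=schema, dtype=str)
    report = {"records": len(rows), "truncated": truncated}
    return frame, report


def write_table(frame: pd.DataFrame, path: str | Path, table: str) -> None:
    """Write a string DataFrame as a '$'-delimited FAERS table.

    Values containing the delimiter are rejected (the dialect has no
    quoting), per the documented write-time policy.
    """
    schema = TABLE_SCHEMAS[table]
    path = Path(path)
    lines = [DELIMITER.join(schema)]
    for row in frame[schema].itertuples(index=False):
        vals = ["" if v is None else str(v) for v in row]
        for v in vals:
            if DELIMITER in v:
                raise ValueError(
                    f"field value {v!r} contains the '{DELIMITER}' delimiter; "
                    "the FAERS dialect has no quoting"
                )
        lines.append(DELIMITER.join(vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _find_table_file(directory: Path, table: str) -> Path | None:
    hits = sorted(directory.glob(f"{table}*.txt")) + sorted(
        directory.glob(f"{table.lower()}*.txt")
    )
    return hits[0] if hits else None


def read_quarter(directory: str | Path) -> tuple[QuarterBundle, ParseReport]:
    """Load one quarter directory into a QuarterBundle.

    All five tables are mandatory; the deleted-cases list (``DELETED*.txt``,
    one CASEID per line) is optional. Child rows whose PRIMARYID has no DEMO
    parent are excluded and counted in the parse report.
    """
    directory = Path(directory)
    missing = [t for t in TABLE_SCHEMAS if _find_table_file(directory, t) is None]
    if missing:
        raise FaersFormatError(
            f"{directory}: missing mandatory table file(s): {', '.join(missing)}"
        )
    report = ParseReport()
    frames: dict[str, pd.DataFrame] = {}
    label = ""
    for table in TABLE_SCHEMAS:
        path = _find_table_file(directory, table)
        frame, rep = read_table(path, table)
        frames[table] = frame
        report.line_counts[table] = rep["records"]
        if rep["truncated"]:
            report.truncated_lines[table] = rep["truncated"]
            report.warnings.append(
                f"{path.name}: {rep['truncated']} line(s) had extra "
                f"'{DELIMITER}'-separated fields and were truncated"
            )
        m = re.match(rf"{table}(.+)\.txt", path.name, flags=re.IGNORECASE)
        if m and not label:
            label = m.group(1)

    parents = set(frames["DEMO"]["PRIMARYID"])
    for table in ("DRUG", "REAC", "OUTC", "THER"):
        frame = frames[table]
        mask = frame["PRIMARYID"].isin(parents)
        n_orphan = int((~mask).sum())
        if n_orphan:
            report.orphans[table] = n_orphan
            frames[table] = frame[mask].reset_index(drop=True)

    deleted: frozenset = frozenset()
    del_hits = sorted(directory.glob("DELETED*.txt")) + sorted(
        directory.glob("deleted*.txt")
    )
    if del_hits:
        deleted = frozenset(
            ln.strip()
            for ln in del_hits[0].read_text(encoding="utf-8").splitlines()
            if ln.strip()
        )

    bundle = QuarterBundle(
        label=label or directory.name,
        demo=frames["DEMO"], drug=frames["DRUG"], reac=frames["REAC"],
        outc=frames["OUTC"], ther=frames["THER"], deleted=deleted,
    )
    return bundle, report


def read_quarters(directories: Iterable[str | Path]) -> tuple[QuarterBundle, ParseReport]:
    """Concatenate several quarter directories into one pooled bundle."""
    bundles = []
    merged = ParseReport()
    for d in directories:
        b, rep = read_quarter(d)
        bundles.append(b)
        for k, v in rep.line_counts.items():
            merged.line_counts[k] = merged.line_counts.get(k, 0) + v
        for k, v in rep.orphans.items():
            merged.orphans[k] = merged.orphans.get(k, 0) + v
        merged.warnings.extend(rep.warnings)
    if not bundles:
        raise FaersFormatError("no quarter directories supplied")
    if len(bundles) == 1:
        return bundles[0], merged
    cat = {
        t: pd.concat([b.tables()[t] for b in bundles], ignore_index=True)
        for t in TABLE_SCHEMAS
    }
    deleted = frozenset().union(*(b.deleted for b in bundles))
    label = "+".join(b.label for b in bundles)
    return (
        QuarterBundle(label=label, demo=cat["DEMO"], drug=cat["DRUG"],
                      reac=cat["REAC"], outc=cat["OUTC"], ther=cat["THER"],
                      deleted=deleted),
        merged,
    )


# ---------------------------------------------------------------------------
# field decoders

def age_to_group(age_value, age_unit: str | None) -> str:
    """Convert a FAERS (AGE, AGE_COD) pair to an age-group label.

    Units: YR years, DEC decades, MON months, WK weeks, DY days. A missing
    unit with a plausible year value (0 < v < 120) is treated as years.
    Bins: <18, 18-65 (both boundaries inclusive in the middle bin), >65.
    Negative or unparseable values map to ``missing``.
    """
    if age_value is None:
        return MISSING
    try:
        v = float(age_value)
    except (TypeError, ValueError):
        return MISSING
    if v != v:  # NaN
        return MISSING
    unit = (age_unit or "").strip().upper()
    if unit in _AGE_UNIT_TO_YEARS:
        years = v * _AGE_UNIT_TO_YEARS[unit]
    elif unit == "" and 0 < v < 120:
        years = v
    else:
        return MISSING
    if years < 0:
        return MISSING
    if years < 18:
        return "<18"
    if years <= 65:
        return "18-65"
    return ">65"


def decode_sex(raw: str | None) -> str:
    return SEX_LABELS.get((raw or "").strip().upper(), MISSING)


def decode_reporter(raw: str | None) -> str:
    return REPORTER_LABELS.get((raw or "").strip().upper(), MISSING)


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date at day, month or year precision."""

    date: _dt.date | None
    precision: str  # 'day' | 'month' | 'year' | 'missing'

    @property
    def is_full(self) -> bool:
        return self.precision == "day"


def parse_date(raw: str | None) -> PartialDate:
    """Parse a yyyymmdd / yyyymm / yyyy FAERS date, keeping its precision.

    Invalid calendar dates degrade to ``missing`` rather than raising.
    """
    s = (raw or "").strip()
    if not s.isdigit():
        return PartialDate(None, MISSING)
    try:
        if len(s) == 8:
            return PartialDate(
                _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), "day")
        if len(s) == 6:
            return PartialDate(_dt.date(int(s[:4]), int(s[4:6]), 1), "month")
        if len(s) == 4:
            return PartialDate(_dt.date(int(s), 1, 1), "year")
    except ValueError:
        return PartialDate(None, MISSING)
    return PartialDate(None, MISSING)


def date_to_str(d: _dt.date | None, precision: str = "day") -> str:
    if d is None:
        return ""
    if precision == "day":
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    if precision == "month":
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}"
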