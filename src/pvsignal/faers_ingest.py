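"""Readers and the case data model for FAERS-style quarterly ASCII extracts.

FAERS quarterly data ship as six ``$``-delimited text tables — DEMO
(demographics, one row per report version), DRUG (one row per drug per
report), REAC (one row per MedDRA preferred term), THER (therapy dates),
OUTC (outcome codes) and INDI (indications).  This module parses those
tables, links them into :class:`CaseReport` objects keyed on the report
identifier, and deduplicates multiple versions of the same case.

Deduplication rule: FAERS re-publishes a case each time it is amended, so a
case identifier can appear under several report identifiers.  We keep, per
case, the report with the latest receipt date, breaking ties by the largest
report identifier (the FDA's "latest case version" convention).  This choice
changes every downstream count and is therefore applied in exactly one
place, :func:`deduplicate`.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("pvsignal")

FAERS_DELIMITER = "$"

#: The six tables of a FAERS quarterly extract and the columns each must carry.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "fda_dt", "sex", "age", "age_cod", "wt",
             "occr_country", "occp_cod"),
    "DRUG": ("primaryid", "caseid", "drugname", "role_cod", "route"),
    "REAC": ("primaryid", "caseid", "pt"),
    "THER": ("primaryid", "caseid", "start_dt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "INDI": ("primaryid", "caseid", "indi_pt"),
}

SEX_CODES = {"F": "female", "M": "male"}

REPORTER_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "CN": "consumer",
    "RN": "registered nurse",
}

OUTCOME_CODES = {
    "HO": "hospitalization",
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}

#: Age-unit code -> multiplicative factor to years (``None`` = not convertible).
AGE_UNIT_TO_YEARS: dict[str, float | None] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": None,
}

#: Ages above this (in years) are treated as data errors and set missing.
MAX_PLAUSIBLE_AGE = 120.0


class FaersFormatError(ValueError):
    """A table file is missing a mandatory column or is otherwise unreadable."""


@dataclass
class IngestLog:
    """Counters accumulated while parsing and linking one dataset."""

    malformed_dates: int = 0
    dropped_no_events: int = 0
    dropped_orphan_rows: int = 0
    duplicates_removed: int = 0
    rows_read: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class DrugRecord:
    """One drug mention on a report.

    ``role`` is the FAERS role code: PS (primary suspect), SS (secondary
    suspect), C (concomitant) or I (interacting).
    """

    drug_name_raw: str
    drug_name_normalized: str
    role: str
    route: str | None = None
    therapy_start_date: _dt.date | None = None
    indication_pt: str | None = None


@dataclass(frozen=True)
class CaseReport:
    """One safety report (one version of one case) after table linking."""

    case_id: int
    report_id: int
    receipt_date: _dt.date | None
    sex: str  # female / male / unknown
    age_years: float | None
    weight_kg: float | None
    country: str | None
    reporter: str  # physician / pharmacist / ... / unknown
    outcomes: tuple[str, ...]
    drugs: tuple[DrugRecord, ...]
    events: tuple[str, ...]
    event_onset_date: _dt.date | None


# ---------------------------------------------------------------------------
# Field parsing
# ---------------------------------------------------------------------------

def parse_faers_date(raw: str | None) -> _dt.date | None:
    """Parse the 8- (YYYYMMDD), 6- (YYYYMM) or 4-digit (YYYY) FAERS date styles.

    Partial dates resolve to the first day of the stated period.  Returns
    ``None`` for blank or malformed values; the caller counts the malformed
    ones.
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        raise ValueError(f"unparseable FAERS date: {raw!r}")
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else 1
    day = int(s[6:8]) if len(s) == 8 else 1
    return _dt.date(year, month, day)  # raises ValueError on e.g. month 13


def _parse_date_field(raw: str, log: IngestLog | None) -> _dt.date | None:
    try:
        return parse_faers_date(raw)
    except ValueError:
        if log is not None:
            log.malformed_dates += 1
        logger.warning("malformed date %r set to missing", raw)
        return None


def parse_age_years(age: str, age_cod: str) -> float | None:
    """Harmonize the FAERS (age, unit-code) pair to years.

    Unknown or hour-scale units, non-numeric values and implausible results
    (> 120 years) all map to missing.
    """
    s = age.strip()
    if not s:
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    factor = AGE_UNIT_TO_YEARS.get(age_cod.strip().upper() or "YR")
    if factor is None:
        return None
    years = value * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE:
        return None
    return years


def _parse_float(raw: str) -> float | None:
    s = raw.strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    return v if v > 0 else None


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------

def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one ``$``-delimited FAERS table into a string DataFrame.

    Column supersets are tolerated; a missing mandatory column raises
    :class:`FaersFormatError` naming the table and column.
    """
    table = table.upper()
    if table not in REQUIRED_COLUMNS:
        raise FaersFormatError(f"unknown FAERS table {table!r}")
    df = pd.read_csv(path, sep=FAERS_DELIMITER, dtype=str,
                     keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise FaersFormatError(
                f"table {table}: mandatory column {col!r} missing from {path}")
    return df


def read_quarter(paths: Mapping[str, str | Path],
                 log: IngestLog | None = None) -> dict[str, pd.DataFrame]:
    """Read the six quarterly tables given a mapping table-name -> file path."""
    tables: dict[str, pd.DataFrame] = {}
    for name in REQUIRED_COLUMNS:
        if name not in {k.upper() for k in paths}:
            raise FaersFormatError(f"no path supplied for table {name}")
    for name, path in paths.items():
        name = name.upper()
        df = read_table(path, name)
        tables[name] = df
        if log is not None:
            log.rows_read[name] = len(df)
        logger.info("read %s: %d rows from %s", name, len(df), path)
    return tables


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _grouped(df: pd.DataFrame) -> dict[str, list[dict]]:
    out: dict[str, list[dict]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["primaryid"].strip(), []).append(row)
    return out


def link_tables(tables: Mapping[str, pd.DataFrame],
                log: IngestLog | None = None) -> list[CaseReport]:
    """Join the six tables into one :class:`CaseReport` per DEMO row.

    Reports with zero REAC rows are dropped (an adverse-event report without
    an event is unusable); DRUG/REAC/... rows whose report id matches no DEMO
    row are dropped.  Both counts are logged.
    """
    tables = {k.upper(): v for k, v in tables.items()}
    demo = tables["DEMO"]
    demo_ids = set(pid.strip() for pid in demo["primaryid"])

    linked: dict[str, dict[str, list[dict]]] = {}
    orphans = 0
    for name in ("DRUG", "REAC", "THER", "OUTC", "INDI"):
        for pid, rows in _grouped(tables[name]).items():
            if pid not in demo_ids:
                orphans += len(rows)
                continue
            linked.setdefault(pid, {}).setdefault(name, []).extend(rows)
    if orphans:
        logger.info("dropped %d rows with no matching DEMO report", orphans)
    if log is not None:
        log.dropped_orphan_rows += orphans

    # Therapy start dates attach to drugs positionally when the THER table has
    # no drug sequence column: the i-th THER row of a report pairs with the
    # i-th DRUG row.  FAERS carries dsg_drug_seq for this; the positional rule
    # covers extracts without it.
    cases: list[CaseReport] = []
    dropped_no_events = 0
    for row in demo.to_dict("records"):
        pid = row["primaryid"].strip()
        sub = linked.get(pid, {})
        reac_rows = sub.get("REAC", [])
        if not reac_rows:
            dropped_no_events += 1
            continue
        drug_rows = sub.get("DRUG", [])
        ther_rows = sub.get("THER", [])
        indi_rows = sub.get("INDI", [])
        drugs = []
        for i, d in enumerate(drug_rows):
            start = (_parse_date_field(ther_rows[i]["start_dt"], log)
                     if i < len(ther_rows) else None)
            indi = (indi_rows[i]["indi_pt"].strip() or None
                    if i < len(indi_rows) else None)
            raw = d["drugname"].strip()
            drugs.append(DrugRecord(
                drug_name_raw=raw,
                drug_name_normalized=raw.upper(),
                role=d["role_cod"].strip().upper(),
                route=d["route"].strip() or None,
                therapy_start_date=start,
                indication_pt=indi,
            ))
        events = tuple(r["pt"].strip() for r in reac_rows if r["pt"].strip())
        if not events:
            dropped_no_events += 1
            continue
        outcomes = tuple(sorted(
            {OUTCOME_CODES[o["outc_cod"].strip().upper()]
             for o in sub.get("OUTC", [])
             if o["outc_cod"].strip().upper() in OUTCOME_CODES}))
        onset = _parse_date_field(row.get("event_dt", ""), log)
        cases.append(CaseReport(
            case_id=int(row["caseid"]),
            report_id=int(pid),
            receipt_date=_parse_date_field(row["fda_dt"], log),
            sex=SEX_CODES.get(row["sex"].strip().upper(), "unknown"),
            age_years=parse_age_years(row["age"], row["age_cod"]),
            weight_kg=_parse_float(row["wt"]),
            country=row["occr_country"].strip() or None,
            reporter=REPORTER_CODES.get(row["occp_cod"].strip().upper(),
                                        "unknown"),
            outcomes=outcomes,
            drugs=tuple(drugs),
            events=events,
            event_onset_date=onset,
        ))
    if dropped_no_events:
        logger.info("dropped %d reports with no REAC rows", dropped_no_events)
    if log is not None:
        log.dropped_no_events += dropped_no_events
    return cases


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(reports: Iterable[CaseReport],
                log: IngestLog | None = None) -> list[CaseReport]:
    """Keep one report per case: latest receipt date, ties to largest report id.

    Missing receipt dates sort before any real date.  The operation removes
    whole reports and never edits fields, so it is idempotent.
    """
    best: dict[int, CaseReport] = {}
    n_in = 0
    for r in reports:
        n_in += 1
        cur = best.get(r.case_id)
        if cur is None or _dedup_key(r) > _dedup_key(cur):
            best[r.case_id] = r
    kept = sorted(best.values(), key=lambda r: r.case_id)
    removed = n_in - len(kept)
    if removed:
        logger.info("deduplication removed %d of %d reports", removed, n_in)
    if log is not None:
        log.duplicates_removed += removed
    return kept


def _dedup_key(r: CaseReport) -> tuple[_dt.date, int]:
    return (r.receipt_date or _dt.date.min, r.report_id)
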