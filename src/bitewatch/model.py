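"""Data model and readers for FAERS-dialect spontaneous report tables.

The public FAERS quarterly extracts ship one ASCII file per table kind
(DEMO, DRUG, REAC, OUTC, THER ...), one record per line, fields separated
by ``$``, first line the header.  This module parses that dialect into
typed records, normalizes the coded fields (dates, age units, sex,
reporter occupation, outcome codes, country) and performs case
deduplication: FAERS stores every revision of a case as a separate report
row, and analyses must keep exactly one row per case.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "RPSR", "INDI")

#: Table kinds accepted but not modelled (report sources, indications).
IGNORED_KINDS = ("RPSR", "INDI")

REQUIRED_COLUMNS = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq"),
}


class FaersFormatError(ValueError):
    """A table file violates the dialect (e.g. a required column is absent)."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Reporter(str, enum.Enum):
    CONSUMER = "consumer"
    HEALTH_PROFESSIONAL = "health-professional"
    OTHER_HEALTH_PROFESSIONAL = "other health-professional"
    PHARMACIST = "pharmacist"
    PHYSICIAN = "physician"
    UNKNOWN = "unknown"


class Outcome(str, enum.Enum):
    DEATH = "death"
    DISABILITY = "disability"
    HOSPITALIZATION = "hospitalization"
    LIFE_THREATENING = "life-threatening"
    OTHER_SERIOUS = "other-serious"
    REQUIRED_INTERVENTION = "required-intervention"
    UNKNOWN = "unknown"


SEX_CODES = {"F": Sex.FEMALE, "M": Sex.MALE}

REPORTER_CODES = {
    "CN": Reporter.CONSUMER,
    "HP": Reporter.HEALTH_PROFESSIONAL,
    "OT": Reporter.OTHER_HEALTH_PROFESSIONAL,
    "PH": Reporter.PHARMACIST,
    "MD": Reporter.PHYSICIAN,
}

OUTCOME_CODES = {
    "DE": Outcome.DEATH,
    "DS": Outcome.DISABILITY,
    "HO": Outcome.HOSPITALIZATION,
    "LT": Outcome.LIFE_THREATENING,
    "OT": Outcome.OTHER_SERIOUS,
    "RI": Outcome.REQUIRED_INTERVENTION,
}

#: Age unit code -> divisor converting the raw value to years.
#: DEC is decades (multiply by ten), hence the 0.1 divisor.
AGE_UNIT_DIVISORS = {
    "YR": 1.0,
    "DEC": 0.1,
    "MON": 12.0,
    "WK": 52.143,
    "DY": 365.25,
    "HR": 8766.0,
}

AGE_PLAUSIBLE_MAX = 120.0


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report (one version of one case)."""

    primary_id: str
    case_id: str
    case_version: int = 0
    fda_receipt_date: date | None = None
    event_date: date | None = None
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    weight_kg: float | None = None
    reporter: Reporter = Reporter.UNKNOWN
    country: str = "unknown"
    outcomes: frozenset[Outcome] = field(default_factory=frozenset)


@dataclass(frozen=True)
class DrugMention:
    primary_id: str
    drug_seq: int
    role_code: str = "PS"
    verbatim_name: str = ""
    active_ingredient: str | None = None


@dataclass(frozen=True)
class EventMention:
    primary_id: str
    preferred_term: str


@dataclass(frozen=True)
class TherapyEpisode:
    primary_id: str
    drug_seq: int
    start_date: date | None = None
    end_date: date | None = None


def parse_faers_date(raw: str | None) -> date | None:
    """Parse a FAERS date field (``YYYYMMDD``, ``YYYYMM`` or ``YYYY``).

    Only full ``YYYYMMDD`` values become dates; partial dates and empty
    fields return ``None`` so they are excluded from interval arithmetic
    rather than imputed.  Garbage is logged and treated as absent.
    """
    if raw is None:
        return None
    raw = str(raw).strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        logger.warning("unparseable date %r treated as absent", raw)
        return None
    if len(raw) != 8:
        return None  # partial date
    try:
        return datetime.strptime(raw, "%Y%m%d").date()
    except ValueError:
        logger.warning("invalid calendar date %r treated as absent", raw)
        return None


def normalize_age(value: float | None, unit_code: str | None) -> float | None:
    """Convert a raw FAERS age to years.

    Units: YR years, DEC decades, MON months, WK weeks, DY days, HR hours.
    An empty unit with a value in (0, 120] is taken to already be years.
    Results outside [0, 120] are implausible and returned as absent.
    """
    if value is None or pd.isna(value):
        return None
    value = float(value)
    if value < 0:
        logger.warning("negative age %s treated as absent", value)
        return None
    unit = (unit_code or "").strip().upper()
    if not unit:
        if 0 < value <= AGE_PLAUSIBLE_MAX:
            return value
        return None
    if unit not in AGE_UNIT_DIVISORS:
        return None
    years = value / AGE_UNIT_DIVISORS[unit]
    if years > AGE_PLAUSIBLE_MAX:
        return None
    return years


def _read_dialect_file(path: Path) -> pd.DataFrame:
    """Read one ``$``-delimited file tolerantly.

    Short rows are padded with empty fields; rows carrying non-empty
    fields beyond the header width are counted, logged and skipped.  A
    trailing empty field (row ending in ``$``) is ignored.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    if not lines or not lines[0].strip():
        raise FaersFormatError(f"{path}: empty file or missing header")
    header = [h.strip().lower() for h in lines[0].split("$")]
    if header and header[-1] == "":
        header = header[:-1]
    ncol = len(header)
    rows: list[list[str]] = []
    bad = 0
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.split("$")
        if len(fields) > ncol:
            extra = fields[ncol:]
            if any(f.strip() for f in extra):
                bad += 1
                continue
            fields = fields[:ncol]
        elif len(fields) < ncol:
            fields = fields + [""] * (ncol - len(fields))
        rows.append(fields)
    if bad:
        logger.warning("%s: skipped %d unparseable rows", path, bad)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    frame.attrs["n_unparseable"] = bad
    return frame


def read_table_frame(directory: str | Path, table_kind: str) -> pd.DataFrame:
    """Read every file of one table kind in ``directory`` into a DataFrame.

    Files are matched case-insensitively on the kind appearing in the file
    name (the FAERS convention, e.g. ``DEMO25Q1.txt``).  Column names are
    lower-cased; required columns are checked.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"input directory not found: {directory}")
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and kind.lower() in p.name.lower()
    )
    if kind in IGNORED_KINDS:
        logger.info("table kind %s accepted but ignored", kind)
        return pd.DataFrame()
    frames = []
    bad = 0
    for p in paths:
        frame = _read_dialect_file(p)
        for col in REQUIRED_COLUMNS[kind]:
            if col not in frame.columns:
                raise FaersFormatError(
                    f"{p}: required column {col!r} missing from header"
                )
        bad += frame.attrs.get("n_unparseable", 0)
        frames.append(frame)
    if not frames:
        out = pd.DataFrame(columns=list(REQUIRED_COLUMNS[kind]))
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["n_unparseable"] = bad
    return out


def _demo_record(row: pd.Series) -> CaseReport:
    get = lambda k: str(row[k]).strip() if k in row.index and pd.notna(row[k]) else ""
    age_raw = get("age")
    try:
        age_val = float(age_raw) if age_raw else None
    except ValueError:
        age_val = None
    wt_raw = get("wt")
    try:
        weight = float(wt_raw) if wt_raw else None
        if weight is not None and weight <= 0:
            weight = None
    except ValueError:
        weight = None
    version_raw = get("caseversion")
    try:
        version = int(float(version_raw)) if version_raw else 0
    except ValueError:
        version = 0
    # Occurrence country preferred, reporter country as fallback.
    country = get("occr_country") or get("reporter_country") or "unknown"
    return CaseReport(
        primary_id=get("primaryid"),
        case_id=get("caseid"),
        case_version=version,
        fda_receipt_date=parse_faers_date(get("fda_dt")),
        event_date=parse_faers_date(get("event_dt")),
        age_years=normalize_age(age_val, get("age_cod")),
        sex=SEX_CODES.get(get("sex").upper(), Sex.UNKNOWN),
        weight_kg=weight,
        reporter=REPORTER_CODES.get(get("occp_cod").upper(), Reporter.UNKNOWN),
        country=country,
    )


def _int_or_zero(raw: str) -> int:
    try:
        return int(float(raw))
    except (ValueError, TypeError):
        return 0


def read_faers_tables(directory: str | Path, table_kind: str):
    """Parse one table kind into typed records.

    DEMO rows become :class:`CaseReport` stubs (outcomes attached
    separately from OUTC), DRUG rows :class:`DrugMention`, REAC rows
    :class:`EventMention`, THER rows :class:`TherapyEpisode`.  OUTC rows
    are returned as ``(primary_id, Outcome)`` pairs.
    """
    kind = table_kind.upper()
    frame = read_table_frame(directory, kind)
    if frame.empty:
        return []
    if kind == "DEMO":
        return [_demo_record(row) for _, row in frame.iterrows()]
    if kind == "DRUG":
        return [
            DrugMention(
                primary_id=str(r.get("primaryid", "")).strip(),
                drug_seq=_int_or_zero(r.get("drug_seq", "0")),
                role_code=str(r.get("role_cod", "PS")).strip().upper() or "PS",
                verbatim_name=str(r.get("drugname", "")).strip(),
                active_ingredient=(str(r["prod_ai"]).strip() or None)
                if "prod_ai" in frame.columns and pd.notna(r.get("prod_ai"))
                else None,
            )
            for _, r in frame.iterrows()
        ]
    if kind == "REAC":
        return [
            EventMention(
                primary_id=str(r["primaryid"]).strip(),
                preferred_term=str(r["pt"]).strip(),
            )
            for _, r in frame.iterrows()
            if str(r["pt"]).strip()
        ]
    if kind == "OUTC":
        return [
            (
                str(r["primaryid"]).strip(),
                OUTCOME_CODES.get(str(r["outc_cod"]).strip().upper(), Outcome.UNKNOWN),
            )
            for _, r in frame.iterrows()
        ]
    if kind == "THER":
        return [
            TherapyEpisode(
                primary_id=str(r["primaryid"]).strip(),
                drug_seq=_int_or_zero(r.get("dsg_drug_seq", "0")),
                start_date=parse_faers_date(r.get("start_dt")),
                end_date=parse_faers_date(r.get("end_dt")),
            )
            for _, r in frame.iterrows()
        ]
    return []


def _pid_sort_key(pid: str):
    s = str(pid)
    return (1, int(s), "") if s.isdigit() else (0, 0, s)


def deduplicate_cases(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep exactly one report per case.

    Retention rule: highest ``case_version``; ties broken by latest FDA
    receipt date, then by highest ``primary_id``.  Idempotent; the output
    size equals the number of distinct case ids.
    """
    best: dict[str, CaseReport] = {}
    for rep in reports:
        key = (
            rep.case_version,
            rep.fda_receipt_date or date.min,
            _pid_sort_key(rep.primary_id),
        )
        prev = best.get(rep.case_id)
        if prev is None:
            best[rep.case_id] = rep
        else:
            prev_key = (
                prev.case_version,
                prev.fda_receipt_date or date.min,
                _pid_sort_key(prev.primary_id),
            )
            if key > prev_key:
                best[rep.case_id] = rep
    return list(best.values())


def dedup_demo_frame(demo: pd.DataFrame) -> pd.DataFrame:
    """Vectorized deduplication of a raw DEMO frame (same rule as
    :func:`deduplicate_cases`); returns the retained rows."""
    if demo.empty:
        return demo
    work = demo.copy()
    work["_ver"] = pd.to_numeric(work.get("caseversion", 0), errors="coerce").fillna(0)
    work["_dt"] = pd.to_numeric(work.get("fda_dt", 0), errors="coerce").fillna(0)
    work["_pid"] = pd.to_numeric(work["primaryid"], errors="coerce").fillna(0)
    work = work.sort_values(["_ver", "_dt", "_pid"], kind="mergesort")
    work = work.drop_duplicates(subset="caseid", keep="last")
    return work.drop(columns=["_ver", "_dt", "_pid"]).reset_index(drop=True)


def write_table_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the ``$``-delimited dialect (round-trip safe
    for fields containing no ``$`` or newline)."""
    path = Path(path)
    cols = list(frame.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("$".join(cols) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")


def reports_to_frame(reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Normalized tabular view of case reports (CSV-exportable)."""
    return pd.DataFrame(
        {
            "primary_id": [r.primary_id for r in reports],
            "case_id": [r.case_id for r in reports],
            "case_version": [r.case_version for r in reports],
            "fda_receipt_date": [r.fda_receipt_date for r in reports],
            "event_date": [r.event_date for r in reports],
            "age_years": [r.age_years for r in reports],
            "sex": [r.sex.value for r in reports],
            "weight_kg": [r.weight_kg for r in reports],
            "reporter": [r.reporter.value for r in reports],
            "country": [r.country for r in reports],
            "outcomes": [";".join(sorted(o.value for o in r.outcomes)) for r in reports],
        }
    )
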