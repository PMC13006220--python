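"""Reading, deduplicating and linking FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as ``$``-delimited text tables (DEMO, DRUG,
REAC, OUTC, THER, INDI) joined on a report-level PRIMARYID. A case that is
re-submitted to the FDA appears under the same CASEID with a higher
CASEVERSION; only the latest version of each case should enter an analysis.
This module parses the tables, applies that deduplication, and assembles one
:class:`CaseBundle` per surviving report.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .dates import PartialDate

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

#: Columns that must be present in the header of each table kind.
REQUIRED_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
    "INDI": ("primaryid", "indi_drug_seq"),
}

DRUG_ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: FAERS reporter occupation codes -> analysis categories.
OCCUPATION_MAP = {
    "CN": "consumer",
    "HP": "health professional",
    "MD": "physician",
    "PH": "pharmacist",
    "LW": "other",
    "OT": "other",
    "RN": "other",
}


class SchemaError(ValueError):
    """A table file is missing a required column."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass
class RawTableRow:
    """One data line of a FAERS table, minimally typed.

    ``caseid``/``caseversion``/``fda_dt`` are populated for DEMO rows only;
    every raw field (lower-cased column name -> string) is kept in
    ``payload`` so downstream parsing can stay table-specific.
    """

    table_kind: str
    primaryid: str
    caseid: Optional[str] = None
    caseversion: Optional[int] = None
    fda_dt: Optional[PartialDate] = None
    payload: Dict[str, str] = field(default_factory=dict)


@dataclass
class DrugRecord:
    drug_seq: int
    drugname: str
    role_cod: str
    prod_ai: Optional[str] = None


@dataclass
class Demographics:
    age_years: Optional[float] = None
    sex: str = "unknown"  # F / M / unknown
    country: Optional[str] = None
    occupation: str = "unknown"
    event_quarter: Optional[Tuple[int, int]] = None
    event_date: Optional[PartialDate] = None
    fda_date: Optional[PartialDate] = None


@dataclass
class CaseBundle:
    """One deduplicated report with all linked rows attached."""

    primaryid: str
    demographics: Demographics
    drugs: List[DrugRecord] = field(default_factory=list)
    reactions: List[str] = field(default_factory=list)
    outcomes: List[str] = field(default_factory=list)
    therapy_starts: Dict[int, PartialDate] = field(default_factory=dict)
    indications: List[str] = field(default_factory=list)

    def unique_pts(self) -> List[str]:
        """Reaction PTs with within-report repeats removed (first-seen order)."""
        seen: Dict[str, None] = {}
        for pt in self.reactions:
            seen.setdefault(pt, None)
        return list(seen)


def _parse_int(raw: object, default: Optional[int] = None) -> Optional[int]:
    try:
        return int(float(str(raw)))
    except (TypeError, ValueError):
        return default


def read_table(path, table_kind: str) -> List[RawTableRow]:
    """Read one ``$``-delimited FAERS table into raw rows.

    The dialect has no quoting; a line whose field count disagrees with the
    header is treated as malformed, logged and skipped. Unparseable dates are
    retained as partial dates (or None), never dropped with their row.
    """
    if table_kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind}")
    path = Path(path)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", pd.errors.ParserWarning)
            df = pd.read_csv(
                path,
                sep="$",
                dtype=str,
                quoting=csv.QUOTE_NONE,
                keep_default_na=False,
                on_bad_lines="warn",
            )
    except pd.errors.EmptyDataError:
        logger.warning("%s table %s is empty", table_kind, path)
        return []
    bad = [w for w in caught if issubclass(w.category, pd.errors.ParserWarning)]
    if bad:
        logger.warning(
            "%s table %s: skipped %d malformed line(s)", table_kind, path, len(bad)
        )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[table_kind]:
        if col not in df.columns:
            raise SchemaError(f"{table_kind} table {path} missing required column '{col}'")
    return rows_from_frame(df, table_kind)


def rows_from_frame(df: pd.DataFrame, table_kind: str) -> List[RawTableRow]:
    """Convert a string-typed DataFrame (one FAERS table) into raw rows."""
    cols = [str(c).lower() for c in df.columns]
    arrays = [
        ["" if v is None or v != v else str(v) for v in df[c].to_numpy()]
        for c in df.columns
    ]
    rows: List[RawTableRow] = []
    is_demo = table_kind == "DEMO"
    for vals in zip(*arrays):
        payload = dict(zip(cols, vals))
        primaryid = payload.get("primaryid", "").strip()
        if not primaryid:
            continue
        row = RawTableRow(table_kind=table_kind, primaryid=primaryid, payload=payload)
        if is_demo:
            row.caseid = payload.get("caseid", "").strip() or None
            row.caseversion = _parse_int(payload.get("caseversion"), default=1)
            row.fda_dt = PartialDate.parse(payload.get("fda_dt"))
        rows.append(row)
    return rows


def deduplicate(demo_rows: Iterable[RawTableRow]) -> List[RawTableRow]:
    """Keep the latest version of each case.

    Within a CASEID group the retained row maximises
    (fda_dt, caseversion, primaryid) lexicographically; missing components
    sort first. Output is sorted by caseid, making the operation
    deterministic and idempotent.
    """

    def key(row: RawTableRow):
        dt = row.fda_dt.sort_key() if row.fda_dt is not None else (0, 0, 0)
        return (dt, row.caseversion if row.caseversion is not None else 0, row.primaryid)

    best: Dict[str, RawTableRow] = {}
    for row in demo_rows:
        cid = row.caseid if row.caseid is not None else row.primaryid
        cur = best.get(cid)
        if cur is None or key(row) > key(cur):
            best[cid] = row
    return [best[cid] for cid in sorted(best)]


def _parse_age(payload: Dict[str, str]) -> Optional[float]:
    raw = payload.get("age", "").strip()
    if not raw:
        return None
    try:
        val = float(raw)
    except ValueError:
        return None
    cod = payload.get("age_cod", "").strip().upper()
    factor = {
        "": 1.0,
        "YR": 1.0,
        "DEC": 10.0,
        "MON": 1.0 / 12.0,
        "WK": 1.0 / 52.1775,
        "DY": 1.0 / 365.25,
        "HR": 1.0 / 8766.0,
    }.get(cod)
    if factor is None:
        return None
    years = val * factor
    if years < 0 or years > 120:  # implausible, treat as missing
        return None
    return years


def _parse_demographics(row: RawTableRow) -> Demographics:
    p = row.payload
    sex = p.get("sex", "").strip().upper()
    country = p.get("occr_country", "").strip().upper() or None
    occ = OCCUPATION_MAP.get(p.get("occp_cod", "").strip().upper(), "unknown")
    event_date = PartialDate.parse(p.get("event_dt"))
    fda = row.fda_dt
    return Demographics(
        age_years=_parse_age(p),
        sex=sex if sex in ("F", "M") else "unknown",
        country=country,
        occupation=occ,
        event_quarter=fda.quarter if fda is not None else None,
        event_date=event_date,
        fda_date=fda,
    )


@dataclass
class LinkResult:
    bundles: List[CaseBundle]
    orphan_counts: Dict[str, int]


def link_cases(tables: Dict[str, Iterable[RawTableRow]]) -> LinkResult:
    """Assemble one CaseBundle per deduplicated DEMO row.

    DRUG/REAC/OUTC/THER/INDI rows attach by primaryid equality; rows whose
    primaryid has no surviving DEMO row are counted as orphans and logged,
    not attached.
    """
    demo = list(tables.get("DEMO", []))
    ids = [r.primaryid for r in demo]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate primaryid in deduplicated DEMO: {dupes[:5]}")

    bundles: Dict[str, CaseBundle] = {}
    for row in demo:
        bundles[row.primaryid] = CaseBundle(
            primaryid=row.primaryid, demographics=_parse_demographics(row)
        )

    orphans: Dict[str, int] = {}
    for kind in ("DRUG", "REAC", "OUTC", "THER", "INDI"):
        n_orphan = 0
        for row in tables.get(kind, []):
            bundle = bundles.get(row.primaryid)
            if bundle is None:
                n_orphan += 1
                continue
            p = row.payload
            if kind == "DRUG":
                role = p.get("role_cod", "").strip().upper()
                bundle.drugs.append(
                    DrugRecord(
                        drug_seq=_parse_int(p.get("drug_seq"), default=0) or 0,
                        drugname=p.get("drugname", "").strip(),
                        role_cod=role if role in DRUG_ROLE_CODES else "C",
                        prod_ai=p.get("prod_ai", "").strip() or None,
                    )
                )
            elif kind == "REAC":
                pt = p.get("pt", "").strip()
                if pt:
                    bundle.reactions.append(pt)
            elif kind == "OUTC":
                code = p.get("outc_cod", "").strip().upper()
                if code:
                    bundle.outcomes.append(code)
            elif kind == "THER":
                seq = _parse_int(p.get("dsg_drug_seq"))
                start = PartialDate.parse(p.get("start_dt"))
                if seq is not None and start is not None:
                    prev = bundle.therapy_starts.get(seq)
                    # keep the earliest day-precision start per drug sequence
                    if prev is None or (
                        start.is_day_precision
                        and (not prev.is_day_precision or start.sort_key() < prev.sort_key())
                    ):
                        bundle.therapy_starts[seq] = start
            elif kind == "INDI":
                indi = p.get("indi_pt", "").strip()
                if indi:
                    bundle.indications.append(indi)
        if n_orphan:
            logger.warning("%s: %d orphan row(s) with no surviving DEMO match", kind, n_orphan)
        orphans[kind] = n_orphan
    return LinkResult(bundles=list(bundles.values()), orphan_counts=orphans)


def bundles_to_tables(bundles: Iterable[CaseBundle]) -> Dict[str, pd.DataFrame]:
    """Export bundles back to the six-table layout (normalized, string-typed)."""
    demo, drug, reac, outc, ther, indi = [], [], [], [], [], []
    for b in bundles:
        d = b.demographics
        demo.append(
            {
                "primaryid": b.primaryid,
                "caseid": b.primaryid,
                "caseversion": "1",
                "fda_dt": str(d.fda_date) if d.fda_date else "",
                "event_dt": str(d.event_date) if d.event_date else "",
                "age": f"{d.age_years:.2f}".rstrip("0").rstrip(".") if d.age_years is not None else "",
                "age_cod": "YR" if d.age_years is not None else "",
                "sex": d.sex if d.sex in ("F", "M") else "",
                "occr_country": d.country or "",
                "occp_cod": {v: k for k, v in OCCUPATION_MAP.items() if k != "LW" and k != "RN"}.get(
                    d.occupation, ""
                ),
            }
        )
        for dr in b.drugs:
            drug.append(
                {
                    "primaryid": b.primaryid,
                    "drug_seq": str(dr.drug_seq),
                    "role_cod": dr.role_cod,
                    "drugname": dr.drugname,
                    "prod_ai": dr.prod_ai or "",
                }
            )
        for pt in b.reactions:
            reac.append({"primaryid": b.primaryid, "pt": pt})
        for code in b.outcomes:
            outc.append({"primaryid": b.primaryid, "outc_cod": code})
        for seq, start in sorted(b.therapy_starts.items()):
            ther.append(
                {"primaryid": b.primaryid, "dsg_drug_seq": str(seq), "start_dt": str(start)}
            )
        for ind in b.indications:
            indi.append({"primaryid": b.primaryid, "indi_drug_seq": "1", "indi_pt": ind})
    cols = {
        "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "age", "age_cod",
                 "sex", "occr_country", "occp_cod"],
        "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        "REAC": ["primaryid", "pt"],
        "OUTC": ["primaryid", "outc_cod"],
        "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
        "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
    }
    data = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther, "INDI": indi}
    return {k: pd.DataFrame(v, columns=cols[k], dtype=str) for k, v in data.items()}


def write_tables(tables: Dict[str, pd.DataFrame], out_dir) -> Dict[str, Path]:
    """Write six-table layout as ``$``-delimited text files (FAERS dialect)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, df in tables.items():
        path = out_dir / f"{kind}.txt"
        df.to_csv(path, sep="$", index=False, quoting=csv.QUOTE_NONE)
        paths[kind] = path
    return paths


def read_tables(in_dir) -> Dict[str, List[RawTableRow]]:
    """Read all six tables from a directory (files named ``<KIND>*.txt``)."""
    in_dir = Path(in_dir)
    out: Dict[str, List[RawTableRow]] = {}
    for kind in TABLE_KINDS:
        matches = sorted(in_dir.glob(f"{kind}*.txt")) + sorted(in_dir.glob(f"{kind.lower()}*.txt"))
        rows: List[RawTableRow] = []
        for path in matches:
            rows.extend(read_table(path, kind))
        out[kind] = rows
    return out
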