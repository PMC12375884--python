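"""Reading and normalising FAERS-format quarterly tables.

FAERS (the FDA Adverse Event Reporting System) publishes each quarter as a
set of "$"-delimited ASCII tables — DEMO (demographics), DRUG, REAC
(reactions), OUTC (outcomes), THER (therapy dates) and INDI (indications) —
keyed by PRIMARYID, with CASEID identifying the underlying case across
report versions.  This module reads those tables verbatim, normalises ages
and weights to years/kg, maps verbatim drug names onto complement-inhibitor
classes through a curated synonym table, maps reaction Preferred Terms (PTs)
into a MedDRA-style PT→HLT→HLGT→SOC hierarchy, and assembles one
:class:`CaseReport` per report restricted to primary-suspect (PS) drugs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

#: Columns that must be present for each table kind.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("PRIMARYID", "CASEID", "FDA_DT"),
    "DRUG": ("PRIMARYID", "DRUGNAME", "ROLE_COD"),
    "REAC": ("PRIMARYID", "PT"),
    "OUTC": ("PRIMARYID", "OUTC_COD"),
    "THER": ("PRIMARYID", "START_DT"),
    "INDI": ("PRIMARYID", "INDI_PT"),
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: FAERS reporter occupation codes → reporter categories.
OCCP_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "LW": "lawyer",
}

DRUG_CLASSES = ("C3", "C5", "FactorB")


class FaersFormatError(ValueError):
    """A FAERS table file does not carry the columns its kind requires."""


@dataclass
class RawRecordSet:
    """One FAERS table, fields preserved verbatim as strings."""

    table_name: str
    rows: pd.DataFrame
    source_quarter: str = ""

    def __post_init__(self) -> None:
        if self.table_name not in TABLE_NAMES:
            raise ValueError(f"unknown FAERS table kind: {self.table_name!r}")


def read_faers_table(path: str | Path, table_name: str) -> RawRecordSet:
    """Read a "$"-delimited FAERS ASCII table, all fields as strings.

    Raises :class:`FaersFormatError` naming the first missing required
    column for the table kind, and propagates OSError for unreadable files.
    """
    table_name = table_name.upper()
    if table_name not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown FAERS table kind: {table_name!r}")
    rows = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    rows.columns = [c.strip().upper() for c in rows.columns]
    for col in REQUIRED_COLUMNS[table_name]:
        if col not in rows.columns:
            raise FaersFormatError(f"{table_name} table {path} lacks required column {col}")
    return RawRecordSet(table_name=table_name, rows=rows)


def write_faers_table(record_set: RawRecordSet, path: str | Path) -> None:
    """Write a table back in the "$"-delimited dialect (round-trip safe)."""
    record_set.rows.to_csv(path, sep="$", index=False, quoting=csv.QUOTE_NONE)


# ---------------------------------------------------------------------------
# unit normalisation


def normalize_age(age_value: str, age_code: str) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years; out-of-range → None.

    Codes: DEC decades, YR years, MON months, WK weeks, DY days, HR hours.
    Ages outside [0, 120] years are treated as data errors and dropped.
    """
    factors = {
        "DEC": 10.0,
        "YR": 1.0,
        "": 1.0,  # FAERS convention: missing code means years
        "MON": 1.0 / 12.0,
        "WK": 7.0 / 365.25,
        "DY": 1.0 / 365.25,
        "HR": 1.0 / 8766.0,
    }
    code = (age_code or "").strip().upper()
    if code not in factors:
        return None
    try:
        value = float(str(age_value).strip())
    except (TypeError, ValueError):
        return None
    years = value * factors[code]
    if not 0.0 <= years <= 120.0:
        return None
    return years


def normalize_weight(wt_value: str, wt_code: str) -> float | None:
    """Convert a FAERS WT/WT_COD pair to kilograms; out-of-range → None."""
    factors = {"KG": 1.0, "": 1.0, "LBS": 0.453592, "GMS": 1e-3}
    code = (wt_code or "").strip().upper()
    if code not in factors:
        return None
    try:
        value = float(str(wt_value).strip())
    except (TypeError, ValueError):
        return None
    kg = value * factors[code]
    if not 0.0 < kg < 400.0:
        return None
    return kg


def parse_faers_date(raw: str) -> date | None:
    """Parse a FAERS date field (YYYYMMDD, YYYYMM or YYYY).

    Partial YYYYMM dates are imputed to day 01; year-only dates carry no
    usable month and are treated as missing for interval/quarter purposes.
    """
    s = str(raw or "").strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1)
    except ValueError:
        return None
    return None


# ---------------------------------------------------------------------------
# reference tables


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


@dataclass
class DrugClassMap:
    """Synonym → (canonical drug, complement-inhibitor class) lookup."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugClassMap":
        """Load a 3-column TSV: synonym, canonical name, class."""
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                synonym, canonical, drug_class = row[0], row[1], row[2]
                if drug_class not in DRUG_CLASSES:
                    raise ValueError(f"unknown drug class {drug_class!r} for {synonym!r}")
                key = _normalize_name(synonym)
                if key in entries:
                    raise ValueError(f"duplicate synonym after normalisation: {synonym!r}")
                entries[key] = (canonical.casefold(), drug_class)
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "DrugClassMap":
        """The shipped synonym table for the six approved inhibitors."""
        with resources.as_file(
            resources.files("compvig.data") / "drug_synonyms.tsv"
        ) as p:
            return cls.from_tsv(p)

    def match(self, verbatim_name: str) -> tuple[str, str] | None:
        return self.entries.get(_normalize_name(verbatim_name))


def match_drug(verbatim_name: str, drug_map: DrugClassMap) -> tuple[str, str] | None:
    """Exact case-insensitive lookup after whitespace normalisation.

    Returns (canonical_name, drug_class) or None.  No fuzzy matching: the
    synonym table is the single auditable source of name coverage.
    """
    return drug_map.match(verbatim_name)


@dataclass
class MeddraMap:
    """Toy MedDRA-style PT → HLT → HLGT → SOC hierarchy.

    The licensed MedDRA dictionary cannot be shipped; users supply their own
    table in the same 5-column TSV format (pt, hlt, hlgt, soc, primary Y/N).
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeddraMap":
        rows = pd.read_csv(
            path, sep="\t", comment="#", dtype=str,
            names=["pt", "hlt", "hlgt", "soc", "primary"], header=0,
        )
        primary = rows[rows["primary"].str.upper() == "Y"]
        dup = primary["pt"].str.casefold().duplicated()
        if dup.any():
            raise ValueError(
                f"PTs with more than one primary SOC: {sorted(primary['pt'][dup])}"
            )
        return cls(rows=rows)

    @classmethod
    def default(cls) -> "MeddraMap":
        with resources.as_file(resources.files("compvig.data") / "meddra_toy.tsv") as p:
            return cls.from_tsv(p)

    def primary_soc(self, pt: str) -> str | None:
        sel = self.rows[
            (self.rows["pt"].str.casefold() == pt.casefold())
            & (self.rows["primary"].str.upper() == "Y")
        ]
        return None if sel.empty else str(sel["soc"].iloc[0])

    def pts_in_soc(self, soc: str) -> set[str]:
        """All PTs whose *primary* SOC is the given one."""
        sel = self.rows[
            (self.rows["soc"].str.casefold() == soc.casefold())
            & (self.rows["primary"].str.upper() == "Y")
        ]
        return set(sel["pt"])


# ---------------------------------------------------------------------------
# case assembly


@dataclass
class CaseReport:
    """One FAERS case after assembly (pre-deduplication)."""

    primaryid: str
    caseid: str
    fda_date: date | None
    event_date: date | None = None
    age_years: float | None = None
    sex: str = "unknown"  # F / M / unknown
    weight_kg: float | None = None
    country: str = ""
    reporter: str = "unknown"
    ps_drug: str = ""
    drug_class: str | None = None  # C3 / C5 / FactorB / None (background)
    therapy_start: date | None = None
    reaction_pts: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    outcomes: frozenset[str] = frozenset()
    concomitant_drugs: tuple[tuple[str, date | None, str], ...] = ()

    @property
    def fatal(self) -> bool:
        return "DE" in self.outcomes


def assemble_cases(
    raw_tables: dict[str, RawRecordSet],
    drug_map: DrugClassMap,
    meddra: MeddraMap | None = None,
    *,
    keep_unmatched: bool = False,
) -> list[CaseReport]:
    """Join the FAERS tables into one CaseReport per retained PRIMARYID.

    A report is retained when its primary-suspect (ROLE_COD "PS") drug
    matches the synonym table by DRUGNAME or PROD_AI (union semantics).
    With ``keep_unmatched=True`` reports whose PS drug does not match are
    kept with ``drug_class=None`` — the background reporting universe needed
    for the c/d cells of disproportionality tables.  PRIMARYIDs appearing in
    DRUG/REAC but absent from DEMO are logged and skipped.
    """
    for required in ("DEMO", "DRUG", "REAC"):
        if required not in raw_tables:
            raise ValueError(f"assemble_cases requires a {required} table")
    demo = raw_tables["DEMO"].rows
    drug = raw_tables["DRUG"].rows
    reac = raw_tables["REAC"].rows

    demo_ids = set(demo["PRIMARYID"])
    for name in ("DRUG", "REAC", "OUTC", "THER", "INDI"):
        if name in raw_tables:
            orphans = set(raw_tables[name].rows["PRIMARYID"]) - demo_ids
            if orphans:
                logger.warning(
                    "%s rows for %d PRIMARYIDs absent from DEMO; skipped",
                    name, len(orphans),
                )

    def _group(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
        return {pid: g for pid, g in table.groupby("PRIMARYID", sort=False)}

    drug_by_id = _group(drug)
    reac_by_id = _group(reac)
    outc_by_id = _group(raw_tables["OUTC"].rows) if "OUTC" in raw_tables else {}
    ther_by_id = _group(raw_tables["THER"].rows) if "THER" in raw_tables else {}
    indi_by_id = _group(raw_tables["INDI"].rows) if "INDI" in raw_tables else {}

    cases: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        pid = row.PRIMARYID
        drows = drug_by_id.get(pid)
        rrows = reac_by_id.get(pid)
        if drows is None or rrows is None:
            continue
        ps = drows[drows["ROLE_COD"].str.strip().str.upper() == "PS"]
        if ps.empty:
            continue
        ps_row = ps.iloc[0]
        matched = match_drug(ps_row["DRUGNAME"], drug_map)
        if matched is None and "PROD_AI" in ps.columns:
            matched = match_drug(ps_row["PROD_AI"], drug_map)
        if matched is None:
            if not keep_unmatched:
                continue
            canonical, drug_class = _normalize_name(ps_row["DRUGNAME"]), None
        else:
            canonical, drug_class = matched

        reaction_pts = frozenset(p.strip() for p in rrows["PT"] if p.strip())
        outcomes = frozenset()
        if pid in outc_by_id:
            outcomes = frozenset(
                c for c in outc_by_id[pid]["OUTC_COD"].str.strip().str.upper()
                if c in OUTCOME_CODES
            )
        indications = frozenset()
        if pid in indi_by_id:
            indications = frozenset(
                p.strip() for p in indi_by_id[pid]["INDI_PT"] if p.strip()
            )

        # therapy start of the PS drug: matched by drug sequence number where
        # the files carry one, else the first THER row of the report
        therapy_start = None
        ther_rows = ther_by_id.get(pid)
        conco_start: dict[str, date | None] = {}
        if ther_rows is not None:
            seq_col = "DSG_DRUG_SEQ" if "DSG_DRUG_SEQ" in ther_rows.columns else None
            ps_seq = str(ps_row["DRUG_SEQ"]) if "DRUG_SEQ" in ps.columns else None
            chosen = None
            if seq_col and ps_seq is not None:
                hit = ther_rows[ther_rows[seq_col].astype(str) == ps_seq]
                if not hit.empty:
                    chosen = hit.iloc[0]["START_DT"]
            if chosen is None:
                chosen = ther_rows.iloc[0]["START_DT"]
            therapy_start = parse_faers_date(chosen)
            if seq_col and "DRUG_SEQ" in drows.columns:
                for trow in ther_rows.itertuples(index=False):
                    conco_start[str(getattr(trow, seq_col))] = parse_faers_date(trow.START_DT)

        concomitant = []
        for crow in drows.itertuples(index=False):
            role = str(crow.ROLE_COD).strip().upper()
            if role == "PS":
                continue
            start = conco_start.get(str(getattr(crow, "DRUG_SEQ", "")), None)
            concomitant.append((str(crow.DRUGNAME).strip(), start, role))

        cases.append(
            CaseReport(
                primaryid=str(pid),
                caseid=str(getattr(row, "CASEID", pid)),
                fda_date=parse_faers_date(getattr(row, "FDA_DT", "")),
                event_date=parse_faers_date(getattr(row, "EVENT_DT", "")),
                age_years=normalize_age(
                    getattr(row, "AGE", ""), getattr(row, "AGE_COD", "")
                ),
                sex={"F": "F", "M": "M"}.get(
                    str(getattr(row, "SEX", "")).strip().upper(), "unknown"
                ),
                weight_kg=normalize_weight(
                    getattr(row, "WT", ""), getattr(row, "WT_COD", "")
                ),
                country=str(getattr(row, "REPORTER_COUNTRY", "")).strip(),
                reporter=OCCP_CODES.get(
                    str(getattr(row, "OCCP_COD", "")).strip().upper(), "unknown"
                ),
                ps_drug=canonical,
                drug_class=drug_class,
                therapy_start=therapy_start,
                reaction_pts=reaction_pts,
                indications=indications,
                outcomes=outcomes,
                concomitant_drugs=tuple(concomitant),
            )
        )
    cases.sort(key=lambda c: c.primaryid)
    return cases
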