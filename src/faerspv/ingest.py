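"""Ingest FAERS-style quarterly ASCII tables into a normalized case store.

FAERS distributes each quarter as a set of "$"-delimited text files (DEMO,
DRUG, REAC, THER, INDI, OUTC, RPSR).  A safety report may appear several
times as amended case *versions* sharing a ``caseid`` but carrying distinct
``primaryid`` values; analyses must keep exactly one version per case.
This module parses the raw tables, removes duplicate case versions
(keeping the latest received version), converts demographics to common
units, normalizes drug names against a synonym map, and exposes the result
as a columnar :class:`CaseStore` plus a per-report :class:`ReportCase` view.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAERS_TABLES = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC", "RPSR")

#: Multiplicative factors converting FAERS age unit codes to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Multiplicative factors converting FAERS weight unit codes to kilograms.
WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.453592, "GMS": 0.001}

AGE_RANGE_YEARS = (0.0, 150.0)
WEIGHT_RANGE_KG = (0.0, 700.0)

#: Salt/ester suffixes stripped from verbatim drug names before lookup.
_SALT_SUFFIXES = (
    "mesylate", "mesilate", "hydrochloride", "hcl", "sodium", "potassium",
    "calcium", "dihydrate", "monohydrate", "tartrate", "sulfate", "sulphate",
    "acetate", "maleate", "citrate", "phosphate", "besylate", "fumarate",
    "succinate", "disoproxil fumarate",
)

#: Small packaged brand->generic map; user maps are merged on top.
DEFAULT_SYNONYMS = {
    "lenvima": "lenvatinib",
    "keytruda": "pembrolizumab",
    "tecentriq": "atezolizumab",
    "rituxan": "rituximab",
    "mabthera": "rituximab",
    "lupkynis": "voclosporin",
    "afinitor": "everolimus",
    "sutent": "sunitinib",
    "eloxatin": "oxaliplatin",
    "paraplatin": "carboplatin",
    "inlyta": "axitinib",
    "camptosar": "irinotecan",
    "taxol": "paclitaxel",
    "prograf": "tacrolimus",
    "advil": "ibuprofen",
    "motrin": "ibuprofen",
    "viread": "tenofovir disoproxil",
    "atripla": "efavirenz/emtricitabine/tenofovir disoproxil",
    "reclast": "zoledronic acid",
    "zometa": "zoledronic acid",
    "prevacid": "lansoprazole",
    "exjade": "deferasirox",
    "entocort": "budesonide",
}

#: Country alias normalization; unknown strings pass through unchanged.
COUNTRY_ALIASES = {
    "US": "United States", "USA": "United States",
    "UNITED STATES": "United States",
    "UNITED STATES OF AMERICA": "United States",
    "JP": "Japan", "JAPAN": "Japan",
    "FR": "France", "FRANCE": "France",
    "CA": "Canada", "CANADA": "Canada",
    "DE": "Germany", "GERMANY": "Germany",
    "GB": "United Kingdom", "UK": "United Kingdom",
    "UNITED KINGDOM": "United Kingdom",
    "CN": "China", "CHINA": "China",
    "IT": "Italy", "ES": "Spain", "BR": "Brazil", "AU": "Australia",
}

DRUG_ROLES = ("PS", "SS", "I", "C")


@dataclass(frozen=True)
class DrugMention:
    """One drug row of a report: normalized name, role code, therapy dates."""

    generic_name: str
    role: str
    therapy_start: pd.Timestamp | None = None
    therapy_end: pd.Timestamp | None = None
    start_imprecise: bool = False


@dataclass
class ReportCase:
    """One deduplicated safety report."""

    primaryid: int
    caseid: int
    receipt_date: pd.Timestamp | None
    event_date: pd.Timestamp | None
    event_date_imprecise: bool
    sex: str  # "male" | "female" | "missing"
    age_years: float  # NaN when missing
    weight_kg: float  # NaN when missing
    country: str  # "missing" when absent
    event_pts: frozenset[str] = frozenset()
    drugs: tuple[DrugMention, ...] = ()

    @property
    def ps_drugs(self) -> tuple[DrugMention, ...]:
        return tuple(d for d in self.drugs if d.role == "PS")


@dataclass
class IngestLog:
    """Row-count bookkeeping for one ingest run."""

    rows_read: dict[str, int] = field(default_factory=dict)
    malformed: dict[str, int] = field(default_factory=dict)
    duplicates_removed: int = 0
    cases_retained: int = 0
    unknown_unit_codes: int = 0

    def as_dict(self) -> dict:
        return {
            "rows_read": dict(self.rows_read),
            "malformed": dict(self.malformed),
            "duplicates_removed": self.duplicates_removed,
            "cases_retained": self.cases_retained,
            "unknown_unit_codes": self.unknown_unit_codes,
        }


# ---------------------------------------------------------------------------
# parsing

def parse_faers_table(path: str | Path, table: str | None = None) -> tuple[pd.DataFrame, int]:
    """Parse one "$"-delimited FAERS table file.

    Column names come from the header row, case-folded to lower case.
    Rows whose field count disagrees with the header are counted and
    skipped, never fatal.  Returns ``(frame, n_malformed)``.

    Raises ``ValueError`` if a DEMO file lacks ``primaryid`` or ``caseid``.
    """
    path = Path(path)
    bad = {"n": 0}

    def _on_bad(row: list[str]):
        bad["n"] += 1
        return None

    frame = pd.read_csv(
        path, sep="$", dtype=str, engine="python",
        on_bad_lines=_on_bad, keep_default_na=False,
    )
    frame.columns = [c.strip().lower() for c in frame.columns]
    if table is None:
        table = _infer_table_name(path.name)
    if table == "DEMO":
        for col in ("primaryid", "caseid"):
            if col not in frame.columns:
                raise ValueError(f"mandatory column {col!r} missing from {path}")
    if bad["n"]:
        logger.warning("%s: skipped %d malformed row(s)", path.name, bad["n"])
    return frame, bad["n"]


def _infer_table_name(filename: str) -> str:
    m = re.match(r"([A-Za-z]+?)\d", filename)
    stem = (m.group(1) if m else Path(filename).stem).upper()
    return stem if stem in FAERS_TABLES else stem


def parse_quarter(paths: Mapping[str, str | Path], log: IngestLog | None = None) -> dict[str, pd.DataFrame]:
    """Parse one quarter's files, keyed by table name ("DEMO", "DRUG", ...)."""
    log = log if log is not None else IngestLog()
    out: dict[str, pd.DataFrame] = {}
    for table, path in paths.items():
        frame, n_bad = parse_faers_table(path, table=table)
        out[table] = frame
        log.rows_read[table] = log.rows_read.get(table, 0) + len(frame)
        log.malformed[table] = log.malformed.get(table, 0) + n_bad
    return out


def discover_quarters(directory: str | Path) -> list[dict[str, Path]]:
    """Find FAERS files grouped by quarter under ``directory``.

    Recognizes the ``DEMOyyQq.txt`` naming convention.
    """
    directory = Path(directory)
    quarters: dict[str, dict[str, Path]] = {}
    for path in sorted(directory.glob("*.txt")):
        m = re.match(r"([A-Z]+)(\d{2}Q\d)\.txt$", path.name, re.IGNORECASE)
        if not m:
            continue
        table, quarter = m.group(1).upper(), m.group(2).upper()
        if table in FAERS_TABLES:
            quarters.setdefault(quarter, {})[table] = path
    return [quarters[q] for q in sorted(quarters)]


# ---------------------------------------------------------------------------
# dates

def parse_faers_dates(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse FAERS date strings of day, month, or year precision.

    Full dates are ``YYYYMMDD``.  Partial dates are completed
    deterministically — ``YYYYMM`` to the 15th, ``YYYY`` to July 1 — and
    flagged imprecise so onset analyses can exclude them.  Returns
    ``(timestamps, imprecise_flags)``.
    """
    s = values.astype(str).str.strip()
    n = s.str.len()
    completed = s.where(n != 6, s + "15")
    completed = completed.where(n != 4, s + "0701")
    valid = n.isin([4, 6, 8])
    dates = pd.to_datetime(completed.where(valid), format="%Y%m%d", errors="coerce")
    imprecise = n.isin([4, 6]) & dates.notna()
    return dates, imprecise


# ---------------------------------------------------------------------------
# deduplication

def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one version per case: latest receipt date, ties to max primaryid.

    Expects numeric ``primaryid``/``caseid`` columns and a datetime
    ``receipt_date`` column.  Idempotent; the result has exactly one row
    per distinct caseid.
    """
    if demo.empty:
        return demo.copy()
    order = demo.sort_values(
        ["caseid", "receipt_date", "primaryid"],
        kind="mergesort", na_position="first",
    )
    return order.drop_duplicates("caseid", keep="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# demographics

def normalize_age(age, age_cod, log: IngestLog | None = None) -> float:
    """Convert a raw AGE/AGE_COD pair to years; out of range -> NaN."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return np.nan
    code = str(age_cod).strip().upper() or "YR"
    if code not in AGE_UNIT_TO_YEARS:
        if log is not None:
            log.unknown_unit_codes += 1
        logger.warning("unknown age unit code %r", age_cod)
        return np.nan
    years = value * AGE_UNIT_TO_YEARS[code]
    lo, hi = AGE_RANGE_YEARS
    return years if lo <= years <= hi else np.nan


def normalize_weight(wt, wt_cod, log: IngestLog | None = None) -> float:
    """Convert a raw WT/WT_COD pair to kilograms; out of range -> NaN."""
    try:
        value = float(wt)
    except (TypeError, ValueError):
        return np.nan
    code = str(wt_cod).strip().upper() or "KG"
    if code not in WEIGHT_UNIT_TO_KG:
        if log is not None:
            log.unknown_unit_codes += 1
        logger.warning("unknown weight unit code %r", wt_cod)
        return np.nan
    kg = value * WEIGHT_UNIT_TO_KG[code]
    lo, hi = WEIGHT_RANGE_KG
    return kg if lo < kg < hi else np.nan


def normalize_sex(raw) -> str:
    code = str(raw).strip().upper()
    return {"M": "male", "F": "female"}.get(code, "missing")


def normalize_country(raw) -> str:
    text = str(raw).strip()
    if not text:
        return "missing"
    return COUNTRY_ALIASES.get(text.upper(), text)


def _vector_units(values: pd.Series, codes: pd.Series, factors: dict[str, float],
                  valid_range: tuple[float, float], open_low: bool,
                  log: IngestLog | None) -> pd.Series:
    vals = pd.to_numeric(values, errors="coerce")
    code = codes.astype(str).str.strip().str.upper()
    default = "YR" if factors is AGE_UNIT_TO_YEARS else "KG"
    code = code.where(code != "", default)
    factor = code.map(factors)
    if log is not None:
        log.unknown_unit_codes += int((factor.isna() & vals.notna()).sum())
    out = vals * factor
    lo, hi = valid_range
    bad = (out <= lo) if open_low else (out < lo)
    return out.mask(bad | (out > hi) | ((out == hi) & open_low))


def normalize_demographics(demo: pd.DataFrame, log: IngestLog | None = None) -> pd.DataFrame:
    """Vectorized demographic normalization of a raw DEMO frame.

    Adds ``sex`` ("male"/"female"/"missing"), ``age_years``, ``weight_kg``
    (NaN when missing or out of range) and a normalized ``country`` column.
    """
    out = demo.copy()
    sex_raw = out.get("sex", pd.Series("", index=out.index)).astype(str).str.strip().str.upper()
    out["sex"] = sex_raw.map({"M": "male", "F": "female"}).fillna("missing")
    out["age_years"] = _vector_units(
        out.get("age", pd.Series("", index=out.index)),
        out.get("age_cod", pd.Series("", index=out.index)),
        AGE_UNIT_TO_YEARS, AGE_RANGE_YEARS, open_low=False, log=log)
    out["weight_kg"] = _vector_units(
        out.get("wt", pd.Series("", index=out.index)),
        out.get("wt_cod", pd.Series("", index=out.index)),
        WEIGHT_UNIT_TO_KG, WEIGHT_RANGE_KG, open_low=True, log=log)
    country_raw = out.get("occr_country", pd.Series("", index=out.index)).astype(str).str.strip()
    upper = country_raw.str.upper()
    out["country"] = upper.map(COUNTRY_ALIASES).fillna(country_raw).replace("", "missing")
    return out


# ---------------------------------------------------------------------------
# drug names

def normalize_drug_name(verbatim: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Map a verbatim drug string to a generic name.

    Case-folds and trims, looks the name up in the synonym map, then
    retries with trailing salt/ester suffixes stripped.  Unmapped names
    pass through case-folded so downstream grouping still works.
    """
    mapping = dict(DEFAULT_SYNONYMS)
    if synonym_map:
        mapping.update({k.casefold().strip(): v for k, v in synonym_map.items()})
    name = str(verbatim).casefold().strip()
    name = re.sub(r"\s+", " ", name)
    if name in mapping:
        return mapping[name]
    stripped = name
    for suffix in _SALT_SUFFIXES:
        if stripped.endswith(" " + suffix):
            stripped = stripped[: -len(suffix) - 1].strip()
    return mapping.get(stripped, stripped)


def normalize_drug_names(values: pd.Series, synonym_map: Mapping[str, str] | None = None) -> pd.Series:
    unique = values.astype(str).drop_duplicates()
    table = {v: normalize_drug_name(v, synonym_map) for v in unique}
    return values.astype(str).map(table)


# ---------------------------------------------------------------------------
# case store

@dataclass
class CaseStore:
    """Columnar store of deduplicated, normalized reports.

    ``demo`` has one row per kept report; ``drugs`` and ``reacs`` carry the
    report's drug mentions and event preferred terms keyed by ``primaryid``.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reacs: pd.DataFrame
    log: IngestLog = field(default_factory=IngestLog)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def ps_drugs(self) -> pd.DataFrame:
        """Drug mentions restricted to primary suspects (the analysis set)."""
        return self.drugs[self.drugs["role"] == "PS"]

    def event_primaryids(self, target_pts: Iterable[str]) -> np.ndarray:
        """primaryids of cases reporting any of the target preferred terms."""
        targets = {str(p).casefold() for p in target_pts}
        hit = self.reacs["pt"].str.casefold().isin(targets)
        return self.reacs.loc[hit, "primaryid"].unique()

    def restrict(self, primaryids: Iterable[int]) -> "CaseStore":
        ids = pd.Index(primaryids)
        return CaseStore(
            demo=self.demo[self.demo["primaryid"].isin(ids)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(ids)].reset_index(drop=True),
            reacs=self.reacs[self.reacs["primaryid"].isin(ids)].reset_index(drop=True),
            log=self.log,
        )

    def case(self, primaryid: int) -> ReportCase:
        row = self.demo[self.demo["primaryid"] == primaryid]
        if row.empty:
            raise KeyError(f"primaryid {primaryid} not in store")
        r = row.iloc[0]
        drugs = tuple(
            DrugMention(
                generic_name=d["generic_name"], role=d["role"],
                therapy_start=None if pd.isna(d["therapy_start"]) else d["therapy_start"],
                therapy_end=None if pd.isna(d.get("therapy_end")) else d.get("therapy_end"),
                start_imprecise=bool(d.get("start_imprecise", False)),
            )
            for _, d in self.drugs[self.drugs["primaryid"] == primaryid].iterrows()
        )
        pts = frozenset(self.reacs.loc[self.reacs["primaryid"] == primaryid, "pt"])
        return ReportCase(
            primaryid=int(r["primaryid"]), caseid=int(r["caseid"]),
            receipt_date=None if pd.isna(r["receipt_date"]) else r["receipt_date"],
            event_date=None if pd.isna(r["event_date"]) else r["event_date"],
            event_date_imprecise=bool(r["event_date_imprecise"]),
            sex=r["sex"], age_years=float(r["age_years"]),
            weight_kg=float(r["weight_kg"]), country=r["country"],
            event_pts=pts, drugs=drugs,
        )

    def iter_cases(self) -> Iterator[ReportCase]:
        for pid in self.demo["primaryid"]:
            yield self.case(int(pid))

    def to_records_json(self, path: str | Path) -> None:
        """Dump the normalized store as newline-delimited JSON per table."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("demo", "drugs", "reacs"):
            frame = getattr(self, name).copy()
            for col in frame.columns:
                if pd.api.types.is_datetime64_any_dtype(frame[col]):
                    frame[col] = frame[col].dt.strftime("%Y-%m-%d")
            frame.to_json(path / f"{name}.ndjson", orient="records", lines=True)


def filter_primary_suspect(case: ReportCase) -> ReportCase:
    """Restrict a case's analysis drug list to primary-suspect mentions.

    Cases with no PS drug keep an empty drug list but still count toward
    event margins downstream (they are "other drug" reports).
    """
    return ReportCase(
        primaryid=case.primaryid, caseid=case.caseid,
        receipt_date=case.receipt_date, event_date=case.event_date,
        event_date_imprecise=case.event_date_imprecise, sex=case.sex,
        age_years=case.age_years, weight_kg=case.weight_kg,
        country=case.country, event_pts=case.event_pts,
        drugs=case.ps_drugs,
    )


def build_store(
    tables: Mapping[str, pd.DataFrame],
    synonym_map: Mapping[str, str] | None = None,
    log: IngestLog | None = None,
) -> CaseStore:
    """Assemble the normalized, deduplicated case store from raw tables.

    ``tables`` maps "DEMO"/"DRUG"/"REAC" (and optionally "THER") to frames
    as returned by :func:`parse_quarter`; frames from several quarters may
    simply be concatenated first.
    """
    log = log if log is not None else IngestLog()
    demo = tables["DEMO"].copy()
    for col in ("primaryid", "caseid"):
        if col not in demo.columns:
            raise ValueError(f"mandatory column {col!r} missing from DEMO")
    demo["primaryid"] = pd.to_numeric(demo["primaryid"], errors="coerce")
    demo = demo.dropna(subset=["primaryid"])
    demo["primaryid"] = demo["primaryid"].astype(np.int64)
    demo["caseid"] = pd.to_numeric(demo["caseid"], errors="coerce").astype("Int64")
    demo["receipt_date"], _ = parse_faers_dates(demo.get("fda_dt", pd.Series("", index=demo.index)))
    demo["event_date"], demo["event_date_imprecise"] = parse_faers_dates(
        demo.get("event_dt", pd.Series("", index=demo.index)))

    n_before = len(demo)
    demo = deduplicate(demo)
    log.duplicates_removed = n_before - len(demo)
    log.cases_retained = len(demo)

    demo = normalize_demographics(demo, log=log)
    kept = pd.Index(demo["primaryid"])

    drug = tables["DRUG"].copy()
    drug["primaryid"] = pd.to_numeric(drug["primaryid"], errors="coerce")
    drug = drug.dropna(subset=["primaryid"])
    drug["primaryid"] = drug["primaryid"].astype(np.int64)
    drug = drug[drug["primaryid"].isin(kept)]
    drug["role"] = drug.get("role_cod", pd.Series("", index=drug.index)).astype(str).str.strip().str.upper()
    drug["generic_name"] = normalize_drug_names(
        drug.get("drugname", pd.Series("", index=drug.index)), synonym_map)
    drug["drug_seq"] = pd.to_numeric(
        drug.get("drug_seq", pd.Series(1, index=drug.index)), errors="coerce")

    ther = tables.get("THER")
    if ther is not None and len(ther):
        ther = ther.copy()
        ther["primaryid"] = pd.to_numeric(ther["primaryid"], errors="coerce")
        ther = ther.dropna(subset=["primaryid"])
        ther["primaryid"] = ther["primaryid"].astype(np.int64)
        ther["start"], ther["start_imprecise"] = parse_faers_dates(
            ther.get("start_dt", pd.Series("", index=ther.index)))
        ther["end"], _ = parse_faers_dates(ther.get("end_dt", pd.Series("", index=ther.index)))
        ther["dsg_drug_seq"] = pd.to_numeric(
            ther.get("dsg_drug_seq", pd.Series(1, index=ther.index)), errors="coerce")
        # earliest start per (report, drug_seq); multiple episodes collapse
        ther = (ther.dropna(subset=["start"])
                    .sort_values(["primaryid", "dsg_drug_seq", "start"], kind="mergesort")
                    .drop_duplicates(["primaryid", "dsg_drug_seq"], keep="first"))
        drug = drug.merge(
            ther[["primaryid", "dsg_drug_seq", "start", "end", "start_imprecise"]],
            left_on=["primaryid", "drug_seq"], right_on=["primaryid", "dsg_drug_seq"],
            how="left")
        drug = drug.rename(columns={"start": "therapy_start", "end": "therapy_end"})
        drug["start_imprecise"] = drug["start_imprecise"].eq(True)
    else:
        drug["therapy_start"] = pd.NaT
        drug["therapy_end"] = pd.NaT
        drug["start_imprecise"] = False

    reac = tables["REAC"].copy()
    reac["primaryid"] = pd.to_numeric(reac["primaryid"], errors="coerce")
    reac = reac.dropna(subset=["primaryid"])
    reac["primaryid"] = reac["primaryid"].astype(np.int64)
    reac = reac[reac["primaryid"].isin(kept)]
    reac["pt"] = reac.get("pt", pd.Series("", index=reac.index)).astype(str).str.strip()
    reac = reac[reac["pt"] != ""].drop_duplicates(["primaryid", "pt"])

    demo_cols = ["primaryid", "caseid", "receipt_date", "event_date",
                 "event_date_imprecise", "sex", "age_years", "weight_kg", "country"]
    drug_cols = ["primaryid", "generic_name", "role", "therapy_start",
                 "therapy_end", "start_imprecise"]
    return CaseStore(
        demo=demo[demo_cols].reset_index(drop=True),
        drugs=drug[drug_cols].reset_index(drop=True),
        reacs=reac[["primaryid", "pt"]].reset_index(drop=True),
        log=log,
    )


def load_faers_directory(
    directory: str | Path,
    synonym_map: Mapping[str, str] | None = None,
) -> CaseStore:
    """Parse every quarter found under ``directory`` into one case store."""
    log = IngestLog()
    quarters = discover_quarters(directory)
    if not quarters:
        raise FileNotFoundError(f"no FAERS quarterly files found under {directory}")
    merged: dict[str, list[pd.DataFrame]] = {}
    for quarter_paths in quarters:
        frames = parse_quarter(quarter_paths, log=log)
        for name, frame in frames.items():
            merged.setdefault(name, []).append(frame)
    tables = {name: pd.concat(parts, ignore_index=True) for name, parts in merged.items()}
    return build_store(tables, synonym_map=synonym_map, log=log)
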