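"""Reading, cleaning and deduplicating FAERS-shaped quarterly ASCII tables.

FAERS quarterly extracts ship one dollar-delimited text file per table
(DEMO, DRUG, REAC, THER, INDI, OUTC) plus, from 2019Q1 on, a deletion list
of case identifiers. A *case* (CASEID) may appear as several report
versions (PRIMARYID); the FDA-recommended rule retains, per case, the
version with the most recent FDA receipt date, breaking ties by the
largest PRIMARYID, and then drops cases named on deletion lists.

This module parses those files into pandas DataFrames, applies the
deduplication rule, normalizes ages and drug names, and maps MedDRA
preferred terms (PTs) to system organ classes (SOCs) via a pluggable
PT->SOC table (a small synthetic fixture map is bundled; the licensed
MedDRA dictionary can be dropped in with the same interface).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAERS_DELIMITER = "$"

#: FAERS table roles understood by :func:`read_faers_tables`.
TABLE_ROLES = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC", "DELETED")

#: Days per unit for age normalization; DEC = decades.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1429,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_REPORTER_LABELS = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "CN": "consumer",
    "LW": "lawyer",
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Trade name -> canonical generic token. Deliberately small and explicit:
#: no fuzzy matching, so normalization is reproducible.
DRUG_SYNONYMS = {
    "KEVZARA": "SARILUMAB",
    "RINVOQ": "UPADACITINIB",
    "ORENCIA": "ABATACEPT",
    "HUMIRA": "ADALIMUMAB",
    "ACTEMRA": "TOCILIZUMAB",
    "TREXALL": "METHOTREXATE",
    "RASUVO": "METHOTREXATE",
    "DELTASONE": "PREDNISONE",
}

_DOSAGE_SUFFIX = re.compile(
    r"[\s,]*(\d+(\.\d+)?\s*(MG|MCG|ML|G|MG/ML|MG/0\.\d+ML)|TABLET[S]?|CAPSULE[S]?|"
    r"INJECTION|SOLUTION|PREFILLED SYRINGE)[\s.]*$"
)


class FaersFormatError(ValueError):
    """Raised for unreadable files or malformed headers."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class RawReportVersion:
    """One report version as filed (pre-deduplication)."""

    primaryid: str
    caseid: str
    fda_dt: str
    sex: str = "unknown"
    age_value: float | None = None
    age_unit: str = "unknown"
    weight_kg: float | None = None
    reporter: str = "unknown"
    country: str = ""
    event_dt: str = ""
    outcome_codes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DrugEntry:
    primaryid: str
    drug_name_raw: str
    drug_name_norm: str
    role: str
    start_dt: str = ""
    indication_pt: str | None = None


@dataclass(frozen=True)
class ReactionEntry:
    primaryid: str
    pt: str


@dataclass
class ReportCase:
    """A deduplicated safety report: retained version + its drug/reaction lists."""

    primaryid: str
    caseid: str
    fda_dt: str
    sex: str
    age_years: float | None
    reporter: str
    country: str
    event_dt: str
    outcome_codes: frozenset[str]
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)


class PtSocMap:
    """Mapping of MedDRA preferred terms to their primary system organ class."""

    def __init__(self, entries: Mapping[str, tuple[str, int]]):
        if not entries:
            raise ValueError("PT->SOC map is empty")
        self._entries = {str(pt).strip(): (soc, int(code)) for pt, (soc, code) in entries.items()}

    def __contains__(self, pt: str) -> bool:
        return pt.strip() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def soc_of(self, pt: str) -> tuple[str, int] | None:
        return self._entries.get(pt.strip())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(pt, soc, code) for pt, (soc, code) in self._entries.items()],
            columns=["pt", "soc_name", "soc_code"],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PtSocMap":
        df = pd.read_csv(path)
        return cls({r.pt: (r.soc_name, int(r.soc_code)) for r in df.itertuples()})

    @classmethod
    def bundled_fixture(cls) -> "PtSocMap":
        """The small synthetic PT->SOC table shipped with the package."""
        with resources.files("faersig.data").joinpath("pt_soc.csv").open("rb") as fh:
            df = pd.read_csv(fh)
        return cls({r.pt: (r.soc_name, int(r.soc_code)) for r in df.itertuples()})


def load_country_regions() -> dict[str, str]:
    """ISO-2 country code -> continent grouping (bundled static table)."""
    with resources.files("faersig.data").joinpath("country_region.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["country"], df["region"]))


# ---------------------------------------------------------------------------
# parsing


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise FaersFormatError(f"{table} table missing: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if FAERS_DELIMITER not in header and table != "DELETED":
        raise FaersFormatError(f"{table}: malformed header (no '$' delimiter): {header!r}")
    df = pd.read_csv(path, sep=re.escape(FAERS_DELIMITER), dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_faers_tables(paths: Mapping[str, str | Path]) -> tuple[dict[str, pd.DataFrame], dict]:
    """Read one quarter's FAERS ASCII tables.

    Parameters
    ----------
    paths
        Mapping of table role (``DEMO``, ``DRUG``, ``REAC``, ``THER``,
        ``INDI``, ``OUTC``, optionally ``DELETED``) to file path. Roles
        are selected by explicit configuration, never guessed from names.

    Returns
    -------
    tables, diagnostics
        ``tables`` maps each role to a string-typed DataFrame (DELETED
        becomes a one-column ``caseid`` frame). ``diagnostics`` counts
        rows rejected for unparseable mandatory keys, per table.
    """
    required = {"DEMO", "DRUG", "REAC"}
    missing = required - set(paths)
    if missing:
        raise FaersFormatError(f"missing required table paths: {sorted(missing)}")
    tables: dict[str, pd.DataFrame] = {}
    diagnostics: dict[str, int] = {}
    for role, path in paths.items():
        role = role.upper()
        if role not in TABLE_ROLES:
            raise FaersFormatError(f"unknown table role {role!r}")
        df = _read_table(Path(path), role)
        if role == "DELETED":
            col = df.columns[0]
            df = df.rename(columns={col: "caseid"})[["caseid"]]
        else:
            n0 = len(df)
            keys = ["primaryid"] + (["caseid"] if "caseid" in df.columns else [])
            mask = np.ones(n0, dtype=bool)
            for k in keys:
                mask &= df[k].str.strip().ne("")
            rejected = int(n0 - mask.sum())
            if rejected:
                logger.warning("%s: rejected %d rows with empty mandatory keys", role, rejected)
            diagnostics[role] = rejected
            df = df[mask].reset_index(drop=True)
        tables[role] = df
    diagnostics.setdefault("DELETED", 0)
    return tables, diagnostics


def parse_faers_date(value: str, *, complete: str = "none") -> pd.Timestamp | None:
    """Parse a FAERS date string (YYYYMMDD, YYYYMM, or YYYY).

    ``complete='first'`` completes partial dates to the first day of the
    period (used only for deduplication ordering); ``complete='none'``
    returns None for anything short of day precision (used for
    time-to-onset arithmetic, which needs day resolution).
    """
    s = str(value).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if complete == "first" and len(s) == 6:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), 1)
        if complete == "first" and len(s) == 4:
            return pd.Timestamp(int(s), 1, 1)
    except ValueError:
        return None
    return None


def normalize_age(age_value, age_unit: str) -> float:
    """Convert a FAERS (age, unit-code) pair to years; NaN when unusable.

    DEC (decades) multiplies by 10; MON/WK/DY/HR divide by the length of
    the unit in years. A value with an unknown unit is accepted as years
    only when plausibly a year count (<= 150); negative values are
    rejected with a warning.
    """
    try:
        v = float(age_value)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(v):
        return float("nan")
    if v < 0:
        logger.warning("negative age value %r rejected", age_value)
        return float("nan")
    unit = str(age_unit).strip().upper()
    if unit in _AGE_FACTORS:
        return v * _AGE_FACTORS[unit]
    if v > 150:
        return float("nan")
    return v


def normalize_drug_name(raw: str) -> str:
    """Canonicalize a verbatim drug name: uppercase, trim, strip dosage
    suffixes, collapse trade/generic synonyms. Idempotent by construction."""
    name = str(raw).strip().upper()
    name = re.sub(r"\s+", " ", name)
    prev = None
    while prev != name:
        prev = name
        name = _DOSAGE_SUFFIX.sub("", name).strip()
    return DRUG_SYNONYMS.get(name, name)


def normalize_reporter(code: str) -> str:
    return _REPORTER_LABELS.get(str(code).strip().upper(), "unknown")


def normalize_sex(code: str) -> str:
    c = str(code).strip().upper()
    return c if c in ("F", "M") else "unknown"


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(demo: pd.DataFrame, deletion_caseids: Iterable[str] = ()) -> pd.DataFrame:
    """Collapse report versions to one row per case, FDA-style.

    Per CASEID the version with the latest FDA receipt date is retained;
    date ties are broken by the numerically largest PRIMARYID. Cases on
    the deletion list are then removed. Partial FDA_DT values are
    completed to the first of their period for ordering only. Idempotent.
    """
    if demo.empty:
        return demo.copy()
    df = demo.copy()
    fda = df["fda_dt"].map(lambda s: parse_faers_date(s, complete="first"))
    df = df[[d is not None for d in fda]].copy()
    df["_fda_order"] = [d for d in fda if d is not None]
    df["_pid_order"] = pd.to_numeric(df["primaryid"], errors="coerce")
    df = df.dropna(subset=["_pid_order"])
    df = df.sort_values(["caseid", "_fda_order", "_pid_order"], kind="mergesort")
    df = df.groupby("caseid", as_index=False, sort=False).tail(1)
    deletions = {str(c) for c in deletion_caseids}
    if deletions:
        df = df[~df["caseid"].isin(deletions)]
    return df.drop(columns=["_fda_order", "_pid_order"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# the deduplicated case container


@dataclass
class CaseData:
    """Deduplicated case-level view of one FAERS load.

    ``demo`` holds exactly one row per caseid (columns: primaryid, caseid,
    fda_dt, sex, age_years, weight_kg, reporter, country, event_dt, year);
    the satellite frames are filtered to the retained primaryids.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    @property
    def caseids(self) -> pd.Series:
        return self.demo["caseid"]

    @classmethod
    def from_tables(cls, tables: Mapping[str, pd.DataFrame]) -> "CaseData":
        """Deduplicate and normalize raw tables into the case-level view."""
        demo_raw = tables["DEMO"]
        deleted = tables.get("DELETED")
        deletion_ids = set(deleted["caseid"].astype(str)) if deleted is not None else set()
        retained = deduplicate(demo_raw, deletion_ids)

        demo = pd.DataFrame(
            {
                "primaryid": retained["primaryid"].astype(str),
                "caseid": retained["caseid"].astype(str),
                "fda_dt": retained["fda_dt"].astype(str),
                "sex": retained.get("sex", pd.Series("", index=retained.index)).map(normalize_sex),
                "age_years": [
                    normalize_age(v, u)
                    for v, u in zip(
                        retained.get("age", pd.Series("", index=retained.index)),
                        retained.get("age_cod", pd.Series("", index=retained.index)),
                    )
                ],
                "weight_kg": pd.to_numeric(
                    retained.get("wt", pd.Series("", index=retained.index)), errors="coerce"
                ),
                "reporter": retained.get("occp_cod", pd.Series("", index=retained.index)).map(
                    normalize_reporter
                ),
                "country": retained.get(
                    "occr_country", pd.Series("", index=retained.index)
                ).astype(str),
                "event_dt": retained.get("event_dt", pd.Series("", index=retained.index)).astype(
                    str
                ),
            }
        )
        demo["year"] = demo["fda_dt"].str.slice(0, 4)
        kept_pids = set(demo["primaryid"])

        def _filter(role: str, cols: dict[str, str]) -> pd.DataFrame:
            t = tables.get(role)
            if t is None or t.empty:
                return pd.DataFrame(columns=["primaryid", "caseid", *cols.values()])
            t = t[t["primaryid"].astype(str).isin(kept_pids)].copy()
            out = pd.DataFrame(
                {"primaryid": t["primaryid"].astype(str), "caseid": t["caseid"].astype(str)}
            )
            for src, dst in cols.items():
                out[dst] = t.get(src, pd.Series("", index=t.index)).astype(str)
            return out.reset_index(drop=True)

        drugs = _filter(
            "DRUG", {"drug_seq": "drug_seq", "drugname": "drug_name_raw", "role_cod": "role"}
        )
        drugs["drug_name_norm"] = drugs["drug_name_raw"].map(normalize_drug_name)
        reac = _filter("REAC", {"pt": "pt"})
        reac["pt"] = reac["pt"].str.strip()
        reac = reac[reac["pt"].ne("")].reset_index(drop=True)
        ther = _filter("THER", {"dsg_drug_seq": "drug_seq", "start_dt": "start_dt"})
        indi = _filter("INDI", {"indi_drug_seq": "drug_seq", "indi_pt": "indi_pt"})
        outc = _filter("OUTC", {"outc_cod": "outc_cod"})

        stage_counts = {
            "raw_report_versions": len(demo_raw),
            "deletion_list": len(deletion_ids),
            "deduplicated_cases": len(demo),
        }
        return cls(demo, drugs, reac, ther, indi, outc, stage_counts)

    def subset(self, caseids: Iterable[str]) -> "CaseData":
        keep = set(caseids)
        return CaseData(
            self.demo[self.demo["caseid"].isin(keep)].reset_index(drop=True),
            self.drugs[self.drugs["caseid"].isin(keep)].reset_index(drop=True),
            self.reac[self.reac["caseid"].isin(keep)].reset_index(drop=True),
            self.ther[self.ther["caseid"].isin(keep)].reset_index(drop=True),
            self.indi[self.indi["caseid"].isin(keep)].reset_index(drop=True),
            self.outc[self.outc["caseid"].isin(keep)].reset_index(drop=True),
            dict(self.stage_counts),
        )


def load_case_data(paths: Mapping[str, str | Path]) -> tuple[CaseData, dict]:
    """Read, deduplicate and normalize one FAERS-shaped load in a single call."""
    tables, diagnostics = read_faers_tables(paths)
    data = CaseData.from_tables(tables)
    return data, diagnostics


# ---------------------------------------------------------------------------
# PT -> SOC annotation and target selection


def map_pt_to_soc(reac: pd.DataFrame, pt_soc_map: PtSocMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate reactions with their SOC; collect unmapped PTs separately.

    Unmapped PTs stay in the annotated frame (with empty SOC) so PT-level
    tallies keep them; SOC-level tallies should drop the empty group. The
    unmapped report is returned for the diagnostics file, never silently.
    """
    if len(pt_soc_map) == 0:
        raise ValueError("PT->SOC map is empty")
    annotated = reac.copy()
    hits = annotated["pt"].map(pt_soc_map.soc_of)
    annotated["soc_name"] = [h[0] if h else "" for h in hits]
    annotated["soc_code"] = [h[1] if h else pd.NA for h in hits]
    unmapped = (
        annotated.loc[annotated["soc_name"].eq(""), "pt"]
        .value_counts()
        .rename_axis("pt")
        .reset_index(name="n_reports")
    )
    return annotated, unmapped


def select_target_reports(
    data: CaseData, drug_name: str, role_filter: Iterable[str] = ("PS",)
) -> pd.Index:
    """Caseids whose drug list contains the target drug in an allowed role.

    The drug name is normalized first, so trade names resolve to the same
    canonical token as the generic.
    """
    target = normalize_drug_name(drug_name)
    roles = set(role_filter)
    hit = data.drugs[
        data.drugs["drug_name_norm"].eq(target) & data.drugs["role"].isin(roles)
    ]
    ids = pd.Index(hit["caseid"].unique())
    if ids.empty:
        logger.warning("no reports found for drug %r with roles %s", target, sorted(roles))
    return ids


def iter_cases(data: CaseData) -> Iterator[ReportCase]:
    """Yield object-level ReportCase views (convenience for small data)."""
    drugs_by_case: dict[str, list[DrugEntry]] = {}
    for r in data.drugs.itertuples():
        drugs_by_case.setdefault(r.caseid, []).append(
            DrugEntry(r.primaryid, r.drug_name_raw, r.drug_name_norm, r.role)
        )
    reac_by_case: dict[str, list[ReactionEntry]] = {}
    for r in data.reac.itertuples():
        reac_by_case.setdefault(r.caseid, []).append(ReactionEntry(r.primaryid, r.pt))
    outc_by_case: dict[str, set[str]] = {}
    for r in data.outc.itertuples():
        outc_by_case.setdefault(r.caseid, set()).add(r.outc_cod)
    for r in data.demo.itertuples():
        yield ReportCase(
            primaryid=r.primaryid,
            caseid=r.caseid,
            fda_dt=r.fda_dt,
            sex=r.sex,
            age_years=None if pd.isna(r.age_years) else float(r.age_years),
            reporter=r.reporter,
            country=r.country,
            event_dt=r.event_dt,
            outcome_codes=frozenset(outc_by_case.get(r.caseid, set())),
            drugs=drugs_by_case.get(r.caseid, []),
            reactions=reac_by_case.get(r.caseid, []),
        )
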