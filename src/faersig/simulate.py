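"""Synthetic FAERS-shaped cohorts with known ground truth.

Every stage of the pipeline is testable without downloading FAERS: this
module generates dollar-delimited quarterly-style tables (DEMO, DRUG,
REAC, THER, INDI, OUTC, DELETED) from a seeded configuration and emits a
manifest of the realized truth (per drug-event co-report counts, per
pair-event counts, injected reporting-rate multipliers, the deletion
list), so recovered statistics can be checked against what was planted.

The sampling model is deliberately the simplest one under which
reporting-rate multipliers are identifiable: each case draws a drug set
from independent marginals, then each event is an independent Bernoulli
with probability ``baseline * product(applicable multipliers)``. A
(drug, event) injection multiplies the event's probability in cases
carrying that drug (optionally only for one sex, which lets tests build
stratum-specific and Simpson-style fixtures); a (drug_a, drug_b, event)
injection multiplies it further in cases carrying both drugs. Cases
that draw no event are resampled (reports always carry at least one
reaction), which conditions on non-emptiness without materially
distorting between-group reporting ratios.

Default demographic mixes, report-year profile, known-onset fraction and
the Weibull onset-time parameters (shape 0.60, scale 161.14 days) mirror
a published sarilumab reporting cohort, so summary tables are visually
comparable to the real thing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import FAERS_DELIMITER

_DATE_MIN, _DATE_MAX = 20170401, 20250331

DEFAULT_DRUGS: dict[str, float] = {
    "SARILUMAB": 0.15,
    "METHOTREXATE": 0.25,
    "UPADACITINIB": 0.06,
    "ABATACEPT": 0.06,
    "ADALIMUMAB": 0.10,
    "PREDNISONE": 0.20,
    "TOCILIZUMAB": 0.05,
}

DEFAULT_EVENTS: dict[str, float] = {
    "Drug ineffective": 0.15,
    "Pain": 0.12,
    "Arthralgia": 0.10,
    "Rheumatoid arthritis": 0.06,
    "Joint swelling": 0.06,
    "Condition aggravated": 0.05,
    "Injection site erythema": 0.04,
    "Nausea": 0.05,
    "Headache": 0.05,
    "Fatigue": 0.05,
    "Infection": 0.04,
    "Nasopharyngitis": 0.03,
    "Rash": 0.03,
    "Malaise": 0.03,
    "Diarrhoea": 0.03,
    "White blood cell count decreased": 0.02,
    "Hepatic enzyme increased": 0.02,
    "Dizziness": 0.02,
    "Pyrexia": 0.02,
    "Alopecia": 0.01,
}

#: Categorical mixes for the demographic columns (reporting-cohort-like).
DEFAULT_SEX = {"F": 0.756, "M": 0.159, "": 0.085}
DEFAULT_AGE_GROUPS = {"<18": 0.0010, "18-44": 0.0847, "45-64": 0.3707, ">=65": 0.2000, "": 0.3436}
DEFAULT_REPORTERS = {"MD": 0.5423, "CN": 0.3759, "PH": 0.0676, "OT": 0.0131, "LW": 0.0001, "": 0.0010}
DEFAULT_YEARS = {
    "2017": 0.0064, "2018": 0.0608, "2019": 0.1068, "2020": 0.1011, "2021": 0.1269,
    "2022": 0.1550, "2023": 0.1469, "2024": 0.2162, "2025": 0.0799,
}
DEFAULT_COUNTRIES = {
    "US": 0.9162, "CA": 0.0238, "GB": 0.0150, "DE": 0.0120, "FR": 0.0120,
    "JP": 0.0100, "BR": 0.0050, "AU": 0.0060,
}
DEFAULT_OUTCOME_PROBS = {
    "DE": 0.0174, "LT": 0.0124, "HO": 0.0876, "DS": 0.0288,
    "CA": 0.0017, "RI": 0.0003, "OT": 0.2214,
}

OTHER_INDICATIONS = ("Psoriatic arthritis", "Still's disease", "Polymyalgia rheumatica")


class SignalInjection(BaseModel):
    """Reporting-rate multiplier for one (drug, event) pair.

    ``sex`` restricts the effect to cases of that sex ('F' or 'M'),
    enabling stratum-specific fixtures.
    """

    drug: str
    event: str
    multiplier: float = Field(gt=0)
    sex: Optional[str] = None


class DDIInjection(BaseModel):
    """Extra multiplier applied only when both drugs are present."""

    drug_a: str
    drug_b: str
    event: str
    multiplier: float = Field(gt=0)


class GeneratorConfig(BaseModel):
    """Seeded configuration of one synthetic cohort."""

    n_cases: int = Field(gt=0)
    seed: int
    target_drug: str = "SARILUMAB"
    drugs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_DRUGS))
    events: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_EVENTS))
    signal_injections: list[SignalInjection] = Field(default_factory=list)
    ddi_injections: list[DDIInjection] = Field(default_factory=list)
    sex_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SEX))
    age_group_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_AGE_GROUPS))
    reporter_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_REPORTERS))
    year_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_YEARS))
    country_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    outcome_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    tto_shape: float = Field(default=0.60, gt=0)
    tto_scale: float = Field(default=161.14, gt=0)
    tto_known_fraction: float = Field(default=0.1306, ge=0, le=1)
    tto_outlier_fraction: float = Field(default=0.01, ge=0, le=1)
    weight_known_fraction: float = Field(default=0.097, ge=0, le=1)
    ra_indication_fraction: float = Field(default=0.8, ge=0, le=1)
    duplicate_rate: float = Field(default=0.10, ge=0, le=1)
    deletion_rate: float = Field(default=0.02, ge=0, le=1)

    @field_validator("drugs", "events")
    @classmethod
    def _probs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {k!r} outside [0, 1]: {p}")
        return v


@dataclass
class GroundTruthManifest:
    """Realized truth of one generated cohort, for oracle-style checks."""

    seed: int
    n_cases_true: int
    drug_event_counts: dict[str, int]
    pair_event_counts: dict[str, int]
    injections: list[dict]
    ddi_injections: list[dict]
    duplicate_caseids: list[str] = dc_field(default_factory=list)
    deletion_caseids: list[str] = dc_field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @staticmethod
    def pair_key(drug: str, event: str) -> str:
        return f"{drug}|{event}"

    @staticmethod
    def ddi_key(drug_a: str, drug_b: str, event: str) -> str:
        return f"{drug_a}+{drug_b}|{event}"


def sample_onset_days(
    n: int, shape: float, scale: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw n Weibull onset times (days) and round to whole days.

    Same-day onsets stay 0 here; downstream Weibull fitting applies its
    0.5-day likelihood shift.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    raw = scale * rng.weibull(shape, size=n)
    return np.rint(raw).astype(int)


def _date_from_year(year: int, rng: np.random.Generator) -> int:
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    dt = year * 10000 + month * 100 + day
    return min(max(dt, _DATE_MIN), _DATE_MAX)


def _ts(yyyymmdd: int) -> pd.Timestamp:
    s = str(yyyymmdd)
    return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8]))


def _fmt(ts: pd.Timestamp) -> str:
    return f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"


def generate_cohort(config: GeneratorConfig) -> tuple[dict[str, pd.DataFrame], GroundTruthManifest]:
    """Sample one deduplicated-truth cohort (no duplicate versions yet).

    Returns FAERS-shaped tables (one row per case in DEMO; satellite
    tables keyed by primaryid/caseid) and the ground-truth manifest with
    realized co-report counts. Raises when an injected multiplier drives
    any per-case event probability above 1.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = list(config.drugs)
    event_names = list(config.events)
    if config.target_drug not in config.drugs:
        raise ValueError(f"target drug {config.target_drug!r} missing from the drug catalog")

    caseids = np.arange(1_000_001, 1_000_001 + n)
    primaryids = caseids * 10 + 5  # version digit 5; duplicates get other digits

    sex = rng.choice(list(config.sex_probs), size=n, p=_norm(config.sex_probs))
    age_group = rng.choice(list(config.age_group_probs), size=n, p=_norm(config.age_group_probs))
    age_bounds = {"<18": (1, 18), "18-44": (18, 45), "45-64": (45, 65), ">=65": (65, 90)}
    age = np.array(
        [
            f"{rng.uniform(*age_bounds[g]):.0f}" if g in age_bounds else ""
            for g in age_group
        ]
    )
    age_cod = np.where(age != "", "YR", "")
    reporter = rng.choice(list(config.reporter_probs), size=n, p=_norm(config.reporter_probs))
    country = rng.choice(list(config.country_probs), size=n, p=_norm(config.country_probs))
    years = rng.choice(list(config.year_probs), size=n, p=_norm(config.year_probs)).astype(int)
    fda_dt = np.array([_date_from_year(y, rng) for y in years])
    wt_known = rng.random(n) < config.weight_known_fraction
    wt = np.where(wt_known, np.round(rng.lognormal(np.log(80), 0.3, size=n), 1), np.nan)

    # drug sets: independent marginals; drug-less cases get the most
    # common background drug so every report lists at least one drug
    probs = np.array([config.drugs[d] for d in drug_names])
    drug_matrix = rng.random((n, len(drug_names))) < probs
    empty = ~drug_matrix.any(axis=1)
    background = [d for d in drug_names if d != config.target_drug] or drug_names
    fallback = max(background, key=lambda d: config.drugs[d])
    drug_matrix[empty, drug_names.index(fallback)] = True

    # per-case event probabilities: baseline x injected multipliers
    p_event = np.tile(np.array([config.events[e] for e in event_names]), (n, 1))
    for inj in config.signal_injections:
        if inj.drug not in config.drugs or inj.event not in config.events:
            raise ValueError(f"injection references unknown drug/event: {inj}")
        rows = drug_matrix[:, drug_names.index(inj.drug)]
        if inj.sex is not None:
            rows = rows & (sex == inj.sex)
        p_event[rows, event_names.index(inj.event)] *= inj.multiplier
    for inj in config.ddi_injections:
        rows = (
            drug_matrix[:, drug_names.index(inj.drug_a)]
            & drug_matrix[:, drug_names.index(inj.drug_b)]
        )
        p_event[rows, event_names.index(inj.event)] *= inj.multiplier
    if p_event.max() > 1:
        raise ValueError("infeasible configuration: baseline x multiplier exceeds 1")

    event_matrix = rng.random((n, len(event_names))) < p_event
    # reports always carry >=1 reaction: resample empty draws
    for _ in range(50):
        empty = ~event_matrix.any(axis=1)
        if not empty.any():
            break
        event_matrix[empty] = rng.random((int(empty.sum()), len(event_names))) < p_event[empty]
    empty = ~event_matrix.any(axis=1)
    if empty.any():  # pathological configs: give up and use the modal event
        event_matrix[empty, int(np.argmax(p_event[empty].sum(axis=0)))] = True

    # onset times for target-drug reports
    target_col = drug_names.index(config.target_drug)
    has_target = drug_matrix[:, target_col]
    u = rng.random(n)
    tto_known = has_target & (u < config.tto_known_fraction)
    tto_outlier = has_target & (u >= config.tto_known_fraction) & (
        u < config.tto_known_fraction + config.tto_outlier_fraction
    )
    tto_days = sample_onset_days(n, config.tto_shape, config.tto_scale, rng)

    start_dt = np.full(n, "", dtype=object)
    event_dt = np.full(n, "", dtype=object)
    for i in np.flatnonzero(tto_known):
        start = _ts(fda_dt[i]) - pd.Timedelta(days=int(tto_days[i]) + int(rng.integers(0, 60)))
        start_dt[i] = _fmt(start)
        event_dt[i] = _fmt(start + pd.Timedelta(days=int(tto_days[i])))
    for i in np.flatnonzero(tto_outlier):  # event precedes start: excluded downstream
        start = _ts(fda_dt[i]) - pd.Timedelta(days=30)
        start_dt[i] = _fmt(start)
        event_dt[i] = _fmt(start - pd.Timedelta(days=int(rng.integers(1, 30))))

    demo = pd.DataFrame(
        {
            "primaryid": primaryids.astype(str),
            "caseid": caseids.astype(str),
            "fda_dt": fda_dt.astype(str),
            "sex": sex,
            "age": age,
            "age_cod": age_cod,
            "wt": ["" if np.isnan(w) else f"{w:g}" for w in wt],
            "occp_cod": reporter,
            "occr_country": country,
            "event_dt": event_dt,
        }
    )

    drug_rows, ther_rows, indi_rows = [], [], []
    for i in range(n):
        present = [drug_names[j] for j in np.flatnonzero(drug_matrix[i])]
        # the target drug is always the primary suspect when present
        if config.target_drug in present:
            present.remove(config.target_drug)
            present.insert(0, config.target_drug)
        for seq, name in enumerate(present, start=1):
            role = "PS" if seq == 1 else "C"
            pid, cid = str(primaryids[i]), str(caseids[i])
            drug_rows.append((pid, cid, str(seq), name, role))
            if name == config.target_drug and start_dt[i]:
                ther_rows.append((pid, cid, str(seq), start_dt[i]))
            # every drug entry carries an indication (the catalog is a
            # rheumatology formulary, so one RA fraction fits all)
            indi = (
                "Rheumatoid arthritis"
                if rng.random() < config.ra_indication_fraction
                else str(rng.choice(OTHER_INDICATIONS))
            )
            indi_rows.append((pid, cid, str(seq), indi))
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "caseid", "drug_seq", "drugname", "role_cod"])
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "caseid", "dsg_drug_seq", "start_dt"])
    indi = pd.DataFrame(indi_rows, columns=["primaryid", "caseid", "indi_drug_seq", "indi_pt"])

    reac_rows = []
    for i in range(n):
        for j in np.flatnonzero(event_matrix[i]):
            reac_rows.append((str(primaryids[i]), str(caseids[i]), event_names[j]))
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"])

    outc_rows = []
    outc_codes = list(config.outcome_probs)
    outc_draws = rng.random((n, len(outc_codes))) < np.array(
        [config.outcome_probs[c] for c in outc_codes]
    )
    for i in range(n):
        for j in np.flatnonzero(outc_draws[i]):
            outc_rows.append((str(primaryids[i]), str(caseids[i]), outc_codes[j]))
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"])

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther, "INDI": indi, "OUTC": outc}
    manifest = _build_manifest(config, drug_matrix, event_matrix, drug_names, event_names)
    return tables, manifest


def _norm(d: dict[str, float]) -> np.ndarray:
    p = np.array(list(d.values()), dtype=float)
    return p / p.sum()


def _build_manifest(
    config: GeneratorConfig,
    drug_matrix: np.ndarray,
    event_matrix: np.ndarray,
    drug_names: list[str],
    event_names: list[str],
    surviving: np.ndarray | None = None,
) -> GroundTruthManifest:
    keep = surviving if surviving is not None else np.ones(len(drug_matrix), dtype=bool)
    dm, em = drug_matrix[keep], event_matrix[keep]
    drug_event = {
        GroundTruthManifest.pair_key(d, e): int((dm[:, i] & em[:, j]).sum())
        for i, d in enumerate(drug_names)
        for j, e in enumerate(event_names)
    }
    pair_event = {}
    for inj in config.ddi_injections:
        ia, ib = drug_names.index(inj.drug_a), drug_names.index(inj.drug_b)
        je = event_names.index(inj.event)
        pair_event[GroundTruthManifest.ddi_key(inj.drug_a, inj.drug_b, inj.event)] = int(
            (dm[:, ia] & dm[:, ib] & em[:, je]).sum()
        )
    return GroundTruthManifest(
        seed=config.seed,
        n_cases_true=int(keep.sum()),
        drug_event_counts=drug_event,
        pair_event_counts=pair_event,
        injections=[i.model_dump() for i in config.signal_injections],
        ddi_injections=[i.model_dump() for i in config.ddi_injections],
    )


def inject_duplicates_and_deletions(
    tables: dict[str, pd.DataFrame],
    config: GeneratorConfig,
    manifest: GroundTruthManifest,
) -> tuple[dict[str, pd.DataFrame], GroundTruthManifest]:
    """Add obsolete report versions and a deletion list.

    A ``duplicate_rate`` fraction of cases gain 1-3 extra versions:
    either with an earlier FDA receipt date (any version digit), or with
    the same date and a smaller PRIMARYID — so both limbs of the
    retention rule get exercised. A ``deletion_rate`` fraction of cases
    go on the deletion list; the manifest's realized counts are
    recomputed over the surviving cases only.
    """
    rng = np.random.default_rng(config.seed + 1)
    demo = tables["DEMO"]
    n = len(demo)

    dup_mask = rng.random(n) < config.duplicate_rate
    extra_rows = []
    for i in np.flatnonzero(dup_mask):
        row = demo.iloc[i]
        caseid = int(row["caseid"])
        n_extra = int(rng.integers(1, 4))
        tie_date = rng.random() < 0.3
        digits = rng.choice([1, 2, 3, 4], size=n_extra, replace=False)
        for k, digit in enumerate(digits):
            dup = row.copy()
            dup["primaryid"] = str(caseid * 10 + int(digit))
            if not tie_date:  # earlier receipt date, so the original wins on date
                earlier = _ts(int(row["fda_dt"])) - pd.Timedelta(days=int(rng.integers(30, 400)))
                dup["fda_dt"] = _fmt(earlier)
            # tie_date: same fda_dt, smaller primaryid -> original wins on id
            extra_rows.append(dup)
    out = dict(tables)
    if extra_rows:
        out["DEMO"] = pd.concat([demo, pd.DataFrame(extra_rows)], ignore_index=True)

    del_mask = rng.random(n) < config.deletion_rate
    deletion_ids = demo.loc[del_mask, "caseid"].tolist()
    out["DELETED"] = pd.DataFrame({"caseid": deletion_ids})

    manifest.duplicate_caseids = demo.loc[dup_mask, "caseid"].tolist()
    manifest.deletion_caseids = deletion_ids
    manifest.n_cases_true = int(n - del_mask.sum())
    if deletion_ids:
        surviving = set(demo["caseid"]) - set(deletion_ids)
        manifest.drug_event_counts = _recount(out, surviving, "drugname", "pt")
        manifest.pair_event_counts = _recount_pairs(out, surviving, config)
    return out, manifest


def _recount(tables: dict[str, pd.DataFrame], surviving: set[str], *_cols) -> dict[str, int]:
    drug = tables["DRUG"]
    reac = tables["REAC"]
    drug = drug[drug["caseid"].isin(surviving)]
    reac = reac[reac["caseid"].isin(surviving)]
    by_drug = drug.groupby("drugname")["caseid"].agg(set)
    by_event = reac.groupby("pt")["caseid"].agg(set)
    return {
        GroundTruthManifest.pair_key(d, e): len(by_drug[d] & by_event[e])
        for d in by_drug.index
        for e in by_event.index
    }


def _recount_pairs(
    tables: dict[str, pd.DataFrame], surviving: set[str], config: GeneratorConfig
) -> dict[str, int]:
    drug = tables["DRUG"]
    reac = tables["REAC"]
    drug = drug[drug["caseid"].isin(surviving)]
    reac = reac[reac["caseid"].isin(surviving)]
    by_drug = drug.groupby("drugname")["caseid"].agg(set)
    by_event = reac.groupby("pt")["caseid"].agg(set)
    out = {}
    for inj in config.ddi_injections:
        ids_a = by_drug.get(inj.drug_a, set())
        ids_b = by_drug.get(inj.drug_b, set())
        ids_e = by_event.get(inj.event, set())
        out[GroundTruthManifest.ddi_key(inj.drug_a, inj.drug_b, inj.event)] = len(
            ids_a & ids_b & ids_e
        )
    return out


def write_faers_ascii(tables: dict[str, pd.DataFrame], directory: str | Path) -> dict[str, Path]:
    """Write tables as dollar-delimited ASCII files (header + records).

    The FAERS dialect has no quoting, so any field containing the
    delimiter is rejected with a clear error. Empty tables produce a
    header-only file. Returns the written paths keyed by table role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for role, df in tables.items():
        path = directory / f"{role}.txt"
        lines = [FAERS_DELIMITER.join(df.columns)]
        for row in df.itertuples(index=False):
            fields = [str(v) for v in row]
            for v in fields:
                if FAERS_DELIMITER in v:
                    raise ValueError(
                        f"{role}: field {v!r} contains the {FAERS_DELIMITER!r} delimiter; "
                        "the FAERS dialect has no quoting"
                    )
            lines.append(FAERS_DELIMITER.join(fields))
        path.write_text("\n".join(lines) + "\n")
        paths[role] = path
    return paths


def simulate_quarter(
    config: GeneratorConfig, directory: str | Path | None = None
) -> tuple[dict[str, pd.DataFrame], GroundTruthManifest, dict[str, Path] | None]:
    """Generate, duplicate/delete, and optionally write one synthetic load."""
    tables, manifest = generate_cohort(config)
    tables, manifest = inject_duplicates_and_deletions(tables, config, manifest)
    paths = None
    if directory is not None:
        paths = write_faers_ascii(tables, directory)
        manifest.to_json(Path(directory) / "ground_truth.json")
    return tables, manifest, paths
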