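"""Orchestration: overall, stratified and indication-restricted analyses.

Ties the parsing, disproportionality, time-to-onset and drug-drug
interaction layers into reproducible runs driven by a single validated
configuration. Every run writes CSV tables (signals per level, onset
bins, ECDF, DDI screen, demographic summary) plus a JSON manifest with
per-stage counts, the seed, and a hash of the configuration, so a rerun
with the same inputs is byte-identical and auditable.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .ddi import detect_ddi
from .io import CaseData, PtSocMap, load_country_regions, map_pt_to_soc, normalize_drug_name, select_target_reports
from .signals import rank_signals, signal_table
from .tto import TTORecord, bin_tto, compute_tto, cumulative_incidence, fit_weibull, tto_summary

logger = logging.getLogger(__name__)

STRATUM_AXES = ("sex", "age_group", "reporter")


class RunConfig(BaseModel):
    """Validated configuration of one analysis run."""

    target_drug: str
    role_filter: list[str] = Field(default_factory=lambda: ["PS"])
    levels: list[str] = Field(default_factory=lambda: ["PT", "SOC"])
    strata_axes: list[str] = Field(default_factory=lambda: list(STRATUM_AXES))
    indication_pt: Optional[str] = "Rheumatoid arthritis"
    co_drugs: list[str] = Field(default_factory=list)
    top_k: int = 50
    ddi_top_k_events: int = 10
    min_stratum_cases: int = 50
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# strata


def stratum_caseids(data: CaseData, axis: str) -> dict[str, pd.Index]:
    """Case sets per stratum level for one axis.

    Sex: male / female (unknown excluded). Age: 18-44 means
    18 <= age < 45, 45-64 means 45 <= age < 65, >=65 means age >= 65;
    under-18 and unknown excluded. Reporter: 'healthcare professional'
    aggregates physicians and other health-professionals; pharmacists
    stand alone; consumers stand alone; unknown and lawyers excluded.
    """
    demo = data.demo
    if axis == "sex":
        return {
            "female": pd.Index(demo.loc[demo["sex"].eq("F"), "caseid"]),
            "male": pd.Index(demo.loc[demo["sex"].eq("M"), "caseid"]),
        }
    if axis == "age_group":
        age = demo["age_years"]
        return {
            "18-44": pd.Index(demo.loc[(age >= 18) & (age < 45), "caseid"]),
            "45-64": pd.Index(demo.loc[(age >= 45) & (age < 65), "caseid"]),
            ">=65": pd.Index(demo.loc[age >= 65, "caseid"]),
        }
    if axis == "reporter":
        rep = demo["reporter"]
        return {
            "healthcare professional": pd.Index(
                demo.loc[rep.isin(["physician", "other health-professional"]), "caseid"]
            ),
            "consumer": pd.Index(demo.loc[rep.eq("consumer"), "caseid"]),
            "pharmacist": pd.Index(demo.loc[rep.eq("pharmacist"), "caseid"]),
        }
    raise ValueError(f"unknown stratification axis {axis!r}; expected one of {STRATUM_AXES}")


# ---------------------------------------------------------------------------
# demographic summary


def demographic_summary(
    data: CaseData,
    tto_records: list[TTORecord] | None = None,
    tto_excluded: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort characteristics table plus numeric summaries.

    Counts and percentages (of the total case count) by sex, age group,
    report year, reporter, outcome and onset-time bin, with a fixed row
    schema — empty categories stay as 0 (0.00%) rows. The second return
    value holds mean/SD/median/quartile summaries for age, onset time
    and weight, and the continent grouping of report countries.
    """
    demo = data.demo
    n = len(demo)
    rows: list[dict] = []

    def add(section: str, category: str, count: int) -> None:
        rows.append(
            {
                "section": section,
                "category": category,
                "n": int(count),
                "pct": round(100.0 * count / n, 2) if n else 0.0,
            }
        )

    add("sex", "Female", (demo["sex"] == "F").sum())
    add("sex", "Male", (demo["sex"] == "M").sum())
    add("sex", "Not specified", (demo["sex"] == "unknown").sum())

    age = demo["age_years"]
    add("age_group", "<18", ((age >= 0) & (age < 18)).sum())
    add("age_group", "18-44", ((age >= 18) & (age < 45)).sum())
    add("age_group", "45-64", ((age >= 45) & (age < 65)).sum())
    add("age_group", ">=65", (age >= 65).sum())
    add("age_group", "Not specified", age.isna().sum())

    for year in sorted(demo["year"].unique()):
        add("report_year", year, (demo["year"] == year).sum())

    for label in (
        "consumer",
        "lawyer",
        "unknown",
        "other health-professional",
        "pharmacist",
        "physician",
    ):
        display = "Not specified" if label == "unknown" else label.capitalize()
        add("reporter", display, (demo["reporter"] == label).sum())

    outc_labels = {
        "DE": "Death",
        "LT": "Life-threatening",
        "HO": "Hospitalization",
        "DS": "Disability",
        "CA": "Congenital anomaly",
        "RI": "Required intervention",
        "OT": "Other",
    }
    outc_cases = data.outc.groupby("outc_cod")["caseid"].nunique()
    for code, label in outc_labels.items():
        add("outcomes", label, int(outc_cases.get(code, 0)))

    if tto_records is not None:
        bins = bin_tto(tto_records, n_all_reports=n)
        for r in bins.itertuples():
            add("tto_bin", f"{r.bin} days", r.n)
        missing = tto_excluded if tto_excluded is not None else n - len(tto_records)
        add("tto_bin", "Missing or outlier", missing)

    regions = load_country_regions()
    region_counts = (
        demo["country"].map(lambda c: regions.get(c, "Other")).value_counts().to_dict()
    )

    numeric = {
        "age_years": _numeric_summary(age),
        "weight_kg": _numeric_summary(demo["weight_kg"]),
        "tto_days": tto_summary(tto_records) if tto_records is not None else {"n": 0},
        "regions": region_counts,
    }
    return pd.DataFrame(rows), numeric


def _numeric_summary(s: pd.Series) -> dict:
    v = pd.to_numeric(s, errors="coerce").dropna()
    if v.empty:
        return {"n": 0, "missing": int(s.isna().sum())}
    return {
        "n": int(len(v)),
        "missing": int(s.isna().sum()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "median": float(v.median()),
        "q1": float(v.quantile(0.25)),
        "q3": float(v.quantile(0.75)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


# ---------------------------------------------------------------------------
# analysis runs


def _check_target_present(data: CaseData, config: RunConfig) -> None:
    target = normalize_drug_name(config.target_drug)
    known = data.drugs["drug_name_norm"].unique().tolist()
    if target not in known:
        suggestions = difflib.get_close_matches(target, known, n=3)
        raise ValueError(
            f"target drug {target!r} absent from the data; close names: {suggestions}"
        )


def run_overall(
    data: CaseData,
    config: RunConfig,
    pt_soc_map: PtSocMap | None = None,
) -> dict:
    """The full single-stratum analysis: signals, onset model, DDI screen.

    Returns a dict of DataFrames/objects; :func:`write_outputs` persists
    them. Deterministic given inputs and configuration.
    """
    _check_target_present(data, config)
    pt_soc_map = pt_soc_map or PtSocMap.bundled_fixture()
    annotated, unmapped = map_pt_to_soc(data.reac, pt_soc_map)

    results: dict = {"run_log": dict(data.stage_counts)}
    target_ids = select_target_reports(data, config.target_drug, config.role_filter)
    results["run_log"]["target_drug_cases"] = len(target_ids)

    for level in config.levels:
        table = signal_table(
            data,
            config.target_drug,
            level=level,
            role_filter=config.role_filter,
            annotated_reac=annotated if level == "SOC" else None,
        )
        results[f"signals_{level.lower()}"] = rank_signals(table, by="frequency")
    if "signals_pt" in results and not results["signals_pt"].empty:
        pt_tab = results["signals_pt"]
        soc_lookup = {
            r.pt: r.soc_name for r in pt_soc_map.as_frame().itertuples()
        }
        pt_tab.insert(0, "soc_name", pt_tab["event"].map(lambda p: soc_lookup.get(p, "")))
        positives = pt_tab[pt_tab["positive"] & pt_tab["soc_name"].ne("")]
        results["positive_pts_per_soc"] = (
            positives.groupby("soc_name")["event"].count().rename("n_positive_pts").reset_index()
        )
    results["unmapped_pts"] = unmapped

    tto_records, tally = compute_tto(data, config.target_drug, config.role_filter)
    results["run_log"].update({f"tto_{k}": v for k, v in tally.items()})
    results["tto_records"] = pd.DataFrame(
        [
            {"caseid": r.caseid, "tto_days": r.tto_days}
            for r in sorted(tto_records, key=lambda r: r.caseid)
        ]
    )
    results["tto_bins"] = bin_tto(tto_records, n_all_reports=data.n_cases)
    if len(tto_records) >= 10 and len({r.tto_days for r in tto_records}) >= 2:
        results["weibull"] = fit_weibull(tto_records)
        results["ecdf"] = cumulative_incidence(tto_records)
    else:
        results["weibull"] = None
        results["ecdf"] = pd.DataFrame(columns=["day", "cumulative_fraction"])

    summary, numeric = demographic_summary(data, tto_records, tally["missing_or_outlier"])
    results["demographics"] = summary
    results["demographics_numeric"] = numeric

    if config.co_drugs:
        results["ddi"] = detect_ddi(
            data,
            config.target_drug,
            config.co_drugs,
            top_k_events=config.ddi_top_k_events,
            role_filter_a=config.role_filter,
        )
    else:
        results["ddi"] = pd.DataFrame(
            columns=["drug_a", "drug_b", "event_pt", "n11", "e11", "omega", "omega_lo", "omega_hi", "significant"]
        )
    return results


def run_stratified(data: CaseData, config: RunConfig) -> pd.DataFrame:
    """Per-stratum signal tables with stratum-restricted backgrounds.

    Within each stratum the whole 2x2 (background included) is computed
    from that stratum's reports only, so population-specific signals
    masked in pooled data can surface. Strata with fewer target-drug
    cases than ``min_stratum_cases`` are emitted with ``sparse=True``.
    Empty strata yield no rows (with a warning), never a crash.
    """
    _check_target_present(data, config)
    frames = []
    for axis in config.strata_axes:
        for label, ids in stratum_caseids(data, axis).items():
            table = signal_table(
                data,
                config.target_drug,
                level="PT",
                role_filter=config.role_filter,
                stratum_caseids=ids,
                stratum_label=f"{axis}:{label}",
            )
            if table.empty:
                continue
            n_target = len(set(select_target_reports(data, config.target_drug, config.role_filter)) & set(ids))
            table.insert(0, "axis", axis)
            table.insert(1, "stratum", label)
            table["sparse"] = n_target < config.min_stratum_cases
            frames.append(rank_signals(table, by="frequency"))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def indication_caseids(data: CaseData, config: RunConfig) -> pd.Index:
    """Reports with the given indication PT on any of their drug entries."""
    hit = data.indi[data.indi["indi_pt"].eq(config.indication_pt)]
    return pd.Index(hit["caseid"].unique())


def run_indication_sensitivity(data: CaseData, config: RunConfig) -> dict:
    """Repeat the analysis restricted to one recorded indication.

    The indication-filtered case set is a strict subset of the overall
    data; the comparison frame reports positive-PT counts under each
    analysis, their overlap, per-PT ROR deltas, and the onset-time
    medians in both.
    """
    _check_target_present(data, config)
    ids = indication_caseids(data, config)
    if ids.empty:
        raise ValueError(f"indication filter {config.indication_pt!r} matches zero reports")
    subset = data.subset(ids)

    overall_pt = rank_signals(
        signal_table(data, config.target_drug, level="PT", role_filter=config.role_filter),
        by="frequency",
    )
    subset_pt = rank_signals(
        signal_table(subset, config.target_drug, level="PT", role_filter=config.role_filter),
        by="frequency",
    )
    overall_tto, _ = compute_tto(data, config.target_drug, config.role_filter)
    subset_tto, _ = compute_tto(subset, config.target_drug, config.role_filter)

    ov_pos = set(overall_pt.loc[overall_pt["positive"], "event"])
    su_pos = set(subset_pt.loc[subset_pt["positive"], "event"])
    merged = overall_pt[["event", "ror"]].merge(
        subset_pt[["event", "ror"]], on="event", suffixes=("_overall", "_restricted")
    )
    merged["ror_delta"] = merged["ror_restricted"] - merged["ror_overall"]

    comparison = {
        "n_cases_overall": data.n_cases,
        "n_cases_restricted": subset.n_cases,
        "positive_pts_overall": len(ov_pos),
        "positive_pts_restricted": len(su_pos),
        "positive_pt_overlap": len(ov_pos & su_pos),
        "tto_median_overall": tto_summary(overall_tto).get("median"),
        "tto_median_restricted": tto_summary(subset_tto).get("median"),
    }
    return {
        "signals_pt": subset_pt,
        "ror_deltas": merged.sort_values("event", kind="mergesort").reset_index(drop=True),
        "comparison": comparison,
        "caseids": ids,
    }


# ---------------------------------------------------------------------------
# persistence


def write_outputs(results: dict, config: RunConfig, outdir: str | Path) -> Path:
    """Write all run products as CSV/JSON under ``outdir``.

    Frames are written even when empty (with headers) so downstream
    tooling can rely on the files existing. The JSON manifest records
    stage counts, the seed, the config hash, and the package version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.csv", index=False)
    if results.get("weibull") is not None:
        (outdir / "weibull.json").write_text(json.dumps(results["weibull"].to_dict(), indent=2))
    if "demographics_numeric" in results:
        (outdir / "demographics_numeric.json").write_text(
            json.dumps(results["demographics_numeric"], indent=2, sort_keys=True)
        )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_counts": results.get("run_log", {}),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def run_all(
    data: CaseData,
    config: RunConfig,
    pt_soc_map: PtSocMap | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Overall + stratified + indication-restricted analyses in one call."""
    results = run_overall(data, config, pt_soc_map)
    results["stratified"] = run_stratified(data, config)
    if config.indication_pt:
        try:
            sens = run_indication_sensitivity(data, config)
        except ValueError as err:
            logger.warning("sensitivity analysis skipped: %s", err)
        else:
            results["sensitivity_signals_pt"] = sens["signals_pt"]
            results["sensitivity_ror_deltas"] = sens["ror_deltas"]
            results["run_log"] = {**results["run_log"], "sensitivity": sens["comparison"]}
    if outdir is not None:
        write_outputs(results, config, outdir)
    return results
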