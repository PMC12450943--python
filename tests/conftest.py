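"""Shared fixtures: hand-built case sets and seeded synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from faersig import CaseData, GeneratorConfig, SignalInjection, simulate_quarter
from faersig.io import normalize_drug_name


def make_case_data(cases: list[dict]) -> CaseData:
    """Build a CaseData directly from per-case specs.

    Each spec may carry: caseid (str), sex ('F'/'M'/'unknown'),
    age_years (float or None), reporter label, drugs (list of
    (name, role) tuples), events (list of PT strings), event_dt /
    start_dt (YYYYMMDD strings, start attached to the first drug),
    indications (list of (drug_name, indi_pt)), outcomes (codes).
    """
    demo_rows, drug_rows, reac_rows, ther_rows, indi_rows, outc_rows = [], [], [], [], [], []
    for i, c in enumerate(cases):
        caseid = str(c.get("caseid", 1000 + i))
        pid = caseid + "5"
        demo_rows.append(
            {
                "primaryid": pid,
                "caseid": caseid,
                "fda_dt": c.get("fda_dt", "20230115"),
                "sex": c.get("sex", "F"),
                "age_years": c.get("age_years", 55.0),
                "weight_kg": c.get("weight_kg", float("nan")),
                "reporter": c.get("reporter", "physician"),
                "country": c.get("country", "US"),
                "event_dt": c.get("event_dt", ""),
                "year": str(c.get("fda_dt", "20230115"))[:4],
            }
        )
        for seq, (name, role) in enumerate(c.get("drugs", []), start=1):
            drug_rows.append(
                {
                    "primaryid": pid,
                    "caseid": caseid,
                    "drug_seq": str(seq),
                    "drug_name_raw": name,
                    "role": role,
                    "drug_name_norm": normalize_drug_name(name),
                }
            )
            if seq == 1 and c.get("start_dt"):
                ther_rows.append(
                    {"primaryid": pid, "caseid": caseid, "drug_seq": "1", "start_dt": c["start_dt"]}
                )
        for pt in c.get("events", []):
            reac_rows.append({"primaryid": pid, "caseid": caseid, "pt": pt})
        for name, indi_pt in c.get("indications", []):
            seq = next(
                s for s, (n, _) in enumerate(c.get("drugs", []), start=1) if n == name
            )
            indi_rows.append(
                {"primaryid": pid, "caseid": caseid, "drug_seq": str(seq), "indi_pt": indi_pt}
            )
        for code in c.get("outcomes", []):
            outc_rows.append({"primaryid": pid, "caseid": caseid, "outc_cod": code})

    def frame(rows, columns):
        return pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)

    return CaseData(
        demo=pd.DataFrame(demo_rows),
        drugs=frame(drug_rows, ["primaryid", "caseid", "drug_seq", "drug_name_raw", "role", "drug_name_norm"]),
        reac=frame(reac_rows, ["primaryid", "caseid", "pt"]),
        ther=frame(ther_rows, ["primaryid", "caseid", "drug_seq", "start_dt"]),
        indi=frame(indi_rows, ["primaryid", "caseid", "drug_seq", "indi_pt"]),
        outc=frame(outc_rows, ["primaryid", "caseid", "outc_cod"]),
    )


@pytest.fixture(scope="session")
def injected_cohort():
    """A seeded 8,000-case cohort with three planted PT signals."""
    config = GeneratorConfig(
        n_cases=8000,
        seed=20240101,
        signal_injections=[
            SignalInjection(drug="SARILUMAB", event="Alopecia", multiplier=6.0),
            SignalInjection(drug="SARILUMAB", event="Injection site erythema", multiplier=5.0),
            SignalInjection(drug="SARILUMAB", event="White blood cell count decreased", multiplier=5.0),
        ],
    )
    tables, manifest, _ = simulate_quarter(config)
    return CaseData.from_tables(tables), manifest, config
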