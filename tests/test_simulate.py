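"""Synthetic-cohort generator: determinism, self-consistency, calibration."""

from __future__ import annotations

import filecmp

import numpy as np
import pandas as pd
import pytest

from faersig import (
    CaseData,
    GeneratorConfig,
    SignalInjection,
    generate_cohort,
    read_faers_tables,
    signal_table,
    simulate_quarter,
    write_faers_ascii,
)


def test_same_seed_gives_byte_identical_files(tmp_path):
    config = GeneratorConfig(n_cases=400, seed=13)
    _, _, paths_a = simulate_quarter(config, tmp_path / "a")
    _, _, paths_b = simulate_quarter(config.model_copy(), tmp_path / "b")
    for role in paths_a:
        assert filecmp.cmp(paths_a[role], paths_b[role], shallow=False), role


def test_manifest_counts_match_emitted_files(tmp_path):
    config = GeneratorConfig(n_cases=1500, seed=23, duplicate_rate=0.1, deletion_rate=0.03)
    _, manifest, paths = simulate_quarter(config, tmp_path)
    tables, _ = read_faers_tables(paths)
    data = CaseData.from_tables(tables)
    by_drug = data.drugs.groupby("drug_name_norm")["caseid"].agg(set)
    by_event = data.reac.groupby("pt")["caseid"].agg(set)
    for key, expected in manifest.drug_event_counts.items():
        drug, event = key.split("|")
        got = len(by_drug.get(drug, set()) & by_event.get(event, set()))
        assert got == expected, key


def test_infeasible_multiplier_rejected():
    config = GeneratorConfig(
        n_cases=100, seed=1,
        signal_injections=[SignalInjection(drug="SARILUMAB", event="Drug ineffective", multiplier=50.0)],
    )
    with pytest.raises(ValueError, match="infeasible"):
        generate_cohort(config)


def test_delimiter_in_field_rejected_at_write(tmp_path):
    df = pd.DataFrame({"primaryid": ["15"], "caseid": ["1"], "pt": ["bad$value"]})
    with pytest.raises(ValueError, match="delimiter"):
        write_faers_ascii({"REAC": df}, tmp_path)


def test_empty_table_writes_header_only_file(tmp_path):
    df = pd.DataFrame(columns=["primaryid", "caseid", "pt"])
    paths = write_faers_ascii({"REAC": df}, tmp_path)
    assert paths["REAC"].read_text() == "primaryid$caseid$pt\n"


def test_null_and_injected_reporting_ratio_calibration():
    """ROR near the planted multiplier; near 1 everywhere else (n=50,000)."""
    config = GeneratorConfig(
        n_cases=50_000, seed=71, duplicate_rate=0.0, deletion_rate=0.0,
        signal_injections=[SignalInjection(drug="SARILUMAB", event="Alopecia", multiplier=4.0)],
    )
    tables, _, _ = simulate_quarter(config)
    data = CaseData.from_tables(tables)
    table = signal_table(data, "SARILUMAB").set_index("event")
    assert 3.5 < table.loc["Alopecia", "ror"] < 4.5
    null_rors = table.drop(index="Alopecia")["ror"]
    assert abs(np.log(null_rors)).max() < 0.35
    assert 0.9 < float(np.median(null_rors)) < 1.1
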