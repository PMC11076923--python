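"""Harmonization: recoding, eligibility, numeric derivation, round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from volunteerbias.codebook import (
    Codebook,
    Eligibility,
    Variable,
    derive_numeric,
    filter_eligible,
    indicator,
    read_person_table,
    recode_table,
    resolve_analysis_column,
    spec_variable,
    validate_person_table,
    write_person_table,
)


def test_variable_rejects_duplicate_levels():
    with pytest.raises(ValueError):
        Variable(name="x", levels=("a", "a"))


def test_variable_rejects_numeric_for_unknown_level():
    with pytest.raises(ValueError):
        Variable(name="x", levels=("a", "b"), numeric={"c": 1.0})


def test_recode_table_maps_and_counts_unmapped():
    cb = Codebook(
        variables=[
            Variable(
                name="health",
                levels=("poor", "good"),
                recode={"bad": "poor", "fine": "good"},
            )
        ]
    )
    raw = pd.DataFrame(
        {"person_id": [1, 2, 3, 4, 5],
         "health": ["bad", "good", "fine", "???", None]}
    )
    out, log = recode_table(raw, cb)
    assert list(out["health"][:3]) == ["poor", "good", "good"]
    assert out["health"].isna().tolist() == [False, False, False, True, True]
    assert log.unmapped == {"health": 1}
    assert log.total == 1


def test_derive_numeric_maps_levels_and_propagates_missing(tiny_codebook):
    df = pd.DataFrame({"age_band": ["40-49", "60-69", None]})
    got = derive_numeric(df, tiny_codebook, "age_band")
    assert got.iloc[0] == 44.5 and got.iloc[1] == 64.5
    assert np.isnan(got.iloc[2])


def test_derive_numeric_requires_numeric_map(tiny_codebook):
    df = pd.DataFrame({"tenure": ["owner"]})
    with pytest.raises(ValueError):
        derive_numeric(df, tiny_codebook, "tenure")


def test_filter_eligible_counts_age_before_region(tiny_codebook):
    cb = Codebook(
        variables=tiny_codebook.variables,
        eligibility=Eligibility(
            cohort_variable="age_band",
            cohort_window=("50-59", "60-69"),
            region_variable="region",
            region_eligible_level="eligible",
        ),
    )
    df = pd.DataFrame(
        {
            "person_id": [1, 2, 3, 4],
            "age_band": ["40-49", "50-59", "40-49", "60-69"],
            "health": ["poor"] * 4,
            "tenure": ["owner"] * 4,
            "region": ["eligible", "ineligible", "ineligible", "eligible"],
        }
    )
    kept, log = filter_eligible(df, cb)
    assert list(kept["person_id"]) == [4]
    # rows 1 and 3 fail the age window (row 3 also fails region but counts
    # under age); row 2 fails region only
    assert log.age == 2
    assert log.region == 1


def test_indicator_is_binary_with_nan_passthrough():
    df = pd.DataFrame({"health": ["poor", "good", None]})
    got = indicator(df, "health", "poor")
    assert got.iloc[0] == 1.0 and got.iloc[1] == 0.0
    assert np.isnan(got.iloc[2])


def test_resolve_analysis_column_indicator_and_numeric(tiny_codebook):
    df = pd.DataFrame({"age_band": ["40-49", "60-69"], "health": ["poor", "good"]})
    ind = resolve_analysis_column(df, tiny_codebook, "health=poor")
    assert list(ind) == [1.0, 0.0]
    num = resolve_analysis_column(df, tiny_codebook, "age_band")
    assert list(num) == [44.5, 64.5]


def test_spec_variable():
    assert spec_variable("health=poor") == "health"
    assert spec_variable("age_band") == "age_band"


def test_person_table_round_trip(tmp_path, tiny_codebook):
    df = pd.DataFrame(
        {
            "person_id": [1, 2],
            "age_band": ["40-49", None],
            "health": ["poor", "good"],
            "tenure": [None, "owner"],
            "region": ["eligible", "eligible"],
        }
    )
    path = tmp_path / "people.csv"
    write_person_table(df, path)
    back = read_person_table(path, tiny_codebook)
    assert back["age_band"].iloc[0] == "40-49"
    assert pd.isna(back["age_band"].iloc[1])
    assert pd.isna(back["tenure"].iloc[0])
    assert back["tenure"].iloc[1] == "owner"


def test_validate_person_table_rejects_bad_level(tiny_codebook):
    df = pd.DataFrame(
        {
            "person_id": [1],
            "age_band": ["40-49"],
            "health": ["wonderful"],
            "tenure": ["owner"],
            "region": ["eligible"],
        }
    )
    with pytest.raises(ValueError, match="health"):
        validate_person_table(df, tiny_codebook)


def test_validate_person_table_rejects_duplicate_ids(tiny_codebook):
    df = pd.DataFrame(
        {
            "person_id": [1, 1],
            "age_band": ["40-49"] * 2,
            "health": ["poor"] * 2,
            "tenure": ["owner"] * 2,
            "region": ["eligible"] * 2,
        }
    )
    with pytest.raises(ValueError):
        validate_person_table(df, tiny_codebook)
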