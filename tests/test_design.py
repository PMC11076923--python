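"""Design matrix: column enumeration, values, pruning, subsetting."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from volunteerbias.design import (
    build_design_matrix,
    expected_column_count,
    interaction_column_name,
    main_column_name,
)


@pytest.fixture
def small_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": np.arange(8),
            "age_band": ["40-49", "50-59", "60-69", "40-49",
                         "50-59", "60-69", "40-49", "50-59"],
            "health": ["poor", "good", "poor", "good",
                       "poor", "good", "poor", "good"],
            "tenure": ["renter", "owner", "owner", "renter",
                       "owner", "renter", "owner", "owner"],
            "region": ["eligible"] * 8,
        }
    )


def test_expected_column_count_combinatorial_oracle():
    # brute-force enumeration over level tuples
    for level_counts in ([2, 3], [3, 4, 2], [2, 2, 2, 5]):
        mains = sum(level_counts)
        inters = sum(
            a * b for a, b in itertools.combinations(level_counts, 2)
        )
        assert expected_column_count(level_counts) == mains + inters


def test_unpruned_design_has_expected_columns(small_table, tiny_codebook):
    d = build_design_matrix(
        small_table, tiny_codebook,
        variables=["age_band", "health", "tenure"], prune=False,
    )
    assert len(d.columns) == expected_column_count([3, 2, 2])
    assert d.X.shape == (8, len(d.columns))


def test_design_column_values_are_correct_dummies(small_table, tiny_codebook):
    d = build_design_matrix(
        small_table, tiny_codebook,
        variables=["age_band", "health", "tenure"], prune=False,
    )
    X = np.asarray(d.X.todense())
    j = d.column_index(main_column_name("health", "poor"))
    assert np.array_equal(X[:, j], (small_table["health"] == "poor").astype(float))
    j = d.column_index(interaction_column_name("health", "poor", "tenure", "owner"))
    manual = (
        (small_table["health"] == "poor") & (small_table["tenure"] == "owner")
    ).astype(float)
    assert np.array_equal(X[:, j], manual)


def test_interaction_equals_product_of_mains(small_table, tiny_codebook):
    d = build_design_matrix(
        small_table, tiny_codebook,
        variables=["age_band", "health", "tenure"], prune=False,
    )
    X = np.asarray(d.X.todense())
    for c in d.columns:
        if not c.startswith("int:"):
            continue
        t1, t2 = c[4:].split("×")
        (v1, l1), (v2, l2) = t1.split("="), t2.split("=")
        j1 = d.column_index(main_column_name(v1, l1))
        j2 = d.column_index(main_column_name(v2, l2))
        j = d.column_index(c)
        assert np.array_equal(X[:, j], X[:, j1] * X[:, j2]), c


def test_pruning_removes_constant_and_duplicate_columns(tiny_codebook):
    # tenure is constant; health duplicates age_band perfectly
    table = pd.DataFrame(
        {
            "person_id": [0, 1, 2, 3],
            "age_band": ["40-49", "40-49", "50-59", "50-59"],
            "health": ["poor", "poor", "good", "good"],
            "tenure": ["owner"] * 4,
            "region": ["eligible"] * 4,
        }
    )
    d = build_design_matrix(
        table, tiny_codebook, variables=["age_band", "health", "tenure"]
    )
    reasons = {reason for _, reason in d.pruned}
    assert "constant" in reasons
    assert any(r.startswith("duplicate") for r in reasons)
    X = np.asarray(d.X.todense())
    # no constant columns remain
    assert all(0 < X[:, j].sum() < len(table) for j in range(X.shape[1]))
    # no duplicate columns remain
    seen = {X[:, j].tobytes() for j in range(X.shape[1])}
    assert len(seen) == X.shape[1]


def test_missing_values_raise(small_table, tiny_codebook):
    small_table.loc[0, "health"] = None
    with pytest.raises(ValueError):
        build_design_matrix(
            small_table, tiny_codebook, variables=["age_band", "health"]
        )


def test_drop_variables_removes_all_touching_columns(small_table, tiny_codebook):
    d = build_design_matrix(
        small_table, tiny_codebook,
        variables=["age_band", "health", "tenure"], prune=False,
    )
    reduced = d.drop_variables({"health"})
    assert all("health=" not in c for c in reduced.columns)
    kept = [c for c in d.columns if "health=" not in c]
    assert reduced.columns == kept


def test_to_triplets_round_trip(small_table, tiny_codebook):
    d = build_design_matrix(
        small_table, tiny_codebook, variables=["health", "tenure"], prune=False
    )
    trip = d.to_triplets()
    X = np.asarray(d.X.todense())
    assert len(trip) == int(X.sum())
    j = d.column_index(main_column_name("tenure", "owner"))
    owners = set(trip.loc[trip["column_name"] == main_column_name("tenure", "owner"), "row_id"])
    assert owners == set(d.row_ids[X[:, j] == 1])
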