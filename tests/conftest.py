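"""Shared fixtures: a tiny codebook and small synthetic samples."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from volunteerbias.codebook import Codebook, Eligibility, Variable
from volunteerbias.synthpop import PopulationSpec, SelectionSpec, generate_population


@pytest.fixture
def tiny_codebook() -> Codebook:
    return Codebook(
        variables=[
            Variable(
                name="age_band",
                levels=("40-49", "50-59", "60-69"),
                numeric={"40-49": 44.5, "50-59": 54.5, "60-69": 64.5},
            ),
            Variable(name="health", levels=("poor", "good"),
                     numeric={"poor": 1.0, "good": 2.0}),
            Variable(name="tenure", levels=("renter", "owner")),
            Variable(name="region", levels=("ineligible", "eligible")),
        ],
        eligibility=Eligibility(
            cohort_variable="age_band",
            cohort_window=("40-49", "50-59", "60-69"),
            region_variable="region",
            region_eligible_level="eligible",
        ),
    )


@pytest.fixture
def tiny_spec() -> PopulationSpec:
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = -0.3   # age vs health
    corr[1, 2] = corr[2, 1] = 0.4    # health vs tenure
    return PopulationSpec(
        n_population=6000,
        variables=[
            ("age_band", ("40-49", "50-59", "60-69"), (0.4, 0.35, 0.25)),
            ("health", ("poor", "good"), (0.3, 0.7)),
            ("tenure", ("renter", "owner"), (0.35, 0.65)),
            ("region", ("ineligible", "eligible"), (0.1, 0.9)),
        ],
        latent_correlation=corr,
        seed=11,
    )


@pytest.fixture
def tiny_population(tiny_spec) -> pd.DataFrame:
    return generate_population(tiny_spec)


@pytest.fixture
def tiny_selection() -> SelectionSpec:
    return SelectionSpec(
        coefficients={
            "main:health=good": 0.6,
            "main:tenure=owner": 0.4,
            "main:age_band=60-69": 0.3,
        },
        target_rate=0.25,
        seed=5,
    )
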