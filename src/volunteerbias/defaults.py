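"""Default synthetic study conditions.

Ten categorical socio-demographic/health variables whose marginals are
loosely calibrated to published census-side summary statistics for a
biobank-eligible population (middle-aged, ~51% female, ~9% in poor health,
~28% degree-educated, ~74% home owners, ~89% white ethnicity, ~18%
one-person households), with a Gaussian-copula latent correlation encoding
plausible socio-demographic structure. The volunteer-selection mechanism
participates at a 5.5% target rate and loads on older age, education, home
ownership and white ethnicity — the direction reported for
healthy-volunteer bias — with two-way interactions (notably age×health,
making poor health a far stronger deterrent at older ages) that produce the
in-cohort reversal of the age→poor-health association and pervasive
distortion of pairwise associations.

The reference sample defaults (5% sampling fraction, 95% response) mirror a
census safeguarded-microdata design.
"""

from __future__ import annotations

import numpy as np

from volunteerbias.codebook import Codebook, Eligibility, Variable
from volunteerbias.synthpop import PopulationSpec, SelectionSpec

REFERENCE_SAMPLING_FRACTION = 0.05
REFERENCE_RESPONSE_RATE = 0.95
TARGET_PARTICIPATION_RATE = 0.055

_VARIABLES: list[tuple[str, tuple[str, ...], tuple[float, ...]]] = [
    ("age_band", ("35-39", "40-49", "50-59", "60-69", "70-74"),
     (0.07, 0.27, 0.31, 0.28, 0.07)),
    ("region", ("ineligible", "eligible"), (0.12, 0.88)),
    ("sex", ("male", "female"), (0.492, 0.508)),
    ("health", ("poor", "fair", "good", "excellent"),
     (0.093, 0.300, 0.496, 0.111)),
    ("education", ("none", "secondary", "vocational", "degree"),
     (0.40, 0.22, 0.10, 0.28)),
    ("employment", ("incapacitated", "unemployed", "retired", "other", "paid_work"),
     (0.069, 0.033, 0.249, 0.040, 0.609)),
    ("tenure", ("renter", "owner"), (0.264, 0.736)),
    ("cars", ("none", "one", "two_plus"), (0.18, 0.42, 0.40)),
    ("ethnicity", ("other", "white"), (0.112, 0.888)),
    ("household", ("multi", "single"), (0.819, 0.181)),
]

_NUMERIC_MAPS = {
    "age_band": {"35-39": 37.0, "40-49": 44.5, "50-59": 54.5,
                 "60-69": 64.5, "70-74": 72.0},
    "health": {"poor": 1.0, "fair": 2.0, "good": 3.0, "excellent": 4.0},
    "education": {"none": 10.0, "secondary": 12.0, "vocational": 14.0,
                  "degree": 17.0},
    "cars": {"none": 0.0, "one": 1.0, "two_plus": 2.4},
}

# latent (copula) correlations; variable order as in _VARIABLES;
# positive values mean later levels co-occur (employment runs
# incapacitated -> unemployed -> retired -> other -> paid_work)
_LATENT_PAIRS = {
    ("age_band", "health"): -0.15,     # older -> worse self-rated health
    ("age_band", "education"): -0.25,  # older cohorts less formally educated
    ("age_band", "employment"): -0.35, # older -> retired/incapacitated side
    ("age_band", "tenure"): 0.25,
    ("age_band", "household"): 0.10,
    ("health", "education"): 0.30,
    ("health", "employment"): 0.40,    # poor health <-> incapacity; work <-> health
    ("health", "tenure"): 0.25,
    ("health", "cars"): 0.25,
    ("education", "employment"): 0.10,
    ("education", "tenure"): 0.25,
    ("education", "cars"): 0.25,
    ("employment", "tenure"): 0.10,
    ("employment", "cars"): 0.15,
    ("tenure", "cars"): 0.40,
    ("tenure", "ethnicity"): 0.10,
    ("tenure", "household"): -0.30,
    ("cars", "household"): -0.45,
    ("sex", "employment"): -0.08,
    ("sex", "cars"): -0.05,
}


def default_latent_correlation() -> np.ndarray:
    names = [v[0] for v in _VARIABLES]
    k = len(names)
    corr = np.eye(k)
    for (a, b), rho in _LATENT_PAIRS.items():
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = rho
    return corr


def default_codebook() -> Codebook:
    return Codebook(
        variables=[
            Variable(name=name, levels=levels, numeric=_NUMERIC_MAPS.get(name))
            for name, levels, _ in _VARIABLES
        ],
        eligibility=Eligibility(
            cohort_variable="age_band",
            cohort_window=("40-49", "50-59", "60-69"),
            region_variable="region",
            region_eligible_level="eligible",
        ),
    )


#: harmonized variables entering the participation model (region drops out
#: after the eligibility filter; age is an eligibility criterion and a model
#: variable, as in a birth-cohort window)
MODEL_VARIABLES = [
    "age_band", "sex", "health", "education", "employment",
    "tenure", "cars", "ethnicity", "household",
]


def default_population_spec(n_population: int = 500_000, seed: int = 0) -> PopulationSpec:
    return PopulationSpec(
        n_population=n_population,
        variables=list(_VARIABLES),
        latent_correlation=default_latent_correlation(),
        seed=seed,
    )


def default_selection_spec(seed: int = 0) -> SelectionSpec:
    """Healthy-volunteer selection at a 5.5% participation rate.

    The index loads on older age, education, home ownership and white
    ethnicity, with two-way interactions doing much of the work — as in
    observed volunteer cohorts, where participation depends on combinations
    of characteristics rather than margins alone. The age×health
    interactions make poor health a much stronger deterrent at older ages,
    which reproduces the qualitative reversal where older cohort members
    appear healthier than younger ones; the remaining interactions distort
    specific pairwise associations (employment×age, employment×education,
    car ownership×tenure/household/health) while leaving the one-way cohort
    margins near their calibrated values.
    """
    return SelectionSpec(
        coefficients={
            "main:age_band=50-59": 0.30,
            "main:age_band=60-69": 0.85,
            "main:health=poor": 0.22,
            "main:health=fair": 0.02,
            "main:health=excellent": 0.04,
            "main:education=secondary": 0.05,
            "main:education=vocational": 0.10,
            "main:education=degree": 0.28,
            "main:employment=unemployed": -0.24,
            "main:employment=incapacitated": -0.30,
            "main:employment=retired": 0.06,
            "main:employment=paid_work": 0.15,
            "main:tenure=owner": 0.45,
            "main:cars=none": 0.22,
            "main:cars=one": 0.02,
            "main:cars=two_plus": 0.07,
            "main:ethnicity=white": 0.40,
            "main:sex=female": 0.08,
            "main:household=single": 0.20,
            "int:age_band=50-59×health=poor": -0.30,
            "int:age_band=50-59×health=fair": -0.07,
            "int:age_band=60-69×health=poor": -0.75,
            "int:age_band=60-69×health=fair": -0.26,
            "int:age_band=60-69×employment=paid_work": -0.30,
            "int:health=poor×cars=none": -0.30,
            "int:education=degree×employment=paid_work": -0.25,
            "int:tenure=owner×cars=none": -0.40,
            "int:cars=none×household=single": -0.35,
        },
        target_rate=TARGET_PARTICIPATION_RATE,
        seed=seed,
    )


DEFAULT_MISSINGNESS = {
    "health": 0.005,
    "education": 0.022,
    "employment": 0.009,
    "cars": 0.007,
}

#: default association batch: linear probability models between binary
#: indicators plus standardized linear models between numeric summaries
DEFAULT_ASSOCIATIONS: list[dict] = [
    {"outcome": "health=poor", "exposure": "age_band=60-69", "kind": "lpm"},
    {"outcome": "health=poor", "exposure": "employment=paid_work", "kind": "lpm"},
    {"outcome": "health=poor", "exposure": "education=degree", "kind": "lpm"},
    {"outcome": "health=poor", "exposure": "tenure=owner", "kind": "lpm"},
    {"outcome": "health=poor", "exposure": "cars=none", "kind": "lpm"},
    {"outcome": "health=poor", "exposure": "employment=incapacitated", "kind": "lpm"},
    {"outcome": "health=fair", "exposure": "age_band=60-69", "kind": "lpm"},
    {"outcome": "employment=paid_work", "exposure": "age_band=60-69", "kind": "lpm"},
    {"outcome": "employment=retired", "exposure": "age_band=60-69", "kind": "lpm"},
    {"outcome": "education=degree", "exposure": "age_band=60-69", "kind": "lpm"},
    {"outcome": "employment=paid_work", "exposure": "education=degree", "kind": "lpm"},
    {"outcome": "cars=none", "exposure": "tenure=owner", "kind": "lpm"},
    {"outcome": "household=single", "exposure": "cars=none", "kind": "lpm"},
    {"outcome": "health", "exposure": "age_band", "kind": "standardized"},
    {"outcome": "education", "exposure": "age_band", "kind": "standardized"},
    {"outcome": "cars", "exposure": "education", "kind": "standardized"},
    {"outcome": "health", "exposure": "education", "kind": "standardized"},
    {"outcome": "health", "exposure": "cars", "kind": "standardized"},
]

#: numeric variables whose cohort SD narrows under concentrated selection
#: (education is excluded: its selection loads on the top category, which
#: widens rather than narrows the volunteer distribution)
SD_NARROWED_VARIABLES = ["age_band", "health", "cars"]
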