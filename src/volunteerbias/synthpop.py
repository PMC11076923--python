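"""Synthetic target population, reference sample and volunteer cohort.

The generator provides ground truth for every downstream stage: an eligible
population of categorical socio-demographic/health variables with a
Gaussian-copula dependence structure, a small representative reference sample
(analogous to census microdata), and a volunteer cohort selected with a known
probit participation mechanism whose per-person probability is retained in a
``true_prob`` column for oracle weighting.

All randomness flows from a single master seed split into named streams
(population, reference, selection, missingness) via ``numpy``'s
``SeedSequence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_STREAMS = {"population": 0, "reference": 1, "selection": 2, "missingness": 3}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child RNG of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class PopulationSpec:
    """Eligible-population generator settings.

    ``variables`` lists ``(name, levels, marginal probabilities)``; the level
    order fixes the direction of the latent Gaussian score, so positive
    latent correlation means "later levels co-occur". ``latent_correlation``
    is the copula correlation matrix in variable order.
    """

    n_population: int
    variables: list[tuple[str, tuple[str, ...], tuple[float, ...]]]
    latent_correlation: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_correlation = np.asarray(self.latent_correlation, dtype=float)
        k = len(self.variables)
        if self.latent_correlation.shape != (k, k):
            raise ValueError(
                f"latent_correlation must be {k}x{k}, got "
                f"{self.latent_correlation.shape}"
            )
        if not np.allclose(self.latent_correlation, self.latent_correlation.T):
            raise ValueError("latent_correlation is not symmetric")
        if not np.allclose(np.diag(self.latent_correlation), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        for name, levels, probs in self.variables:
            if len(levels) != len(probs):
                raise ValueError(f"{name}: levels/probabilities length mismatch")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name}: marginal probabilities sum to {sum(probs)}")
            if any(p < 0 for p in probs):
                raise ValueError(f"{name}: negative marginal probability")

    @property
    def names(self) -> list[str]:
        return [v[0] for v in self.variables]


@dataclass
class SelectionSpec:
    """Probit (optionally logit) participation mechanism.

    ``coefficients`` map design-column names (``main:VAR=LEVEL`` or
    ``int:VAR1=L1×VAR2=L2``) to slopes on the latent participation index.
    If ``target_rate`` is set, the intercept is re-solved so the realized
    mean participation probability hits the target within ±0.001.
    """

    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    target_rate: float | None = None
    seed: int = 0
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.link not in ("probit", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.target_rate is not None and not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")

    def link_cdf(self, eta: np.ndarray) -> np.ndarray:
        if self.link == "probit":
            return stats.norm.cdf(eta)
        return 1.0 / (1.0 + np.exp(-eta))


def _check_psd(corr: np.ndarray) -> None:
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        raise ValueError(
            "latent correlation matrix is not positive semi-definite: "
            f"smallest eigenvalue {eigvals[0]:.3e}"
        )


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Generate the eligible population by Gaussian-copula discretization.

    Correlated standard-normal scores are thresholded at the marginal
    quantile cut-points, so each variable's marginal matches its
    specification exactly in distribution while pairwise dependence is
    governed by the latent correlation.
    """
    _check_psd(spec.latent_correlation)
    rng = stream_rng(spec.seed, "population")
    k = len(spec.variables)
    # eigh factorization tolerates PSD-singular matrices (cholesky does not)
    w, v = np.linalg.eigh(spec.latent_correlation)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((spec.n_population, k)) @ factor.T

    data: dict[str, object] = {
        "person_id": np.arange(spec.n_population, dtype=np.int64)
    }
    for j, (name, levels, probs) in enumerate(spec.variables):
        cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        codes = np.searchsorted(cuts, z[:, j])
        data[name] = pd.Categorical.from_codes(codes, categories=list(levels))
    df = pd.DataFrame(data)
    df["source"] = "population"
    return df


def design_column_values(table: pd.DataFrame, column: str) -> np.ndarray:
    """Evaluate one design-matrix column name on a person table.

    Supports ``main:VAR=LEVEL`` and ``int:VAR1=L1×VAR2=L2``.
    """
    if column.startswith("main:"):
        terms = [column[5:]]
    elif column.startswith("int:"):
        terms = column[4:].split("×")
    else:
        raise KeyError(f"unrecognized design column {column!r}")
    out = np.ones(len(table))
    for term in terms:
        var, _, level = term.partition("=")
        if var not in table.columns:
            raise KeyError(f"design column {column!r} references unknown variable {var!r}")
        out *= (table[var].astype("object") == level).to_numpy(dtype=float)
    return out


def selection_index(table: pd.DataFrame, sel: SelectionSpec) -> np.ndarray:
    """Linear participation index x'beta (without the intercept)."""
    eta = np.zeros(len(table))
    for col, beta in sel.coefficients.items():
        eta += beta * design_column_values(table, col)
    return eta


def solve_intercept(eta: np.ndarray, sel: SelectionSpec) -> float:
    """Intercept making the mean participation probability hit target_rate."""
    assert sel.target_rate is not None
    target = sel.target_rate

    def gap(c: float) -> float:
        return float(sel.link_cdf(c + eta).mean() - target)

    lo, hi = -20.0, 20.0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def draw_volunteers(
    pop: pd.DataFrame, sel: SelectionSpec
) -> pd.DataFrame:
    """Draw the volunteer cohort under the probit participation mechanism.

    Each person participates independently with probability
    ``link(intercept + x'beta)``; participants are returned with their true
    participation probability in ``true_prob`` (source set to ``cohort``).
    """
    eta = selection_index(pop, sel)
    intercept = sel.intercept
    if sel.target_rate is not None:
        intercept = solve_intercept(eta, sel)
    prob = sel.link_cdf(intercept + eta)
    if np.any(prob <= np.finfo(float).tiny) or np.any(prob >= 1.0 - 1e-15):
        warnings.warn(
            "some participation probabilities are 0 or 1 to machine precision; "
            "weights for those strata are undefined/unstable",
            stacklevel=2,
        )
    rng = stream_rng(sel.seed, "selection")
    take = rng.random(len(pop)) < prob
    cohort = pop.loc[take].copy()
    cohort["true_prob"] = prob[take]
    cohort["source"] = "cohort"
    return cohort


def draw_reference_sample(
    pop: pd.DataFrame,
    sampling_fraction: float = 0.05,
    response_rate: float = 0.95,
    seed: int = 0,
    response_coefficients: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw the census-like reference sample.

    A simple random ``sampling_fraction`` of the population is invited and
    responds with probability ``response_rate``; by default response is
    independent of every variable. ``response_coefficients`` (design-column
    name -> slope) introduce response dependence for sensitivity runs, with
    the intercept re-solved to keep the mean response rate.
    """
    if not 0 < sampling_fraction <= 1:
        raise ValueError("sampling_fraction must lie in (0, 1]")
    if not 0 < response_rate <= 1:
        raise ValueError("response_rate must lie in (0, 1]")
    expected = len(pop) * sampling_fraction * response_rate
    if expected < 50:
        raise ValueError(
            f"expected reference size {expected:.1f} < 50; too small to "
            "estimate participation weights"
        )
    rng = stream_rng(seed, "reference")
    invited = rng.random(len(pop)) < sampling_fraction
    if response_coefficients:
        sel = SelectionSpec(
            coefficients=response_coefficients, target_rate=min(response_rate, 1 - 1e-9)
        )
        eta = selection_index(pop, sel)
        prob = sel.link_cdf(solve_intercept(eta, sel) + eta)
        respond = rng.random(len(pop)) < prob
    elif response_rate < 1:
        respond = rng.random(len(pop)) < response_rate
    else:
        respond = np.ones(len(pop), dtype=bool)
    ref = pop.loc[invited & respond].copy()
    ref["source"] = "reference"
    if "true_prob" in ref.columns:
        ref = ref.drop(columns="true_prob")
    return ref


def inject_missingness(
    table: pd.DataFrame, rates: dict[str, float], seed: int = 0
) -> pd.DataFrame:
    """Set values missing completely at random at per-variable rates."""
    for var, rate in rates.items():
        if not 0 <= rate < 1:
            raise ValueError(f"missingness rate for {var!r} must lie in [0, 1)")
        if var not in table.columns:
            raise KeyError(f"no variable {var!r} in table")
    out = table.copy()
    rng = stream_rng(seed, "missingness")
    for var, rate in rates.items():
        if rate == 0:
            continue
        mask = rng.random(len(out)) < rate
        col = out[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            codes = col.cat.codes.to_numpy().copy()
            codes[mask] = -1
            out[var] = pd.Categorical.from_codes(
                codes, categories=col.cat.categories
            )
        else:
            out.loc[mask, var] = np.nan
    return out
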