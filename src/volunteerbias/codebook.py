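"""Variable codebook, recoding, numeric mappings and eligibility filtering.

Person-level data live in ordinary :class:`pandas.DataFrame` objects with one
row per person, a ``person_id`` column, a ``source`` column (``population``,
``cohort`` or ``reference``), optionally a ``true_prob`` column (synthetic
provenance only) and one column per harmonized categorical variable.
Missing values are ``NaN``/``pd.NA`` in memory and the empty field in CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: reserved columns that are never harmonized variables
RESERVED_COLUMNS = ("person_id", "source", "true_prob")


@dataclass(frozen=True)
class Variable:
    """One harmonized categorical variable.

    Parameters
    ----------
    name
        Column name in person tables.
    levels
        Ordered category levels. Order matters: it fixes design-matrix
        column order and, for synthetic generation, the direction of the
        latent score.
    recode
        Optional raw-value -> level map applied by :func:`recode_table`.
        Raw values already equal to a level always pass through.
    numeric
        Optional level -> numeric map (e.g. qualification -> years of
        education) used by :func:`derive_numeric`. When present it must be
        defined for every level.
    """

    name: str
    levels: tuple[str, ...]
    recode: Mapping[str, str] | None = None
    numeric: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"variable {self.name!r} has no levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")
        if self.recode is not None:
            bad = {lv for lv in self.recode.values() if lv not in self.levels}
            if bad:
                raise ValueError(
                    f"recode map of {self.name!r} targets unknown levels {sorted(bad)}"
                )
        if self.numeric is not None:
            missing = [lv for lv in self.levels if lv not in self.numeric]
            if missing:
                raise ValueError(
                    f"numeric map of {self.name!r} lacks levels {missing}"
                )


@dataclass(frozen=True)
class Eligibility:
    """Eligibility window: a birth-cohort (age-band) window plus a region flag.

    Geographic eligibility is a pre-computed flag: ``region_variable`` must
    equal ``region_eligible_level``. The ``cohort_variable`` must take a
    level inside ``cohort_window``.
    """

    cohort_variable: str
    cohort_window: tuple[str, ...]
    region_variable: str
    region_eligible_level: str


@dataclass
class Codebook:
    """Ordered collection of :class:`Variable` plus an eligibility rule."""

    variables: list[Variable]
    eligibility: Eligibility | None = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in codebook")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)


@dataclass
class RecodeLog:
    """Counts of raw values that could not be mapped, per variable."""

    unmapped: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.unmapped.values())


def recode_table(
    raw: pd.DataFrame, codebook: Codebook
) -> tuple[pd.DataFrame, RecodeLog]:
    """Recode raw values into codebook levels.

    Values equal to a declared level pass through unchanged; values with an
    entry in the variable's recode map are mapped; anything else (other than
    missing) becomes missing and is counted in the returned log.
    """
    absent = [v.name for v in codebook.variables if v.name not in raw.columns]
    if absent:
        raise KeyError(f"table lacks codebook variable(s): {absent}")
    out = raw.copy()
    log = RecodeLog()
    for var in codebook.variables:
        col = out[var.name]
        values = col.astype("object")
        mask_missing = values.isna()
        allowed = set(var.levels)
        mapped = values.copy()
        if var.recode:
            to_map = ~mask_missing & ~values.isin(list(allowed))
            mapped[to_map] = values[to_map].map(var.recode)
        unknown = ~mask_missing & ~mapped.isin(list(allowed)) & ~mapped.isna()
        n_unmapped = int(unknown.sum() + (mapped.isna() & ~mask_missing).sum())
        if n_unmapped:
            log.unmapped[var.name] = n_unmapped
        mapped[unknown] = np.nan
        out[var.name] = pd.Categorical(mapped, categories=var.levels)
    return out, log


def derive_numeric(
    table: pd.DataFrame, codebook: Codebook, variable: str
) -> pd.Series:
    """Map a categorical variable to its numeric values (missing stays NaN)."""
    var = codebook[variable]
    if var.numeric is None:
        raise ValueError(f"variable {variable!r} has no numeric map")
    col = table[variable].astype("object")
    return col.map(var.numeric).astype(float)


@dataclass
class EligibilityLog:
    """Exclusion counts by reason. Rows failing the age window are counted
    under ``age`` regardless of their region flag."""

    age: int = 0
    region: int = 0


def filter_eligible(
    table: pd.DataFrame, codebook: Codebook
) -> tuple[pd.DataFrame, EligibilityLog]:
    """Keep rows inside the birth-cohort window with an eligible region flag."""
    elig = codebook.eligibility
    if elig is None:
        raise ValueError("codebook declares no eligibility rule")
    for needed in (elig.cohort_variable, elig.region_variable):
        if needed not in table.columns:
            raise KeyError(f"table lacks eligibility variable {needed!r}")
    in_window = table[elig.cohort_variable].isin(list(elig.cohort_window))
    in_region = table[elig.region_variable].astype("object").eq(
        elig.region_eligible_level
    )
    log = EligibilityLog(
        age=int((~in_window).sum()),
        region=int((in_window & ~in_region).sum()),
    )
    kept = table[in_window & in_region].copy()
    if kept.empty:
        import warnings

        warnings.warn("eligibility filter removed every row", stacklevel=2)
    return kept, log


def validate_person_table(
    table: pd.DataFrame, codebook: Codebook, *, require_complete: bool = False
) -> None:
    """Check codebook conformance; raise ``ValueError`` on violation."""
    if "person_id" not in table.columns:
        raise ValueError("person table lacks a person_id column")
    if table["person_id"].duplicated().any():
        raise ValueError("person_id values are not unique")
    for var in codebook.variables:
        if var.name not in table.columns:
            raise ValueError(f"person table lacks variable {var.name!r}")
        col = table[var.name]
        nonmissing = col.dropna()
        bad = set(nonmissing.astype(str).unique()) - set(var.levels)
        if bad:
            raise ValueError(
                f"variable {var.name!r} contains undeclared levels {sorted(bad)}"
            )
        if require_complete and col.isna().any():
            raise ValueError(f"variable {var.name!r} has missing values")


def write_person_table(table: pd.DataFrame, path) -> None:
    """Write a person table as CSV with empty-field missing markers."""
    table.to_csv(path, index=False, na_rep="")


def read_person_table(path, codebook: Codebook | None = None) -> pd.DataFrame:
    """Read a person table written by :func:`write_person_table`.

    Empty fields become missing. With a codebook, variables are recoded and
    validated; a missing codebook variable raises ``KeyError`` naming it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    if "true_prob" in df.columns:
        df["true_prob"] = df["true_prob"].astype(float)
    if codebook is not None:
        df, _ = recode_table(df, codebook)
        validate_person_table(df, codebook)
    return df


def indicator(table: pd.DataFrame, variable: str, level: str) -> pd.Series:
    """0/1 dummy for ``variable == level`` with NaN where the value is missing."""
    col = table[variable].astype("object")
    out = (col == level).astype(float)
    out[col.isna()] = np.nan
    return out


def resolve_analysis_column(
    table: pd.DataFrame, codebook: Codebook, spec: str
) -> pd.Series:
    """Resolve an association-variable spec to a numeric column.

    ``"VAR=LEVEL"`` yields the 0/1 indicator of that level; a bare ``"VAR"``
    yields the variable's numeric mapping.
    """
    if "=" in spec:
        name, level = spec.split("=", 1)
        var = codebook[name]
        if level not in var.levels:
            raise KeyError(f"{level!r} is not a level of {name!r}")
        return indicator(table, name, level)
    return derive_numeric(table, codebook, spec)


def spec_variable(spec: str) -> str:
    """Variable name underlying an association-variable spec."""
    return spec.split("=", 1)[0]
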