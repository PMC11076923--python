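"""Inverse-probability weight construction.

With the participation model fitted on concatenated cohort (1) / reference
(0) data, the inverse odds ``(1 - pi) / pi`` of membership is proportional to
the target-population density over the cohort density, so weighting the
cohort by it mimics the target population. Any constant sampling-fraction
factor is absorbed by normalization. A plain ``1 / pi`` variant is available
behind the ``formula`` flag. Oracle weights (inverse true selection
probability, synthetic data only) provide ground truth for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMALIZATIONS = ("mean-one", "sum-n")
FORMULAS = ("inverse-odds", "inverse-probability")


@dataclass
class WeightSet:
    """Per-person positive weights with a normalization convention."""

    person_id: np.ndarray
    weight: np.ndarray
    normalization: str
    excluded: dict[object, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    boundary_unstable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.person_id = np.asarray(self.person_id)
        self.weight = np.asarray(self.weight, dtype=float)
        if len(self.person_id) != len(self.weight):
            raise ValueError("person_id / weight length mismatch")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be strictly positive")
        excluded_ids = set(self.excluded)
        if excluded_ids & set(self.person_id.tolist()):
            raise ValueError("excluded ids overlap weighted ids")

    def __len__(self) -> int:
        return len(self.weight)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weight, index=pd.Index(self.person_id, name="person_id"))

    def align_to(self, person_ids: np.ndarray) -> np.ndarray:
        """Weights in the order of ``person_ids`` (raises on unknown id)."""
        s = self.as_series()
        out = s.reindex(person_ids)
        if out.isna().any():
            raise KeyError("some requested person_ids have no weight")
        return out.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"person_id": self.person_id, "weight": self.weight})


def normalize_weights(raw: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "mean-one":
        return raw / raw.mean()
    if normalization == "sum-n":
        return raw * (len(raw) / raw.sum())
    raise ValueError(f"unknown normalization {normalization!r}")


def compute_ip_weights(
    person_id: np.ndarray,
    probabilities: np.ndarray,
    normalization: str = "mean-one",
    formula: str = "inverse-odds",
    boundary_eps: float = 1e-8,
    provenance: dict | None = None,
) -> WeightSet:
    """Build IP weights from predicted participation probabilities.

    Only cohort members receive weights; pass their ids and probabilities.
    Probabilities at the clip boundary are flagged as boundary-unstable.
    """
    pi = np.asarray(probabilities, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if formula == "inverse-odds":
        raw = (1.0 - pi) / pi
    elif formula == "inverse-probability":
        raw = 1.0 / pi
    else:
        raise ValueError(f"unknown formula {formula!r}")
    boundary = (pi <= boundary_eps) | (pi >= 1 - boundary_eps)
    prov = dict(provenance or {})
    prov.setdefault("formula", formula)
    return WeightSet(
        person_id=np.asarray(person_id),
        weight=normalize_weights(raw, normalization),
        normalization=normalization,
        provenance=prov,
        boundary_unstable=boundary,
    )


def oracle_weights(cohort: pd.DataFrame, normalization: str = "mean-one") -> WeightSet:
    """Ground-truth weights 1 / true_prob for a synthetic cohort."""
    if "true_prob" not in cohort.columns or cohort["true_prob"].isna().any():
        raise ValueError("oracle weights require a complete true_prob column")
    raw = 1.0 / cohort["true_prob"].to_numpy(dtype=float)
    return WeightSet(
        person_id=cohort["person_id"].to_numpy(),
        weight=normalize_weights(raw, normalization),
        normalization=normalization,
        provenance={"formula": "oracle 1/true_prob"},
    )
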