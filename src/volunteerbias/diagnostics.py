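"""Effective-sample-size and robustness diagnostics for IP weights.

Two effective-sample-size (ESS) notions are reported. The Kish ESS,
``(sum w)^2 / sum w^2``, depends only on the weight distribution and is
invariant to rescaling. The regression-specific ESS is the size of an
equal-weight simple random sample with the same precision as the weighted
regression: ``n * (se_unweighted / se_weighted)^2``.

Leave-one-out robustness re-estimates the participation model after removing
both variables of each configured association from the design (all their
dummies and interactions), recomputes weights and asks how much bias
reduction survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from volunteerbias.codebook import spec_variable
from volunteerbias.design import DesignMatrix
from volunteerbias.inference import run_association_batch
from volunteerbias.probit import cross_validate_lambda, predict_probability
from volunteerbias.weights import WeightSet, compute_ip_weights


def kish_ess(w: np.ndarray | WeightSet) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    if isinstance(w, WeightSet):
        w = w.weight
    w = np.asarray(w, dtype=float)
    if len(w) == 0:
        raise ValueError("empty weights")
    return float(w.sum() ** 2 / np.sum(w * w))


def regression_ess(se_unweighted: float, se_weighted: float, n: int) -> float:
    """SRS-equivalent sample size n * (se_unweighted / se_weighted)^2."""
    if se_unweighted <= 0 or se_weighted <= 0:
        raise ValueError("standard errors must be positive")
    return float(n * (se_unweighted / se_weighted) ** 2)


def weight_summary(w: np.ndarray | WeightSet) -> dict:
    """Deterministic summary of the weight distribution."""
    boundary = 0
    if isinstance(w, WeightSet):
        if w.boundary_unstable is not None:
            boundary = int(w.boundary_unstable.sum())
        w = w.weight
    w = np.asarray(w, dtype=float)
    if len(w) == 0:
        raise ValueError("empty weights")
    qs = np.quantile(w, [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    return {
        "n": int(len(w)),
        "min": float(w.min()),
        "q01": float(qs[0]),
        "q05": float(qs[1]),
        "q25": float(qs[2]),
        "median": float(qs[3]),
        "q75": float(qs[4]),
        "q95": float(qs[5]),
        "q99": float(qs[6]),
        "max": float(w.max()),
        "max_min_ratio": float(w.max() / w.min()),
        "boundary_unstable": boundary,
    }


@dataclass
class ESSReport:
    """Kish and regression-specific effective sample sizes."""

    n_cohort: int
    kish: float
    kish_fraction: float
    per_association: list[dict] = field(default_factory=list)
    mean_regression_ess: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_cohort": self.n_cohort,
            "kish_ess": self.kish,
            "kish_fraction": self.kish_fraction,
            "mean_regression_ess": self.mean_regression_ess,
            "per_association": self.per_association,
        }


def build_ess_report(weights: WeightSet, associations: pd.DataFrame) -> ESSReport:
    """ESS report from a weight set and an association-batch table."""
    n = len(weights)
    kish = kish_ess(weights)
    per = []
    for _, row in associations.iterrows():
        ess = regression_ess(row["se_unweighted"], row["se_weighted"], row["n_cohort"])
        per.append(
            {
                "outcome": row["outcome"],
                "exposure": row["exposure"],
                "regression_ess": ess,
                "fraction": ess / row["n_cohort"],
            }
        )
    mean_ess = float(np.mean([p["regression_ess"] for p in per])) if per else float("nan")
    return ESSReport(
        n_cohort=n,
        kish=kish,
        kish_fraction=kish / n,
        per_association=per,
        mean_regression_ess=mean_ess,
    )


@dataclass
class RobustnessReport:
    """Leave-one-out robustness of the weights."""

    per_association: list[dict]
    mean_bias_reduction_full: float
    mean_bias_reduction_reduced: float

    def to_dict(self) -> dict:
        return {
            "mean_bias_reduction_full": self.mean_bias_reduction_full,
            "mean_bias_reduction_reduced": self.mean_bias_reduction_reduced,
            "per_association": self.per_association,
        }


def leave_one_out_robustness(
    design: DesignMatrix,
    labels: np.ndarray,
    cohort: pd.DataFrame,
    reference: pd.DataFrame,
    pairs: list[dict],
    codebook,
    full_batch: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
    normalization: str = "mean-one",
    formula: str = "inverse-odds",
    bias_tol: float = 1e-3,
    max_iter: int = 2000,
) -> RobustnessReport:
    """Refit weights without each association's variables; recompute bias reduction.

    For every configured pair, all main and interaction columns touching
    either variable are removed, the participation model is re-estimated
    with the same cross-validation procedure and seed (the full lambda path
    is re-searched), and the pair's bias reduction is recomputed under the
    reduced-model weights.
    """
    labels = np.asarray(labels, dtype=float)
    cohort_mask = labels > 0.5
    per = []
    design_vars = {
        t.partition("=")[0]
        for c in design.columns
        for t in c.split(":", 1)[1].split("×")
    }
    for pair in pairs:
        dropped = {spec_variable(pair["outcome"]), spec_variable(pair["exposure"])}
        unknown = dropped - design_vars
        if unknown:
            raise KeyError(f"association variables not in design: {sorted(unknown)}")
        reduced = design.drop_variables(dropped)
        cv = cross_validate_lambda(
            reduced.X, labels, grid=grid, folds=folds, seed=seed,
            columns=reduced.columns, max_iter=max_iter,
        )
        pi, _ = predict_probability(cv.fit, reduced.X[cohort_mask])
        wts = compute_ip_weights(
            design.row_ids[cohort_mask], pi,
            normalization=normalization, formula=formula,
        )
        batch = run_association_batch(
            cohort, reference, [pair], wts, codebook, bias_tol=bias_tol
        )
        per.append(
            {
                "outcome": pair["outcome"],
                "exposure": pair["exposure"],
                "dropped": sorted(dropped),
                "chosen_lambda": cv.chosen_lambda,
                "bias_reduction_reduced": float(batch["bias_reduction"].iloc[0]),
            }
        )
    full_defined = full_batch[full_batch["bias_defined"]]
    reduced_vals = [
        p["bias_reduction_reduced"]
        for p in per
        if np.isfinite(p["bias_reduction_reduced"])
    ]
    return RobustnessReport(
        per_association=per,
        mean_bias_reduction_full=float(full_defined["bias_reduction"].mean()),
        mean_bias_reduction_reduced=float(np.mean(reduced_vals)) if reduced_vals else float("nan"),
    )
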