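"""Weighted and unweighted association estimation.

Bivariate linear (probability) models are fitted by weighted least squares
with heteroskedasticity-robust (HC1 sandwich) standard errors; weights are
treated as sampling weights. Standardized linear models standardize outcome
and exposure to mean 0 / variance 1 (using weighted moments when weighted),
so slopes are correlation-scale. Cross-sample coefficient differences are
tested with the two-sample Z statistic

    z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2)

treating the samples as independent, and bias reduction of a weighted
estimate relative to a reference-sample estimate is

    1 - |beta_w - beta_ref| / |beta_unw - beta_ref|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from volunteerbias.codebook import Codebook, resolve_analysis_column


def weighted_mean(x: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted mean sum(w x) / sum(w)."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    if w is None:
        return float(x.mean())
    w = np.asarray(w, dtype=float)
    if len(w) != len(x):
        raise ValueError("length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * x) / np.sum(w))


def weighted_sd(x: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted sample SD with weights normalized to sum to n.

    sqrt( sum w_i (x_i - xbar_w)^2 / (sum w_i - 1) ); reduces to the ordinary
    sample SD under uniform weights. Zero variance returns 0.
    """
    x = np.asarray(x, dtype=float)
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    w = w * (len(w) / w.sum())
    if w.sum() <= 1:
        raise ValueError("sum of normalized weights must exceed 1")
    xbar = weighted_mean(x, w)
    return float(np.sqrt(np.sum(w * (x - xbar) ** 2) / (w.sum() - 1.0)))


@dataclass
class AssociationEstimate:
    """A bivariate slope with a robust standard error."""

    outcome: str
    exposure: str
    beta: float
    robust_se: float
    n_used: int
    weighted: bool
    sample: str = ""

    def __post_init__(self) -> None:
        if self.robust_se <= 0:
            raise ValueError("robust_se must be positive")

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.robust_se
        return (self.beta - half, self.beta + half)


@dataclass
class AssociationComparison:
    """Z test of equality of two slopes from (approximately) independent samples."""

    a: AssociationEstimate
    b: AssociationEstimate
    z: float
    p_two_sided: float


def _drop_incomplete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return tuple(a[mask] for a in arrays)


def fit_bivariate_lpm(
    y: np.ndarray,
    x: np.ndarray,
    w: np.ndarray | None = None,
    outcome: str = "y",
    exposure: str = "x",
    sample: str = "",
    cov_type: str = "HC1",
) -> AssociationEstimate:
    """Bivariate (weighted) least squares slope with a sandwich SE.

    With a binary outcome this is a linear probability model and the slope a
    risk difference. The sandwich is HC1 by default (HC0 via ``cov_type``):
    bread (X'WX)^-1, meat sum w_i^2 e_i^2 x_i x_i', scaled n/(n-2) for HC1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if w is None:
        y, x = _drop_incomplete(y, x)
        wts = np.ones(len(y))
    else:
        y, x, wts = _drop_incomplete(y, x, np.asarray(w, dtype=float))
    if len(y) < 3:
        raise ValueError("too few complete observations")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant among used rows")
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=wts).fit(cov_type=cov_type)
    return AssociationEstimate(
        outcome=outcome,
        exposure=exposure,
        beta=float(res.params[1]),
        robust_se=float(res.bse[1]),
        n_used=len(y),
        weighted=w is not None,
        sample=sample,
    )


def fit_standardized_linear(
    y: np.ndarray,
    x: np.ndarray,
    w: np.ndarray | None = None,
    outcome: str = "y",
    exposure: str = "x",
    sample: str = "",
    cov_type: str = "HC1",
) -> AssociationEstimate:
    """Slope between variables standardized to mean 0 / variance 1.

    Standardization uses weighted moments when weights are supplied, so the
    weighted slope targets the population correlation scale.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if w is None:
        y, x = _drop_incomplete(y, x)
        wts = None
    else:
        y, x, wts = _drop_incomplete(y, x, np.asarray(w, dtype=float))
    sds = [weighted_sd(v, wts) for v in (y, x)]
    if min(sds) == 0:
        raise ValueError("zero variance; cannot standardize")
    ys = (y - weighted_mean(y, wts)) / sds[0]
    xs = (x - weighted_mean(x, wts)) / sds[1]
    return fit_bivariate_lpm(
        ys, xs, wts, outcome=outcome, exposure=exposure, sample=sample,
        cov_type=cov_type,
    )


def compare_associations(
    a: AssociationEstimate, b: AssociationEstimate
) -> AssociationComparison:
    """Two-sample Z test that two slopes are equal."""
    if (a.outcome, a.exposure) != (b.outcome, b.exposure):
        raise ValueError(
            "estimates are for different outcome/exposure pairs: "
            f"{(a.outcome, a.exposure)} vs {(b.outcome, b.exposure)}"
        )
    z = (a.beta - b.beta) / np.sqrt(a.robust_se**2 + b.robust_se**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationComparison(a=a, b=b, z=float(z), p_two_sided=float(p))


def bias_reduction(
    ref: float, unweighted: float, weighted: float, tol: float = 1e-10
) -> float:
    """Fraction of the unweighted bias removed by weighting.

    1 - |weighted - ref| / |unweighted - ref|. Negative values mean the
    weighting moved the estimate further from the reference; values cannot
    exceed 1. Undefined (raises) when the unweighted bias is below ``tol``.
    """
    denom = abs(unweighted - ref)
    if denom <= tol:
        raise ValueError("unweighted bias below tolerance; bias reduction undefined")
    return 1.0 - abs(weighted - ref) / denom


def run_association_batch(
    cohort: pd.DataFrame,
    reference: pd.DataFrame,
    pairs: list[dict],
    weights,
    codebook: Codebook,
    bias_tol: float = 1e-3,
    min_bias_z: float = 4.0,
) -> pd.DataFrame:
    """Estimate each configured association in reference, cohort and weighted cohort.

    Each pair is ``{"outcome": spec, "exposure": spec, "kind": "lpm"|
    "standardized"}`` where a spec is ``VAR=LEVEL`` (indicator) or ``VAR``
    (numeric mapping). Returns one row per association with the three
    estimates, the reference-vs-unweighted Z test and the bias reduction.

    Bias reduction is only meaningful when the unweighted estimate is
    genuinely biased; a pair where reference and unweighted estimates are
    statistically indistinguishable would contribute pure reference noise.
    ``bias_defined`` therefore requires both ``|unweighted - reference| >
    bias_tol`` and ``|z| > min_bias_z`` for the reference-vs-unweighted
    difference (undefined pairs keep their raw value but are excluded from
    averages).
    """
    w_cohort = weights.align_to(cohort["person_id"].to_numpy())
    rows = []
    for pair in pairs:
        kind = pair.get("kind", "lpm")
        fitter = fit_bivariate_lpm if kind == "lpm" else fit_standardized_linear
        out_spec, exp_spec = pair["outcome"], pair["exposure"]
        y_ref = resolve_analysis_column(reference, codebook, out_spec).to_numpy()
        x_ref = resolve_analysis_column(reference, codebook, exp_spec).to_numpy()
        y_coh = resolve_analysis_column(cohort, codebook, out_spec).to_numpy()
        x_coh = resolve_analysis_column(cohort, codebook, exp_spec).to_numpy()
        est_ref = fitter(y_ref, x_ref, outcome=out_spec, exposure=exp_spec,
                         sample="reference")
        est_unw = fitter(y_coh, x_coh, outcome=out_spec, exposure=exp_spec,
                         sample="cohort")
        est_w = fitter(y_coh, x_coh, w_cohort, outcome=out_spec,
                       exposure=exp_spec, sample="cohort")
        cmp_unw = compare_associations(est_ref, est_unw)
        try:
            br = bias_reduction(est_ref.beta, est_unw.beta, est_w.beta, tol=bias_tol)
            defined = abs(cmp_unw.z) > min_bias_z
        except ValueError:
            br, defined = float("nan"), False
        rows.append(
            {
                "outcome": out_spec,
                "exposure": exp_spec,
                "kind": kind,
                "beta_reference": est_ref.beta,
                "se_reference": est_ref.robust_se,
                "beta_unweighted": est_unw.beta,
                "se_unweighted": est_unw.robust_se,
                "beta_weighted": est_w.beta,
                "se_weighted": est_w.robust_se,
                "n_reference": est_ref.n_used,
                "n_cohort": est_unw.n_used,
                "z_vs_reference": cmp_unw.z,
                "p_vs_reference": cmp_unw.p_two_sided,
                "bias_reduction": br,
                "bias_defined": defined,
            }
        )
    return pd.DataFrame(rows)
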