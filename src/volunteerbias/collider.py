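"""Collider-bias simulation under linear-Gaussian selection scenarios.

Participation S is a collider on the path from exposure X to outcome Y
whenever both influence selection (directly or through a shared cause U).
The structural model is

    U ~ N(0, 1)
    X = u_x * U + e_x,            e_x ~ N(0, sd_x^2)
    Y = b * X + u_y * U + e_y,    e_y ~ N(0, sd_y^2)
    S = 1{ a_x * X + a_y * Y + a_u * U + e_s > c },  e_s ~ N(0, sd_s^2)

with the threshold c solved analytically for a target selection rate (the
selection index is Gaussian). Because (X, Y, S*) is jointly Gaussian, the
selected-sample regression slope of Y on X has an exact oracle via
one-dimensional numerical integration over the truncated selection index,
independent of any Monte-Carlo simulation.

Estimating Y ~ X with a linear control for a collider-path covariate does
not remove the bias; weighting by the true inverse selection probabilities
does. Named presets cover the canonical selection archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats


@dataclass(frozen=True)
class ColliderScenario:
    """Structural coefficients for one selection scenario."""

    b: float = 0.5          # X -> Y
    a_x: float = 0.0        # X -> S*
    a_y: float = 0.0        # Y -> S*
    a_u: float = 0.0        # U -> S*
    u_x: float = 0.0        # U -> X
    u_y: float = 0.0        # U -> Y
    sd_x: float = 1.0
    sd_y: float = 1.0
    sd_s: float = 1.0
    selection_rate: float = 0.3
    n: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.selection_rate < 1:
            raise ValueError("selection_rate must lie in (0, 1)")
        if min(self.sd_x, self.sd_y, self.sd_s) <= 0:
            raise ValueError("noise SDs must be positive")

    # --- closed-form second moments of (X, Y, S*) -----------------------
    def moments(self) -> dict[str, float]:
        var_x = self.u_x**2 + self.sd_x**2
        cov_xu = self.u_x
        cov_xy = self.b * var_x + self.u_y * cov_xu
        var_y = self.b**2 * var_x + self.u_y**2 + self.sd_y**2 + 2 * self.b * self.u_y * cov_xu
        cov_yu = self.b * cov_xu + self.u_y
        cov_xs = self.a_x * var_x + self.a_y * cov_xy + self.a_u * cov_xu
        cov_ys = self.a_x * cov_xy + self.a_y * var_y + self.a_u * cov_yu
        var_s = (
            self.a_x**2 * var_x
            + self.a_y**2 * var_y
            + self.a_u**2
            + 2 * self.a_x * self.a_y * cov_xy
            + 2 * self.a_x * self.a_u * cov_xu
            + 2 * self.a_y * self.a_u * cov_yu
            + self.sd_s**2
        )
        return {
            "var_x": var_x, "var_y": var_y, "cov_xy": cov_xy,
            "cov_xs": cov_xs, "cov_ys": cov_ys, "var_s": var_s,
        }

    @property
    def threshold(self) -> float:
        """Selection cut c with P(S* > c) = selection_rate (S* has mean 0)."""
        return float(np.sqrt(self.moments()["var_s"]) * stats.norm.isf(self.selection_rate))

    @property
    def population_slope(self) -> float:
        m = self.moments()
        return m["cov_xy"] / m["var_x"]


def simulate_scenario(sc: ColliderScenario) -> pd.DataFrame:
    """Simulate (X, Y, U, S) plus the true per-person selection probability."""
    rng = np.random.default_rng(sc.seed)
    u = rng.standard_normal(sc.n)
    x = sc.u_x * u + sc.sd_x * rng.standard_normal(sc.n)
    y = sc.b * x + sc.u_y * u + sc.sd_y * rng.standard_normal(sc.n)
    index = sc.a_x * x + sc.a_y * y + sc.a_u * u
    c = sc.threshold
    p_sel = stats.norm.sf((c - index) / sc.sd_s)
    s = (index + sc.sd_s * rng.standard_normal(sc.n) > c).astype(int)
    return pd.DataFrame({"X": x, "Y": y, "U": u, "S": s, "p_select": p_sel})


def _ols_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray | None = None) -> float:
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
    return float(model.fit().params[1])


def selected_slope_oracle(sc: ColliderScenario) -> float:
    """Exact selected-sample slope of Y on X given S* > c.

    (X, Y, S*) is jointly Gaussian, so conditional on S* = l the mean of
    (X, Y) is linear in l and the covariance constant; integrating the
    conditional moments over the truncated density of S* gives the selected
    first and second moments, hence the slope, by 1-D quadrature.
    """
    m = sc.moments()
    sig_s = np.sqrt(m["var_s"])
    c = sc.threshold
    p = stats.norm.sf(c / sig_s)
    bx = m["cov_xs"] / m["var_s"]          # E[X | S*=l] = bx * l
    by = m["cov_ys"] / m["var_s"]
    # residual (l-independent) conditional moments
    rxx = m["var_x"] - m["cov_xs"] ** 2 / m["var_s"]
    rxy = m["cov_xy"] - m["cov_xs"] * m["cov_ys"] / m["var_s"]

    def trunc_moment(k: int) -> float:
        f = lambda l: l**k * stats.norm.pdf(l / sig_s) / sig_s
        val, _ = integrate.quad(f, c, c + 12 * sig_s, limit=200)
        return val / p

    m1, m2 = trunc_moment(1), trunc_moment(2)
    ex, ey = bx * m1, by * m1
    exx = rxx + bx**2 * m2
    exy = rxy + bx * by * m2
    var_x_sel = exx - ex**2
    cov_xy_sel = exy - ex * ey
    return float(cov_xy_sel / var_x_sel)


def scenario_bias(
    sc: ColliderScenario, replicates: int = 20, seed: int = 0
) -> dict[str, float]:
    """Monte-Carlo selected-sample slope, bias against the population slope."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    slopes = []
    for r in range(replicates):
        df = simulate_scenario(replace(sc, seed=seed + r))
        sel = df[df["S"] == 1]
        slopes.append(_ols_slope(sel["Y"].to_numpy(), sel["X"].to_numpy()))
    slopes = np.asarray(slopes)
    pop = sc.population_slope
    return {
        "population_slope": pop,
        "mean_selected_slope": float(slopes.mean()),
        "bias": float(slopes.mean() - pop),
        "mc_se": float(slopes.std(ddof=1) / np.sqrt(replicates)),
    }


def adjustment_vs_weighting(
    sc: ColliderScenario, seed: int | None = None
) -> dict[str, float]:
    """Compare naive, covariate-adjusted and true-probability-weighted slopes.

    On the selected sample: (i) naive OLS of Y on X; (ii) OLS of Y on X with
    U as a linear control (the strategy of "adjusting for variables that
    drive participation"); (iii) WLS of Y on X weighted by 1/p_select. When
    selection depends on Y (or on a collider-path variable), (ii) remains
    biased while (iii) is consistent; when U is a plain confounder and
    selection ignores X and Y, (ii) is the valid back-door adjustment.
    """
    if seed is not None:
        sc = replace(sc, seed=seed)
    df = simulate_scenario(sc)
    sel = df[df["S"] == 1]
    y, x, u = (sel[c].to_numpy() for c in ("Y", "X", "U"))
    naive = _ols_slope(y, x)
    adjusted = float(
        sm.OLS(y, sm.add_constant(np.column_stack([x, u]))).fit().params[1]
    )
    weighted = _ols_slope(y, x, w=1.0 / sel["p_select"].to_numpy())
    return {
        "population_slope": sc.population_slope,
        "naive": naive,
        "adjusted": adjusted,
        "weighted": weighted,
        "n_selected": int(len(sel)),
    }


#: canonical selection archetypes (direction of collider bias differs)
SCENARIO_PRESETS: dict[str, ColliderScenario] = {
    "no-selection": ColliderScenario(b=0.5),
    "selection-on-exposure": ColliderScenario(b=0.5, a_x=1.0),
    "selection-on-outcome": ColliderScenario(b=0.5, a_y=1.0),
    "selection-on-both": ColliderScenario(b=0.5, a_x=1.0, a_y=1.0),
    "selection-on-common-cause": ColliderScenario(
        b=0.5, a_u=1.0, u_x=0.8, u_y=0.8
    ),
    "independent-causes": ColliderScenario(b=0.0, a_x=1.0, a_y=1.0),
}
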