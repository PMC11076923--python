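"""L1-penalized probit participation model.

The participation model is a probit regression of sample membership
(cohort = 1, reference = 0) on the dummy + interaction design, fitted by
minimizing the mean negative log-likelihood plus an L1 penalty on the slopes
(the intercept is never penalized):

    (1/N) * sum_i -[ s_i log Phi(eta_i) + (1 - s_i) log(1 - Phi(eta_i)) ]
        + lambda * sum_j |beta_j|

Optimization is FISTA (accelerated proximal gradient) with a fixed step from
the exact curvature bound of the probit log-likelihood (per-observation
curvature in eta is below 1, so the gradient is Lipschitz with constant
sigma_max(X)^2 / N). Convergence is declared on the KKT subgradient
residual. The penalty level is chosen by stratified K-fold cross-validation
minimizing held-out deviance, warm-started along a decreasing lambda path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import log_ndtr, ndtr, ndtri


def _phi_log(eta: np.ndarray) -> np.ndarray:
    return -0.5 * eta * eta - 0.5 * np.log(2.0 * np.pi)


def negloglik(eta: np.ndarray, s: np.ndarray) -> float:
    """Mean probit negative log-likelihood at linear predictor eta."""
    ll = np.where(s > 0.5, log_ndtr(eta), log_ndtr(-eta))
    return float(-ll.mean())


def _dnll_deta(eta: np.ndarray, s: np.ndarray) -> np.ndarray:
    """d/d(eta) of the per-observation negative log-likelihood.

    For s=1 this is -phi/Phi(eta); for s=0 it is phi/Phi(-eta). Evaluated in
    log space for stability far in the tails.
    """
    logpdf = _phi_log(eta)
    pos = np.exp(logpdf - log_ndtr(eta))
    neg = np.exp(logpdf - log_ndtr(-eta))
    return np.where(s > 0.5, -pos, neg)


@dataclass
class ProbitLassoFit:
    """One penalized-probit solution."""

    intercept: float
    coef: np.ndarray
    columns: list[str]
    lambda_: float
    n_iter: int
    kkt_norm: float
    converged: bool
    separation_suspected: bool = False

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))

    def active_set(self) -> list[str]:
        return [c for c, b in zip(self.columns, self.coef) if b != 0.0]

    def coefficients(self) -> dict[str, float]:
        """Sparse column -> coefficient map (nonzero slopes only)."""
        return {c: float(b) for c, b in zip(self.columns, self.coef) if b != 0.0}


@dataclass
class ParticipationFit:
    """Cross-validated penalized-probit fit."""

    lambda_grid: np.ndarray
    chosen_lambda: float
    cv_deviance: np.ndarray
    fit: ProbitLassoFit
    folds: int
    seed: int
    path: list[ProbitLassoFit] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return self.fit.n_selected


def _as_matrix(X) -> sparse.csr_matrix:
    if sparse.issparse(X):
        return X.tocsr()
    return sparse.csr_matrix(np.asarray(X, dtype=float))


def _spectral_norm_sq(X: sparse.csr_matrix, n_iter: int = 50, seed: int = 0) -> float:
    """Squared top singular value of X by power iteration on X'X."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(X.shape[1])
    v /= np.linalg.norm(v)
    ev = 1.0
    for _ in range(n_iter):
        w = X.T @ (X @ v)
        ev = float(np.linalg.norm(w))
        if ev == 0.0:
            return 1.0
        v = w / ev
    return ev


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def lambda_max(X, s: np.ndarray) -> float:
    """Smallest penalty that zeroes every slope (KKT entry condition).

    At beta = 0 with the intercept at its optimum Phi^{-1}(mean(s)), a slope
    enters the active set as soon as lambda drops below |grad_j|; the max of
    these gradients over j is therefore the top of the path.
    """
    X = _as_matrix(X)
    s = np.asarray(s, dtype=float)
    eta = np.full(X.shape[0], ndtri(s.mean()))
    g = X.T @ _dnll_deta(eta, s) / X.shape[0]
    return float(np.abs(g).max())


def lambda_grid(lmax: float, n_points: int = 12, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing penalty path from lmax down to lmax * ratio."""
    return np.geomspace(lmax, lmax * ratio, n_points)


def _kkt_residual(g0: float, g: np.ndarray, beta: np.ndarray, lam: float) -> float:
    r_active = np.abs(g + lam * np.sign(beta))
    r_inactive = np.maximum(np.abs(g) - lam, 0.0)
    resid = np.where(beta != 0.0, r_active, r_inactive)
    return max(abs(g0), float(resid.max(initial=0.0)))


def _fista_subproblem(
    X: sparse.csr_matrix,
    s: np.ndarray,
    lam: float,
    b0: float,
    beta: np.ndarray,
    step: float,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, int, float]:
    """FISTA with backtracking line search and gradient-based adaptive restart.

    Minimizes the penalized mean negative log-likelihood over the given
    columns; ``step`` is the initial step size, grown after easy iterations
    and backtracked against the quadratic upper bound when too large.
    Returns (intercept, coef, iterations, kkt residual).
    """
    n = X.shape[0]
    yb0, ybeta = b0, beta.copy()
    t_acc = 1.0
    kkt = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta_y = yb0 + X @ ybeta
        d = _dnll_deta(eta_y, s)
        f_y = negloglik(eta_y, s)
        g0 = float(d.mean())
        g = X.T @ d / n
        # backtracking on the smooth part's quadratic upper bound
        while True:
            new_b0 = yb0 - step * g0
            new_beta = _soft_threshold(ybeta - step * g, step * lam)
            eta_new = new_b0 + X @ new_beta
            f_new = negloglik(eta_new, s)
            db0, dbeta = new_b0 - yb0, new_beta - ybeta
            quad = (
                f_y
                + g0 * db0
                + float(g @ dbeta)
                + (db0 * db0 + float(dbeta @ dbeta)) / (2.0 * step)
            )
            if f_new <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        step *= 1.1  # tentatively grow for the next iteration

        if it % 10 == 0 or it == max_iter:
            d_new = _dnll_deta(eta_new, s)
            g_new = X.T @ d_new / n
            kkt = _kkt_residual(float(d_new.mean()), g_new, new_beta, lam)
            if kkt < tol:
                return new_b0, new_beta, it, kkt

        # adaptive restart: drop momentum when it opposes descent
        if (yb0 - new_b0) * (new_b0 - b0) + float(
            (ybeta - new_beta) @ (new_beta - beta)
        ) > 0:
            t_acc = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc))
        mom = (t_acc - 1.0) / t_next
        yb0 = new_b0 + mom * (new_b0 - b0)
        ybeta = new_beta + mom * (new_beta - beta)
        b0, beta = new_b0, new_beta
        t_acc = t_next
    return b0, beta, it, kkt


def fit_penalized_probit(
    X,
    s: np.ndarray,
    lam: float,
    columns: list[str] | None = None,
    warm_start: tuple[float, np.ndarray] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    lipschitz: float | None = None,
) -> ProbitLassoFit:
    """Fit the L1-penalized probit with an unpenalized intercept.

    The solver is proximal gradient (FISTA) with backtracking and adaptive
    restart, wrapped in a working-set strategy: the subproblem is solved
    over the currently active columns plus any columns violating the KKT
    entry condition, and the full-design KKT residual is re-checked until no
    violations remain. ``tol`` is the KKT subgradient-residual tolerance
    (infinity norm over intercept and slopes); ``warm_start`` is
    ``(intercept, coef)``.
    """
    X = _as_matrix(X)
    Xc = X.tocsc()
    s = np.asarray(s, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if s.min() == s.max():
        raise ValueError("labels contain a single class")
    if columns is None:
        columns = [f"x{j}" for j in range(p)]

    if warm_start is not None:
        b0, beta = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    else:
        b0, beta = float(ndtri(np.clip(s.mean(), 1e-6, 1 - 1e-6))), np.zeros(p)

    total_iter = 0
    kkt = np.inf
    for _outer in range(50):
        eta = b0 + X @ beta
        d = _dnll_deta(eta, s)
        g0 = float(d.mean())
        g = X.T @ d / n
        kkt = _kkt_residual(g0, g, beta, lam)
        if kkt < tol:
            break
        work = np.nonzero((beta != 0.0) | (np.abs(g) > lam - tol))[0]
        if lam == 0.0:
            work = np.arange(p)
        if len(work) == 0:
            # intercept-only problem
            Xw = sparse.csr_matrix((n, 0))
            bw = np.zeros(0)
        else:
            Xw = Xc[:, work].tocsr()
            bw = beta[work]
        if lipschitz is not None and len(work) == p:
            lw = lipschitz
        else:
            lw = _spectral_norm_sq(Xw) / n if Xw.shape[1] else 0.0
        step = 1.0 / (lw + 1.0)
        budget = max_iter - total_iter
        if budget <= 0:
            break
        b0, bw, used, _ = _fista_subproblem(
            Xw, s, lam, b0, bw, step, budget, tol * 0.5
        )
        beta = np.zeros(p)
        if len(work):
            beta[work] = bw
        total_iter += used
    it = total_iter

    separation = False
    # |coef| > 8 on the probit scale means fitted probabilities below ~1e-15
    # for some cells — the MLE is diverging along a separating direction
    if lam == 0.0 and (np.abs(beta).max(initial=0.0) > 8.0 or abs(b0) > 8.0):
        separation = True
        warnings.warn(
            "unpenalized probit coefficients diverge; data may be perfectly "
            "separated",
            stacklevel=2,
        )
    return ProbitLassoFit(
        intercept=b0,
        coef=beta,
        columns=list(columns),
        lambda_=lam,
        n_iter=it,
        kkt_norm=kkt,
        converged=bool(kkt < tol),
        separation_suspected=separation,
    )


def _stratified_folds(s: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment stratified on the binary label."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(s), dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(s == cls)[0]
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} members; cannot form {k} "
                "stratified folds"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _fit_path(X, s, grid, columns, max_iter, tol, lipschitz) -> list[ProbitLassoFit]:
    fits = []
    warm = None
    for lam in grid:
        fit = fit_penalized_probit(
            X, s, lam, columns=columns, warm_start=warm,
            max_iter=max_iter, tol=tol, lipschitz=lipschitz,
        )
        warm = (fit.intercept, fit.coef)
        fits.append(fit)
    return fits


def cross_validate_lambda(
    X,
    s: np.ndarray,
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    columns: list[str] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    refit_active_set: bool = True,
) -> ParticipationFit:
    """Choose lambda by stratified K-fold CV on held-out deviance.

    The chosen lambda minimizes the mean held-out deviance (minimum rule);
    the returned fit is re-estimated on all data at that lambda,
    warm-started along the path. Deterministic given the seed.

    With ``refit_active_set`` (default), the LASSO is used for variable
    selection only: the final coefficients are the unpenalized probit fit
    restricted to the selected columns. This removes the L1 shrinkage that
    would otherwise compress the participation index and under-disperse the
    inverse-probability weights.
    """
    X = _as_matrix(X)
    s = np.asarray(s, dtype=float)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if grid is None:
        grid = lambda_grid(lambda_max(X, s))
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")

    fold = _stratified_folds(s.astype(int), folds, seed)
    lipschitz_full = _spectral_norm_sq(X) / X.shape[0]
    deviance = np.zeros((folds, len(grid)))
    for f in range(folds):
        train = fold != f
        test = ~train
        Xtr = sparse.csr_matrix(X[train])
        fits = _fit_path(
            Xtr, s[train], grid, columns, max_iter, tol,
            _spectral_norm_sq(Xtr) / Xtr.shape[0],
        )
        Xte = sparse.csr_matrix(X[test])
        for g, fit in enumerate(fits):
            eta = fit.intercept + Xte @ fit.coef
            deviance[f, g] = 2.0 * negloglik(eta, s[test])

    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))
    path = _fit_path(X, s, grid[: best + 1], columns, max_iter, tol, lipschitz_full)
    final = path[-1]
    if refit_active_set and final.n_selected > 0:
        active = np.nonzero(final.coef)[0]
        Xa = sparse.csc_matrix(X)[:, active].tocsr()
        sub = fit_penalized_probit(
            Xa,
            s,
            0.0,
            columns=[final.columns[j] for j in active],
            warm_start=(final.intercept, final.coef[active]),
            max_iter=2 * max_iter,
            tol=tol,
        )
        coef = np.zeros(X.shape[1])
        coef[active] = sub.coef
        final = ProbitLassoFit(
            intercept=sub.intercept,
            coef=coef,
            columns=final.columns,
            lambda_=final.lambda_,
            n_iter=final.n_iter + sub.n_iter,
            kkt_norm=sub.kkt_norm,
            converged=final.converged and sub.converged,
            separation_suspected=sub.separation_suspected,
        )
    return ParticipationFit(
        lambda_grid=grid,
        chosen_lambda=float(grid[best]),
        cv_deviance=mean_dev,
        fit=final,
        folds=folds,
        seed=seed,
        path=path,
    )


def predict_probability(
    fit: ProbitLassoFit, X, columns: list[str] | None = None, eps: float = 1e-8
) -> tuple[np.ndarray, int]:
    """Predicted participation probabilities Phi(intercept + x'beta).

    Probabilities are clipped to [eps, 1 - eps]; the clip count is returned
    alongside. If ``columns`` is given, it is checked to cover the fit's
    active set (and the design is assumed column-aligned with the fit).
    """
    X = _as_matrix(X)
    if columns is not None:
        missing = set(fit.active_set()) - set(columns)
        if missing:
            raise KeyError(f"design lacks active columns: {sorted(missing)}")
    eta = fit.intercept + X @ fit.coef
    p = ndtr(eta)
    clipped = int(np.sum((p < eps) | (p > 1 - eps)))
    return np.clip(p, eps, 1 - eps), clipped
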