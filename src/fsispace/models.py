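"""Spatial econometric models: OLS baseline, SAR, SEM, SDM.

Estimation is concentrated maximum likelihood.  For the spatial-lag family
(SAR, SDM) the autoregressive parameter rho is profiled out: at each rho
the remaining coefficients are ordinary least squares of y - rho*Wy on the
design, and the log-determinant log|I - rho W| is evaluated through the
eigenvalues of W.  The spatial-error model concentrates the likelihood in
lambda via the Cochrane-Orcutt-style transform (I - lambda W).

Panels are treated as pooled cross-sections: observations must be ordered
year-major (all units of the first year, then the next), the weight matrix
enters block-diagonally, and the log-determinant is T * sum(log(1 - rho*w_i)).

Asymptotic standard errors come from the observed information: the
numerical Hessian of the exact log-likelihood at the ML estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .core import PanelDataset
from .weights import WeightMatrix

Model = Literal["OLS", "SAR", "SEM", "SDM"]


@dataclass
class ModelFit:
    model: Model
    coefficients: dict[str, tuple[float, float]]   # name -> (estimate, se)
    rho: float | None
    lambda_err: float | None
    sigma2: float
    loglik: float
    aic: float
    r_squared: float
    n_obs: int
    # internals used by diagnostics / effects / placebo
    params: np.ndarray = field(repr=False, default=None)
    vcov: np.ndarray | None = field(repr=False, default=None)
    param_names: list[str] = field(repr=False, default_factory=list)
    x_names: list[str] = field(repr=False, default_factory=list)
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)
    boundary: bool = False

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]

    def se(self, name: str) -> float:
        return self.coefficients[name][1]


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a culprit: a column whose removal restores full relative rank
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                raise np.linalg.LinAlgError(
                    f"design matrix is rank deficient; column {names[j]!r} "
                    "is collinear with the others"
                )
        raise np.linalg.LinAlgError("design matrix is rank deficient")


def ols_fit(y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None) -> ModelFit:
    """Least squares with conventional standard errors and Gaussian loglik."""
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    _check_design(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid / n)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * float(resid @ resid) / (n - k))
    ll = float(-n / 2 * (np.log(2 * np.pi * sigma2) + 1))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    coefs = {nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)}
    return ModelFit(
        model="OLS", coefficients=coefs, rho=None, lambda_err=None,
        sigma2=sigma2, loglik=ll, aic=2 * k - 2 * ll, r_squared=r2, n_obs=n,
        params=beta, vcov=xtx_inv * sigma2 * n / (n - k), param_names=names,
        x_names=[nm for nm in names if nm != "const"], _y=y, _X=X, resid=resid,
    )


# -------------------------------------------------------- LM diagnostics --

@dataclass(frozen=True)
class LMDiagnostics:
    lm_lag: tuple[float, float]
    lm_error: tuple[float, float]
    robust_lag: tuple[float, float]
    robust_error: tuple[float, float]


def _full_w(wm: WeightMatrix, n_obs: int) -> np.ndarray:
    """Block-diagonal kron(I_T, W) matching year-major observation order."""
    n = wm.n
    if n_obs % n:
        raise ValueError(f"{n_obs} observations not a multiple of {n} units")
    T = n_obs // n
    return np.kron(np.eye(T), wm.w)


def lm_tests(fit: ModelFit, wm: WeightMatrix) -> LMDiagnostics:
    """Anselin Lagrange-multiplier tests for spatial lag and error
    dependence on OLS residuals, with the robust variants; chi2(1)
    p-values."""
    if fit.model != "OLS":
        raise ValueError("LM tests are computed on the OLS baseline fit")
    y, X, e = fit._y, fit._X, fit.resid
    n = len(y)
    W = _full_w(wm, n)
    sigma2 = float(e @ e / n)
    T1 = float(np.trace(W @ W + W.T @ W))
    We = W @ e
    Wy = W @ y
    d_err = float(e @ We) / sigma2
    d_lag = float(e @ Wy) / sigma2
    beta = fit.params
    WXb = W @ (X @ beta)
    # M = I - X(X'X)^{-1}X'
    XtX_inv = np.linalg.inv(X.T @ X)
    MWXb = WXb - X @ (XtX_inv @ (X.T @ WXb))
    D = float(WXb @ MWXb) / sigma2 + T1
    lm_err = d_err**2 / T1
    lm_lag = d_lag**2 / D
    rob_lag = (d_lag - d_err) ** 2 / (D - T1) if D > T1 else np.nan
    denom = T1 * (1 - T1 / D)
    rob_err = (d_err - T1 / D * d_lag) ** 2 / denom if denom > 0 else np.nan

    def p(stat: float) -> float:
        return float(stats.chi2.sf(stat, df=1)) if np.isfinite(stat) else np.nan

    return LMDiagnostics(
        lm_lag=(float(lm_lag), p(lm_lag)),
        lm_error=(float(lm_err), p(lm_err)),
        robust_lag=(float(rob_lag), p(rob_lag)),
        robust_error=(float(rob_err), p(rob_err)),
    )


# ------------------------------------------------------------ ML engine --

def _wlag(a: np.ndarray, W: np.ndarray, T: int) -> np.ndarray:
    """Apply kron(I_T, W) without forming it (year-major ordering)."""
    n = W.shape[0]
    if a.ndim == 1:
        return (a.reshape(T, n) @ W.T).ravel()
    return np.concatenate([(a[:, j].reshape(T, n) @ W.T).ravel()[:, None]
                           for j in range(a.shape[1])], axis=1)


def _spatial_ml(
    y: np.ndarray,
    X: np.ndarray,
    wm: WeightMatrix,
    model: Model,
    names: Sequence[str],
    compute_se: bool = True,
) -> ModelFit:
    if not wm.row_standardized:
        raise ValueError("spatial ML requires a row-standardized weight matrix")
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n_obs = len(y)
    n = wm.n
    T = n_obs // n
    if T * n != n_obs:
        raise ValueError(f"{n_obs} observations not divisible by {n} units")
    W = wm.w
    ev = np.linalg.eigvals(W)
    re_ev = np.real(ev)
    lo = 1.0 / re_ev.min() + 1e-6 if re_ev.min() < 0 else -0.999999
    hi = 1.0 - 1e-6

    def logdet(r: float) -> float:
        return float(T * np.sum(np.log(1.0 - r * ev)).real)

    names = list(names)
    if model == "SDM":
        # lag the non-constant columns whose lag is not the column itself
        # (intercept and year dummies are invariant under a row-standardized
        # within-year lag and would duplicate themselves)
        lag_cols, lag_names = [], []
        for j, nm in enumerate(names):
            if np.ptp(X[:, j]) == 0:
                continue
            lagged = _wlag(X[:, j], W, T)
            if np.allclose(lagged, X[:, j]):
                continue
            lag_cols.append(lagged)
            lag_names.append(f"W_{nm}")
        Z = np.column_stack([X, *lag_cols]) if lag_cols else X
        z_names = names + lag_names
    elif model in ("SAR", "SEM"):
        Z = X
        z_names = names
    else:
        raise ValueError(f"unknown spatial model {model!r}")
    _check_design(Z, z_names)
    kz = Z.shape[1]

    if model in ("SAR", "SDM"):
        Wy = _wlag(y, W, T)
        # residual-maker applied once
        Q, _ = np.linalg.qr(Z)
        e0 = y - Q @ (Q.T @ y)
        e1 = Wy - Q @ (Q.T @ Wy)

        def negll_conc(r: float) -> float:
            e = e0 - r * e1
            s2 = float(e @ e / n_obs)
            return -(-(n_obs / 2) * (np.log(2 * np.pi * s2) + 1) + logdet(r))

        res = optimize.minimize_scalar(
            negll_conc, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        rho = float(res.x)
        boundary = min(rho - lo, hi - rho) < 1e-5
        if boundary:
            warnings.warn(f"spatial parameter at interval boundary: {rho:.4f}")
        delta, _, _, _ = np.linalg.lstsq(Z, y - rho * Wy, rcond=None)
        e = y - rho * Wy - Z @ delta
        sigma2 = float(e @ e / n_obs)
        ll = float(-(n_obs / 2) * (np.log(2 * np.pi * sigma2) + 1) + logdet(rho))

        def full_ll(psi: np.ndarray) -> float:
            d, r, s2 = psi[:kz], psi[kz], psi[kz + 1]
            if not (lo < r < hi) or s2 <= 0:
                return -1e12
            u = y - r * Wy - Z @ d
            return float(
                -(n_obs / 2) * np.log(2 * np.pi * s2)
                - u @ u / (2 * s2) + logdet(r)
            )

        psi_hat = np.concatenate([delta, [rho, sigma2]])
        param_names = z_names + ["rho", "sigma2"]
        spatial = ("rho", rho)
        fitted = rho * Wy + Z @ delta
    else:  # SEM
        def transform(lam: float):
            ys = y - lam * _wlag(y, W, T)
            Xs = Z - lam * _wlag(Z, W, T)
            beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
            u = ys - Xs @ beta
            return beta, float(u @ u / n_obs)

        def negll_conc(lam: float) -> float:
            _, s2 = transform(lam)
            return -(-(n_obs / 2) * (np.log(2 * np.pi * s2) + 1) + logdet(lam))

        res = optimize.minimize_scalar(
            negll_conc, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x)
        boundary = min(lam - lo, hi - lam) < 1e-5
        delta, sigma2 = transform(lam)
        ll = float(-(n_obs / 2) * (np.log(2 * np.pi * sigma2) + 1) + logdet(lam))

        def full_ll(psi: np.ndarray) -> float:
            d, l_, s2 = psi[:kz], psi[kz], psi[kz + 1]
            if not (lo < l_ < hi) or s2 <= 0:
                return -1e12
            u0 = y - Z @ d
            u = u0 - l_ * _wlag(u0, W, T)
            return float(
                -(n_obs / 2) * np.log(2 * np.pi * s2)
                - u @ u / (2 * s2) + logdet(l_)
            )

        psi_hat = np.concatenate([delta, [lam, sigma2]])
        param_names = z_names + ["lambda", "sigma2"]
        spatial = ("lambda", lam)
        e = y - Z @ delta
        fitted = Z @ delta

    if compute_se:
        H = approx_hess(psi_hat, full_ll)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(-H)
        diag = np.diag(vcov).copy()
        diag[diag < 0] = np.nan
        ses = np.sqrt(diag)
    else:
        vcov = None
        ses = np.full(len(psi_hat), np.nan)

    coefs = {nm: (float(b), float(s)) for nm, b, s in zip(z_names, psi_hat, ses)}
    coefs[spatial[0]] = (spatial[1], float(ses[kz]))
    r = np.corrcoef(y, fitted)[0, 1]
    k_model = kz + 1  # slopes + spatial parameter
    return ModelFit(
        model=model,
        coefficients=coefs,
        rho=spatial[1] if spatial[0] == "rho" else None,
        lambda_err=spatial[1] if spatial[0] == "lambda" else None,
        sigma2=sigma2,
        loglik=ll,
        aic=2 * k_model - 2 * ll,
        r_squared=float(r**2),
        n_obs=n_obs,
        params=psi_hat,
        vcov=vcov,
        param_names=param_names,
        x_names=[
            nm for j, nm in enumerate(names)
            if nm != "const" and not nm.startswith("year_") and np.ptp(X[:, j]) > 0
        ],
        _y=y,
        _X=X,
        resid=e,
        boundary=boundary,
    )


def sar_fit(y, X, wm: WeightMatrix, names=None, compute_se: bool = True) -> ModelFit:
    """Spatial autoregressive model y = rho*Wy + X beta + eps."""
    names = list(names) if names is not None else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    return _spatial_ml(y, X, wm, "SAR", names, compute_se)


def sem_fit(y, X, wm: WeightMatrix, names=None, compute_se: bool = True) -> ModelFit:
    """Spatial error model y = X beta + u, u = lambda*Wu + eps."""
    names = list(names) if names is not None else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    return _spatial_ml(y, X, wm, "SEM", names, compute_se)


def sdm_fit(y, X, wm: WeightMatrix, names=None, compute_se: bool = True) -> ModelFit:
    """Spatial Durbin model y = rho*Wy + X beta + WX theta + eps.

    Constant columns of X are not lagged (W 1 = 1 under row
    standardization would duplicate the intercept).
    """
    names = list(names) if names is not None else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    return _spatial_ml(y, X, wm, "SDM", names, compute_se)


def dense_loglik(
    y: np.ndarray, X: np.ndarray, wm: WeightMatrix, rho: float,
    delta: np.ndarray, sigma2: float, model: Model = "SDM",
) -> float:
    """Literal dense-matrix log-likelihood (oracle for the concentrated
    engine): log|I - rho W| via slogdet of the full matrix."""
    y = np.asarray(y, float).ravel()
    n_obs = len(y)
    A = np.eye(n_obs) - rho * _full_w(wm, n_obs)
    sign, logdet = np.linalg.slogdet(A)
    if model == "SDM":
        T = n_obs // wm.n
        lag_cols = []
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                continue
            lagged = _wlag(X[:, j], wm.w, T)
            if np.allclose(lagged, X[:, j]):
                continue
            lag_cols.append(lagged)
        Z = np.column_stack([X, *lag_cols]) if lag_cols else X
    else:
        Z = X
    u = A @ y - Z @ np.asarray(delta, float)
    return float(
        -(n_obs / 2) * np.log(2 * np.pi * sigma2)
        - u @ u / (2 * sigma2) + sign * logdet
    )


# --------------------------------------------------------------- effects --

@dataclass
class EffectsTable:
    table: pd.DataFrame     # covariate x (direct, direct_se, indirect, ...)
    n_draws: int

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _effects_point(
    wm: WeightMatrix, rho: float, beta_r: float, theta_r: float
) -> tuple[float, float, float]:
    n = wm.n
    M = np.linalg.inv(np.eye(n) - rho * wm.w)
    S = M * beta_r + (M @ wm.w) * theta_r
    direct = float(np.trace(S) / n)
    total = float(S.sum() / n)
    return direct, total - direct, total


def effects_decomposition(
    fit: ModelFit, wm: WeightMatrix, n_draws: int = 1000, seed: int = 0
) -> EffectsTable:
    """LeSage-Pace direct / indirect / total effects for SAR or SDM fits.

    For covariate r the impact matrix is
    S_r = (I - rho W)^{-1} (I beta_r + W theta_r); direct is the average
    diagonal, total the average row sum, indirect their difference.
    Standard errors come from ``n_draws`` simulations of (rho, beta,
    theta) from the asymptotic normal of the ML estimate.
    """
    if fit.model not in ("SAR", "SDM"):
        raise ValueError("effects decomposition needs a spatial-lag fit (SAR/SDM)")
    if fit.rho is None:
        raise ValueError("fit has no spatial lag parameter")
    idx = {nm: i for i, nm in enumerate(fit.param_names)}
    rows = {}
    draws_needed = [idx["rho"]]
    name_slots = {}
    for nm in fit.x_names:
        b_i = idx[nm]
        t_i = idx.get(f"W_{nm}")
        name_slots[nm] = (b_i, t_i)
        draws_needed.append(b_i)
        if t_i is not None:
            draws_needed.append(t_i)
    for nm, (b_i, t_i) in name_slots.items():
        beta_r = fit.params[b_i]
        theta_r = fit.params[t_i] if t_i is not None else 0.0
        rows[nm] = _effects_point(wm, fit.rho, beta_r, theta_r)

    if fit.vcov is None:
        raise ValueError("fit was computed without a covariance matrix")
    rng = np.random.default_rng(seed)
    mean = fit.params[:-1]          # drop sigma2
    V = fit.vcov[:-1, :-1]
    # draw from the asymptotic normal; symmetrize for safety
    V = (V + V.T) / 2
    evals, evecs = np.linalg.eigh(V)
    evals[evals < 0] = 0.0
    L = evecs * np.sqrt(evals)
    z = rng.standard_normal((n_draws, len(mean)))
    draws = mean + z @ L.T
    rho_i = idx["rho"]
    ev_min = float(np.min(np.real(np.linalg.eigvals(wm.w))))
    lo, hi = (1.0 / ev_min + 1e-6 if ev_min < 0 else -0.999), 0.999999
    sims = {nm: [] for nm in name_slots}
    for d in range(n_draws):
        r = float(np.clip(draws[d, rho_i], lo, hi))
        n_ = wm.n
        M = np.linalg.inv(np.eye(n_) - r * wm.w)
        tr_M = np.trace(M) / n_
        tr_MW = np.trace(M @ wm.w) / n_
        sum_M = M.sum() / n_
        sum_MW = (M @ wm.w).sum() / n_
        for nm, (b_i, t_i) in name_slots.items():
            b = draws[d, b_i]
            t = draws[d, t_i] if t_i is not None else 0.0
            direct = b * tr_M + t * tr_MW
            total = b * sum_M + t * sum_MW
            sims[nm].append((direct, total - direct, total))
    records = []
    for nm, (direct, indirect, total) in rows.items():
        sd = np.std(np.array(sims[nm]), axis=0, ddof=1)
        records.append(
            {
                "covariate": nm,
                "direct": direct, "direct_se": sd[0],
                "indirect": indirect, "indirect_se": sd[1],
                "total": total, "total_se": sd[2],
            }
        )
    table = pd.DataFrame(records).set_index("covariate")
    return EffectsTable(table=table, n_draws=n_draws)


# --------------------------------------------------------------- placebo --

@dataclass(frozen=True)
class PlaceboResult:
    observed: float
    permuted: tuple[float, ...]
    p_value: float


def placebo_test(
    y: np.ndarray,
    X: np.ndarray,
    wm: WeightMatrix,
    target: str,
    names: Sequence[str],
    n_perm: int = 99,
    seed: int = 0,
    model: Model = "SDM",
) -> PlaceboResult:
    """Permutation placebo: the target column is shuffled across units
    within each year and the model re-estimated; the two-sided placebo
    p-value is the share of permuted coefficients at least as large in
    magnitude as the observed one."""
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    names = list(names)
    if target not in names:
        raise KeyError(f"target term {target!r} not in design")
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n = wm.n
    T = len(y) // n
    fitter = {"SDM": sdm_fit, "SAR": sar_fit, "OLS": None}[model]

    def coef_of(Xp: np.ndarray) -> float:
        if model == "OLS":
            f = ols_fit(y, Xp, names)
        else:
            f = fitter(y, Xp, wm, names, compute_se=False)
        return f.coef(target)

    observed = coef_of(X)
    j = names.index(target)
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_perm):
        Xp = X.copy()
        col = Xp[:, j].reshape(T, n)
        for t in range(T):
            col[t] = col[t][rng.permutation(n)]
        Xp[:, j] = col.ravel()
        permuted.append(coef_of(Xp))
    permuted = np.array(permuted)
    p = float((1 + np.sum(np.abs(permuted) >= abs(observed))) / (n_perm + 1))
    return PlaceboResult(observed, tuple(float(b) for b in permuted), p)


# ----------------------------------------------------------- panel glue --

def panel_arrays(
    panel: PanelDataset,
    y_field: str,
    x_fields: Sequence[str],
    wm: WeightMatrix,
    year_dummies: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Year-major (year blocks, units in weight-matrix order) y and design
    arrays with intercept and optional year fixed-effect dummies."""
    units = list(wm.units)
    df = panel.data.set_index(["year", "unit"]).sort_index()
    years = panel.years
    order = pd.MultiIndex.from_product([years, units], names=["year", "unit"])
    df = df.loc[order]
    y = df[y_field].to_numpy(float)
    cols = [np.ones(len(df))]
    names = ["const"]
    for f in x_fields:
        cols.append(df[f].to_numpy(float))
        names.append(f)
    if year_dummies:
        for yr in years[1:]:
            cols.append((df.index.get_level_values("year") == yr).astype(float))
            names.append(f"year_{yr}")
    X = np.column_stack(cols)
    return y, X, names
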