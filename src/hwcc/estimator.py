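"""Conditional quasi-Poisson regression for the case-crossover panel.

The count model is log E(Y_si) = alpha_s + x_si' beta, with one nuisance
intercept alpha_s per stratum s. Conditioning on the stratum totals Y_s
eliminates the intercepts and leaves the multinomial (conditional-logit)
profile likelihood

    l(beta) = sum_s [ sum_i y_si x_si' beta  -  Y_s log sum_i exp(x_si' beta) ],

which this module maximizes by Newton's method with step halving. The result
is numerically identical to a Poisson fit with explicit stratum dummies, but
scales to thousands of strata. Overdispersion is handled quasi-likelihood
style: the Pearson dispersion phi scales the covariance, changing standard
errors and p-values but never point estimates.

Strata contribute nothing unless they are *informative*: total count > 0 and
at least one exposure column varying within the stratum. Effects are reported
as percent change per unit exposure, (e^beta - 1) x 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import STRATUM_COLS

Z95 = 1.959963984540054  # two-sided 95% normal quantile

EXPOSURE_FORMS = {
    "linear_hwi": ("dhwi", "nhwi"),
    "binary_hw": ("dhw_flag", "nhw_flag"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the exposure side of the conditional model.

    exposure_form: 'linear_hwi' (per-degree HWIs, the main model),
        'binary_hw' (event indicator secondary model), 'spline_hwi'
        (natural-cubic-spline exposure response), or 'lagged_hwi'
        (single-lag model at ``lag`` days).
    covariates: extra same-day linear covariate columns (e.g. 'rh' for the
        humidity-adjusted sensitivity model).
    spline_knots: interior knot percentiles of the HWI distribution.
    knots_on_positive: place spline knots on heatwave-day (positive) HWI
        values only; pooling the zeros would collapse both knots to 0.
    dispersion_floor: optional floor applied to phi when scaling SEs
        (None = pure quasi-likelihood sqrt(phi) scaling, the default).
    """

    exposure_form: str = "linear_hwi"
    covariates: tuple[str, ...] = ()
    spline_knots: tuple[float, ...] = (0.10, 0.50)
    knots_on_positive: bool = True
    lag: int = 0
    dispersion_floor: float | None = None
    tol: float = 1e-10
    max_iter: int = 100


@dataclass
class EffectEstimate:
    """Effect on the percent-change scale with Wald uncertainty."""

    label: str
    beta: float
    se_beta: float
    percent_change: float
    se_percent: float
    ci95: tuple[float, float]
    p_value: float


@dataclass
class FitResult:
    params: pd.Series
    cov: pd.DataFrame            # quasi-scaled (phi or floored phi)
    cov_unscaled: pd.DataFrame   # model-based (phi = 1)
    dispersion: float
    n_informative_strata: int
    n_rows_used: int
    converged: bool
    n_iter: int
    loglik: float
    spec: ModelSpec
    extras: dict = field(default_factory=dict)

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def effect(self, name: str, label: str | None = None) -> EffectEstimate:
        return percent_change(
            float(self.params[name]), self.se(name), label=label or name
        )

    def effects(self) -> list[EffectEstimate]:
        return [self.effect(name) for name in self.params.index]


def percent_change(beta: float, se_beta: float, label: str = "") -> EffectEstimate:
    """(e^beta - 1) x 100 with Wald 95% CI and two-sided p-value."""
    if not (np.isfinite(beta) and np.isfinite(se_beta)):
        raise ValueError("beta and se must be finite")
    if se_beta <= 0:
        raise ValueError("se must be positive")
    pc = (math.exp(beta) - 1.0) * 100.0
    lo = (math.exp(beta - Z95 * se_beta) - 1.0) * 100.0
    hi = (math.exp(beta + Z95 * se_beta) - 1.0) * 100.0
    se_pc = math.exp(beta) * se_beta * 100.0  # delta method
    z = beta / se_beta
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(label, beta, se_beta, pc, se_pc, (lo, hi), p)


# ---------------------------------------------------------------------------
# profile-likelihood Newton core


def _stratum_codes(panel: pd.DataFrame) -> np.ndarray:
    return panel.groupby(STRATUM_COLS, sort=False).ngroup().to_numpy()


def _informative_rows(y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    n_strata = codes.max() + 1 if codes.size else 0
    ytot = np.bincount(codes, weights=y, minlength=n_strata)
    varies = np.zeros(n_strata, dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        mn = np.full(n_strata, np.inf)
        mx = np.full(n_strata, -np.inf)
        np.minimum.at(mn, codes, col)
        np.maximum.at(mx, codes, col)
        varies |= (mx - mn) > 0
    keep = (ytot > 0) & varies
    return keep[codes]


def _loglik(beta, y, X, codes, ytot, n_strata):
    eta = X @ beta
    m = np.full(n_strata, -np.inf)
    np.maximum.at(m, codes, eta)
    w = np.exp(eta - m[codes])
    denom = np.bincount(codes, weights=w, minlength=n_strata)
    ll = float(y @ eta - ytot @ (np.log(denom) + m))
    return ll, eta, w, denom, m


def _fit_profile(y, X, codes, tol=1e-10, max_iter=100):
    """Newton maximization of the conditional (multinomial) log-likelihood."""
    n, p = X.shape
    n_strata = int(codes.max()) + 1
    ytot = np.bincount(codes, weights=y, minlength=n_strata)
    beta = np.zeros(p)
    ll, eta, w, denom, m = _loglik(beta, y, X, codes, ytot, n_strata)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = w / denom[codes]
        mu = ytot[codes] * pi
        grad = X.T @ (y - mu)
        Px = np.empty((n_strata, p))
        for j in range(p):
            Px[:, j] = np.bincount(codes, weights=pi * X[:, j], minlength=n_strata)
        H = X.T @ (mu[:, None] * X) - Px.T @ (ytot[:, None] * Px)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "model unidentifiable: singular information matrix "
                "(collinear exposures within strata)"
            ) from exc
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, eta_n, w_n, denom_n, m_n = _loglik(
                cand, y, X, codes, ytot, n_strata
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll_prev = cand, ll
        ll, eta, w, denom, m = ll_new, eta_n, w_n, denom_n, m_n
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
    if not converged:
        gnorm = float(np.linalg.norm(X.T @ (y - ytot[codes] * (w / denom[codes]))))
        raise RuntimeError(
            f"conditional Poisson fit did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3e})"
        )
    pi = w / denom[codes]
    mu = ytot[codes] * pi
    Px = np.empty((n_strata, p))
    for j in range(p):
        Px[:, j] = np.bincount(codes, weights=pi * X[:, j], minlength=n_strata)
    H = X.T @ (mu[:, None] * X) - Px.T @ (ytot[:, None] * Px)
    cov = np.linalg.inv(H)
    return beta, cov, mu, ll, it, n_strata


def pearson_dispersion(
    y: np.ndarray, mu: np.ndarray, n_strata: int, n_params: int
) -> float:
    """Pearson X^2 / residual df over informative strata.

    df = n_rows - n_strata - n_params, since the conditional fit profiles out
    one intercept per stratum in addition to the exposure coefficients.
    """
    df = len(y) - n_strata - n_params
    if df <= 0:
        raise ValueError(
            f"non-positive residual degrees of freedom ({df}); "
            "too few rows for dispersion estimation"
        )
    x2 = float(np.sum((y - mu) ** 2 / mu))
    return x2 / df


def _design_matrix(panel: pd.DataFrame, spec: ModelSpec):
    if spec.exposure_form in EXPOSURE_FORMS:
        cols = list(EXPOSURE_FORMS[spec.exposure_form])
    else:
        raise ValueError(
            f"unknown exposure_form {spec.exposure_form!r}; "
            f"use fit_spline_model/fit_lag_model for spline/lag fits"
        )
    cols += list(spec.covariates)
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks column(s): {missing}")
    X = panel[cols].to_numpy(dtype=float)
    return X, cols


def fit_conditional_poisson(
    panel: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    exposure_cols: list[str] | None = None,
) -> FitResult:
    """Fit the conditional quasi-Poisson model on a stratified panel.

    ``exposure_cols`` overrides the columns implied by ``spec.exposure_form``
    (used internally by the spline and lag fits). Raises ``RuntimeError``
    ('model unidentifiable') when no stratum has both a positive total count
    and within-stratum exposure variation.
    """
    if exposure_cols is None:
        X, names = _design_matrix(panel, spec)
    else:
        names = list(exposure_cols) + list(spec.covariates)
        X = panel[names].to_numpy(dtype=float)
    y = panel["count"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    codes = _stratum_codes(panel)

    keep = _informative_rows(y, X, codes)
    if not keep.any():
        raise RuntimeError(
            "model unidentifiable: no informative strata "
            "(need total count > 0 and within-stratum exposure variation)"
        )
    y_i, X_i = y[keep], X[keep]
    codes_i = pd.factorize(codes[keep])[0]

    beta, cov_u, mu, ll, n_iter, n_strata = _fit_profile(
        y_i, X_i, codes_i, tol=spec.tol, max_iter=spec.max_iter
    )
    try:
        phi = pearson_dispersion(y_i, mu, n_strata, len(names))
    except ValueError:
        phi = float("nan")  # no residual df; SEs stay model-based
    if np.isnan(phi):
        scale = 1.0
    elif spec.dispersion_floor is None:
        scale = phi
    else:
        scale = max(phi, spec.dispersion_floor)
    params = pd.Series(beta, index=names)
    cov_unscaled = pd.DataFrame(cov_u, index=names, columns=names)
    return FitResult(
        params=params,
        cov=cov_unscaled * scale,
        cov_unscaled=cov_unscaled,
        dispersion=phi,
        n_informative_strata=n_strata,
        n_rows_used=int(keep.sum()),
        converged=True,
        n_iter=n_iter,
        loglik=ll,
        spec=spec,
    )


def fit_binary_model(panel: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> FitResult:
    """Secondary analysis: binary daytime/nighttime heatwave indicators."""
    return fit_conditional_poisson(panel, replace(spec, exposure_form="binary_hw"))


# ---------------------------------------------------------------------------
# natural cubic spline exposure-response


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    ``knots`` are the full ascending knot sequence including boundaries; the
    basis has len(knots) - 1 columns and omits the intercept. All columns
    vanish at x = knots[0], so with a boundary knot at 0 the fitted curve is
    anchored at log-RR = 0 for HWI = 0.
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "coincident or unordered spline knots; supply distinct knots "
            "(e.g. place them on positive HWI values only)"
        )
    x = np.asarray(x, dtype=float)
    K = len(knots)
    kK = knots[-1]

    def d(k):
        return (
            np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3
        ) / (kK - knots[k])

    cols = [x - knots[0]]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


def spline_knots_for(
    values: np.ndarray,
    interior_percentiles=(0.10, 0.50),
    on_positive: bool = True,
) -> np.ndarray:
    """Knot sequence [0, interior..., max] over the HWI distribution."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if on_positive:
        v = v[v > 0]
    if v.size < 3:
        raise ValueError("too few distinct positive HWI values to place knots")
    interior = np.quantile(v, interior_percentiles)
    knots = np.concatenate([[0.0], interior, [v.max()]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "coincident spline knots for this HWI distribution; consider "
            "different percentiles or knots_on_positive=True"
        )
    return knots


def fit_spline_model(
    panel: pd.DataFrame, spec: ModelSpec = ModelSpec(exposure_form="spline_hwi")
) -> tuple[FitResult, dict[str, pd.DataFrame]]:
    """Natural-cubic-spline exposure-response for both HWIs.

    Returns the fit plus, per exposure, a curve frame (hwi, log_rr, se,
    rr_ci_low/high) anchored at log-RR = 0 at HWI = 0.
    """
    work = panel.copy()
    names: list[str] = []
    bases: dict[str, tuple[np.ndarray, list[str]]] = {}
    for expo in ("dhwi", "nhwi"):
        knots = spline_knots_for(
            work[expo].to_numpy(),
            interior_percentiles=spec.spline_knots,
            on_positive=spec.knots_on_positive,
        )
        B = natural_spline_basis(work[expo].to_numpy(), knots)
        cols = [f"{expo}_ns{j + 1}" for j in range(B.shape[1])]
        work[cols] = B
        names += cols
        bases[expo] = (knots, cols)
    fit = fit_conditional_poisson(work, spec, exposure_cols=names)

    curves: dict[str, pd.DataFrame] = {}
    for expo, (knots, cols) in bases.items():
        grid = np.linspace(0.0, knots[-1], 60)
        Bg = natural_spline_basis(grid, knots)
        b = fit.params[cols].to_numpy()
        V = fit.cov.loc[cols, cols].to_numpy()
        log_rr = Bg @ b
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bg, V, Bg), 0.0))
        curves[expo] = pd.DataFrame(
            {
                "hwi": grid,
                "log_rr": log_rr,
                "se": se,
                "rr_ci_low": np.exp(log_rr - Z95 * se),
                "rr_ci_high": np.exp(log_rr + Z95 * se),
            }
        )
        fit.extras[f"knots_{expo}"] = knots
    return fit, curves


# ---------------------------------------------------------------------------
# single-lag models


def lag_exposure(
    panel: pd.DataFrame, exposure: pd.DataFrame, lag: int
) -> pd.DataFrame:
    """Join exposure measured ``lag`` days before each outcome day.

    Outcome days whose lagged date falls outside exposure coverage are
    dropped (early-season days for lag >= 1).
    """
    if not 0 <= lag <= 6:
        raise ValueError(f"lag must be in [0, 6], got {lag}")
    lagged = exposure.copy()
    lagged["date"] = pd.to_datetime(lagged["date"]) + pd.Timedelta(days=lag)
    lagged = lagged[["location_id", "date", "dhwi", "nhwi", "dhw_flag", "nhw_flag"]]
    lagged = lagged.rename(
        columns={c: f"{c}_lag{lag}" for c in ("dhwi", "nhwi", "dhw_flag", "nhw_flag")}
    )
    base = panel.drop(
        columns=[c for c in ("dhwi", "nhwi", "dhw_flag", "nhw_flag") if c in panel],
    )
    out = base.merge(lagged, on=["location_id", "date"], how="inner")
    out = out.rename(
        columns={f"{c}_lag{lag}": c for c in ("dhwi", "nhwi", "dhw_flag", "nhw_flag")}
    )
    out.attrs = dict(panel.attrs)
    out.attrs["lag"] = lag
    return out.reset_index(drop=True)


def fit_lag_model(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    lag: int,
    spec: ModelSpec = ModelSpec(),
) -> FitResult:
    """Single-lag conditional quasi-Poisson fit (exposure at day - lag)."""
    shifted = lag_exposure(panel, exposure, lag)
    fit = fit_conditional_poisson(shifted, replace(spec, lag=lag))
    fit.extras["lag"] = lag
    return fit
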