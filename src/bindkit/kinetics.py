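"""Enzyme-inhibition kinetics: IC50, Lineweaver-Burk, Ki, reversibility.

The module estimates:

* IC50 from a dose-response table, via a fixed-asymptote logistic
  (%inhibition = 100 / (1 + (IC50/[I])^h), floor 0 / ceiling 100);
* apparent Michaelis parameters per inhibitor level from ordinary least
  squares on the double-reciprocal (Lineweaver-Burk) transform
  1/v = (Km_app/Vmax_app)(1/[S]) + 1/Vmax_app;
* the inhibition mode from how Km_app and Vmax_app move with [I]
  (competitive: Vmax constant, Km_app rising; noncompetitive: Km constant,
  Vmax falling; uncompetitive: both falling with constant ratio);
* Ki from the secondary plot Km_app = Km*[I]/Ki + Km;
* reversibility from velocity-vs-enzyme lines per inhibitor level
  (parallel lines with [I]-shifted intercepts -> irreversible titration of
  active enzyme; origin-passing fans of decreasing slope -> reversible).

A direct nonlinear fit of the untransformed rate law is provided as a
cross-check on the reciprocal-transform estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import (
    IC50Result,
    InhibitionResult,
    KineticDataset,
    LineweaverFit,
    ReversibilityResult,
)
from .exceptions import (
    FitDegenerateError,
    IndeterminateIC50Error,
    NoInhibitionError,
    PreconditionError,
    ValidationError,
)

#: Relative tolerance under which Vmax/Km/slopes count as "unchanged".
DEFAULT_TOL = 0.05


def rate_law(S, I, km: float, vmax: float, ki: float | None = None,
             mode: str = "none", alpha: float = 2.0):
    """Initial velocity of a Michaelis-Menten enzyme under one inhibition mode.

    S, I : substrate and inhibitor concentrations (mol/L), broadcastable.
    mode : one of competitive, noncompetitive, uncompetitive, mixed, none.
    alpha : Ki'/Ki for mixed inhibition (the ES-complex affinity ratio).
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValidationError("concentrations must be >= 0")
    if mode == "none":
        return vmax * S / (km + S)
    if ki is None or ki <= 0:
        raise PreconditionError("ki must be > 0 for inhibited modes")
    if mode == "competitive":
        return vmax * S / (km * (1 + I / ki) + S)
    if mode == "noncompetitive":
        return vmax * S / ((km + S) * (1 + I / ki))
    if mode == "uncompetitive":
        return vmax * S / (km + S * (1 + I / ki))
    if mode == "mixed":
        return vmax * S / (km * (1 + I / ki) + S * (1 + I / (alpha * ki)))
    raise ValidationError(f"unknown inhibition mode: {mode!r}")


def logistic_inhibition(I, ic50: float, hill: float):
    """Percent inhibition of the fixed-asymptote (0-100) logistic model."""
    I = np.asarray(I, dtype=float)
    with np.errstate(divide="ignore"):
        out = 100.0 / (1.0 + (ic50 / np.where(I > 0, I, np.nan)) ** hill)
    return np.where(I > 0, out, 0.0)


# ---------------------------------------------------------------------------
# IC50
# ---------------------------------------------------------------------------

class IC50Estimator(RegressorMixin, BaseEstimator):
    """Two-parameter logistic dose-response fit with fixed 0/100 asymptotes.

    Attributes (after fit): ``ic50_`` (mol/L), ``hill_slope_``, ``r_squared_``.
    """

    def __init__(self, max_iter: int = 10000):
        self.max_iter = max_iter

    def fit(self, X, y):
        I = np.asarray(X, dtype=float).reshape(-1)
        pct = np.asarray(y, dtype=float).reshape(-1)
        if I.size != pct.size:
            raise PreconditionError("concentration and %inhibition length mismatch")
        if np.any(I < 0):
            raise ValidationError("inhibitor concentrations must be >= 0")
        mask = I > 0
        I, pct = I[mask], pct[mask]
        if np.unique(I).size < 4:
            raise PreconditionError("IC50 fit needs >= 4 positive concentration levels")
        order = np.argsort(I)
        I, pct = I[order], pct[order]
        if pct.max() <= 50.0 or pct.min() >= 50.0:
            raise IndeterminateIC50Error(
                "dose-response data do not cross 50% inhibition"
            )
        # monotonicity check, generous to noise
        drops = np.diff(pct)
        if np.any(drops < -10.0):
            warnings.warn("dose-response not monotone beyond noise", stacklevel=2)

        # initial IC50 from the linear interpolation of the 50% crossing
        above = np.argmax(pct > 50.0)
        if above == 0:
            ic50_init = I[0]
        else:
            x0, x1 = I[above - 1], I[above]
            y0, y1 = pct[above - 1], pct[above]
            ic50_init = x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)
        popt, _ = optimize.curve_fit(
            logistic_inhibition, I, pct,
            p0=[ic50_init, 1.0],
            bounds=([0.0, 1e-3], [np.inf, 100.0]),
            maxfev=self.max_iter, xtol=1e-14, ftol=1e-14,
        )
        self.ic50_, self.hill_slope_ = float(popt[0]), float(popt[1])
        resid = pct - logistic_inhibition(I, *popt)
        ss_tot = float(np.sum((pct - pct.mean()) ** 2))
        self.r_squared_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X):
        return logistic_inhibition(np.asarray(X, dtype=float).reshape(-1),
                                   self.ic50_, self.hill_slope_)

    def result(self) -> IC50Result:
        return IC50Result(self.ic50_, self.hill_slope_, self.r_squared_)


def estimate_ic50(dose_response: pd.DataFrame) -> IC50Result:
    """IC50 from a table with columns inhibitor_M, inhibition_pct."""
    est = IC50Estimator().fit(
        dose_response["inhibitor_M"].to_numpy(),
        dose_response["inhibition_pct"].to_numpy(),
    )
    return est.result()


# ---------------------------------------------------------------------------
# Lineweaver-Burk
# ---------------------------------------------------------------------------

class LineweaverBurkRegressor(RegressorMixin, BaseEstimator):
    """OLS of 1/v on 1/[S]; Km_app = slope/intercept, Vmax_app = 1/intercept."""

    def fit(self, X, y):
        S = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if np.any(S <= 0):
            raise ValidationError("substrate concentrations must be > 0")
        zero = v <= 0
        if zero.any():
            warnings.warn(f"excluding {int(zero.sum())} zero-velocity points",
                          stacklevel=2)
            S, v = S[~zero], v[~zero]
        if np.unique(S).size < 3:
            raise PreconditionError("Lineweaver-Burk fit needs >= 3 distinct [S]")
        fit = stats.linregress(1.0 / S, 1.0 / v)
        if fit.intercept <= 0:
            raise FitDegenerateError("1/Vmax intercept <= 0: fit degenerate")
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.km_app_ = float(fit.slope / fit.intercept)
        self.vmax_app_ = float(1.0 / fit.intercept)
        self.r_squared_ = float(fit.rvalue**2)
        return self

    def predict(self, X):
        S = np.asarray(X, dtype=float).reshape(-1)
        return self.vmax_app_ * S / (self.km_app_ + S)


def fit_lineweaver(dataset: KineticDataset | pd.DataFrame,
                   inhibitor_conc: float = 0.0) -> LineweaverFit:
    """Double-reciprocal fit of one inhibitor level of a kinetic dataset."""
    if isinstance(dataset, KineticDataset):
        sub = dataset.subset(inhibitor_conc)
    else:
        sub = dataset[np.isclose(dataset["inhibitor_M"], inhibitor_conc)]
    if sub.empty:
        raise PreconditionError(f"no rows at inhibitor_M = {inhibitor_conc}")
    est = LineweaverBurkRegressor().fit(sub["substrate_M"].to_numpy(),
                                        sub["velocity"].to_numpy())
    return LineweaverFit(
        inhibitor_conc=float(inhibitor_conc),
        slope=est.slope_, intercept=est.intercept_,
        km_app=est.km_app_, vmax_app=est.vmax_app_,
        r_squared=est.r_squared_,
    )


def _rel_spread(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = np.abs(x).mean()
    return float((x.max() - x.min()) / m) if m > 0 else 0.0


def classify_mode(fits: list[LineweaverFit], tol: float = DEFAULT_TOL) -> str:
    """Inhibition mode from how Km_app/Vmax_app move across inhibitor levels."""
    if len(fits) < 3:
        raise PreconditionError("mode classification needs >= 3 inhibitor levels")
    fits = sorted(fits, key=lambda f: f.inhibitor_conc)
    if fits[0].inhibitor_conc != 0:
        raise PreconditionError("mode classification needs an [I] = 0 level")
    km = np.array([f.km_app for f in fits])
    vmax = np.array([f.vmax_app for f in fits])
    km_const = _rel_spread(km) <= tol
    vmax_const = _rel_spread(vmax) <= tol
    km_up = bool(np.all(np.diff(km) > 0)) and not km_const
    km_down = bool(np.all(np.diff(km) < 0)) and not km_const
    vmax_down = bool(np.all(np.diff(vmax) < 0)) and not vmax_const
    ratio_const = _rel_spread(km / vmax) <= tol
    if km_const and vmax_const:
        return "none"
    if vmax_const and km_up:
        return "competitive"
    if km_const and vmax_down:
        return "noncompetitive"
    if ratio_const and km_down and vmax_down:
        return "uncompetitive"
    return "mixed"


def fit_ki_secondary(fits: list[LineweaverFit],
                     tol: float = DEFAULT_TOL) -> InhibitionResult:
    """Ki and Km from the secondary plot of Km_app against [I].

    Km_app = (Km/Ki)*[I] + Km, so the line's intercept is Km and
    Ki = intercept/slope.  Requires a competitive-type rise of Km_app.
    """
    if len(fits) < 3:
        raise PreconditionError("secondary plot needs >= 3 inhibitor levels")
    fits = sorted(fits, key=lambda f: f.inhibitor_conc)
    I = np.array([f.inhibitor_conc for f in fits])
    km_app = np.array([f.km_app for f in fits])
    fit = stats.linregress(I, km_app)
    if fit.slope <= 0 or _rel_spread(km_app) <= tol:
        raise NoInhibitionError("Km_app does not increase with [I]; Ki undefined")
    mode = classify_mode(fits, tol=tol)
    km = float(fit.intercept)
    ki = float(fit.intercept / fit.slope)
    vmax = float(np.mean([f.vmax_app for f in fits]))
    return InhibitionResult(
        mode=mode, km=km, vmax=vmax, ki=ki,
        secondary_slope=float(fit.slope),
        secondary_intercept=km,
        secondary_r_squared=float(fit.rvalue**2),
        lineweaver_fits=list(fits),
    )


def analyze_kinetics(data: pd.DataFrame | KineticDataset,
                     tol: float = DEFAULT_TOL,
                     estimator: str = "lineweaver") -> InhibitionResult:
    """Full kinetic path: per-[I] Lineweaver-Burk fits, mode call, Ki.

    ``estimator="lineweaver"`` takes Km/Vmax/Ki from the double-reciprocal
    secondary plot; ``estimator="nonlinear"`` replaces them with the global
    nonlinear fit of the competitive rate law (robust when reciprocal noise
    amplification at strongly-inhibited levels distorts the transformed
    lines), keeping the per-level fits and mode call for diagnostics.
    For modes without a competitive component (where the secondary plot has
    no positive slope) Ki is reported as None.
    """
    if estimator not in ("lineweaver", "nonlinear"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    ds = data if isinstance(data, KineticDataset) else KineticDataset(data)
    levels = ds.inhibitor_levels()
    grids = [tuple(np.sort(ds.subset(i)["substrate_M"].unique())) for i in levels]
    if len(set(grids)) != 1:
        raise ValidationError("substrate grids differ across inhibitor levels")
    fits = [fit_lineweaver(ds, i) for i in levels]
    mode = classify_mode(fits, tol=tol)
    if mode in ("competitive", "mixed"):
        res = fit_ki_secondary(fits, tol=tol)
        res.mode = mode
        if estimator == "nonlinear":
            km, vmax, ki = fit_competitive_global(ds)
            res.km, res.vmax, res.ki = km, vmax, ki
        return res
    km0 = fits[0].km_app
    vmax0 = fits[0].vmax_app
    return InhibitionResult(
        mode=mode, km=km0, vmax=vmax0, ki=None,
        secondary_slope=0.0, secondary_intercept=km0,
        secondary_r_squared=float("nan"), lineweaver_fits=fits,
    )


def fit_michaelis_menten(S, v, p0=None):
    """Nonlinear least-squares (Km, Vmax) on the untransformed rate law."""
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if p0 is None:
        p0 = [np.median(S), v.max() * 1.5]
    popt, _ = optimize.curve_fit(
        lambda s, km, vmax: vmax * s / (km + s), S, v, p0=p0,
        bounds=([0, 0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14, maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def fit_competitive_global(data: pd.DataFrame | KineticDataset):
    """Global nonlinear (Km, Vmax, Ki) fit of the competitive rate law.

    Cross-check for the reciprocal-transform path; fits all inhibitor levels
    jointly.
    """
    df = data.data if isinstance(data, KineticDataset) else data
    S = df["substrate_M"].to_numpy(float)
    I = df["inhibitor_M"].to_numpy(float)
    v = df["velocity"].to_numpy(float)

    def model(X, km, vmax, ki):
        s, i = X
        return vmax * s / (km * (1 + i / ki) + s)

    p0 = [np.median(S), v.max() * 1.2, max(np.median(I[I > 0]), 1e-9) if (I > 0).any() else 1e-7]
    popt, _ = optimize.curve_fit(model, (S, I), v, p0=p0,
                                 bounds=([0, 0, 0], [np.inf] * 3),
                                 xtol=1e-14, ftol=1e-14, maxfev=50000)
    return float(popt[0]), float(popt[1]), float(popt[2])


# ---------------------------------------------------------------------------
# Reversibility diagnostic
# ---------------------------------------------------------------------------

def assess_reversibility(data: pd.DataFrame, tol_slope: float = DEFAULT_TOL
                         ) -> ReversibilityResult:
    """Irreversible vs reversible call from velocity-vs-enzyme lines per [I].

    Irreversible inactivation removes a fixed amount of enzyme, so v vs [E]
    lines at rising [I] stay parallel while their intercepts shift;
    reversible inhibition rescales the slope, so the lines fan out of the
    origin.
    """
    required = {"enzyme_UmL", "inhibitor_M", "velocity"}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"reversibility table missing columns: {sorted(missing)}")
    levels = np.sort(data["inhibitor_M"].unique())
    if levels.size < 2:
        raise PreconditionError("reversibility needs >= 2 inhibitor levels")
    slopes, intercepts, r2 = [], [], []
    for lvl in levels:
        sub = data[np.isclose(data["inhibitor_M"], lvl)]
        if sub["enzyme_UmL"].nunique() < 3:
            raise PreconditionError("each level needs >= 3 enzyme concentrations")
        fit = stats.linregress(sub["enzyme_UmL"].to_numpy(float),
                               sub["velocity"].to_numpy(float))
        slopes.append(float(fit.slope))
        intercepts.append(float(fit.intercept))
        r2.append(float(fit.rvalue**2))
    slopes_a = np.array(slopes)
    inter_a = np.array(intercepts)
    slope_cv = float(np.std(slopes_a) / np.abs(np.mean(slopes_a)))
    vscale = float(np.abs(data["velocity"]).max())
    inter_small = np.all(np.abs(inter_a) <= tol_slope * vscale)
    inter_mag = np.abs(inter_a)
    inter_monotone = bool(np.all(np.diff(inter_mag) >= -tol_slope * vscale)
                          and inter_mag[-1] > inter_mag[0] + tol_slope * vscale)
    slopes_down = bool(np.all(np.diff(slopes_a) < 0)
                       and slope_cv > tol_slope)

    if slope_cv <= tol_slope and inter_small and not inter_monotone:
        verdict = "indeterminate"          # identical lines: no inhibitor effect
    elif slope_cv <= tol_slope and inter_monotone:
        verdict = "irreversible"
    elif slopes_down and inter_small:
        verdict = "reversible"
    else:
        verdict = "indeterminate"
    return ReversibilityResult(
        inhibitor_levels=[float(x) for x in levels],
        slopes=slopes, intercepts=intercepts, r_squared=r2,
        slope_cv=slope_cv, verdict=verdict,
    )
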