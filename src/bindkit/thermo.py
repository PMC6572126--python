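"""Van't Hoff analysis of temperature-resolved association constants.

The binding constant of a 1:1 ligand-protein complex measured at several
temperatures is fit to the linear van't Hoff relation in decadic logs,

    lg Ka = -dH / (2.303 R T) + dS / (2.303 R),

giving the binding enthalpy dH (J/mol) from the slope and entropy dS
(J/mol/K) from the intercept; the Gibbs energy follows as dG = dH - T*dS.
The sign pattern of (dH, dS) classifies the dominant interaction following
the Ross-Subramanian convention: both positive -> hydrophobic; both negative
-> hydrogen bonds / van der Waals; dH ~ 0 with dS > 0 -> electrostatic.

Note on wording: dH > 0 is an endothermic binding; the module labels strictly
by sign.
"""

from __future__ import annotations

import math
from numbers import Real

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import ThermoResult
from .exceptions import PreconditionError

#: Gas constant, J/mol/K.
R_GAS = 8.314

#: ln(10) rounded as conventionally printed in the decadic van't Hoff form.
LOG10_FACTOR = 2.303

#: |dH| below this (J/mol) counts as "approximately athermal" for force calls.
DH_ZERO_THRESHOLD = 4.0e3


def predict_ka(dH: float, dS: float, T: float) -> float:
    """Association constant (L/mol) implied by (dH, dS) at temperature T (K)."""
    if T <= 0:
        raise PreconditionError("temperature must be > 0 K")
    lg_ka = -dH / (LOG10_FACTOR * R_GAS * T) + dS / (LOG10_FACTOR * R_GAS)
    return 10.0 ** lg_ka


def gibbs(dH: float, dS: float, T: float) -> float:
    """Gibbs free energy change dG = dH - T*dS (J/mol); negative = spontaneous."""
    if T <= 0:
        raise PreconditionError("temperature must be > 0 K")
    return dH - T * dS


def classify_forces(
    dH: float, dS: float, dh_zero_threshold: float = DH_ZERO_THRESHOLD
) -> str:
    """Dominant binding force from the signs of dH and dS (Ross rules)."""
    if abs(dH) < dh_zero_threshold and dS > 0:
        return "electrostatic"
    if dH > 0 and dS > 0:
        return "hydrophobic"
    if dH < 0 and dS < 0:
        return "hbond_vdw"
    return "indeterminate"


class VantHoffRegressor(RegressorMixin, BaseEstimator):
    """Linear van't Hoff fit of lg Ka on 1/T.

    Parameters
    ----------
    dh_zero_threshold : float
        |dH| (J/mol) below which the force classifier treats the binding as
        athermal.

    Attributes
    ----------
    dh_ : float
        Binding enthalpy, J/mol (= -2.303 R * slope).
    ds_ : float
        Binding entropy, J/mol/K (= 2.303 R * intercept).
    r_ : float
        Pearson correlation of the lg Ka vs 1/T line (nan for 2 points).
    dg_ : dict
        T (K) -> dG (J/mol) at each fitted temperature.
    force_class_ : str
    """

    def __init__(self, dh_zero_threshold: float = DH_ZERO_THRESHOLD):
        self.dh_zero_threshold = dh_zero_threshold

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).reshape(-1)
        ka = np.asarray(y, dtype=float).reshape(-1)
        if T.size != ka.size:
            raise PreconditionError("temperatures and Ka must have equal length")
        if T.size < 2:
            raise PreconditionError("van't Hoff fit needs at least 2 temperatures")
        if np.any(T <= 0):
            raise PreconditionError("temperatures must be > 0 K")
        if np.any(ka <= 0):
            raise PreconditionError("all Ka must be > 0")

        x = 1.0 / T
        lg_ka = np.log10(ka)
        if T.size == 2:
            slope = (lg_ka[1] - lg_ka[0]) / (x[1] - x[0])
            intercept = lg_ka[0] - slope * x[0]
            self.r_ = float("nan")
            self.low_confidence_ = True
        else:
            fit = stats.linregress(x, lg_ka)
            slope, intercept = fit.slope, fit.intercept
            self.r_ = float(fit.rvalue)
            self.low_confidence_ = False

        self.dh_ = float(-LOG10_FACTOR * R_GAS * slope)
        self.ds_ = float(LOG10_FACTOR * R_GAS * intercept)
        self.temperatures_ = T
        self.dg_ = {float(t): gibbs(self.dh_, self.ds_, float(t)) for t in T}
        self.force_class_ = classify_forces(self.dh_, self.ds_, self.dh_zero_threshold)
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return np.array([predict_ka(self.dh_, self.ds_, float(t)) for t in T])

    def result(self) -> ThermoResult:
        return ThermoResult(
            dH=self.dh_,
            dS=self.ds_,
            dG_per_T=dict(self.dg_),
            vant_hoff_r=self.r_,
            force_class=self.force_class_,
            spontaneous={t: g < 0 for t, g in self.dg_.items()},
            low_confidence=self.low_confidence_,
        )


def vant_hoff_fit(ka_by_temperature: dict) -> ThermoResult:
    """Fit lg Ka vs 1/T and return enthalpy, entropy, dG per T and force class.

    Parameters
    ----------
    ka_by_temperature : mapping
        Temperature (K) -> association constant Ka (L/mol).
    """
    if isinstance(ka_by_temperature, dict):
        items = sorted(ka_by_temperature.items())
        T = [t for t, _ in items]
        ka = [k for _, k in items]
    else:  # (T, Ka) pairs
        T, ka = zip(*ka_by_temperature)
    if len(T) < 2:
        raise PreconditionError("van't Hoff fit needs at least 2 temperatures")
    if not all(isinstance(t, Real) and math.isfinite(t) for t in T):
        raise PreconditionError("temperatures must be finite numbers")
    est = VantHoffRegressor().fit(np.asarray(T), np.asarray(ka))
    return est.result()
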