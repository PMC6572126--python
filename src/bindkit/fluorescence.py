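"""Fluorescence-quenching binding analysis and synchronous-shift detection.

A protein's intrinsic fluorescence is titrated with a quenching ligand.
After inner-filter correction (F_c = F_m * exp((A1 + A2)/2), with A1/A2 the
ligand absorbances at the excitation and emission wavelengths), three linear
analyses extract the binding picture at each temperature:

* Stern-Volmer, F0/F = 1 + K_SV [Q]: slope K_SV; the bimolecular quenching
  rate constant K_q = K_SV / tau0 against the diffusion limit
  2.0e10 L/mol/s separates static (ground-state complex) from dynamic
  (collisional) quenching.
* Modified Stern-Volmer, F0/(F0 - F) = 1/(f_a K_a [Q]) + 1/f_a: association
  constant K_a and accessible fraction f_a.
* Double-log, lg((F0 - F)/F) = lg K_b + n lg[Q]: apparent binding constant
  K_b and number of binding sites n.  (A paper-literal convention reading
  the intercept as n*lg K_b is selectable.)

Synchronous-fluorescence spectra at fixed excitation-emission offsets
(delta-lambda 15 nm -> tyrosine, 60 nm -> tryptophan) are scanned for peak
drift; a blue shift signals a more hydrophobic fluorophore environment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import QuenchResult, SyncShiftResult, TitrationSeries
from .exceptions import FitDegenerateError, PreconditionError, ValidationError

#: Default unquenched biomolecule fluorescence lifetime, s.
DEFAULT_TAU0 = 1.0e-8

#: Maximum diffusion-limited (scatter collision) quenching rate constant
#: for a biomacromolecule, L/mol/s.
KQ_DIFFUSION_LIMIT = 2.0e10

#: delta-lambda (nm) -> dominating fluorophore in synchronous scans.
RESIDUE_BY_DELTA = {15: "tyrosine", 60: "tryptophan"}


def inner_filter_correct(F_m, A1, A2):
    """Correct measured intensities for absorption of excitation and emission.

    F_c = F_m * exp((A1 + A2)/2).  Identity when A1 = A2 = 0.
    """
    F_m = np.asarray(F_m, dtype=float)
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    if np.any(A1 < 0) or np.any(A2 < 0):
        raise ValidationError("absorbances must be >= 0")
    out = F_m * np.exp((A1 + A2) / 2.0)
    return out if out.ndim else float(out)


def corrected_intensities(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray, bool]:
    """([Q], F_corrected, was_corrected) for a titration series.

    Applies the inner-filter correction whenever absorbances are present;
    otherwise returns the measured intensities flagged uncorrected.
    """
    q = series.points["quencher_M"].to_numpy(float)
    f = series.points["F"].to_numpy(float)
    if series.has_absorbances:
        f = inner_filter_correct(f, series.points["A1"].to_numpy(float),
                                 series.points["A2"].to_numpy(float))
        return q, np.asarray(f), True
    return q, f, False


def _split_series(series: TitrationSeries):
    q, f, corrected = corrected_intensities(series)
    f0 = float(f[q == 0][0])
    nz = q > 0
    return q[nz], f[nz], f0, corrected


class SternVolmerRegressor(RegressorMixin, BaseEstimator):
    """OLS of F0/F on [Q]; slope is K_SV, and K_q = K_SV/tau0.

    Attributes: ``ksv_`` (L/mol), ``kq_`` (L/mol/s), ``r_``, ``mechanism_``.
    """

    def __init__(self, tau0: float = DEFAULT_TAU0):
        self.tau0 = tau0

    def fit(self, X, y):
        """X: nonzero quencher concentrations (mol/L); y: F0/F ratios."""
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if self.tau0 <= 0:
            raise PreconditionError("tau0 must be > 0")
        if q.size < 3:
            raise PreconditionError("Stern-Volmer fit needs >= 3 nonzero [Q] points")
        self.enhanced_ = bool(np.median(ratio) < 1.0)
        if self.enhanced_:
            warnings.warn("systematic fluorescence enhancement: F > F0", stacklevel=2)
        fit = stats.linregress(q, ratio)
        self.ksv_ = float(fit.slope)
        self.kq_ = float(fit.slope / self.tau0)
        self.r_ = float(fit.rvalue)
        self.intercept_ = float(fit.intercept)
        self.mechanism_ = ("indeterminate" if self.enhanced_
                           else classify_quenching(self.kq_))
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.ksv_ * q


def stern_volmer_fit(series: TitrationSeries, tau0: float = DEFAULT_TAU0
                     ) -> tuple[float, float, float]:
    """(K_SV, K_q, r) from a titration series (inner-filter corrected)."""
    q, f, f0, _ = _split_series(series)
    est = SternVolmerRegressor(tau0=tau0).fit(q, f0 / f)
    return est.ksv_, est.kq_, est.r_


def classify_quenching(k_q: float) -> str:
    """Static vs dynamic from K_q against the diffusion limit 2.0e10 L/mol/s."""
    if k_q < 0:
        raise PreconditionError("K_q must be >= 0")
    if k_q > KQ_DIFFUSION_LIMIT:
        return "static"
    if k_q < KQ_DIFFUSION_LIMIT:
        return "dynamic"
    return "indeterminate"


class ModifiedSternVolmerRegressor(RegressorMixin, BaseEstimator):
    """OLS of F0/(F0-F) on 1/[Q]; f_a = 1/intercept, K_a = intercept/slope."""

    def fit(self, X, y):
        """X: nonzero quencher concentrations; y: F0/(F0 - F) ratios."""
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if q.size < 3:
            raise PreconditionError(
                "modified Stern-Volmer fit needs >= 3 nonzero [Q] points")
        fit = stats.linregress(1.0 / q, ratio)
        if fit.intercept <= 0:
            raise FitDegenerateError("1/f_a intercept <= 0: fit degenerate")
        self.fa_ = float(1.0 / fit.intercept)
        self.ka_ = float(fit.intercept / fit.slope)
        self.r_ = float(fit.rvalue)
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ / q


def modified_stern_volmer_fit(series: TitrationSeries) -> tuple[float, float, float]:
    """(K_a, f_a, r) via F0/(F0-F) = 1/(f_a K_a [Q]) + 1/f_a."""
    q, f, f0, _ = _split_series(series)
    keep = f < f0
    if not keep.all():
        warnings.warn("excluding points with F >= F0 at nonzero [Q]", stacklevel=2)
        q, f = q[keep], f[keep]
    est = ModifiedSternVolmerRegressor().fit(q, f0 / (f0 - f))
    return est.ka_, est.fa_, est.r_


class DoubleLogRegressor(RegressorMixin, BaseEstimator):
    """OLS of lg((F0-F)/F) on lg[Q]; slope = n, intercept -> K_b.

    convention="standard": intercept = lg K_b (K_b = 10**intercept).
    convention="paper":    intercept = n * lg K_b (K_b = 10**(intercept/n)).
    """

    def __init__(self, convention: str = "standard"):
        self.convention = convention

    def fit(self, X, y):
        """X: nonzero quencher concentrations; y: (F0 - F)/F ratios."""
        if self.convention not in ("standard", "paper"):
            raise ValidationError(f"unknown convention {self.convention!r}")
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        keep = ratio > 0
        if not keep.all():
            warnings.warn("excluding points with nonpositive (F0-F)/F", stacklevel=2)
            q, ratio = q[keep], ratio[keep]
        if q.size < 3:
            raise PreconditionError("double-log fit needs >= 3 usable points")
        fit = stats.linregress(np.log10(q), np.log10(ratio))
        self.n_ = float(fit.slope)
        if self.n_ <= 0:
            raise FitDegenerateError("binding-site slope n <= 0")
        lg_kb = fit.intercept if self.convention == "standard" else fit.intercept / self.n_
        self.kb_ = float(10.0 ** lg_kb)
        self.r_ = float(fit.rvalue)
        self.intercept_ = float(fit.intercept)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return 10.0 ** (self.intercept_ + self.n_ * np.log10(q))


def double_log_fit(series: TitrationSeries, convention: str = "standard"
                   ) -> tuple[float, float, float]:
    """(K_b, n, r) via lg((F0-F)/F) = lg K_b + n lg[Q]."""
    q, f, f0, _ = _split_series(series)
    est = DoubleLogRegressor(convention=convention).fit(q, (f0 - f) / f)
    return est.kb_, est.n_, est.r_


def analyze_titration(series: TitrationSeries, tau0: float = DEFAULT_TAU0,
                      convention: str = "standard") -> QuenchResult:
    """All three quenching/binding fits for one temperature in one result."""
    _, _, _, corrected = _split_series(series)
    ksv, kq, r_sv = stern_volmer_fit(series, tau0=tau0)
    ka, fa, r_msv = modified_stern_volmer_fit(series)
    kb, n, r_dl = double_log_fit(series, convention=convention)
    return QuenchResult(
        temperature=series.temperature,
        k_sv=ksv, k_q=kq, tau0=tau0,
        mechanism=classify_quenching(kq),
        k_a=ka, f_a=fa, k_b=kb, n=n,
        r_stern_volmer=r_sv, r_modified_sv=r_msv, r_double_log=r_dl,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Synchronous-fluorescence peak shifts
# ---------------------------------------------------------------------------

def _parabolic_peak(wl: np.ndarray, inten: np.ndarray) -> tuple[float, float]:
    """Sub-grid peak position and height by 3-point parabolic interpolation."""
    if np.ptp(inten) <= 1e-12 * max(abs(inten).max(), 1.0):
        raise ValidationError("flat spectrum: no peak to locate")
    k = int(np.argmax(inten))
    if k == 0 or k == inten.size - 1:
        return float(wl[k]), float(inten[k])
    y0, y1, y2 = inten[k - 1], inten[k], inten[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[k]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    step = wl[k + 1] - wl[k]
    return float(wl[k] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def detect_sync_shift(spectra: pd.DataFrame, delta_lambda: int,
                      flat_tol: float = 1e-9) -> SyncShiftResult:
    """Peak drift of a synchronous-fluorescence series across quencher levels.

    ``spectra`` columns: wavelength_nm, intensity, quencher_M; all quencher
    levels must share one wavelength grid.
    """
    if delta_lambda not in RESIDUE_BY_DELTA:
        raise ValidationError("delta_lambda must be 15 or 60 nm")
    required = {"wavelength_nm", "intensity", "quencher_M"}
    missing = required - set(spectra.columns)
    if missing:
        raise ValidationError(f"spectra table missing columns: {sorted(missing)}")
    levels = np.sort(spectra["quencher_M"].unique())
    if levels.size < 2:
        raise PreconditionError("shift detection needs >= 2 quencher levels")
    grids = {tuple(np.sort(spectra[spectra["quencher_M"] == q]["wavelength_nm"]))
             for q in levels}
    if len(grids) != 1:
        raise ValidationError("quencher levels use different wavelength grids")

    peaks, heights = [], []
    for q in levels:
        sub = spectra[spectra["quencher_M"] == q].sort_values("wavelength_nm")
        pos, h = _parabolic_peak(sub["wavelength_nm"].to_numpy(float),
                                 sub["intensity"].to_numpy(float))
        peaks.append(pos)
        heights.append(h)
    heights_a = np.array(heights)
    scale = max(abs(heights_a).max(), 1.0)
    dh = np.diff(heights_a)
    if np.all(np.abs(dh) <= flat_tol * scale):
        trend = "flat"
    elif np.all(dh < flat_tol * scale):
        trend = "decreasing"
    elif np.all(dh > -flat_tol * scale):
        trend = "increasing"
    else:
        trend = "flat"
    return SyncShiftResult(
        delta_lambda=int(delta_lambda),
        residue_label=RESIDUE_BY_DELTA[delta_lambda],
        peak_at_zero=peaks[0],
        peak_at_max=peaks[-1],
        shift=peaks[-1] - peaks[0],
        intensity_trend=trend,
    )
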