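"""In-memory containers shared across the analysis stages.

Tabular assay data travel as pandas DataFrames with canonical column names
(``substrate_M``, ``inhibitor_M``, ``enzyme_UmL``, ``velocity``,
``quencher_M``, ``temperature_K``, ``F``, ``A1``, ``A2``, ``wavelength_nm``,
``intensity``).  The dataclasses here hold fitted results with units recorded
in the field docstrings, and serialize losslessly through ``to_dict``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import PreconditionError, ValidationError


def _asdict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.generic):
            v = v.item()
        elif dataclasses.is_dataclass(v):
            v = _asdict(v)
        elif isinstance(v, (list, tuple)):
            v = [_asdict(x) if dataclasses.is_dataclass(x) else x for x in v]
        elif isinstance(v, dict):
            v = {str(k): (vv.item() if isinstance(vv, np.generic) else vv) for k, vv in v.items()}
        out[f.name] = v
    return out


@dataclass
class KineticDataset:
    """Velocities over a substrate x inhibitor grid.

    substrate_M and inhibitor_M in mol/L, velocity in a.u./min; enzyme_UmL
    (U/mL) is optional and only used by the reversibility diagnostic.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"substrate_M", "inhibitor_M", "velocity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"KineticDataset missing columns: {sorted(missing)}")
        if (self.data["substrate_M"] <= 0).any():
            raise ValidationError("substrate_M must be > 0 for double-reciprocal use")
        if (self.data["velocity"] < 0).any():
            raise ValidationError("velocity must be >= 0")

    def inhibitor_levels(self) -> np.ndarray:
        return np.sort(self.data["inhibitor_M"].unique())

    def subset(self, inhibitor_conc: float) -> pd.DataFrame:
        return self.data[np.isclose(self.data["inhibitor_M"], inhibitor_conc)]


@dataclass
class TitrationSeries:
    """Fluorescence readouts vs quencher concentration at one temperature.

    ``points`` columns: quencher_M (strictly increasing, first row 0), F
    (measured intensity, a.u.), optional A1/A2 (absorbance at excitation and
    emission wavelengths, AU).
    """

    temperature: float
    points: pd.DataFrame
    readout_wavelength: float = 340.0

    def __post_init__(self) -> None:
        required = {"quencher_M", "F"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValidationError(f"TitrationSeries missing columns: {sorted(missing)}")
        if self.temperature <= 0:
            raise ValidationError("temperature_K must be > 0")
        q = self.points["quencher_M"].to_numpy(float)
        if not np.any(q == 0):
            raise ValidationError("titration must include a quencher_M = 0 row")
        if np.sum(q == 0) > 1:
            raise ValidationError("exactly one quencher_M = 0 row is allowed")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("quencher_M must be strictly increasing")
        if (self.points["F"] <= 0).any():
            raise ValidationError("intensities must be > 0")

    @property
    def has_absorbances(self) -> bool:
        return {"A1", "A2"}.issubset(self.points.columns)


@dataclass
class LineweaverFit:
    """Double-reciprocal line at one inhibitor level."""

    inhibitor_conc: float          # mol/L
    slope: float                   # Km_app/Vmax_app
    intercept: float               # 1/Vmax_app
    km_app: float                  # mol/L
    vmax_app: float                # a.u./min
    r_squared: float

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class InhibitionResult:
    """Inhibition mode plus Km/Vmax/Ki from the secondary plot."""

    mode: str                      # competitive | noncompetitive | uncompetitive | mixed | none
    km: float                      # mol/L
    vmax: float                    # a.u./min
    ki: Optional[float]            # mol/L; None when mode does not define one
    secondary_slope: float         # Km/Ki, dimensionless
    secondary_intercept: float     # Km, mol/L
    secondary_r_squared: float
    lineweaver_fits: list[LineweaverFit] = field(default_factory=list)

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class IC50Result:
    ic50: float                    # mol/L
    hill_slope: float
    fit_r_squared: float

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class ReversibilityResult:
    """Velocity-vs-[E] line fits per inhibitor level and the verdict."""

    inhibitor_levels: list[float]
    slopes: list[float]
    intercepts: list[float]
    r_squared: list[float]
    slope_cv: float
    verdict: str                   # irreversible | reversible | indeterminate

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class QuenchResult:
    """Per-temperature quenching and binding constants."""

    temperature: float             # K
    k_sv: float                    # L/mol (Stern-Volmer slope)
    k_q: float                     # L/mol/s (= k_sv / tau0)
    tau0: float                    # s, unquenched fluorophore lifetime
    mechanism: str                 # static | dynamic | indeterminate
    k_a: float                     # L/mol, modified Stern-Volmer association constant
    f_a: float                     # accessible fraction
    k_b: float                     # L/mol, double-log apparent binding constant
    n: float                       # binding sites
    r_stern_volmer: float
    r_modified_sv: float
    r_double_log: float
    corrected: bool = True         # inner-filter correction applied?

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise PreconditionError("tau0 must be > 0")

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class ThermoResult:
    """Van't Hoff fit outputs and the binding-force call."""

    dH: float                      # J/mol
    dS: float                      # J/mol/K
    dG_per_T: dict[float, float]   # K -> J/mol
    vant_hoff_r: float
    force_class: str               # hydrophobic | hbond_vdw | electrostatic | indeterminate
    spontaneous: dict[float, bool]
    low_confidence: bool = False   # two-temperature fit (r undefined)

    def to_dict(self) -> dict:
        return _asdict(self)


@dataclass
class SyncShiftResult:
    """Synchronous-fluorescence peak drift between zero and maximal quencher."""

    delta_lambda: int              # 15 or 60 nm
    residue_label: str             # tyrosine (15) or tryptophan (60)
    peak_at_zero: float            # nm
    peak_at_max: float             # nm
    shift: float                   # nm, signed; negative = blue shift
    intensity_trend: str           # decreasing | increasing | flat

    def to_dict(self) -> dict:
        return _asdict(self)
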