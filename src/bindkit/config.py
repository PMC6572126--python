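"""Ground-truth simulation parameters.

:class:`SimulationConfig` holds every parameter the synthetic-assay generator
needs: the kinetic constants of a Michaelis-Menten enzyme with an inhibitor,
the logistic dose-response, the van't Hoff enthalpy/entropy that set the
temperature dependence of the association constant, inner-filter absorbance,
and the synchronous-fluorescence peak geometry.  Defaults reproduce the
conditions of a xanthine oxidase / chalcone-inhibitor titration study:
substrate (xanthine) 25-100 uM, inhibitor 0-0.8 uM, quencher 0-36.36 uM,
temperatures 298/304/310 K.

The same config + the same seed always generates bit-identical datasets.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

InhibitionMode = Literal["competitive", "noncompetitive", "uncompetitive", "mixed", "none"]

#: Mean quencher increment grid: 12 evenly spaced points from 0 to 36.36 uM.
_DEFAULT_QUENCHER = [round(x, 10) for x in np.linspace(0.0, 36.36e-6, 12)]


class SimulationConfig(BaseModel):
    """Ground truth, noise level and seed for every synthetic assay."""

    seed: int = 0

    # --- Michaelis-Menten kinetics with inhibitor ---
    km_true: float = Field(50e-6, gt=0, description="Michaelis constant, mol/L")
    vmax_true: float = Field(1.0, gt=0, description="Maximal velocity, a.u./min")
    ki_true: float = Field(0.46e-7, gt=0, description="Inhibition constant, mol/L")
    inhibition_mode: InhibitionMode = "competitive"
    mixed_alpha: float = Field(2.0, gt=0, description="Ki'/Ki ratio for mixed inhibition")

    # --- dose-response ---
    ic50_true: float = Field(2.93e-6, gt=0, description="IC50, mol/L")
    hill_slope: float = Field(1.0, gt=0)

    # --- binding thermodynamics (van't Hoff model for Ka(T)) ---
    dH_true: float = Field(103.45e3, description="Binding enthalpy, J/mol")
    dS_true: float = Field(427.94, description="Binding entropy, J/mol/K")

    # --- fluorescence titration ---
    f0: float = Field(1000.0, gt=0, description="Unquenched intensity, a.u.")
    fa_true: float = Field(1.0, gt=0, le=1.0, description="Accessible fraction")
    n_sites_true: float = Field(1.0, gt=0, description="Binding sites per protein")
    temperatures: list[float] = Field(default_factory=lambda: [298.0, 304.0, 310.0])
    inner_filter_slope: float = Field(
        1.0e4, ge=0, description="Absorbance (AU) per mol/L of quencher at 280/340 nm"
    )

    # --- concentration grids (mol/L except enzyme, U/mL) ---
    substrate_grid: list[float] = Field(
        default_factory=lambda: [25e-6, 37.5e-6, 50e-6, 75e-6, 100e-6]
    )
    inhibitor_grid: list[float] = Field(
        default_factory=lambda: [0.0, 0.2e-6, 0.4e-6, 0.8e-6]
    )
    dose_grid: list[float] = Field(
        default_factory=lambda: [0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6, 16e-6]
    )
    quencher_grid: list[float] = Field(default_factory=lambda: list(_DEFAULT_QUENCHER))
    enzyme_grid: list[float] = Field(
        default_factory=lambda: [0.006, 0.012, 0.018, 0.024, 0.030]
    )

    # --- noise ---
    noise_sd_rel: float = Field(0.02, ge=0, description="Relative Gaussian noise SD")

    # --- synchronous fluorescence geometry ---
    peak_centers: dict[int, float] = Field(
        default_factory=lambda: {15: 290.0, 60: 276.0},
        description="Zero-quencher peak position (nm) per delta-lambda",
    )
    peak_shift_per_conc: dict[int, float] = Field(
        default_factory=lambda: {15: -1.1e5, 60: -2.75e4},
        description="Peak drift, nm per mol/L of quencher, per delta-lambda",
    )
    peak_width_nm: float = Field(8.0, gt=0, description="Gaussian sigma of sync peaks")
    emission_peaks: list[float] = Field(
        default_factory=lambda: [340.0, 405.0],
        description="Emission-spectrum peak centers, nm",
    )

    @field_validator(
        "substrate_grid", "inhibitor_grid", "dose_grid", "quencher_grid", "enzyme_grid"
    )
    @classmethod
    def _nonnegative_concentrations(cls, v: list[float]) -> list[float]:
        if any(x < 0 for x in v):
            raise ValueError("concentrations must be >= 0")
        return v

    @field_validator("temperatures")
    @classmethod
    def _positive_kelvin(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("temperatures must be nonempty")
        if any(t <= 0 for t in v):
            raise ValueError("temperatures must be > 0 K")
        return v

    @model_validator(mode="after")
    def _substrate_positive(self) -> "SimulationConfig":
        if any(s <= 0 for s in self.substrate_grid):
            raise ValueError("substrate_grid must be strictly positive")
        return self

    def rng(self) -> np.random.Generator:
        """Fresh generator from the configured seed (determinism contract)."""
        return np.random.default_rng(self.seed)

    # --- serialization ---
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))
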