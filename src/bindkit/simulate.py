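"""Synthetic assay generator with known ground truth.

Every dataset the analysis stages consume can be generated here from a
:class:`~bindkit.config.SimulationConfig`, so each stage has a closed-loop
parameter-recovery test:

* ``simulate_kinetics`` — Michaelis-Menten velocities on a substrate x
  inhibitor grid under the configured inhibition mode;
* ``simulate_dose_response`` — logistic %inhibition vs inhibitor;
* ``simulate_reversibility`` — velocity vs enzyme concentration per
  inhibitor level, under an irreversible (parallel lines) or reversible
  (origin fan) ground truth;
* ``simulate_titration`` — static-quenching fluorescence titrations whose
  Ka(T) follows the van't Hoff relation of the configured (dH, dS), with
  inner-filter attenuation applied to the measured intensities;
* ``simulate_emission_spectra`` — full 300-500 nm emission spectra rendered
  as two Gaussian peaks (340/405 nm);
* ``simulate_synchronous`` — synchronous-fluorescence Gaussians whose
  center drifts linearly with quencher concentration.

Noise is multiplicative Gaussian (``noise_sd_rel``), clipped at physical
bounds; rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import KineticDataset, TitrationSeries
from .exceptions import PreconditionError, ValidationError
from .kinetics import logistic_inhibition, rate_law
from .thermo import predict_ka

#: Scan windows (nm) for synchronous fluorescence per delta-lambda.
SYNC_WINDOWS = {15: (260.0, 330.0), 60: (250.0, 330.0)}


def _noisy(values: np.ndarray, rng: np.random.Generator, sd_rel: float,
           lo: float | None = 0.0, hi: float | None = None) -> np.ndarray:
    if sd_rel > 0:
        values = values * (1.0 + rng.normal(0.0, sd_rel, size=values.shape))
    if lo is not None or hi is not None:
        values = np.clip(values, lo, hi)
    return values


def simulate_kinetics(config: SimulationConfig) -> KineticDataset:
    """Velocity table over the substrate x inhibitor grid."""
    if not config.substrate_grid or config.inhibitor_grid is None \
            or len(config.inhibitor_grid) == 0:
        raise PreconditionError("substrate_grid and inhibitor_grid must be nonempty")
    rng = config.rng()
    S, I = np.meshgrid(np.sort(config.substrate_grid),
                       np.sort(config.inhibitor_grid), indexing="ij")
    v = rate_law(S, I, config.km_true, config.vmax_true, config.ki_true,
                 mode=config.inhibition_mode, alpha=config.mixed_alpha)
    v = _noisy(v, rng, config.noise_sd_rel)
    df = pd.DataFrame({
        "substrate_M": S.ravel(),
        "inhibitor_M": I.ravel(),
        "velocity": v.ravel(),
    })
    return KineticDataset(df)


def simulate_dose_response(config: SimulationConfig) -> pd.DataFrame:
    """%inhibition vs inhibitor concentration from the logistic model."""
    if not config.dose_grid:
        raise PreconditionError("dose_grid must be nonempty")
    rng = config.rng()
    I = np.sort(np.asarray(config.dose_grid, dtype=float))
    pct = logistic_inhibition(I, config.ic50_true, config.hill_slope)
    pct = _noisy(pct, rng, config.noise_sd_rel, lo=0.0, hi=100.0)
    return pd.DataFrame({"inhibitor_M": I, "inhibition_pct": pct})


def simulate_reversibility(config: SimulationConfig,
                           truth: str = "irreversible") -> pd.DataFrame:
    """Velocity vs enzyme concentration per inhibitor level.

    ``truth="irreversible"``: v = s*([E] - e0([I])) with a common slope and
    an [I]-proportional loss of active enzyme (parallel lines).
    ``truth="reversible"``: v = s/(1 + [I]/Ki) * [E] (origin fan).
    """
    if truth not in ("irreversible", "reversible"):
        raise ValidationError(f"unknown reversibility ground truth {truth!r}")
    E = np.sort(np.asarray(config.enzyme_grid, dtype=float))
    levels = np.sort(np.asarray(config.inhibitor_grid, dtype=float))
    if E.size < 3:
        raise PreconditionError("enzyme_grid needs >= 3 levels")
    if levels.size < 2:
        raise PreconditionError("reversibility needs >= 2 inhibitor levels")
    rng = config.rng()
    # slope: activity per U/mL, scaled so v(max E, I=0) = vmax_true
    s = config.vmax_true / E.max()
    rows = []
    imax = levels.max() if levels.max() > 0 else 1.0
    for lvl in levels:
        if truth == "irreversible":
            # up to 80% of the lowest enzyme level titrated away at max [I],
            # keeping every velocity positive so the lines stay linear
            e0 = 0.8 * E.min() * (lvl / imax)
            v = s * np.maximum(E - e0, 0.0)
        else:
            v = s / (1.0 + lvl / config.ki_true) * E
        v = _noisy(v, rng, config.noise_sd_rel)
        rows.append(pd.DataFrame({
            "enzyme_UmL": E, "inhibitor_M": lvl, "velocity": v,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_titration(config: SimulationConfig) -> list[TitrationSeries]:
    """One static-quenching titration series per configured temperature.

    The true quenched intensity follows the pure-static limit
    F0/F = 1 + Ka(T)[Q] with Ka(T) from the van't Hoff (dH, dS); the
    measured intensity is then attenuated by the inverse inner-filter factor
    with A1 = A2 = inner_filter_slope * [Q].
    """
    if any(t <= 0 for t in config.temperatures):
        raise PreconditionError("temperatures must be > 0 K")
    q = np.sort(np.asarray(config.quencher_grid, dtype=float))
    if q.size == 0 or q[0] != 0.0:
        raise PreconditionError("quencher_grid must include 0")
    rng = config.rng()
    out = []
    for T in config.temperatures:
        ka = predict_ka(config.dH_true, config.dS_true, T)
        f_true = config.f0 / (1.0 + ka * q)
        A = config.inner_filter_slope * q
        f_meas = f_true * np.exp(-(A + A) / 2.0)
        f_meas = _noisy(f_meas, rng, config.noise_sd_rel, lo=1e-12)
        out.append(TitrationSeries(
            temperature=float(T),
            points=pd.DataFrame({
                "quencher_M": q, "F": f_meas, "A1": A, "A2": A,
            }),
        ))
    return out


def simulate_emission_spectra(config: SimulationConfig,
                              temperature: float | None = None) -> pd.DataFrame:
    """Full emission spectra (300-500 nm) as two Gaussian peaks per [Q]."""
    T = float(temperature if temperature is not None else config.temperatures[0])
    ka = predict_ka(config.dH_true, config.dS_true, T)
    q = np.sort(np.asarray(config.quencher_grid, dtype=float))
    wl = np.arange(300.0, 500.0 + 0.5, 0.5)
    rng = config.rng()
    rows = []
    for qi in q:
        quench = 1.0 / (1.0 + ka * qi)
        inten = np.zeros_like(wl)
        for center, amp in zip(config.emission_peaks, (1.0, 0.55)):
            inten += amp * config.f0 * quench * np.exp(
                -0.5 * ((wl - center) / (2.0 * config.peak_width_nm)) ** 2)
        inten = _noisy(inten, rng, config.noise_sd_rel, lo=0.0)
        rows.append(pd.DataFrame({
            "wavelength_nm": wl, "intensity": inten,
            "quencher_M": qi, "temperature_K": T,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_synchronous(config: SimulationConfig, delta_lambda: int
                         ) -> pd.DataFrame:
    """Synchronous-fluorescence Gaussian series whose center drifts with [Q]."""
    if delta_lambda not in SYNC_WINDOWS:
        raise ValidationError("delta_lambda must be 15 or 60 nm")
    lo, hi = SYNC_WINDOWS[delta_lambda]
    center0 = config.peak_centers[delta_lambda]
    shift = config.peak_shift_per_conc[delta_lambda]
    q = np.sort(np.asarray(config.quencher_grid, dtype=float))
    centers = center0 + shift * q
    margin = 2.0 * config.peak_width_nm
    if centers.min() < lo + margin or centers.max() > hi - margin:
        raise ValidationError(
            f"peak drifts outside the {lo}-{hi} nm scan window for "
            f"delta_lambda={delta_lambda}")
    ka = predict_ka(config.dH_true, config.dS_true, config.temperatures[0])
    wl = np.arange(lo, hi + 0.5, 0.5)
    rng = config.rng()
    rows = []
    for qi, c in zip(q, centers):
        amp = config.f0 / (1.0 + ka * qi)
        inten = amp * np.exp(-0.5 * ((wl - c) / config.peak_width_nm) ** 2)
        inten = _noisy(inten, rng, config.noise_sd_rel, lo=0.0)
        rows.append(pd.DataFrame({
            "wavelength_nm": wl, "intensity": inten,
            "quencher_M": qi, "delta_lambda_nm": delta_lambda,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write every assay as CSV plus a YAML sidecar of the config.

    Returns a mapping of assay name -> file path, the layout
    the pipeline reader expects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    kin = simulate_kinetics(config)
    kin.data.to_csv(out / "activity.csv", index=False)
    paths["activity"] = str(out / "activity.csv")

    simulate_dose_response(config).to_csv(out / "dose_response.csv", index=False)
    paths["dose"] = str(out / "dose_response.csv")

    simulate_reversibility(config).to_csv(out / "reversibility.csv", index=False)
    paths["reversibility"] = str(out / "reversibility.csv")

    tit = []
    for series in simulate_titration(config):
        df = series.points.copy()
        df.insert(1, "temperature_K", series.temperature)
        tit.append(df)
    pd.concat(tit, ignore_index=True).to_csv(out / "titration.csv", index=False)
    paths["titration"] = str(out / "titration.csv")

    sync = pd.concat([simulate_synchronous(config, d) for d in (15, 60)],
                     ignore_index=True)
    sync.to_csv(out / "synchronous.csv", index=False)
    paths["synchronous"] = str(out / "synchronous.csv")

    config.to_yaml(out / "config.yaml")
    paths["config"] = str(out / "config.yaml")
    return paths
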