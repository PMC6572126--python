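"""Table validation, pipeline orchestration and the structured report.

``run_pipeline`` executes every analysis stage whose input table exists —
dose-response IC50, Lineweaver-Burk mode/Ki, reversibility, per-temperature
quenching/binding fits, van't Hoff thermodynamics (from the fitted Ka values),
and synchronous-shift detection — and collects the results, stage statuses
and provenance (input hashes, software version, seed) into one JSON-ready
report.  Stages with missing inputs are marked "skipped"; a stage error is
recorded without aborting the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import KineticDataset, TitrationSeries
from .exceptions import BindkitError, ValidationError
from .fluorescence import DEFAULT_TAU0, analyze_titration, detect_sync_shift
from .kinetics import analyze_kinetics, assess_reversibility, estimate_ic50
from .thermo import vant_hoff_fit

logger = logging.getLogger("bindkit")

#: Unit-suffix factors for concentration columns; canonical suffix is _M.
_UNIT_FACTORS = {"_M": 1.0, "_mM": 1e-3, "_uM": 1e-6, "_nM": 1e-9}

#: schema name -> (required columns, optional columns)
SCHEMAS = {
    "activity": ({"substrate_M", "inhibitor_M", "velocity"}, {"enzyme_UmL"}),
    "dose": ({"inhibitor_M", "inhibition_pct"}, set()),
    "reversibility": ({"enzyme_UmL", "inhibitor_M", "velocity"}, set()),
    "titration": ({"quencher_M", "temperature_K", "F"}, {"A1", "A2"}),
    "synchronous": ({"wavelength_nm", "intensity", "quencher_M"},
                    {"delta_lambda_nm", "temperature_K"}),
}

_CONC_COLUMNS = ("substrate", "inhibitor", "quencher")


def _coerce_units(df: pd.DataFrame) -> pd.DataFrame:
    """Rename concentration columns with unit suffixes to mol/L."""
    renames = {}
    for col in df.columns:
        for stem in _CONC_COLUMNS:
            for suffix, factor in _UNIT_FACTORS.items():
                if col == stem + suffix and suffix != "_M":
                    df[col] = df[col] * factor
                    renames[col] = stem + "_M"
    return df.rename(columns=renames)


def validate_table(path, schema_name: str) -> pd.DataFrame:
    """Read a CSV, check headers against the schema, coerce units, validate.

    Raises :class:`ValidationError` naming the offending column.
    """
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    required, optional = SCHEMAS[schema_name]
    df = _coerce_units(pd.read_csv(path))
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{schema_name} table {path.name} missing columns: {sorted(missing)}")
    unknown = set(df.columns) - required - optional
    if unknown:
        raise ValidationError(
            f"{schema_name} table {path.name} has unknown columns: {sorted(unknown)}")
    for col in df.columns:
        if col.endswith("_M") or col in ("enzyme_UmL",):
            if (df[col] < 0).any():
                raise ValidationError(f"negative values in column {col!r}")
    if df.duplicated().any():
        raise ValidationError(f"{schema_name} table {path.name} has duplicate rows")
    if schema_name == "titration":
        for T, grp in df.groupby("temperature_K"):
            if not (grp["quencher_M"] == 0).any():
                raise ValidationError(
                    f"titration at {T} K missing the quencher_M = 0 row")
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _titration_series(df: pd.DataFrame) -> list[TitrationSeries]:
    out = []
    for T, grp in df.groupby("temperature_K"):
        cols = ["quencher_M", "F"] + [c for c in ("A1", "A2") if c in grp.columns]
        pts = grp.sort_values("quencher_M")[cols].reset_index(drop=True)
        out.append(TitrationSeries(temperature=float(T), points=pts))
    return sorted(out, key=lambda s: s.temperature)


def run_pipeline(inputs: dict, tau0: float = DEFAULT_TAU0,
                 convention: str = "standard", seed: int | None = None) -> dict:
    """Run every stage whose input path is present; return the report dict.

    ``inputs`` maps assay names (``dose``, ``activity``, ``reversibility``,
    ``titration``, ``synchronous``) to CSV paths.
    """
    if not inputs:
        raise ValidationError("at least one assay table is required")
    report: dict = {
        "stages": {},
        "provenance": {
            "software": f"bindkit {__version__}",
            "seed": seed,
            "tau0_s": tau0,
            "eq3_convention": convention,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                       for k, v in inputs.items() if Path(str(v)).exists()},
        },
    }
    errors = 0

    def _run(name: str, fn):
        nonlocal errors
        try:
            result = fn()
            report["stages"][name] = {"status": "ok", "result": result}
            logger.info("stage %s: %s", name, json.dumps(result, default=str)[:400])
        except BindkitError as exc:
            errors += 1
            report["stages"][name] = {"status": "error", "error": str(exc)}
            logger.error("stage %s failed: %s", name, exc)

    if "dose" in inputs:
        _run("ic50", lambda: estimate_ic50(validate_table(inputs["dose"], "dose")
                                           ).to_dict())
    else:
        report["stages"]["ic50"] = {"status": "skipped"}

    if "activity" in inputs:
        _run("inhibition", lambda: analyze_kinetics(
            KineticDataset(validate_table(inputs["activity"], "activity"))).to_dict())
    else:
        report["stages"]["inhibition"] = {"status": "skipped"}

    if "reversibility" in inputs:
        _run("reversibility", lambda: assess_reversibility(
            validate_table(inputs["reversibility"], "reversibility")).to_dict())
    else:
        report["stages"]["reversibility"] = {"status": "skipped"}

    quench_results = []
    if "titration" in inputs:
        def _quench():
            series = _titration_series(validate_table(inputs["titration"], "titration"))
            for s in series:
                quench_results.append(analyze_titration(s, tau0=tau0,
                                                        convention=convention))
            return [qr.to_dict() for qr in quench_results]
        _run("quenching", _quench)
    else:
        report["stages"]["quenching"] = {"status": "skipped"}

    if len(quench_results) >= 2:
        _run("thermodynamics", lambda: vant_hoff_fit(
            {qr.temperature: qr.k_a for qr in quench_results}).to_dict())
    else:
        report["stages"]["thermodynamics"] = {"status": "skipped"}

    if "synchronous" in inputs:
        def _sync():
            df = validate_table(inputs["synchronous"], "synchronous")
            out = []
            if "delta_lambda_nm" in df.columns:
                for d, grp in df.groupby("delta_lambda_nm"):
                    out.append(detect_sync_shift(grp, int(d)).to_dict())
            else:
                out.append(detect_sync_shift(df, 15).to_dict())
            return out
        _run("synchronous", _sync)
    else:
        report["stages"]["synchronous"] = {"status": "skipped"}

    report["n_errors"] = errors
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def summarize(report: dict) -> str:
    """Human-readable one-screen summary of a pipeline report."""
    lines = ["bindkit pipeline report", "=" * 23]
    for name, stage in report["stages"].items():
        status = stage["status"]
        if status != "ok":
            lines.append(f"{name:15s} {status}")
            continue
        r = stage["result"]
        if name == "ic50":
            lines.append(f"{name:15s} IC50 = {r['ic50']:.3g} mol/L "
                         f"(hill {r['hill_slope']:.2f})")
        elif name == "inhibition":
            ki = r["ki"]
            ki_s = f", Ki = {ki:.3g} mol/L" if ki is not None else ""
            lines.append(f"{name:15s} mode = {r['mode']}, Km = {r['km']:.3g} mol/L, "
                         f"Vmax = {r['vmax']:.3g}{ki_s}")
        elif name == "reversibility":
            lines.append(f"{name:15s} verdict = {r['verdict']} "
                         f"(slope CV {r['slope_cv']:.3f})")
        elif name == "quenching":
            for qr in r:
                lines.append(
                    f"{name:15s} T={qr['temperature']:.0f}K  "
                    f"K_SV={qr['k_sv']:.3g}  K_q={qr['k_q']:.3g} ({qr['mechanism']})  "
                    f"K_a={qr['k_a']:.3g}  n={qr['n']:.2f}")
        elif name == "thermodynamics":
            lines.append(f"{name:15s} dH = {r['dH']/1e3:.2f} kJ/mol, "
                         f"dS = {r['dS']:.2f} J/mol/K, force = {r['force_class']}")
        elif name == "synchronous":
            for sr in r:
                lines.append(f"{name:15s} dλ={sr['delta_lambda']}nm "
                             f"({sr['residue_label']}): shift {sr['shift']:+.2f} nm, "
                             f"intensity {sr['intensity_trend']}")
    return "\n".join(lines)
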