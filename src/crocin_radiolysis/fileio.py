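"""Plain-text file formats for traces, spectra, dose series, line lists,
thermochemistry records and MC trajectories.

All formats are delimited text: leading ``# key=value`` metadata lines
followed by a CSV table, so files stay diff-able and readable in any
editor.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticTrace
from .mc_conformers import Trajectory
from .spectral_calibration import Spectrum
from .spectrum_synthesis import LineEnsemble
from .thermochem import ThermoRecord

__all__ = [
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "read_dose_series",
    "write_dose_series",
    "read_linelist",
    "write_linelist",
    "read_thermo_record",
    "write_thermo_record",
    "write_trajectory",
]


def _split_meta(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            if value:
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    table = pd.read_csv(io.StringIO("\n".join(body)))
    return meta, table


def _write_with_meta(path: str | Path, meta: dict[str, object], table: pd.DataFrame) -> None:
    lines = [f"# {k}={v}" for k, v in meta.items() if v is not None]
    Path(path).write_text("\n".join(lines) + "\n" + table.to_csv(index=False))


def write_trace(path: str | Path, trace: KineticTrace) -> None:
    _write_with_meta(
        path,
        {"wavelength_nm": trace.wavelength_nm, "path_cm": trace.path_cm},
        pd.DataFrame({"time_s": trace.times_s, "absorbance": trace.absorbance}),
    )


def read_trace(path: str | Path) -> KineticTrace:
    meta, table = _split_meta(path)
    return KineticTrace(
        table["time_s"].to_numpy(),
        table["absorbance"].to_numpy(),
        wavelength_nm=float(meta.get("wavelength_nm", "nan")),
        path_cm=float(meta.get("path_cm", 1.0)),
    )


def write_spectrum(path: str | Path, spectrum: Spectrum, dose_gy: float | None = None) -> None:
    _write_with_meta(
        path,
        {
            "kind": spectrum.kind,
            "path_cm": spectrum.path_cm,
            "species": spectrum.species,
            "dose_Gy": dose_gy,
        },
        pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm, "value": spectrum.values}),
    )


def read_spectrum(path: str | Path) -> Spectrum:
    meta, table = _split_meta(path)
    return Spectrum(
        table["wavelength_nm"].to_numpy(),
        table["value"].to_numpy(),
        kind=meta.get("kind", "absorbance"),
        path_cm=float(meta["path_cm"]) if "path_cm" in meta else None,
        species=meta.get("species"),
    )


def write_dose_series(
    path: str | Path, series: dict[float, Spectrum], path_cm: float | None = None
) -> None:
    """Wide table: wavelength_nm, dose_<D> columns (absorbance per dose)."""
    doses = sorted(series)
    grid = series[doses[0]].wavelength_nm
    data = {"wavelength_nm": grid}
    for d in doses:
        spec = series[d]
        if not np.allclose(spec.wavelength_nm, grid):
            raise ValueError("dose series spectra must share a grid to be tabulated")
        data[f"dose_{d:g}"] = spec.values
        if path_cm is None:
            path_cm = spec.path_cm
    _write_with_meta(path, {"kind": "absorbance", "path_cm": path_cm}, pd.DataFrame(data))


def read_dose_series(path: str | Path) -> dict[float, Spectrum]:
    meta, table = _split_meta(path)
    grid = table["wavelength_nm"].to_numpy()
    path_cm = float(meta["path_cm"]) if "path_cm" in meta else None
    out: dict[float, Spectrum] = {}
    for col in table.columns:
        if col.startswith("dose_"):
            dose = float(col[len("dose_"):])
            out[dose] = Spectrum(
                grid, table[col].to_numpy(), kind="absorbance", path_cm=path_cm
            )
    return out


def write_linelist(path: str | Path, ensemble: LineEnsemble) -> None:
    _write_with_meta(
        path,
        {
            "ground_s2": ensemble.ground_s2,
            "species": ensemble.species,
            "total_steps": ensemble.total_steps,
            "burn_in": ensemble.burn_in,
            "stride": ensemble.stride,
        },
        ensemble.lines,
    )


def read_linelist(path: str | Path) -> LineEnsemble:
    meta, table = _split_meta(path)
    return LineEnsemble(
        table,
        ground_s2=float(meta["ground_s2"]),
        species=meta.get("species", ""),
        total_steps=int(meta.get("total_steps", 0)),
        burn_in=int(meta.get("burn_in", 0)),
        stride=int(meta.get("stride", 1)),
    )


def write_thermo_record(path: str | Path, record: ThermoRecord) -> None:
    table = pd.DataFrame(
        [
            {
                "label": record.label,
                "delta_g_pcm_ev": record.delta_g_pcm_ev,
                "delta_g_gas_ev": record.delta_g_gas_ev,
                "delta_h_gas_ev": record.delta_h_gas_ev,
                "temperature_k": record.temperature_k,
            }
        ]
    )
    _write_with_meta(path, {}, table)


def read_thermo_record(path: str | Path) -> ThermoRecord:
    _, table = _split_meta(path)
    row = table.iloc[0]
    return ThermoRecord(
        delta_g_pcm_ev=float(row["delta_g_pcm_ev"]),
        delta_g_gas_ev=float(row["delta_g_gas_ev"]),
        delta_h_gas_ev=float(row["delta_h_gas_ev"]),
        temperature_k=float(row["temperature_k"]),
        label=str(row["label"]),
    )


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    table = pd.DataFrame(
        {
            "step": [r.step for r in trajectory.records],
            "conformer": [r.conformer for r in trajectory.records],
            "energy_ev": [r.energy_ev for r in trajectory.records],
        }
    )
    meta = {
        "seed": trajectory.settings.seed,
        "steps": trajectory.settings.steps,
        "burn_in": trajectory.settings.burn_in,
        "stride": trajectory.settings.stride,
        "temperature_k": trajectory.settings.temperature_k,
    }
    _write_with_meta(path, meta, table)
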