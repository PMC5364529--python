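"""Tabular readers/writers and fit-report serialization.

All tabular formats are comma-separated UTF-8 with optional ``#``-prefixed
metadata/provenance header lines (``# key=value``).  Schemas:

* titration: wide format — first column ``denaturant``, one column per
  wavelength, header row of wavelength labels;
* kinetic trace: ``time,signal`` with ``# denaturant=``, ``# dead_time=``;
* chevron: ``phase,branch,denaturant,k_obs``;
* melt: ``temperature_C,signal``;
* ITC: ``injection_volume_uL,heat_ucal`` with concentration/temperature
  metadata;
* HDX: long format ``residue,time,intensity`` (optional ``label`` column).

Fit reports are flat JSON records that round-trip without loss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import BindingThermo, ITCIsotherm
from .equilibrium import TitrationSeries, TwoStateEqParams
from .exceptions import DataError
from .hdx import ResidueExchangeSeries
from .kinetics import ChevronDataset, ChevronFit, KineticTrace
from .thermal import MeltCurve

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_trace_csv", "write_trace_csv",
    "read_chevron_csv", "write_chevron_csv",
    "read_melt_csv", "write_melt_csv",
    "read_itc_csv", "write_itc_csv",
    "read_hdx_csv", "write_hdx_csv",
    "read_fasta_sequence",
    "write_report", "read_report",
]


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path, required: list) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    for col in required:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if not bad.empty and col not in ("branch", "label"):
            raise DataError(
                f"{path}: non-numeric value in column '{col}' at row "
                f"{bad.index[0] + 1}"
            )
    return df


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


# -- titration --------------------------------------------------------------

def read_titration_csv(path, probe: str = "fluorescence") -> TitrationSeries:
    df = _read_table(path, ["denaturant"])
    channels = [c for c in df.columns if c != "denaturant"]
    if not channels:
        raise DataError(f"{path}: no wavelength columns")
    mat = df[channels].to_numpy(dtype=float).T
    return TitrationSeries(
        denaturant_concs=df["denaturant"].to_numpy(dtype=float),
        channels=channels,
        signal_matrix=mat,
        probe=probe,
        label=Path(path).stem,
    )


def write_titration_csv(path, series: TitrationSeries) -> None:
    df = pd.DataFrame(series.signal_matrix.T, columns=list(series.channels))
    df.insert(0, "denaturant", series.denaturant_concs)
    _write_with_meta(path, df, {"probe": series.probe})


# -- kinetic traces ---------------------------------------------------------

def read_trace_csv(path) -> KineticTrace:
    meta = _read_metadata(path)
    df = _read_table(path, ["time", "signal"])
    return KineticTrace(
        times=df["time"].to_numpy(dtype=float),
        signal=df["signal"].to_numpy(dtype=float),
        final_denaturant=float(meta.get("denaturant", 0.0)),
        dead_time=float(meta.get("dead_time", 2e-3)),
        source=meta.get("source", "stopped-flow"),
    )


def write_trace_csv(path, trace: KineticTrace) -> None:
    df = pd.DataFrame({"time": trace.times, "signal": trace.signal})
    _write_with_meta(path, df, {
        "denaturant": trace.final_denaturant,
        "dead_time": trace.dead_time,
        "source": trace.source,
    })


# -- chevron ----------------------------------------------------------------

def read_chevron_csv(path, phase: int | None = None) -> ChevronDataset:
    df = _read_table(path, ["phase", "branch", "denaturant", "k_obs"])
    if phase is not None:
        df = df[df["phase"] == phase]
        if df.empty:
            raise DataError(f"{path}: no rows for phase {phase}")
    return ChevronDataset(
        denaturant=df["denaturant"].to_numpy(dtype=float),
        k_obs=df["k_obs"].to_numpy(dtype=float),
        branch=list(df["branch"]),
        phase_label=int(df["phase"].iloc[0]),
    )


def write_chevron_csv(path, dataset: ChevronDataset) -> None:
    df = pd.DataFrame({
        "phase": dataset.phase_label,
        "branch": list(dataset.branch),
        "denaturant": dataset.denaturant,
        "k_obs": dataset.k_obs,
    })
    _write_with_meta(path, df, {})


# -- melts ------------------------------------------------------------------

def read_melt_csv(path) -> MeltCurve:
    meta = _read_metadata(path)
    df = _read_table(path, ["temperature_C", "signal"])
    return MeltCurve(
        temperatures=df["temperature_C"].to_numpy(dtype=float) + 273.15,
        signal=df["signal"].to_numpy(dtype=float),
        wavelength_nm=float(meta.get("wavelength", 215.0)),
        ligand_label=meta.get("ligand") or None,
    )


def write_melt_csv(path, curve: MeltCurve) -> None:
    df = pd.DataFrame({
        "temperature_C": curve.temperatures - 273.15,
        "signal": curve.signal,
    })
    meta = {"wavelength": curve.wavelength_nm}
    if curve.ligand_label:
        meta["ligand"] = curve.ligand_label
    _write_with_meta(path, df, meta)


# -- ITC --------------------------------------------------------------------

def read_itc_csv(path) -> ITCIsotherm:
    meta = _read_metadata(path)
    df = _read_table(path, ["injection_volume_uL", "heat_ucal"])
    required_meta = ["cell_concentration_uM", "syringe_concentration_uM",
                     "cell_volume_uL", "temperature_K"]
    missing = [k for k in required_meta if k not in meta]
    if missing:
        raise DataError(f"{path}: missing metadata line(s) {missing}")
    return ITCIsotherm(
        cell_concentration=float(meta["cell_concentration_uM"]),
        syringe_concentration=float(meta["syringe_concentration_uM"]),
        cell_volume=float(meta["cell_volume_uL"]),
        injection_volumes=df["injection_volume_uL"].to_numpy(dtype=float),
        heats=df["heat_ucal"].to_numpy(dtype=float),
        temperature=float(meta["temperature_K"]),
    )


def write_itc_csv(path, iso: ITCIsotherm) -> None:
    df = pd.DataFrame({
        "injection_volume_uL": iso.injection_volumes,
        "heat_ucal": iso.heats,
    })
    _write_with_meta(path, df, {
        "cell_concentration_uM": iso.cell_concentration,
        "syringe_concentration_uM": iso.syringe_concentration,
        "cell_volume_uL": iso.cell_volume,
        "temperature_K": iso.temperature,
    })


# -- HDX --------------------------------------------------------------------

def read_hdx_csv(path, sequence: str | None = None) -> list:
    df = _read_table(path, ["residue", "time", "intensity"])
    out = []
    for res, grp in df.groupby("residue"):
        grp = grp.sort_values("time")
        label = ""
        if "label" in grp.columns:
            label = str(grp["label"].iloc[0])
        elif sequence is not None and 1 <= int(res) <= len(sequence):
            label = sequence[int(res) - 1]
        out.append(ResidueExchangeSeries(
            residue_index=int(res),
            residue_label=label,
            times=grp["time"].to_numpy(dtype=float),
            intensities=grp["intensity"].to_numpy(dtype=float),
        ))
    return out


def write_hdx_csv(path, series_list) -> None:
    rows = []
    for s in series_list:
        for t, i in zip(s.times, s.intensities):
            rows.append({"residue": s.residue_index, "label": s.residue_label,
                         "time": t, "intensity": i})
    _write_with_meta(path, pd.DataFrame(rows), {})


def read_fasta_sequence(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return str(records[0].seq)


# -- fit reports ------------------------------------------------------------

_DERIVED = {
    ChevronFit: ("dg", "m_kin", "d50"),
    TwoStateEqParams: ("d50",),
    BindingThermo: ("dg", "tds", "kd"),
}


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def write_report(result, path, status: str = "converged") -> dict:
    """Serialize a fit result to a flat JSON record and return the record.

    Failed fits are written with ``status: non-converged`` and no parameter
    block.  Derived quantities (ΔG, m_kin, [D]50%, TΔS, K_D) are included
    for the types that define them.
    """
    record = {"type": type(result).__name__, "status": status}
    if status == "converged":
        record.update(_to_jsonable(result))
        for cls, props in _DERIVED.items():
            if isinstance(result, cls):
                for prop in props:
                    record[prop] = _to_jsonable(getattr(result, prop))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_to_jsonable)
        fh.write("\n")
    return record


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
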