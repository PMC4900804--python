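"""Tabular I/O, run configuration and machine-readable fit reports.

CSV dialects (header row mandatory, units encoded in column names):

=============  ==============================================================
kind           columns
=============  ==============================================================
dissociation   experiment_id, time_min, y, modulator_conc_M
modulation     experiment_id, conc_M, y [, radioligand_conc_M]
saturation     experiment_id, conc_M, y
spectra        wavelength_nm, <one intensity column per cell>
references     wavelength_nm, em_d, em_a [, em_b]
tcspc          bin_time_ns, counts_par, counts_perp, irf_par, irf_perp
=============  ==============================================================

Reports are JSON: every fitted parameter with its standard error, the
sum of squares, degrees of freedom and any model-comparison tests, plus the
seed and a configuration hash so a run can be reproduced byte-for-byte
(timestamps live in a sidecar ``.log`` file, not in the artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__ as _pkg_version
from .datasets import (DecayHistogram, DissociationTrace, EmissionSpectrum,
                       ModulationCurve, ReferenceSpectra, SaturationCurve)
from .exceptions import ParseError

__all__ = ["RunConfig", "read_table", "write_table", "write_report",
           "config_hash"]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "."
    concentration_unit: str = "M"          # "M" or "log10M" for affinities
    tolerances: dict[str, float] = {}
    parameters: dict[str, dict] = {}       # per-subcommand blocks

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_table(path, kind: str):
    """Read a CSV of the given kind into typed dataset objects."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:                       # malformed file
        raise ParseError(f"{path}: {exc}") from exc
    if kind == "dissociation":
        _require(df, ["experiment_id", "time_min", "y", "modulator_conc_M"], path)
        out = []
        for (eid, conc), grp in df.groupby(["experiment_id", "modulator_conc_M"],
                                           sort=False):
            grp = grp.sort_values("time_min")
            out.append(DissociationTrace(times=grp["time_min"].to_numpy(),
                                         bound=grp["y"].to_numpy(),
                                         modulator_conc=float(conc),
                                         experiment_id=str(eid)))
        return out
    if kind == "modulation":
        _require(df, ["experiment_id", "conc_M", "y"], path)
        out = []
        for eid, grp in df.groupby("experiment_id", sort=False):
            rl = (float(grp["radioligand_conc_M"].iloc[0])
                  if "radioligand_conc_M" in grp else None)
            out.append(ModulationCurve(modulator_conc=grp["conc_M"].to_numpy(),
                                       response=grp["y"].to_numpy(),
                                       radioligand_conc=rl,
                                       experiment_id=str(eid)))
        return out
    if kind == "saturation":
        _require(df, ["experiment_id", "conc_M", "y"], path)
        return [SaturationCurve(ligand_conc_total=grp["conc_M"].to_numpy(),
                                bound=grp["y"].to_numpy(),
                                experiment_id=str(eid))
                for eid, grp in df.groupby("experiment_id", sort=False)]
    if kind == "spectra":
        _require(df, ["wavelength_nm"], path)
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        cells = [c for c in df.columns if c != "wavelength_nm"]
        if not cells:
            raise ParseError(f"{path}: no per-cell intensity columns")
        return [EmissionSpectrum(wavelengths=wl,
                                 intensities=df[c].to_numpy(dtype=float),
                                 cell_id=str(c)) for c in cells]
    if kind == "references":
        _require(df, ["wavelength_nm", "em_d", "em_a"], path)
        em_b = df["em_b"].to_numpy(dtype=float) if "em_b" in df else None
        return ReferenceSpectra(wavelengths=df["wavelength_nm"].to_numpy(float),
                                em_d=df["em_d"].to_numpy(float),
                                em_a=df["em_a"].to_numpy(float), em_b=em_b)
    if kind == "tcspc":
        cols = ["bin_time_ns", "counts_par", "counts_perp", "irf_par",
                "irf_perp"]
        _require(df, cols, path)
        period = 12.5
        if "period_ns" in df.columns:
            period = float(df["period_ns"].iloc[0])
        return DecayHistogram(bin_times=df["bin_time_ns"].to_numpy(float),
                              counts_par=df["counts_par"].to_numpy(float),
                              counts_perp=df["counts_perp"].to_numpy(float),
                              irf_par=df["irf_par"].to_numpy(float),
                              irf_perp=df["irf_perp"].to_numpy(float),
                              period=period)
    raise ParseError(f"unknown table kind {kind!r}")


def write_table(objects, path, kind: str) -> None:
    """Serialise dataset objects back to the CSV dialect ``read_table`` reads."""
    path = Path(path)
    if kind == "dissociation":
        rows = [{"experiment_id": tr.experiment_id, "time_min": t, "y": y,
                 "modulator_conc_M": tr.modulator_conc}
                for tr in objects for t, y in zip(tr.times, tr.bound)]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "modulation":
        rows = []
        for cu in objects:
            for a, y in zip(cu.modulator_conc, cu.response):
                row = {"experiment_id": cu.experiment_id, "conc_M": a, "y": y}
                if cu.radioligand_conc is not None:
                    row["radioligand_conc_M"] = cu.radioligand_conc
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "saturation":
        rows = [{"experiment_id": cu.experiment_id, "conc_M": p, "y": y}
                for cu in objects for p, y in zip(cu.ligand_conc_total, cu.bound)]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "spectra":
        df = pd.DataFrame({"wavelength_nm": objects[0].wavelengths})
        for sp in objects:
            df[sp.cell_id] = sp.intensities
        df.to_csv(path, index=False)
    elif kind == "references":
        refs = objects
        df = pd.DataFrame({"wavelength_nm": refs.wavelengths,
                           "em_d": refs.em_d, "em_a": refs.em_a})
        if refs.em_b is not None:
            df["em_b"] = refs.em_b
        df.to_csv(path, index=False)
    elif kind == "tcspc":
        hist = objects
        pd.DataFrame({"bin_time_ns": hist.bin_times,
                      "counts_par": hist.counts_par,
                      "counts_perp": hist.counts_perp,
                      "irf_par": hist.irf_par,
                      "irf_perp": hist.irf_perp,
                      "period_ns": hist.period}).to_csv(path, index=False)
    else:
        raise ParseError(f"unknown table kind {kind!r}")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_dict(result) -> dict:
    """Flatten any Results object into plain JSON-serialisable types."""
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = {f.name: _jsonable(getattr(result, f.name))
                   for f in dataclasses.fields(result)
                   if not f.name.startswith("_") and f.name not in ("hist",)}
    else:
        payload = {k: _jsonable(v) for k, v in vars(result).items()
                   if not k.startswith("_")}
    payload["result_type"] = type(result).__name__
    return payload


def write_report(result, path, config: RunConfig | None = None) -> dict:
    """Write a JSON fit/simulation report (plus a timestamped sidecar log)."""
    path = Path(path)
    report = {
        "package": "allokit",
        "version": _pkg_version,
        "result": result_to_dict(result),
    }
    if config is not None:
        report["seed"] = config.seed
        report["config_hash"] = config_hash(config)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    log = path.with_suffix(path.suffix + ".log")
    log.write_text(f"written {time.strftime('%Y-%m-%dT%H:%M:%S')} "
                   f"by allokit {_pkg_version}\n")
    return report
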