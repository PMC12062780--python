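"""File formats: instrument-export-like CSV dialects plus JSON sidecars.

Every trace is a two-column UTF-8 CSV with a mandatory header; acquisition
metadata travels in a ``<file>.meta.json`` sidecar so the CSVs stay
bit-exact and diffable.  All writers stamp a schema version and, where a
run configuration is known, its hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import ArrivalTimeDistribution, MassSpectrum, TitrationDataset

__all__ = [
    "SCHEMA_VERSION",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_atd_csv",
    "write_atd_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectrum_mzml",
    "config_hash",
]

SCHEMA_VERSION = "1.0"


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_sidecar(path: Path, meta: dict[str, Any]) -> None:
    meta = {"schema_version": SCHEMA_VERSION, **meta}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def _read_sidecar(path: Path) -> dict[str, Any]:
    sc = _sidecar(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def write_spectrum_csv(spectrum: MassSpectrum, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, index=False, float_format="%.6f"
    )
    _write_sidecar(
        path,
        {
            "kind": "spectrum",
            "trap_voltage": spectrum.trap_voltage,
            "sample_id": spectrum.sample_id,
            **spectrum.metadata,
        },
    )


def read_spectrum_csv(path: str | Path) -> MassSpectrum:
    path = Path(path)
    df = _read_csv(path, ["mz", "intensity"])
    meta = _read_sidecar(path)
    return MassSpectrum(
        mz=df["mz"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        trap_voltage=meta.get("trap_voltage"),
        sample_id=meta.get("sample_id", path.stem),
        metadata=meta,
    )


def write_atd_csv(atd: ArrivalTimeDistribution, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"drift_time_ms": atd.drift_time, "intensity": atd.intensity}
    ).to_csv(path, index=False, float_format="%.6f")
    _write_sidecar(
        path,
        {
            "kind": "atd",
            "trap_voltage": atd.trap_voltage,
            "charge": atd.charge,
            "inhibitor": atd.inhibitor,
            "replicate": atd.replicate,
            **atd.metadata,
        },
    )


def read_atd_csv(path: str | Path) -> ArrivalTimeDistribution:
    path = Path(path)
    df = _read_csv(path, ["drift_time_ms", "intensity"])
    meta = _read_sidecar(path)
    required = ("trap_voltage", "charge")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(
            f"{path}: sidecar {_sidecar(path).name} missing metadata {missing}"
        )
    return ArrivalTimeDistribution(
        drift_time=df["drift_time_ms"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        trap_voltage=float(meta["trap_voltage"]),
        charge=int(meta["charge"]),
        inhibitor=meta.get("inhibitor", ""),
        replicate=int(meta.get("replicate", 1)),
        metadata=meta,
    )


_TITRATION_COLUMNS = {
    "itc": ["injection", "heat_ucal"],
    "spr": ["concentration_M", "response_RU", "replicate"],
    "mst": ["concentration_M", "fnorm"],
}


def write_titration_csv(data: TitrationDataset, path: str | Path) -> None:
    path = Path(path)
    cols = _TITRATION_COLUMNS[data.assay]
    if data.assay == "spr":
        rep = data.replicate if data.replicate is not None else np.ones_like(data.x)
        df = pd.DataFrame({cols[0]: data.x, cols[1]: data.y, cols[2]: rep})
    else:
        df = pd.DataFrame({cols[0]: data.x, cols[1]: data.y})
    df.to_csv(path, index=False, float_format="%.10g")
    _write_sidecar(path, {"kind": "titration", "assay": data.assay, **data.design})


def read_titration_csv(path: str | Path) -> TitrationDataset:
    path = Path(path)
    meta = _read_sidecar(path)
    assay = meta.get("assay")
    if assay not in _TITRATION_COLUMNS:
        raise ValueError(f"{path}: unknown or missing assay tag {assay!r}")
    cols = _TITRATION_COLUMNS[assay]
    df = _read_csv(path, cols)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    design = {k: v for k, v in meta.items() if k not in ("kind", "schema_version")}
    return TitrationDataset(
        assay=assay,
        x=df[cols[0]].to_numpy(dtype=float),
        y=df[cols[1]].to_numpy(dtype=float),
        replicate=rep,
        design=design,
    )


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"{path}: unparseable CSV ({err})") from err
    if df.empty:
        raise ValueError(f"{path}: empty data file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_spectrum_mzml(path: str | Path, scan_index: int = 0) -> MassSpectrum:
    """Optional adapter: load one profile scan from an mzML file.

    Requires ``pyteomics``; the CSV readers are the core interface.
    """
    try:
        from pyteomics import mzml  # noqa: PLC0415
    except ImportError as err:  # pragma: no cover
        raise ImportError("mzML ingestion requires the pyteomics package") from err
    with mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if i == scan_index:
                return MassSpectrum(
                    mz=np.asarray(scan["m/z array"], dtype=float),
                    intensity=np.asarray(scan["intensity array"], dtype=float),
                    sample_id=scan.get("id", ""),
                )
    raise IndexError(f"scan {scan_index} not found in {path}")
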