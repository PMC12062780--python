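"""Core data containers for the CIU screening pipeline.

All traces are plain numpy arrays wrapped in lightweight dataclasses that
validate the invariants every downstream step relies on (monotone axes,
non-negative intensities, matching lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MassSpectrum",
    "ArrivalTimeDistribution",
    "PeakCentroid",
    "ChargeStateAssignment",
    "TitrationDataset",
]


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("trace arrays must be one-dimensional")
    return arr


def _check_trace(axis: np.ndarray, intensity: np.ndarray, axis_name: str) -> None:
    if axis.shape != intensity.shape:
        raise ValueError(f"{axis_name} and intensity must have equal length")
    if axis.size and np.any(np.diff(axis) <= 0):
        raise ValueError(f"{axis_name} must be strictly increasing")
    if np.any(intensity < 0):
        raise ValueError("intensities must be non-negative")


@dataclass
class MassSpectrum:
    """A profile native mass spectrum: m/z (Th) versus intensity (counts)."""

    mz: np.ndarray
    intensity: np.ndarray
    trap_voltage: float | None = None
    sample_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = _as_float_array(self.mz)
        self.intensity = _as_float_array(self.intensity)
        _check_trace(self.mz, self.intensity, "mz")

    @property
    def base_peak_height(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class ArrivalTimeDistribution:
    """An ion-mobility arrival-time distribution for one charge state.

    ``trap_voltage`` is the collisional-activation voltage (V) at which the
    trace was acquired; ``charge`` is the selected charge state.
    """

    drift_time: np.ndarray
    intensity: np.ndarray
    trap_voltage: float
    charge: int
    inhibitor: str = ""
    replicate: int = 1
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drift_time = _as_float_array(self.drift_time)
        self.intensity = _as_float_array(self.intensity)
        _check_trace(self.drift_time, self.intensity, "drift_time")

    @property
    def grid_step(self) -> float:
        if self.drift_time.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.drift_time)))


@dataclass(frozen=True)
class PeakCentroid:
    """A centroided spectral peak (parabolic apex) with height and area."""

    mz: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("centroid height must be positive")


@dataclass
class ChargeStateAssignment:
    """A charge-state series belonging to one molecular species.

    ``charges[i]`` carries ``per_charge_mass[i]``; masses are neutral (Da).
    """

    charges: list[int]
    per_charge_mass: list[float]
    mean_mass: float
    mass_sd: float
    peaks: list[PeakCentroid] = field(default_factory=list)
    species_label: str | None = None  # "apo" | "holo"

    def __post_init__(self) -> None:
        if sorted(self.charges) != list(range(min(self.charges), max(self.charges) + 1)):
            raise ValueError("charges must be consecutive integers")
        if len(self.charges) != len(self.per_charge_mass):
            raise ValueError("charges and per-charge masses must align")

    @property
    def total_height(self) -> float:
        return float(sum(p.height for p in self.peaks))


@dataclass
class TitrationDataset:
    """Concentration–response (or injection–heat) data for one binding assay.

    assay: "itc" (x = injection index, y = μcal per injection),
           "spr" (x = analyte concentration in M, y = equilibrium RU),
           "mst" (x = ligand concentration in M, y = Fnorm).
    """

    assay: str
    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None
    design: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ("itc", "spr", "mst"):
            raise ValueError(f"unknown assay {self.assay!r}")
        self.x = _as_float_array(self.x)
        self.y = _as_float_array(self.y)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.assay in ("spr", "mst") and np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.x.shape:
                raise ValueError("replicate ids must align with x")
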