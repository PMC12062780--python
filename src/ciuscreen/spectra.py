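"""Native mass-spectrum processing.

Peak picking, charge-state assignment of narrow native envelopes, neutral
mass determination, ligand-mass measurement from the apo/holo mass shift,
and quantitation of the ligand-bound fraction from peak heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .constants import PROTON_MASS
from .datatypes import ChargeStateAssignment, MassSpectrum, PeakCentroid

__all__ = [
    "pick_peaks",
    "assign_charge_states",
    "label_species",
    "measure_ligand_mass",
    "quantify_bound_fraction",
    "SpectrumAnalysis",
    "analyze_spectrum",
]

# tolerance on the real-valued charge solution before integer rounding
CHARGE_TOLERANCE = 0.2
# neutral-mass window for grouping peaks into one species (Da)
MASS_WINDOW = 5.0


def pick_peaks(
    spectrum: MassSpectrum, min_rel_height: float = 0.05
) -> list[PeakCentroid]:
    """Centroid prominent local maxima above a relative-height threshold.

    Maxima must both exceed ``min_rel_height`` x base peak and be prominent
    by the same amount, so noise wiggles riding on a broad profile peak are
    not reported as separate peaks.  The reported m/z is the
    intensity-weighted centroid of the region above half the apex height
    (robust to point noise); the height is the three-point parabolic apex;
    the area is the trapezoidal integral of the contiguous region above the
    threshold.  Returned sorted by m/z.
    """
    if not (0.0 < min_rel_height < 1.0):
        raise ValueError("min_rel_height must lie in (0, 1)")
    y = spectrum.intensity
    if y.size == 0 or y.max() <= 0:
        return []
    threshold = min_rel_height * y.max()
    idx, _ = find_peaks(y, height=threshold, prominence=threshold)
    mz = spectrum.mz
    out = []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            apex_h = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        else:
            apex_h = float(y[i])
        # FWHM region around the apex
        half = 0.5 * y[i]
        lo = i
        while lo > 0 and y[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] >= half:
            hi += 1
        w = y[lo : hi + 1]
        apex_mz = float(np.average(mz[lo : hi + 1], weights=w))
        # contiguous above-threshold region for the area
        alo = i
        while alo > 0 and y[alo - 1] >= threshold and y[alo - 1] <= y[alo]:
            alo -= 1
        ahi = i
        while ahi < y.size - 1 and y[ahi + 1] >= threshold and y[ahi + 1] <= y[ahi]:
            ahi += 1
        area = float(np.trapezoid(y[alo : ahi + 1], mz[alo : ahi + 1]))
        out.append(PeakCentroid(mz=apex_mz, height=float(apex_h), area=area))
    return sorted(out, key=lambda p: p.mz)


def _mass(mz: float, z: int) -> float:
    return z * (mz - PROTON_MASS)


@dataclass
class _Candidate:
    mass: float
    members: dict[int, PeakCentroid]  # charge -> peak


def assign_charge_states(
    peaks: list[PeakCentroid],
    max_charge: int = 30,
    charge_tolerance: float = CHARGE_TOLERANCE,
    mass_window: float = MASS_WINDOW,
) -> tuple[list[ChargeStateAssignment], list[PeakCentroid]]:
    """Group peaks into charge-state series and determine neutral masses.

    For every (peak, candidate charge) hypothesis, the supporting peaks are
    those whose real-valued charge solution for that neutral mass rounds to
    an integer within ``charge_tolerance`` and whose implied mass falls
    within ``mass_window``.  Series of at least two consecutive charges are
    accepted greedily by descending support; everything else is returned as
    unassigned rather than silently dropped.

    Returns (assignments sorted by mean mass, unassigned peaks).
    """
    remaining = list(peaks)
    assignments: list[ChargeStateAssignment] = []
    while len(remaining) >= 2:
        best: _Candidate | None = None
        for p in remaining:
            for z in range(1, max_charge + 1):
                mass = _mass(p.mz, z)
                if mass <= 0:
                    continue
                members: dict[int, PeakCentroid] = {}
                for q in remaining:
                    z_real = mass / (q.mz - PROTON_MASS)
                    z_int = int(round(z_real))
                    if z_int < 1 or abs(z_real - z_int) > charge_tolerance:
                        continue
                    if abs(_mass(q.mz, z_int) - mass) > mass_window:
                        continue
                    if z_int not in members or abs(_mass(q.mz, z_int) - mass) < abs(
                        _mass(members[z_int].mz, z_int) - mass
                    ):
                        members[z_int] = q
                members = _largest_consecutive_run(members, anchor=z)
                if len(members) >= 2 and (
                    best is None or len(members) > len(best.members)
                ):
                    best = _Candidate(mass=mass, members=members)
        if best is None:
            break
        charges = sorted(best.members)
        masses = [_mass(best.members[z].mz, z) for z in charges]
        mean = float(np.mean(masses))
        sd = float(np.std(masses, ddof=1)) if len(masses) > 1 else 0.0
        assignments.append(
            ChargeStateAssignment(
                charges=charges,
                per_charge_mass=masses,
                mean_mass=mean,
                mass_sd=sd,
                peaks=[best.members[z] for z in charges],
            )
        )
        used = set(id(p) for p in best.members.values())
        remaining = [p for p in remaining if id(p) not in used]
    assignments.sort(key=lambda a: a.mean_mass)
    return assignments, remaining


def _largest_consecutive_run(
    members: dict[int, PeakCentroid], anchor: int
) -> dict[int, PeakCentroid]:
    """Longest run of consecutive charges containing ``anchor`` (if any)."""
    if not members:
        return {}
    charges = sorted(members)
    runs: list[list[int]] = [[charges[0]]]
    for z in charges[1:]:
        if z == runs[-1][-1] + 1:
            runs[-1].append(z)
        else:
            runs.append([z])
    containing = [r for r in runs if anchor in r]
    run = max(containing or runs, key=len)
    return {z: members[z] for z in run}


def label_species(
    assignments: list[ChargeStateAssignment],
) -> list[ChargeStateAssignment]:
    """Label the lightest species ``apo`` and any heavier ones ``holo``."""
    ordered = sorted(assignments, key=lambda a: a.mean_mass)
    for i, a in enumerate(ordered):
        a.species_label = "apo" if i == 0 else "holo"
    return ordered


def measure_ligand_mass(
    apo: ChargeStateAssignment, holo: ChargeStateAssignment
) -> tuple[float, float]:
    """Ligand mass from the holo−apo mass shift, with propagated sd."""
    if not apo.charges or not holo.charges:
        raise ValueError("both assignments must be nonempty")
    diff = holo.mean_mass - apo.mean_mass
    if diff < 0:
        raise ValueError(
            "holo species lighter than apo: species assignment is inconsistent"
        )
    return diff, math.sqrt(apo.mass_sd**2 + holo.mass_sd**2)


def quantify_bound_fraction(
    apo_peaks: list[PeakCentroid], holo_peaks: list[PeakCentroid]
) -> float:
    """Bound fraction from peak heights: Σholo / (Σholo + Σapo)."""
    apo_sum = sum(p.height for p in apo_peaks)
    holo_sum = sum(p.height for p in holo_peaks)
    total = apo_sum + holo_sum
    if total <= 0:
        raise ValueError("no apo or holo signal: bound fraction undefined")
    return holo_sum / total


@dataclass
class SpectrumAnalysis:
    """End-to-end analysis of one native spectrum."""

    peaks: list[PeakCentroid]
    species: list[ChargeStateAssignment]
    unassigned: list[PeakCentroid] = field(default_factory=list)

    @property
    def apo(self) -> ChargeStateAssignment | None:
        for a in self.species:
            if a.species_label == "apo":
                return a
        return None

    @property
    def holo(self) -> ChargeStateAssignment | None:
        for a in self.species:
            if a.species_label == "holo":
                return a
        return None

    @property
    def bound_fraction(self) -> float:
        holo_peaks = self.holo.peaks if self.holo else []
        apo_peaks = self.apo.peaks if self.apo else []
        return quantify_bound_fraction(apo_peaks, holo_peaks)

    @property
    def ligand_mass(self) -> tuple[float, float]:
        if self.apo is None or self.holo is None:
            raise ValueError("need both apo and holo species for a ligand mass")
        return measure_ligand_mass(self.apo, self.holo)


def analyze_spectrum(
    spectrum: MassSpectrum, min_rel_height: float = 0.05, max_charge: int = 30
) -> SpectrumAnalysis:
    """Pick peaks, assign charges, and label apo/holo species."""
    peaks = pick_peaks(spectrum, min_rel_height)
    assignments, unassigned = assign_charge_states(peaks, max_charge=max_charge)
    return SpectrumAnalysis(
        peaks=peaks, species=label_species(assignments), unassigned=unassigned
    )
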