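"""Type I / type II inhibitor calls from CIU fingerprints.

A kinase inhibitor that binds the active ('DFG in') conformation (type I)
destabilises the gas-phase protein less than one that traps the inactive
('DFG out') conformation (type II).  The screening statistic is the relative
population of the extended (7.6 ms) conformer at each calibrated trap
voltage; calibration gives, per (voltage, class), the mean, standard
deviation and observed range of that statistic.  Classification is
nearest-class-mean per voltage, with an overall call only when all voltages
agree — disagreement is reported as ``ambiguous`` rather than forced binary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .mobility import CIUFingerprint

TYPE_I = "type_I"
TYPE_II = "type_II"
AMBIGUOUS = "ambiguous"

__all__ = [
    "TYPE_I",
    "TYPE_II",
    "AMBIGUOUS",
    "CalibrationEntry",
    "CalibrationTable",
    "default_calibration",
    "classify_voltage",
    "classify_inhibitor",
    "classify_panel",
    "ClassificationResult",
    "PanelSummary",
]


@dataclass(frozen=True)
class CalibrationEntry:
    """Class statistics of the unfolded-percent score at one trap voltage."""

    mean: float
    sd: float
    low: float
    high: float  # may be +inf for a one-sided range

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.low <= self.mean <= self.high):
            raise ValueError("range must bracket the mean")


@dataclass
class CalibrationTable:
    """Per-(voltage, class) calibration of the unfolding statistic."""

    entries: dict[tuple[float, str], CalibrationEntry]

    def __post_init__(self) -> None:
        for v in self.voltages:
            lo = self.entries[(v, TYPE_I)]
            hi = self.entries[(v, TYPE_II)]
            if hi.mean <= lo.mean:
                raise ValueError(
                    f"type II mean must exceed type I mean at {v} V"
                )

    @property
    def voltages(self) -> list[float]:
        return sorted({v for (v, _cls) in self.entries})

    def entry(self, voltage: float, cls: str) -> CalibrationEntry:
        return self.entries[(float(voltage), cls)]

    def midpoint(self, voltage: float) -> float:
        """Decision boundary: midpoint between the two class means."""
        return 0.5 * (
            self.entry(voltage, TYPE_I).mean + self.entry(voltage, TYPE_II).mean
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            f"{v}:{c}": {"mean": e.mean, "sd": e.sd, "low": e.low,
                         "high": None if math.isinf(e.high) else e.high}
            for (v, c), e in self.entries.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        payload = json.loads(Path(path).read_text())
        entries = {}
        for key, e in payload.items():
            v, c = key.split(":")
            high = math.inf if e["high"] is None else float(e["high"])
            entries[(float(v), c)] = CalibrationEntry(
                float(e["mean"]), float(e["sd"]), float(e["low"]), high
            )
        return cls(entries)


def default_calibration() -> CalibrationTable:
    """FGFR1 calibration of the 7.6 ms conformer intensity (% of base peak).

    Means/sds and ranges at 21 V and 24 V trap voltage; the 21 V type II
    range is one-sided (scores above 40% were observed without a stated
    upper bound).
    """
    return CalibrationTable(
        {
            (21.0, TYPE_I): CalibrationEntry(27.6, 3.9, 22.0, 35.0),
            (21.0, TYPE_II): CalibrationEntry(48.9, 4.4, 40.0, math.inf),
            (24.0, TYPE_I): CalibrationEntry(44.2, 5.6, 30.0, 50.0),
            (24.0, TYPE_II): CalibrationEntry(76.7, 11.6, 64.0, 95.0),
        }
    )


def classify_voltage(score: float, voltage: float, calib: CalibrationTable) -> str:
    """Nearest-class-mean call at one voltage; an exact tie is ambiguous."""
    d1 = abs(score - calib.entry(voltage, TYPE_I).mean)
    d2 = abs(score - calib.entry(voltage, TYPE_II).mean)
    if d1 == d2:
        return AMBIGUOUS
    return TYPE_I if d1 < d2 else TYPE_II


@dataclass
class ClassificationResult:
    inhibitor: str
    call: str
    per_voltage_call: dict[float, str]
    scores: dict[float, float]
    confidence_note: str = ""

    def __post_init__(self) -> None:
        calls = set(self.per_voltage_call.values())
        consistent = len(calls) == 1 and AMBIGUOUS not in calls
        if consistent != (self.call != AMBIGUOUS):
            raise ValueError("overall call inconsistent with per-voltage calls")


def classify_inhibitor(
    fp: CIUFingerprint, calib: CalibrationTable | None = None
) -> ClassificationResult:
    """Classify one inhibitor from its replicate-averaged CIU fingerprint.

    Requires a score at every calibrated voltage; the overall call is the
    common per-voltage class, or ``ambiguous`` when the voltages disagree.
    """
    if calib is None:
        calib = default_calibration()
    scores: dict[float, float] = {}
    for v in calib.voltages:
        if v not in fp.per_voltage:
            raise ValueError(f"fingerprint for {fp.inhibitor!r} missing {v} V")
        scores[v] = fp.per_voltage[v].mean
    per_voltage = {v: classify_voltage(s, v, calib) for v, s in scores.items()}
    calls = set(per_voltage.values())
    call = per_voltage[calib.voltages[0]] if len(calls) == 1 else AMBIGUOUS
    if AMBIGUOUS in calls:
        call = AMBIGUOUS

    notes = []
    for v, s in scores.items():
        cls = per_voltage[v]
        if cls == AMBIGUOUS:
            notes.append(f"{v:g} V: on decision boundary")
            continue
        sd = calib.entry(v, cls).sd
        dist = abs(s - calib.midpoint(v))
        notes.append(
            f"{v:g} V: {dist / sd:.1f} class-sd from boundary" if sd > 0
            else f"{v:g} V: boundary distance {dist:.1f}%"
        )
    return ClassificationResult(
        inhibitor=fp.inhibitor,
        call=call,
        per_voltage_call=per_voltage,
        scores=scores,
        confidence_note="; ".join(notes),
    )


@dataclass
class PanelSummary:
    """Per-inhibitor calls plus class counts for a screened panel."""

    results: list[ClassificationResult]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {TYPE_I: 0, TYPE_II: 0, AMBIGUOUS: 0}
            for r in self.results:
                self.counts[r.call] += 1

    def result_for(self, inhibitor: str) -> ClassificationResult:
        for r in self.results:
            if r.inhibitor == inhibitor:
                return r
        raise KeyError(inhibitor)


def classify_panel(
    fingerprints: list[CIUFingerprint], calib: CalibrationTable | None = None
) -> PanelSummary:
    """Classify every inhibitor in a screened panel."""
    if not fingerprints:
        raise ValueError("empty panel")
    names = [fp.inhibitor for fp in fingerprints]
    if len(set(names)) != len(names):
        raise ValueError("duplicate inhibitor names in panel")
    return PanelSummary([classify_inhibitor(fp, calib) for fp in fingerprints])
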