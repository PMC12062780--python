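"""Arrival-time-distribution processing and the CIU unfolding statistic.

Collision-induced unfolding (CIU) of the protein–inhibitor complex produces
two dominant conformer populations in the ion-mobility arrival-time
distribution (ATD): a compact conformer near 5.5 ms and an extended one near
7.6 ms.  ``TwoConformerModel`` fits the ATD with two equal-width Gaussians
whose centers are constrained to narrow windows around the expected drift
times; the screening statistic is the extended-component area expressed as a
percentage of the compact base peak,

    unfold_percent = 100 * area_extended / area_compact.

Because the two components share one width, this area ratio equals the
apex-height ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .datatypes import ArrivalTimeDistribution

__all__ = [
    "DEFAULT_CENTERS",
    "DEFAULT_CENTER_WINDOW",
    "TwoConformerModel",
    "ConformerFit",
    "fit_two_conformers",
    "unfolded_percent",
    "select_analysis_charge",
    "build_fingerprint",
    "CIUFingerprint",
    "VoltageScore",
]

DEFAULT_CENTERS = (5.5, 7.6)  # ms, compact / extended conformer drift times
DEFAULT_CENTER_WINDOW = 0.3  # ms
# extended components below this fraction of the compact area are reported
# as absent rather than as tiny (possibly negative-noise) populations
DETECTION_FLOOR = 1e-3

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _two_gaussians(t, a1, a2, c1, c2, sd):
    return a1 * np.exp(-0.5 * ((t - c1) / sd) ** 2) + a2 * np.exp(
        -0.5 * ((t - c2) / sd) ** 2
    )


@dataclass
class ConformerFit:
    """Results of a two-conformer ATD fit.

    Areas are in counts·ms; ``unfold_percent`` is the extended area as a
    percentage of the compact (base-peak) area.
    """

    compact_center: float
    extended_center: float
    width_sd: float
    compact_area: float
    extended_area: float
    residual_rms: float
    param_se: dict[str, float] = field(default_factory=dict)
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.compact_area < 0 or self.extended_area < 0:
            raise ValueError("component areas must be non-negative")

    @property
    def unfold_percent(self) -> float:
        return unfolded_percent(self)

    def summary(self) -> str:
        lines = [
            "Two-conformer ATD fit",
            "=" * 38,
            f"compact center   {self.compact_center:8.3f} ms",
            f"extended center  {self.extended_center:8.3f} ms",
            f"shared width sd  {self.width_sd:8.3f} ms",
            f"compact area     {self.compact_area:10.2f}",
            f"extended area    {self.extended_area:10.2f}",
            f"unfold percent   {self.unfold_percent:8.2f} %",
            f"residual rms     {self.residual_rms:10.4f}  (n={self.n_points})",
        ]
        return "\n".join(lines)


class TwoConformerModel:
    """Two equal-width Gaussian conformers fitted to one ATD.

    Parameters
    ----------
    atd : ArrivalTimeDistribution
        The trace to fit.
    expected_centers : (float, float)
        Expected compact and extended drift times (ms).
    center_window : float
        Half-width (ms) of the box constraint on each fitted center.
    """

    def __init__(
        self,
        atd: ArrivalTimeDistribution,
        expected_centers: tuple[float, float] = DEFAULT_CENTERS,
        center_window: float = DEFAULT_CENTER_WINDOW,
    ) -> None:
        if center_window <= 0:
            raise ValueError("center_window must be positive")
        t = atd.drift_time
        for c in expected_centers:
            if not (t[0] <= c <= t[-1]):
                raise ValueError(f"expected center {c} ms outside data span")
        self.atd = atd
        self.expected_centers = (float(expected_centers[0]), float(expected_centers[1]))
        self.center_window = float(center_window)

    def _initial_guess(self) -> tuple[float, float, float]:
        """Apex heights at the expected centers, from a lightly smoothed trace.

        Smoothing (5-point quadratic Savitzky–Golay) is used only to seed the
        optimiser; the fit itself runs on the raw intensities.
        """
        y = self.atd.intensity
        if y.size >= 5:
            y = savgol_filter(y, 5, 2)
        t = self.atd.drift_time
        c1, c2 = self.expected_centers
        a1 = max(float(y[np.argmin(np.abs(t - c1))]), 0.0)
        a2 = max(float(y[np.argmin(np.abs(t - c2))]), 0.0)
        return a1, a2, 0.35

    def fit(self) -> ConformerFit:
        t = self.atd.drift_time
        y = self.atd.intensity
        c1, c2 = self.expected_centers
        w = self.center_window
        a1_0, a2_0, sd_0 = self._initial_guess()
        ymax = max(float(y.max()), 1e-12)
        step = self.atd.grid_step
        lower = [0.0, 0.0, c1 - w, c2 - w, max(0.5 * step, 1e-3)]
        upper = [2 * ymax, 2 * ymax, c1 + w, c2 + w, 2.0]
        p0 = [
            min(max(a1_0, 1e-6 * ymax), 2 * ymax),
            min(max(a2_0, 0.0), 2 * ymax),
            c1,
            c2,
            min(max(sd_0, lower[4] * 1.01), upper[4] * 0.99),
        ]
        try:
            popt, pcov = curve_fit(
                _two_gaussians, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except RuntimeError as err:  # pragma: no cover - pathological input
            resid = y - _two_gaussians(t, *p0)
            raise RuntimeError(
                f"two-conformer fit failed to converge: {err}; "
                f"initial residual rms {np.sqrt(np.mean(resid**2)):.4g}"
            ) from err
        a1, a2, f1, f2, sd = popt
        resid = y - _two_gaussians(t, *popt)
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        compact_area = a1 * sd * _SQRT_2PI
        extended_area = a2 * sd * _SQRT_2PI
        if compact_area > 0 and extended_area < DETECTION_FLOOR * compact_area:
            extended_area = 0.0
        return ConformerFit(
            compact_center=float(f1),
            extended_center=float(f2),
            width_sd=float(sd),
            compact_area=float(compact_area),
            extended_area=float(extended_area),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            param_se={
                "compact_amp": float(se[0]),
                "extended_amp": float(se[1]),
                "compact_center": float(se[2]),
                "extended_center": float(se[3]),
                "width_sd": float(se[4]),
            },
            n_points=int(t.size),
        )


def fit_two_conformers(
    atd: ArrivalTimeDistribution,
    expected_centers: tuple[float, float] = DEFAULT_CENTERS,
    center_window: float = DEFAULT_CENTER_WINDOW,
) -> ConformerFit:
    """Fit two equal-width Gaussian conformers to an ATD."""
    return TwoConformerModel(atd, expected_centers, center_window).fit()


def unfolded_percent(fit: ConformerFit) -> float:
    """Extended-conformer area as a percentage of the compact base peak."""
    if fit.compact_area <= 0:
        raise ValueError("compact base peak has zero area; percent undefined")
    return 100.0 * fit.extended_area / fit.compact_area


def select_analysis_charge(atds: list[ArrivalTimeDistribution]) -> int:
    """Lowest charge state in the collection — most native-like ions."""
    if not atds:
        raise ValueError("empty ATD collection")
    return min(a.charge for a in atds)


@dataclass(frozen=True)
class VoltageScore:
    """Replicate unfold-percent scores at one trap voltage."""

    replicates: tuple[float, ...]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (min(self.replicates) - 1e-9 <= self.mean <= max(self.replicates) + 1e-9):
            raise ValueError("mean outside replicate range")


@dataclass
class CIUFingerprint:
    """Per-voltage unfolding scores for one inhibitor."""

    inhibitor: str
    per_voltage: dict[float, VoltageScore]
    charge: int | None = None

    @property
    def voltages(self) -> list[float]:
        return sorted(self.per_voltage)


def build_fingerprint(
    atds: list[ArrivalTimeDistribution],
    expected_centers: tuple[float, float] = DEFAULT_CENTERS,
    center_window: float = DEFAULT_CENTER_WINDOW,
) -> CIUFingerprint:
    """Fit every replicate ATD of one inhibitor and aggregate per voltage.

    Replicates at one voltage are summarised as arithmetic mean and sample
    standard deviation (0 for a single replicate).  All traces must come
    from the same inhibitor and the same charge state.
    """
    if not atds:
        raise ValueError("no ATDs supplied")
    names = {a.inhibitor for a in atds}
    if len(names) != 1:
        raise ValueError(f"ATDs from multiple inhibitors: {sorted(names)}")
    charges = {a.charge for a in atds}
    if len(charges) != 1:
        raise ValueError(f"inconsistent charge states across replicates: {sorted(charges)}")

    by_voltage: dict[float, list[float]] = {}
    for atd in atds:
        fit = fit_two_conformers(atd, expected_centers, center_window)
        by_voltage.setdefault(float(atd.trap_voltage), []).append(fit.unfold_percent)

    per_voltage = {}
    for v, scores in by_voltage.items():
        arr = np.asarray(scores)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        per_voltage[v] = VoltageScore(tuple(scores), float(arr.mean()), sd)
    return CIUFingerprint(
        inhibitor=names.pop(), per_voltage=per_voltage, charge=charges.pop()
    )
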