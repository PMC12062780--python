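"""Seeded forward models for every input the screening pipeline consumes.

No raw instrument data accompany the study conditions this package targets,
so every pipeline input is generated here with known ground truth:

* native ESI mass spectra of a ~36 kDa kinase domain presenting a narrow
  11+–13+ charge-state envelope, with optional 1:1 ligand adducts;
* CIU arrival-time distributions built from two equal-width Gaussian
  conformers (compact 5.5 ms, extended 7.6 ms) whose area ratio is the
  ground-truth unfolded percent;
* ten-inhibitor CIU panels in which each inhibitor's unfolding truth is
  drawn from the class-calibrated truncated-normal model at 21 V and 24 V;
* voltage-dependent ligand stripping (logistic decay of bound fraction);
* ITC, SPR and MST titrations from the closed-form models in
  :mod:`ciuscreen.binding`.

All generators are bit-reproducible under their seed.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import binding
from .classify import TYPE_I, TYPE_II, CalibrationTable, default_calibration
from .constants import PROTON_MASS
from .datatypes import ArrivalTimeDistribution, MassSpectrum, TitrationDataset

__all__ = [
    "NoiseModel",
    "NOISELESS",
    "InhibitorProfile",
    "PanelSpec",
    "CIUPanel",
    "default_panel_inhibitors",
    "default_drift_grid",
    "truth_from_latent",
    "simulate_native_spectrum",
    "simulate_atd",
    "simulate_ciu_panel",
    "simulate_stripping_series",
    "simulate_itc",
    "simulate_spr",
    "simulate_mst",
]

DEFAULT_PROTEIN_MASS = 36000.0  # Da, kinase-domain scale
DEFAULT_CHARGES = (11, 12, 13)
COMPACT_CENTER = 5.5  # ms
EXTENDED_CENTER = 7.6  # ms
CONFORMER_WIDTH_SD = 0.35  # ms; equal widths make area ratio == apex ratio
# one-sided 21 V type II calibration range is capped here for simulation
TYPE_II_21V_TRUTH_CAP = 60.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise levels for each simulated data type.

    Trace noise is expressed as a fraction of the clean base peak; heat
    noise is absolute (μcal); SPR noise is a fraction of Rmax and MST noise
    a fraction of the Fnorm span.
    """

    spectrum_noise_sd: float = 0.01
    atd_noise_sd: float = 0.02
    heat_noise_sd: float = 0.1
    spr_noise_sd: float = 0.02
    mst_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if min(
            self.spectrum_noise_sd,
            self.atd_noise_sd,
            self.heat_noise_sd,
            self.spr_noise_sd,
            self.mst_noise_sd,
        ) < 0:
            raise ValueError("noise levels must be non-negative")


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class InhibitorProfile:
    """Ground-truth description of one inhibitor in a simulated panel.

    ``unfold_score_truth`` maps trap voltage (V) to the true unfolded
    percent; when ``None`` the panel simulator draws it from the class
    truth model.
    """

    name: str
    true_class: str
    kd: float
    ligand_mass: float
    unfold_score_truth: dict[float, float] | None = None

    def __post_init__(self) -> None:
        if self.true_class not in (TYPE_I, TYPE_II):
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.unfold_score_truth is not None:
            vs = sorted(self.unfold_score_truth)
            vals = [self.unfold_score_truth[v] for v in vs]
            if any(x < 0 for x in vals):
                raise ValueError("unfold truth must be non-negative")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("unfold truth must be nondecreasing in voltage")


def default_panel_inhibitors() -> list[InhibitorProfile]:
    """The ten-compound screening panel: 7 type I, 3 type II.

    Kd values for compound D, Ponatinib, JK-P3 and Linifanib are the
    reported affinities; the remaining Kd values and the non-commercial
    ligand masses are synthetic placeholders within the reported nM–μM span.
    """
    uM, nM = 1e-6, 1e-9
    return [
        InhibitorProfile("Compound A", TYPE_I, 100 * nM, 420.5),
        InhibitorProfile("Compound B", TYPE_I, 250 * nM, 389.4),
        InhibitorProfile("Compound C", TYPE_I, 1.2 * uM, 405.9),
        InhibitorProfile("Compound D", TYPE_I, 36 * nM, 441.5),
        InhibitorProfile("Compound E", TYPE_I, 3.5 * uM, 462.5),
        InhibitorProfile("JK-P3", TYPE_I, 25 * uM, 293.3),
        InhibitorProfile("JK-P5", TYPE_I, 8 * uM, 343.4),
        InhibitorProfile("Ponatinib", TYPE_II, 8 * nM, 532.56),
        InhibitorProfile("Linifanib", TYPE_II, 37 * uM, 375.41),
        InhibitorProfile("Sorafenib", TYPE_II, 2 * uM, 464.82),
    ]


@dataclass(frozen=True)
class PanelSpec:
    """A CIU screening panel design: inhibitors, voltages, replicates, seed."""

    inhibitors: tuple[InhibitorProfile, ...] = field(
        default_factory=lambda: tuple(default_panel_inhibitors())
    )
    voltages: tuple[float, ...] = (21.0, 24.0)
    replicates: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.voltages:
            raise ValueError("need at least one trap voltage")
        names = [p.name for p in self.inhibitors]
        if len(set(names)) != len(names):
            raise ValueError("inhibitor names must be unique")


def default_drift_grid() -> np.ndarray:
    """Default 200-bin drift-time axis: 0–14 ms at 0.07 ms spacing."""
    return np.arange(0.0, 14.0, 0.07)


def _class_truth_table(calib: CalibrationTable | None = None):
    """Truth-model parameters per (voltage, class), from the calibration.

    The open upper bound of the 21 V type II range is capped for simulation.
    """
    calib = calib or default_calibration()
    table = {}
    for (v, cls), e in calib.entries.items():
        high = TYPE_II_21V_TRUTH_CAP if math.isinf(e.high) else e.high
        table[(v, cls)] = (e.mean, e.sd, e.low, high)
    return table


def truth_from_latent(u: float, voltage: float, true_class: str) -> float:
    """Ground-truth unfolded percent for latent stability score u ~ N(0,1).

    truth = clip(mean + u·sd, class range); one latent score per inhibitor
    is shared across voltages so CIU fingerprints are internally monotone.
    """
    mean, sd, low, high = _class_truth_table()[(float(voltage), true_class)]
    return float(np.clip(mean + u * sd, low, high))


def simulate_native_spectrum(
    protein_mass: float = DEFAULT_PROTEIN_MASS,
    ligand_mass: float = 0.0,
    bound_fraction: float = 0.0,
    charges=DEFAULT_CHARGES,
    peak_width: float = 1.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    mz_step: float = 0.05,
    mz_pad: float = 30.0,
    sample_id: str = "",
    trap_voltage: float | None = None,
) -> MassSpectrum:
    """Simulate a profile native spectrum of apo and 1:1 ligand-bound protein.

    Each charge z contributes an apo Gaussian at (M + z·m_p)/z and, when
    ``bound_fraction > 0``, a holo Gaussian at (M + m_L + z·m_p)/z; the
    holo:apo height ratio equals bound_fraction/(1 - bound_fraction) and a
    Gaussian charge-envelope weighting is applied across z.
    """
    charges = sorted(int(z) for z in charges)
    if not charges:
        raise ValueError("charge set must be nonempty")
    if protein_mass <= 0:
        raise ValueError("protein mass must be positive")
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError("bound fraction must lie in [0, 1]")
    if bound_fraction == 1.0 and ligand_mass == 0.0:
        raise ValueError("fully bound species requires a nonzero ligand mass")
    if peak_width <= 0:
        raise ValueError("peak width must be positive")

    z_arr = np.asarray(charges, dtype=float)
    apo_mz = (protein_mass + z_arr * PROTON_MASS) / z_arr
    holo_mz = (protein_mass + ligand_mass + z_arr * PROTON_MASS) / z_arr
    env_center = z_arr.mean()
    env_sd = max((z_arr.max() - z_arr.min()) / 2.0, 0.5)
    weights = np.exp(-0.5 * ((z_arr - env_center) / env_sd) ** 2)

    lo = min(apo_mz.min(), holo_mz.min()) - mz_pad
    hi = max(apo_mz.max(), holo_mz.max()) + mz_pad
    mz = np.arange(lo, hi + mz_step, mz_step)
    intensity = np.zeros_like(mz)
    for w, am, hm in zip(weights, apo_mz, holo_mz):
        intensity += w * (1.0 - bound_fraction) * np.exp(
            -0.5 * ((mz - am) / peak_width) ** 2
        )
        if bound_fraction > 0:
            intensity += w * bound_fraction * np.exp(
                -0.5 * ((mz - hm) / peak_width) ** 2
            )

    base = intensity.max() if intensity.size else 0.0
    if noise.spectrum_noise_sd > 0 and base > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, noise.spectrum_noise_sd * base, intensity.shape
        )
        intensity = np.clip(intensity, 0.0, None)
    return MassSpectrum(
        mz=mz,
        intensity=intensity,
        trap_voltage=trap_voltage,
        sample_id=sample_id,
        metadata={
            "protein_mass": protein_mass,
            "ligand_mass": ligand_mass,
            "bound_fraction": bound_fraction,
            "charges": charges,
            "seed": seed,
        },
    )


def simulate_atd(
    unfold_percent: float,
    compact_center: float = COMPACT_CENTER,
    extended_center: float = EXTENDED_CENTER,
    width_sd: float = CONFORMER_WIDTH_SD,
    grid: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    trap_voltage: float = 21.0,
    charge: int = 11,
    inhibitor: str = "",
    replicate: int = 1,
) -> ArrivalTimeDistribution:
    """Simulate an ATD as two equal-width Gaussian conformers.

    The extended:compact area ratio equals ``unfold_percent / 100``; the
    compact apex is normalised to 100 counts.
    """
    if unfold_percent < 0:
        raise ValueError("unfold percent must be non-negative")
    if width_sd <= 0:
        raise ValueError("width_sd must be positive")
    t = default_drift_grid() if grid is None else np.asarray(grid, dtype=float)
    if not (t[0] <= compact_center <= t[-1]) or not (
        t[0] <= extended_center <= t[-1]
    ):
        raise ValueError("conformer centers must lie inside the drift-time grid")

    metadata: dict = {"truth_unfold_percent": unfold_percent, "seed": seed}
    step = float(np.median(np.diff(t)))
    if step > width_sd:
        metadata["warning"] = (
            f"grid spacing {step:.3g} ms coarser than component width "
            f"{width_sd:.3g} ms; conformers may be unresolved"
        )

    compact_amp = 100.0
    extended_amp = compact_amp * unfold_percent / 100.0
    y = compact_amp * np.exp(-0.5 * ((t - compact_center) / width_sd) ** 2)
    y += extended_amp * np.exp(-0.5 * ((t - extended_center) / width_sd) ** 2)
    base = y.max()
    if noise.atd_noise_sd > 0 and base > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise.atd_noise_sd * base, y.shape), 0.0, None)
    return ArrivalTimeDistribution(
        drift_time=t,
        intensity=y,
        trap_voltage=trap_voltage,
        charge=charge,
        inhibitor=inhibitor,
        replicate=replicate,
        metadata=metadata,
    )


@dataclass
class CIUPanel:
    """Simulated CIU panel: all replicate ATDs plus the ground-truth table."""

    atds: list[ArrivalTimeDistribution]
    truth: pd.DataFrame
    spec: PanelSpec

    def atds_for(self, inhibitor: str) -> list[ArrivalTimeDistribution]:
        return [a for a in self.atds if a.inhibitor == inhibitor]


def simulate_ciu_panel(
    spec: PanelSpec | None = None, noise: NoiseModel = NoiseModel()
) -> CIUPanel:
    """Simulate a full CIU screening panel with known ground truth.

    For each inhibitor one latent stability score u ~ N(0, 1) is drawn and
    shared across voltages; the per-voltage truth is the class mean + u·sd,
    clipped to the class range.  Replicates differ only by ATD noise.
    """
    spec = spec or PanelSpec()
    rng = np.random.default_rng(spec.seed)
    # distinct noise seed per (inhibitor, voltage, replicate), derived from
    # the panel seed so reruns are bit-identical
    seed_pool = np.random.SeedSequence(spec.seed).generate_state(
        len(spec.inhibitors) * len(spec.voltages) * spec.replicates
    ) % (2**31)

    atds: list[ArrivalTimeDistribution] = []
    rows = []
    k = 0
    for prof in spec.inhibitors:
        u = float(rng.standard_normal())
        for v in spec.voltages:
            if prof.unfold_score_truth is not None:
                truth = prof.unfold_score_truth[v]
            else:
                truth = truth_from_latent(u, v, prof.true_class)
            rows.append(
                {
                    "inhibitor": prof.name,
                    "true_class": prof.true_class,
                    "latent_u": u,
                    "voltage": v,
                    "truth_percent": truth,
                }
            )
            for rep in range(1, spec.replicates + 1):
                atds.append(
                    simulate_atd(
                        truth,
                        noise=noise,
                        seed=int(seed_pool[k]),
                        trap_voltage=v,
                        charge=11,
                        inhibitor=prof.name,
                        replicate=rep,
                    )
                )
                k += 1
    return CIUPanel(atds=atds, truth=pd.DataFrame(rows), spec=spec)


def simulate_stripping_series(
    bound_fraction_0: float,
    voltages,
    v50: float = 20.0,
    steepness: float = 3.0,
) -> dict[float, float]:
    """Logistic gas-phase ligand stripping: b(V) = b0 / (1 + exp((V - v50)/s))."""
    if not (0.0 <= bound_fraction_0 <= 1.0):
        raise ValueError("initial bound fraction must lie in [0, 1]")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    return {
        float(v): bound_fraction_0 / (1.0 + math.exp((v - v50) / steepness))
        for v in voltages
    }


def simulate_itc(
    kd: float,
    n_stoich: float = 1.0,
    dh_kcal: float = -10.0,
    cell_conc: float = 20e-6,
    syringe_conc: float = 200e-6,
    cell_volume_ul: float = 200.0,
    inj_volume_ul: float = 2.0,
    n_inj: int = 19,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> TitrationDataset:
    """Simulate per-injection ITC heats from the one-site model."""
    design = binding.ITCDesign(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume_ul=cell_volume_ul,
        inj_volume_ul=inj_volume_ul,
        n_inj=n_inj,
    )
    if kd > 0 and n_stoich * cell_conc / kd > 1e6:
        _warnings.warn(
            "c-value above 1e6: isotherm is numerically rectangular",
            RuntimeWarning,
        )
    heats = binding.itc_heats(kd, n_stoich, dh_kcal, design)
    if noise.heat_noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise.heat_noise_sd, heats.shape)
    return TitrationDataset(
        assay="itc",
        x=np.arange(1, n_inj + 1, dtype=float),
        y=heats,
        design={
            "cell_conc": cell_conc,
            "syringe_conc": syringe_conc,
            "cell_volume_ul": cell_volume_ul,
            "inj_volume_ul": inj_volume_ul,
            "true_kd": kd,
            "seed": seed,
        },
    )


def simulate_spr(
    kd: float,
    rmax: float = 100.0,
    top_conc: float = 500e-6,
    fold_range: float = 256.0,
    dilution_factor: float = 2.0,
    replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> TitrationDataset:
    """Simulate equilibrium SPR responses over a serial-dilution dose series.

    A ``fold_range`` of 256 with 2-fold dilutions gives 9 concentrations;
    each is measured ``replicates`` times.
    """
    if top_conc <= 0:
        raise ValueError("top concentration must be positive")
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    n_conc = int(round(math.log(fold_range) / math.log(dilution_factor))) + 1
    concs = top_conc / dilution_factor ** np.arange(n_conc - 1, -1, -1, dtype=float)
    x = np.tile(concs, replicates)
    rep = np.repeat(np.arange(1, replicates + 1), n_conc)
    y = binding.spr_req(kd, rmax, x)
    if noise.spr_noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise.spr_noise_sd * rmax, y.shape)
    return TitrationDataset(
        assay="spr",
        x=x,
        y=y,
        replicate=rep,
        design={"rmax": rmax, "top_conc": top_conc, "true_kd": kd, "seed": seed},
    )


def simulate_mst(
    kd: float,
    fnorm_unbound: float = 850.0,
    fnorm_bound: float = 900.0,
    protein_conc: float = 60e-9,
    conc_series: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> TitrationDataset:
    """Simulate an MST dose–response series (Hill n = 1, no depletion)."""
    if fnorm_bound == fnorm_unbound:
        raise ValueError("no signal window: bound and unbound Fnorm are equal")
    if conc_series is None:
        conc_series = 500e-6 / 2.0 ** np.arange(15, -1, -1, dtype=float)
    x = np.asarray(conc_series, dtype=float)
    if protein_conc > kd / 10.0:
        _warnings.warn(
            "protein concentration within 10x of Kd; "
            "the no-depletion model is approximate",
            RuntimeWarning,
        )
    y = binding.mst_fnorm(kd, fnorm_unbound, fnorm_bound, x)
    if noise.mst_noise_sd > 0:
        rng = np.random.default_rng(seed)
        span = abs(fnorm_bound - fnorm_unbound)
        y = y + rng.normal(0.0, noise.mst_noise_sd * span, y.shape)
    return TitrationDataset(
        assay="mst",
        x=x,
        y=y,
        design={
            "protein_conc": protein_conc,
            "true_kd": kd,
            "fnorm_unbound": fnorm_unbound,
            "fnorm_bound": fnorm_bound,
            "seed": seed,
        },
    )
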