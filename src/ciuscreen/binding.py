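"""Equilibrium binding-affinity models: one-site ITC, 1:1 SPR, MST Hill n=1.

Each assay has a closed-form model function plus a Model class whose
``fit()`` returns an :class:`AffinityResults` carrying the estimates, their
standard errors and fit diagnostics.

Units: concentrations in molar (M), ITC heats in μcal with ΔH in kcal/mol,
SPR responses in resonance units (RU), MST responses in Fnorm (Fhot/Fcold,
typically reported ×1000).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .datatypes import TitrationDataset

__all__ = [
    "ITCDesign",
    "itc_heats",
    "spr_req",
    "mst_fnorm",
    "mst_fraction_bound",
    "AffinityResults",
    "ITCOneSiteModel",
    "SPRSteadyStateModel",
    "MSTHillModel",
    "fit_itc_one_site",
    "fit_spr_steady_state",
    "fit_mst_hill",
]

KCAL_TO_UCAL = 1e9
LN10 = math.log(10.0)


@dataclass(frozen=True)
class ITCDesign:
    """Titration design: cell/syringe concentrations (M) and volumes (μL)."""

    cell_conc: float = 20e-6
    syringe_conc: float = 200e-6
    cell_volume_ul: float = 200.0
    inj_volume_ul: float = 2.0
    n_inj: int = 19

    def __post_init__(self) -> None:
        if min(self.cell_conc, self.syringe_conc, self.cell_volume_ul,
               self.inj_volume_ul) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if self.n_inj < 1:
            raise ValueError("need at least one injection")


def _diluted_concentrations(design: ITCDesign) -> tuple[np.ndarray, np.ndarray]:
    """Cell (Mt) and titrant (Xt) concentrations after each injection.

    Displaced-volume bookkeeping: each injection pushes mixed cell contents
    out of the fixed working volume V0.  With d = cumulative injected
    volume / V0, the second-order-accurate continuous-displacement forms are

        Mt = M0 (1 - d/2) / (1 + d/2),   Xt = X0 d / (1 + d/2).
    """
    i = np.arange(1, design.n_inj + 1)
    d = i * design.inj_volume_ul / design.cell_volume_ul
    mt = design.cell_conc * (1 - d / 2) / (1 + d / 2)
    xt = design.syringe_conc * d / (1 + d / 2)
    return mt, xt


def itc_heats(
    kd: float, n_stoich: float, dh_kcal: float, design: ITCDesign
) -> np.ndarray:
    """Per-injection heats (μcal) from the one-site binding isotherm.

    Cumulative heat after injection i:

        Q_i = (n Mt ΔH V0 / 2) [1 + r + K - sqrt((1 + r + K)^2 - 4r)]

    with r = Xt/(n Mt), K = Kd/(n Mt); the observed injection heat corrects
    for the heat carried out by the displaced volume:

        ΔQ_i = Q_i + (dV_i/V0) (Q_i + Q_{i-1})/2 - Q_{i-1}.
    """
    if kd < 0:
        raise ValueError("kd must be non-negative")
    if n_stoich <= 0:
        raise ValueError("stoichiometry must be positive")
    mt, xt = _diluted_concentrations(design)
    v0_l = design.cell_volume_ul * 1e-6
    r = xt / (n_stoich * mt)
    k = kd / (n_stoich * mt)
    disc = (1 + r + k) ** 2 - 4 * r
    if np.any(disc < 0):
        _warnings.warn("isotherm discriminant clamped at zero", RuntimeWarning)
        disc = np.clip(disc, 0.0, None)
    q_cum = (
        n_stoich * mt * dh_kcal * v0_l / 2.0 * (1 + r + k - np.sqrt(disc))
    ) * KCAL_TO_UCAL
    dq = np.empty_like(q_cum)
    frac = design.inj_volume_ul / design.cell_volume_ul
    prev = 0.0
    for j, q in enumerate(q_cum):
        dq[j] = q + frac * (q + prev) / 2.0 - prev
        prev = q
    return dq


def spr_req(kd: float, rmax: float, conc) -> np.ndarray | float:
    """Equilibrium SPR response for a 1:1 interaction: Req = Rmax C/(Kd + C)."""
    c = np.asarray(conc, dtype=float)
    out = rmax * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def mst_fnorm(kd: float, fnorm_unbound: float, fnorm_bound: float, conc):
    """MST dose response (Hill n = 1, no ligand depletion)."""
    c = np.asarray(conc, dtype=float)
    out = fnorm_unbound + (fnorm_bound - fnorm_unbound) * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def bound_fraction_equilibrium(p_total: float, l_total: float, kd: float) -> float:
    """Fraction of protein ligand-bound at equilibrium (quadratic solve).

    [PL] is the smaller root of [PL]^2 - (P+L+Kd)[PL] + P·L = 0.
    """
    if min(p_total, l_total) < 0 or kd < 0:
        raise ValueError("concentrations and kd must be non-negative")
    if p_total == 0:
        return 0.0
    s = p_total + l_total + kd
    pl = (s - math.sqrt(s * s - 4.0 * p_total * l_total)) / 2.0
    return pl / p_total


def mst_fraction_bound(fnorm, fnorm_unbound: float, fnorm_bound: float):
    """Fraction bound = (Fnorm - Fnorm[unbound]) / (Fnorm[bound] - Fnorm[unbound])."""
    window = fnorm_bound - fnorm_unbound
    if window == 0:
        raise ValueError("no signal window: bound and unbound Fnorm are equal")
    out = (np.asarray(fnorm, dtype=float) - fnorm_unbound) / window
    return float(out) if out.ndim == 0 else out


@dataclass
class AffinityResults:
    """Fitted affinity with standard errors and diagnostics.

    ``params``/``bse`` hold the assay-specific parameter set; ``kd`` and
    ``kd_se`` are always present (M).
    """

    assay: str
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    nobs: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.params["kd"] <= 0:
            raise ValueError("fitted kd must be positive")
        if any(v < 0 for v in self.bse.values()):
            raise ValueError("standard errors must be non-negative")

    @property
    def kd(self) -> float:
        return self.params["kd"]

    @property
    def kd_se(self) -> float:
        return self.bse["kd"]

    def summary(self) -> str:
        title = {
            "itc": "ITC one-site binding fit",
            "spr": "SPR 1:1 steady-state affinity fit",
            "mst": "MST Hill (n = 1) fit",
        }[self.assay]
        lines = [title, "=" * len(title)]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:>14s}  {value: .6g}  (se {se:.3g})")
        lines.append(f"{'rss':>14s}  {self.rss:.6g}   nobs {self.nobs}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def _kd_param(params: lmfit.Parameters, kd_init: float) -> None:
    # kd is fitted on a log10 scale: strictly positive and well-conditioned
    # regardless of the concentration unit the data arrive in
    params.add("log10_kd", value=math.log10(max(kd_init, 1e-18)), min=-18, max=12)


def _kd_and_se(result: lmfit.minimizer.MinimizerResult) -> tuple[float, float]:
    p = result.params["log10_kd"]
    kd = 10.0 ** p.value
    se = LN10 * kd * (p.stderr or 0.0)
    return kd, se


class ITCOneSiteModel:
    """One-site ITC binding model fitted to per-injection heats.

    Free parameters: Kd, stoichiometry n, molar enthalpy ΔH (kcal/mol).
    """

    def __init__(self, data: TitrationDataset) -> None:
        if data.assay != "itc":
            raise ValueError("ITCOneSiteModel requires an ITC dataset")
        if data.y.size < 6:
            raise ValueError("need at least 6 injections to fit three parameters")
        if not np.any(data.y != 0):
            raise ValueError("all injection heats are zero: no binding signal")
        design = data.design
        self.design = ITCDesign(
            cell_conc=design["cell_conc"],
            syringe_conc=design["syringe_conc"],
            cell_volume_ul=design.get("cell_volume_ul", 200.0),
            inj_volume_ul=design.get("inj_volume_ul", 2.0),
            n_inj=int(data.y.size),
        )
        self.data = data

    def _initial(self) -> lmfit.Parameters:
        y = self.data.y
        design = self.design
        params = lmfit.Parameters()
        # half-saturation heuristic: Kd ~ a twentieth of the cell
        # concentration puts the initial c-value in the Wiseman window
        _kd_param(params, design.cell_conc / 20.0)
        params.add("n_stoich", value=1.0, min=0.05, max=5.0)
        inj_mol = design.syringe_conc * design.inj_volume_ul * 1e-6
        dh0 = float(y[0]) / (inj_mol * KCAL_TO_UCAL)
        params.add("dh_kcal", value=dh0 if dh0 != 0 else -1.0)
        return params

    def fit(self) -> AffinityResults:
        y = self.data.y

        def resid(p):
            model = itc_heats(
                10.0 ** p["log10_kd"].value,
                p["n_stoich"].value,
                p["dh_kcal"].value,
                self.design,
            )
            return model - y

        out = lmfit.minimize(resid, self._initial())
        kd, kd_se = _kd_and_se(out)
        warn = []
        c_value = out.params["n_stoich"].value * self.design.cell_conc / kd
        if not (1.0 <= c_value <= 1000.0):
            warn.append(
                f"c-value {c_value:.3g} outside the Wiseman window [1, 1000]; "
                "Kd weakly constrained by isotherm shape"
            )
        return AffinityResults(
            assay="itc",
            params={
                "kd": kd,
                "n_stoich": out.params["n_stoich"].value,
                "dh_kcal": out.params["dh_kcal"].value,
            },
            bse={
                "kd": kd_se,
                "n_stoich": out.params["n_stoich"].stderr or 0.0,
                "dh_kcal": out.params["dh_kcal"].stderr or 0.0,
            },
            rss=float(np.sum(out.residual**2)),
            nobs=int(y.size),
            warnings=warn,
        )


class SPRSteadyStateModel:
    """1:1 steady-state SPR affinity model: Req = Rmax C / (Kd + C)."""

    def __init__(self, data: TitrationDataset) -> None:
        if data.assay != "spr":
            raise ValueError("SPRSteadyStateModel requires an SPR dataset")
        if np.unique(data.x[data.x > 0]).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        if not np.any(data.y > 0):
            raise ValueError("responses non-positive everywhere: no binding signal")
        self.data = data

    def _initial(self) -> lmfit.Parameters:
        x, y = self.data.x, self.data.y
        params = lmfit.Parameters()
        ymax = float(y.max())
        half = x[y >= ymax / 2.0]
        _kd_param(params, float(half.min()) if half.size else float(np.median(x)))
        params.add("rmax", value=1.1 * ymax, min=0.0)
        return params

    def fit(self) -> AffinityResults:
        x, y = self.data.x, self.data.y

        def resid(p):
            return spr_req(10.0 ** p["log10_kd"].value, p["rmax"].value, x) - y

        out = lmfit.minimize(resid, self._initial())
        kd, kd_se = _kd_and_se(out)
        warn = []
        if float(x.max()) < kd:
            warn.append(
                f"top concentration {x.max():.3g} M below fitted Kd {kd:.3g} M; "
                "saturation not reached, fit unreliable"
            )
        return AffinityResults(
            assay="spr",
            params={"kd": kd, "rmax": out.params["rmax"].value},
            bse={"kd": kd_se, "rmax": out.params["rmax"].stderr or 0.0},
            rss=float(np.sum(out.residual**2)),
            nobs=int(y.size),
            warnings=warn,
        )


class MSTHillModel:
    """MST dose–response with a Hill coefficient fixed at 1.

    Fits (Kd, Fnorm_unbound, Fnorm_bound); no ligand-depletion correction,
    valid when the labelled-protein concentration is well below Kd.
    """

    def __init__(self, data: TitrationDataset) -> None:
        if data.assay != "mst":
            raise ValueError("MSTHillModel requires an MST dataset")
        if np.ptp(data.y) == 0:
            raise ValueError("no signal window: Fnorm constant across the series")
        self.data = data

    def _initial(self) -> lmfit.Parameters:
        x, y = self.data.x, self.data.y
        order = np.argsort(x)
        f0, f1 = float(y[order[0]]), float(y[order[-1]])
        params = lmfit.Parameters()
        mid = f0 + 0.5 * (f1 - f0)
        crossing = x[np.abs(y - mid) == np.abs(y - mid).min()]
        _kd_param(params, float(crossing[0]) if crossing.size else float(np.median(x)))
        params.add("fnorm_unbound", value=f0)
        params.add("fnorm_bound", value=f1)
        return params

    def fit(self) -> AffinityResults:
        x, y = self.data.x, self.data.y

        def resid(p):
            return (
                mst_fnorm(
                    10.0 ** p["log10_kd"].value,
                    p["fnorm_unbound"].value,
                    p["fnorm_bound"].value,
                    x,
                )
                - y
            )

        out = lmfit.minimize(resid, self._initial())
        f0 = out.params["fnorm_unbound"].value
        f1 = out.params["fnorm_bound"].value
        if abs(f1 - f0) < 1e-9 * max(abs(f0), abs(f1), 1.0):
            raise RuntimeError("signal window collapsed during fit")
        kd, kd_se = _kd_and_se(out)
        warn = []
        protein_conc = self.data.design.get("protein_conc")
        if protein_conc is not None and protein_conc > kd / 10.0:
            warn.append(
                "protein concentration within 10x of Kd; "
                "no-depletion assumption questionable"
            )
        return AffinityResults(
            assay="mst",
            params={"kd": kd, "fnorm_unbound": f0, "fnorm_bound": f1},
            bse={
                "kd": kd_se,
                "fnorm_unbound": out.params["fnorm_unbound"].stderr or 0.0,
                "fnorm_bound": out.params["fnorm_bound"].stderr or 0.0,
            },
            rss=float(np.sum(out.residual**2)),
            nobs=int(y.size),
            warnings=warn,
        )


def fit_itc_one_site(data: TitrationDataset) -> AffinityResults:
    return ITCOneSiteModel(data).fit()


def fit_spr_steady_state(data: TitrationDataset) -> AffinityResults:
    return SPRSteadyStateModel(data).fit()


def fit_mst_hill(data: TitrationDataset) -> AffinityResults:
    return MSTHillModel(data).fit()
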