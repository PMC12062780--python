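"""Diagnostic plots for fits and fingerprints (matplotlib)."""

from __future__ import annotations

import numpy as np

from .binding import AffinityResults, itc_heats, ITCDesign, mst_fnorm, spr_req
from .datatypes import ArrivalTimeDistribution, TitrationDataset
from .mobility import CIUFingerprint, ConformerFit, _two_gaussians

__all__ = ["plot_conformer_fit", "plot_fingerprints", "plot_affinity_fit"]


def plot_conformer_fit(atd: ArrivalTimeDistribution, fit: ConformerFit, ax=None):
    """Overlay the two fitted conformers on the raw ATD."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = atd.drift_time
    sqrt2pi = np.sqrt(2 * np.pi)
    a1 = fit.compact_area / (fit.width_sd * sqrt2pi)
    a2 = fit.extended_area / (fit.width_sd * sqrt2pi)
    ax.plot(t, atd.intensity, color="0.4", lw=0.8, label="data")
    ax.plot(
        t,
        _two_gaussians(t, a1, a2, fit.compact_center, fit.extended_center, fit.width_sd),
        "k-",
        label="fit",
    )
    for c, a, name in (
        (fit.compact_center, a1, "compact"),
        (fit.extended_center, a2, "extended"),
    ):
        ax.plot(t, a * np.exp(-0.5 * ((t - c) / fit.width_sd) ** 2), "--", label=name)
    ax.set_xlabel("drift time (ms)")
    ax.set_ylabel("intensity")
    ax.legend(frameon=False)
    ax.set_title(f"unfolded: {fit.unfold_percent:.1f}% of base peak")
    return ax


def plot_fingerprints(fingerprints: list[CIUFingerprint], ax=None):
    """Unfolded percent vs trap voltage, one line per inhibitor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for fp in fingerprints:
        vs = fp.voltages
        means = [fp.per_voltage[v].mean for v in vs]
        sds = [fp.per_voltage[v].sd for v in vs]
        ax.errorbar(vs, means, yerr=sds, marker="o", capsize=3, label=fp.inhibitor)
    ax.set_xlabel("trap voltage (V)")
    ax.set_ylabel("extended conformer (% of base peak)")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_affinity_fit(data: TitrationDataset, fit: AffinityResults, ax=None):
    """Overlay the fitted binding model on the titration data."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = fit.params
    if fit.assay == "itc":
        design = ITCDesign(
            cell_conc=data.design["cell_conc"],
            syringe_conc=data.design["syringe_conc"],
            cell_volume_ul=data.design.get("cell_volume_ul", 200.0),
            inj_volume_ul=data.design.get("inj_volume_ul", 2.0),
            n_inj=int(data.y.size),
        )
        model = itc_heats(p["kd"], p["n_stoich"], p["dh_kcal"], design)
        ax.plot(data.x, data.y, "ko", label="injection heats")
        ax.plot(data.x, model, "r-", label="one-site fit")
        ax.set_xlabel("injection")
        ax.set_ylabel("heat (μcal)")
    else:
        grid = np.geomspace(data.x[data.x > 0].min(), data.x.max(), 200)
        if fit.assay == "spr":
            model = spr_req(p["kd"], p["rmax"], grid)
            ax.set_ylabel("Req (RU)")
        else:
            model = mst_fnorm(p["kd"], p["fnorm_unbound"], p["fnorm_bound"], grid)
            ax.set_ylabel("Fnorm")
        ax.semilogx(data.x, data.y, "ko", label="data")
        ax.semilogx(grid, model, "r-", label="fit")
        ax.set_xlabel("concentration (M)")
    ax.legend(frameon=False)
    ax.set_title(f"Kd = {fit.kd:.3g} M")
    return ax
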