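"""Affinity models: isotherm algebra vs a brute-force oracle, fit recovery."""

import numpy as np
import pytest

from ciuscreen.binding import (
    ITCDesign,
    ITCOneSiteModel,
    bound_fraction_equilibrium,
    fit_itc_one_site,
    fit_mst_hill,
    fit_spr_steady_state,
    itc_heats,
    mst_fraction_bound,
    spr_req,
)
from ciuscreen.datatypes import TitrationDataset
from ciuscreen.synthdata import (
    NOISELESS,
    NoiseModel,
    simulate_itc,
    simulate_mst,
    simulate_spr,
)

from conftest import oracle_itc_heats

DESIGNS = [
    ITCDesign(),  # 19 x 2 uL of 200 uM into 20 uM in 200 uL
    ITCDesign(cell_conc=10e-6, syringe_conc=150e-6, cell_volume_ul=250.0,
              inj_volume_ul=1.5, n_inj=25),
]


class TestITCModel:
    @pytest.mark.parametrize("design", DESIGNS)
    @pytest.mark.parametrize("kd,n,dh", [
        (36e-9, 1.0, -10.0),
        (2e-6, 0.8, -6.5),
        (50e-6, 1.2, 4.0),
    ])
    def test_matches_equilibrium_oracle(self, design, kd, n, dh):
        """The closed-form isotherm equals a direct quadratic solve of [PL]
        followed by the same heat bookkeeping, on every injection."""
        model = itc_heats(kd, n, dh, design)
        oracle = oracle_itc_heats(kd, n, dh, design)
        scale = np.abs(oracle).max()
        assert np.all(np.abs(model - oracle) <= 1e-6 * scale)

    def test_zero_enthalpy_gives_zero_heats(self):
        assert np.allclose(itc_heats(36e-9, 1.0, 0.0, ITCDesign()), 0.0)

    def test_stoichiometric_limit(self):
        """At Kd -> 0 each pre-equivalence injection releases the heat of the
        moles injected; post-equivalence injections release ~nothing."""
        design = ITCDesign()
        heats = itc_heats(1e-18, 1.0, -10.0, design)
        inj_mol = design.syringe_conc * design.inj_volume_ul * 1e-6
        per_inj = -10.0 * inj_mol * 1e9  # ucal
        # equivalence at Xt/Mt = 1: 20 uM * 200 uL needs 4 nmol = 10 injections
        assert np.allclose(heats[:8], per_inj, rtol=1e-2)
        assert np.all(np.abs(heats[12:]) < 1e-2 * np.abs(per_inj))

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            ITCDesign(cell_conc=0.0)
        with pytest.raises(ValueError):
            itc_heats(1e-9, 0.0, -10.0, ITCDesign())


class TestITCFit:
    def test_noiseless_recovery_at_reported_affinity(self):
        fit = fit_itc_one_site(simulate_itc(36e-9, noise=NOISELESS))
        assert fit.kd == pytest.approx(36e-9, rel=0.01)
        assert fit.params["n_stoich"] == pytest.approx(1.0, abs=0.01)
        assert fit.params["dh_kcal"] == pytest.approx(-10.0, rel=0.01)

    def test_substoichiometric_recovery(self):
        ds = simulate_itc(200e-9, n_stoich=0.5, noise=NOISELESS)
        fit = fit_itc_one_site(ds)
        assert fit.params["n_stoich"] == pytest.approx(0.50, abs=0.01)

    def test_all_zero_heats_rejected(self):
        ds = simulate_itc(36e-9, dh_kcal=0.0, noise=NOISELESS)
        with pytest.raises(ValueError, match="zero"):
            fit_itc_one_site(ds)

    def test_wiseman_window_warning(self):
        ds = simulate_itc(1e-12, noise=NOISELESS)  # c-value ~2e7
        fit = fit_itc_one_site(ds)
        assert any("c-value" in w for w in fit.warnings)

    def test_too_few_injections_rejected(self):
        ds = simulate_itc(36e-9, n_inj=4, noise=NOISELESS)
        with pytest.raises(ValueError):
            ITCOneSiteModel(ds)

    def test_median_bias_small_under_noise(self):
        """Across 100 noisy titrations at the standard design, the median
        relative bias of the fitted Kd stays below 5%."""
        noise = NoiseModel()  # 0.1 ucal heat noise
        errs = []
        for seed in range(100):
            ds = simulate_itc(36e-9, noise=noise, seed=seed)
            errs.append(fit_itc_one_site(ds).kd / 36e-9 - 1.0)
        assert abs(np.median(errs)) < 0.05


class TestSPR:
    def test_half_saturation_response(self):
        assert spr_req(37e-6, 100.0, 37e-6) == pytest.approx(50.0)
        assert spr_req(37e-6, 100.0, 0.0) == 0.0

    @pytest.mark.parametrize("kd,top", [(37e-6, 500e-6), (8e-9, 1e-6)])
    def test_noiseless_recovery(self, kd, top):
        ds = simulate_spr(kd, top_conc=top, noise=NOISELESS)
        fit = fit_spr_steady_state(ds)
        assert fit.kd == pytest.approx(kd, rel=0.01)

    def test_unsaturated_design_flagged(self):
        ds = simulate_spr(37e-6, top_conc=37e-8, noise=NOISELESS)
        fit = fit_spr_steady_state(ds)
        assert any("saturation" in w for w in fit.warnings)

    def test_nonpositive_responses_rejected(self):
        ds = TitrationDataset(
            assay="spr",
            x=np.geomspace(1e-9, 1e-5, 9),
            y=np.zeros(9),
        )
        with pytest.raises(ValueError):
            fit_spr_steady_state(ds)


class TestMST:
    def test_fraction_bound_formula(self):
        assert mst_fraction_bound(850.0, 850.0, 900.0) == 0.0
        assert mst_fraction_bound(900.0, 850.0, 900.0) == 1.0
        assert mst_fraction_bound(875.0, 850.0, 900.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            mst_fraction_bound(875.0, 850.0, 850.0)

    def test_noiseless_recovery(self):
        ds = simulate_mst(25e-6, noise=NOISELESS)
        fit = fit_mst_hill(ds)
        assert fit.kd == pytest.approx(25e-6, rel=0.01)
        assert fit.params["fnorm_unbound"] == pytest.approx(850.0, rel=1e-3)
        assert fit.params["fnorm_bound"] == pytest.approx(900.0, rel=1e-3)

    def test_constant_fnorm_rejected(self):
        ds = TitrationDataset(
            assay="mst", x=np.geomspace(1e-8, 5e-4, 16), y=np.full(16, 850.0)
        )
        with pytest.raises(ValueError):
            fit_mst_hill(ds)


class TestUnitsAndSummaries:
    def test_kd_unit_round_trip(self):
        """Rescaling all concentrations rescales the fitted Kd identically."""
        ds = simulate_spr(37e-6, noise=NOISELESS)
        scaled = TitrationDataset(
            assay="spr", x=ds.x * 1e9, y=ds.y, replicate=ds.replicate,
            design=ds.design,
        )
        kd_m = fit_spr_steady_state(ds).kd
        kd_nm = fit_spr_steady_state(scaled).kd
        assert kd_nm == pytest.approx(kd_m * 1e9, rel=1e-6)

    def test_summary_lists_parameters(self):
        fit = fit_itc_one_site(simulate_itc(36e-9, noise=NOISELESS))
        text = fit.summary()
        assert "kd" in text and "n_stoich" in text and "dh_kcal" in text

    def test_equilibrium_bound_fraction(self):
        # kd == both concentrations: [PL] = (3 - sqrt(5))/2 * C
        bf = bound_fraction_equilibrium(1e-6, 1e-6, 1e-6)
        assert bf == pytest.approx((3 - np.sqrt(5)) / 2, rel=1e-12)
        assert bound_fraction_equilibrium(1e-6, 0.0, 1e-6) == 0.0
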