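"""Generator correctness: closed-form peak positions, truth model, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciuscreen.classify import TYPE_I, TYPE_II
from ciuscreen.constants import PROTON_MASS
from ciuscreen.synthdata import (
    NOISELESS,
    InhibitorProfile,
    NoiseModel,
    PanelSpec,
    default_drift_grid,
    simulate_atd,
    simulate_ciu_panel,
    simulate_itc,
    simulate_mst,
    simulate_native_spectrum,
    simulate_spr,
    simulate_stripping_series,
    truth_from_latent,
)

APO_APEXES = {
    # (36000 + z * 1.00728) / z, evaluated independently
    11: 3273.734,
    12: 3001.007,
    13: 2770.238,
}


class TestNativeSpectrum:
    def test_apo_apexes_match_closed_form(self):
        ms = simulate_native_spectrum(36000.0, noise=NOISELESS)
        step = ms.mz[1] - ms.mz[0]
        for z, expected in APO_APEXES.items():
            window = np.abs(ms.mz - expected) < 5.0
            apex = ms.mz[window][np.argmax(ms.intensity[window])]
            assert apex == pytest.approx(expected, abs=step)

    def test_unbound_sample_has_no_holo_peaks(self):
        apo = simulate_native_spectrum(36000.0, noise=NOISELESS)
        holo_mz = (36000.0 + 532.5 + np.array([11, 12, 13]) * PROTON_MASS) / np.array(
            [11, 12, 13]
        )
        for m in holo_mz:
            near = np.abs(apo.mz - m) < 2.0
            if not near.any():  # outside the simulated window: trivially absent
                continue
            # anything there is only the tail of the neighbouring apo peak
            assert apo.intensity[near].max() < 1e-3 * apo.base_peak_height

    def test_half_bound_gives_equal_apo_holo_heights(self):
        ms = simulate_native_spectrum(
            36000.0, ligand_mass=532.5, bound_fraction=0.5, noise=NOISELESS
        )
        for z in (11, 12, 13):
            apo_m = (36000.0 + z * PROTON_MASS) / z
            holo_m = (36000.0 + 532.5 + z * PROTON_MASS) / z
            h_apo = ms.intensity[np.argmin(np.abs(ms.mz - apo_m))]
            h_holo = ms.intensity[np.argmin(np.abs(ms.mz - holo_m))]
            # tolerance covers the grid-sampling offset of the two apexes
            assert h_apo == pytest.approx(h_holo, rel=1e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"charges": ()},
            {"bound_fraction": 1.0, "ligand_mass": 0.0},
            {"bound_fraction": 1.5},
            {"protein_mass": -1.0},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_native_spectrum(**{"protein_mass": 36000.0, **kwargs})

    def test_seed_determinism(self):
        a = simulate_native_spectrum(36000.0, seed=7)
        b = simulate_native_spectrum(36000.0, seed=7)
        assert np.array_equal(a.intensity, b.intensity)
        c = simulate_native_spectrum(36000.0, seed=8)
        assert not np.array_equal(a.intensity, c.intensity)


class TestATD:
    def test_zero_unfold_is_single_component(self):
        atd = simulate_atd(0.0, noise=NOISELESS)
        # no intensity above noise floor at the extended center
        i_ext = np.argmin(np.abs(atd.drift_time - 7.6))
        assert atd.intensity[i_ext] < 1e-6 * atd.intensity.max()

    def test_full_unfold_has_equal_apexes(self):
        atd = simulate_atd(100.0, noise=NOISELESS)
        t = atd.drift_time
        h_c = atd.intensity[np.argmin(np.abs(t - 5.5))]
        h_e = atd.intensity[np.argmin(np.abs(t - 7.6))]
        assert h_c == pytest.approx(h_e, rel=1e-6)

    @pytest.mark.parametrize("unfold", [0.0, 27.6, 48.9, 76.7, 120.0])
    def test_area_conservation(self, unfold):
        atd = simulate_atd(unfold, noise=NOISELESS)
        total = np.trapezoid(atd.intensity, atd.drift_time)
        analytic = 100.0 * 0.35 * np.sqrt(2 * np.pi) * (1 + unfold / 100.0)
        assert total == pytest.approx(analytic, rel=1e-6)

    def test_coarse_grid_records_warning(self):
        grid = np.arange(0.0, 14.0, 0.5)
        atd = simulate_atd(50.0, grid=grid, noise=NOISELESS)
        assert "warning" in atd.metadata

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_atd(10.0, grid=np.arange(6.0, 14.0, 0.07))

    def test_seed_determinism(self):
        a = simulate_atd(40.0, seed=3)
        b = simulate_atd(40.0, seed=3)
        assert np.array_equal(a.intensity, b.intensity)


class TestPanelTruthModel:
    def test_latent_zero_recovers_class_means(self):
        assert truth_from_latent(0.0, 21.0, TYPE_I) == pytest.approx(27.6)
        assert truth_from_latent(0.0, 21.0, TYPE_II) == pytest.approx(48.9)
        assert truth_from_latent(0.0, 24.0, TYPE_I) == pytest.approx(44.2)
        assert truth_from_latent(0.0, 24.0, TYPE_II) == pytest.approx(76.7)

    @given(st.floats(-6, 6), st.sampled_from([TYPE_I, TYPE_II]))
    @settings(deadline=None)
    def test_truth_monotone_in_voltage_for_any_latent(self, u, cls):
        assert truth_from_latent(u, 24.0, cls) > truth_from_latent(u, 21.0, cls)

    @given(st.floats(-6, 6))
    def test_truth_respects_class_ranges(self, u):
        assert 22.0 <= truth_from_latent(u, 21.0, TYPE_I) <= 35.0
        assert 40.0 <= truth_from_latent(u, 21.0, TYPE_II) <= 60.0
        assert 30.0 <= truth_from_latent(u, 24.0, TYPE_I) <= 50.0
        assert 64.0 <= truth_from_latent(u, 24.0, TYPE_II) <= 95.0

    def test_panel_truth_in_range_and_monotone(self):
        panel = simulate_ciu_panel(PanelSpec(seed=11))
        t = panel.truth
        t2 = t[(t.true_class == TYPE_II) & (t.voltage == 24.0)]
        assert ((t2.truth_percent >= 64.0) & (t2.truth_percent <= 95.0)).all()
        wide = t.pivot(index="inhibitor", columns="voltage", values="truth_percent")
        assert (wide[24.0] > wide[21.0]).all()

    def test_panel_shape_and_determinism(self):
        spec = PanelSpec(seed=5)
        a = simulate_ciu_panel(spec)
        b = simulate_ciu_panel(spec)
        assert len(a.atds) == 10 * 2 * 3
        assert all(
            np.array_equal(x.intensity, y.intensity) for x, y in zip(a.atds, b.atds)
        )
        assert a.truth.equals(b.truth)

    def test_explicit_truth_profile_is_honoured(self):
        prof = InhibitorProfile(
            "custom", TYPE_I, 1e-7, 400.0,
            unfold_score_truth={21.0: 25.0, 24.0: 45.0},
        )
        panel = simulate_ciu_panel(PanelSpec(inhibitors=(prof,), seed=1))
        assert set(panel.truth.truth_percent) == {25.0, 45.0}

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            InhibitorProfile("x", TYPE_I, -1.0, 400.0)
        with pytest.raises(ValueError):
            InhibitorProfile(
                "x", TYPE_I, 1e-6, 400.0,
                unfold_score_truth={21.0: 50.0, 24.0: 40.0},
            )
        with pytest.raises(ValueError):
            PanelSpec(replicates=0)


class TestStripping:
    def test_logistic_midpoint_and_zero(self):
        out = simulate_stripping_series(0.8, [20.0], v50=20.0)
        assert out[20.0] == pytest.approx(0.4)
        assert all(v == 0 for v in simulate_stripping_series(0.0, [6, 21, 24]).values())

    @given(
        st.floats(0.01, 1.0),
        st.floats(5.0, 35.0),
        st.floats(0.5, 10.0),
    )
    @settings(deadline=None)
    def test_nonincreasing_in_voltage(self, b0, v50, steep):
        voltages = [6.0, 21.0, 24.0, 30.0, 39.0]
        out = simulate_stripping_series(b0, voltages, v50=v50, steepness=steep)
        series = [out[v] for v in voltages]
        assert all(b >= a for a, b in zip(series[1:], series))

    def test_bad_steepness_rejected(self):
        with pytest.raises(ValueError):
            simulate_stripping_series(0.5, [21.0], steepness=0.0)


class TestTitrationSimulators:
    def test_itc_zero_enthalpy_gives_zero_heats(self):
        ds = simulate_itc(36e-9, dh_kcal=0.0, noise=NOISELESS)
        assert np.allclose(ds.y, 0.0)

    def test_itc_no_binding_limit(self):
        ds = simulate_itc(kd=10.0, noise=NOISELESS)  # 1e9-fold above cell conc
        assert np.all(np.abs(ds.y) < 1e-3)

    def test_itc_huge_c_value_warns(self):
        with pytest.warns(RuntimeWarning):
            simulate_itc(kd=1e-15, noise=NOISELESS)

    def test_spr_design_yields_nine_concentrations(self):
        ds = simulate_spr(37e-6, noise=NOISELESS)
        assert np.unique(ds.x).size == 9
        assert ds.x.size == 27  # triplicates

    def test_mst_requires_signal_window(self):
        with pytest.raises(ValueError):
            simulate_mst(25e-6, fnorm_unbound=850.0, fnorm_bound=850.0)

    def test_mst_depletion_warning(self):
        with pytest.warns(RuntimeWarning):
            simulate_mst(100e-9, protein_conc=60e-9, noise=NOISELESS)

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(spectrum_noise_sd=-0.1)

    def test_titration_seed_determinism(self):
        a = simulate_itc(36e-9, seed=2)
        b = simulate_itc(36e-9, seed=2)
        assert np.array_equal(a.y, b.y)


def test_default_grid_is_200_bins():
    grid = default_drift_grid()
    assert grid.size == 200
    assert np.allclose(np.diff(grid), 0.07)
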