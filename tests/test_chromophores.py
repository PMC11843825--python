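"""Chromophore library and layered forward model."""

import numpy as np
import pytest

from burndyn.chromophores import (
    ChromophoreLoadError,
    LayerModelConfig,
    PerfusionProfile,
    RemissionSpectrum,
    isosbestic_wavelength,
    layer_absorption,
    load_chromophores,
    read_spectrum_csv,
    render_spectrum,
    write_spectrum_csv,
)


class TestLibrary:
    def test_default_grid_is_450_1000_step5(self, lib):
        assert lib.n_bands == 111
        assert lib.wavelengths[0] == 450.0
        assert lib.wavelengths[-1] == 1000.0
        assert np.allclose(np.diff(lib.wavelengths), 5.0)

    def test_curves_nonnegative_and_finite(self, lib):
        for name in ("eps_hbo2", "eps_hb", "mu_melanin", "mu_water", "mu_fat",
                     "mus_reduced"):
            arr = getattr(lib, name)
            assert np.all(np.isfinite(arr)) and np.all(arr >= 0)

    def test_isosbestic_point_exists_in_green(self, lib):
        wl = isosbestic_wavelength(lib)
        assert 500.0 <= wl <= 600.0
        # oxy and deoxy agree there within interpolation tolerance
        eo = np.interp(wl, lib.wavelengths, lib.eps_hbo2)
        ed = np.interp(wl, lib.wavelengths, lib.eps_hb)
        assert eo == pytest.approx(ed, abs=1e-9)

    def test_truncated_table_raises(self, tmp_path):
        src = tmp_path / "bad.csv"
        src.write_text("wavelength_nm,eps_hbo2\n450,1.0\n")
        with pytest.raises(ChromophoreLoadError):
            load_chromophores(src)

    def test_nan_entry_names_wavelength(self, tmp_path, lib):
        import pandas as pd

        df = pd.DataFrame(
            {
                "wavelength_nm": [450.0, 455.0, 460.0],
                "eps_hbo2": [1.0, np.nan, 1.0],
                "eps_hb": 1.0,
                "mu_melanin": 0.1,
                "mu_water": 0.0,
                "mu_fat": 0.0,
                "mus_reduced": 2.0,
            }
        )
        src = tmp_path / "nan.csv"
        df.to_csv(src, index=False)
        with pytest.raises(ChromophoreLoadError, match="455"):
            load_chromophores(src, grid=np.array([450.0, 455.0, 460.0]))


class TestLayerAbsorption:
    def test_zero_blood_gives_baseline_only(self, lib, model_cfg):
        p = PerfusionProfile(np.zeros(6), np.zeros(6))
        mu = layer_absorption(p, 3, lib, model_cfg)
        baseline = (model_cfg.f_water * lib.mu_water
                    + model_cfg.f_fat * lib.mu_fat)
        np.testing.assert_allclose(mu, baseline)

    def test_melanin_only_in_layer1(self, lib, model_cfg):
        p = PerfusionProfile(np.zeros(6), np.zeros(6))
        mu1 = layer_absorption(p, 1, lib, model_cfg)
        mu2 = layer_absorption(p, 2, lib, model_cfg)
        assert np.all(mu1 >= mu2)
        assert np.any(mu1 > mu2)

    def test_saturation_matters_at_560_not_at_isosbestic(self, lib, model_cfg):
        v = np.full(6, 0.5)
        oxy = PerfusionProfile(v, np.ones(6))
        deoxy = PerfusionProfile(v, np.zeros(6))
        mu_o = layer_absorption(oxy, 1, lib, model_cfg)
        mu_d = layer_absorption(deoxy, 1, lib, model_cfg)
        i560 = int(np.argmin(np.abs(lib.wavelengths - 560)))
        assert mu_o[i560] != pytest.approx(mu_d[i560], abs=1e-3)
        wl_iso = isosbestic_wavelength(lib)
        # evaluate on a grid containing the crossing
        grid = np.sort(np.append(lib.wavelengths, wl_iso))
        lib2 = load_chromophores(grid=grid)
        j = int(np.argmin(np.abs(lib2.wavelengths - wl_iso)))
        mu_o2 = layer_absorption(oxy, 1, lib2, model_cfg)
        mu_d2 = layer_absorption(deoxy, 1, lib2, model_cfg)
        assert mu_o2[j] == pytest.approx(mu_d2[j], abs=1e-9)

    def test_hemoglobin_term_linear_in_vhb(self, lib, model_cfg):
        x = np.full(6, 0.7)
        p1 = PerfusionProfile(np.full(6, 0.2), x)
        p2 = PerfusionProfile(np.full(6, 0.4), x)
        p0 = PerfusionProfile(np.zeros(6), x)
        mu0 = layer_absorption(p0, 2, lib, model_cfg)
        d1 = layer_absorption(p1, 2, lib, model_cfg) - mu0
        d2 = layer_absorption(p2, 2, lib, model_cfg) - mu0
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_bad_layer_index(self, lib, model_cfg):
        p = PerfusionProfile(np.zeros(6), np.zeros(6))
        with pytest.raises(ValueError):
            layer_absorption(p, 0, lib, model_cfg)
        with pytest.raises(ValueError):
            layer_absorption(p, 7, lib, model_cfg)


class TestRenderSpectrum:
    def test_bloodless_spectrum_ignores_saturation(self, lib, model_cfg):
        zero_v = np.zeros(6)
        a = render_spectrum(PerfusionProfile(zero_v, np.zeros(6)), lib, model_cfg)
        b = render_spectrum(PerfusionProfile(zero_v, np.ones(6)), lib, model_cfg)
        np.testing.assert_array_equal(a.remission, b.remission)
        assert np.all(a.remission > 0)

    def test_remission_decreases_with_upper_vhb_at_560(self, lib, model_cfg):
        i560 = int(np.argmin(np.abs(lib.wavelengths - 560)))
        vals = []
        for v1 in np.arange(0.0, 1.0001, 0.1):
            v = np.zeros(6)
            v[0] = v1
            spec = render_spectrum(
                PerfusionProfile(v, np.full(6, 0.5)), lib, model_cfg
            )
            vals.append(spec.remission[i560])
        assert np.all(np.diff(vals) < 0)

    def test_upper_layer_change_outweighs_deep_layer_change(self, lib, model_cfg):
        base = PerfusionProfile(np.full(6, 0.3), np.full(6, 0.6))
        r0 = render_spectrum(base, lib, model_cfg).remission

        def bumped(layer):
            v = np.full(6, 0.3)
            v[layer] += 0.2
            return render_spectrum(
                PerfusionProfile(v, np.full(6, 0.6)), lib, model_cfg
            ).remission

        d_top = np.linalg.norm(bumped(0) - r0)
        d_bottom = np.linalg.norm(bumped(5) - r0)
        assert d_top >= d_bottom

    def test_saturation_invariant_at_isosbestic_wavelength(self, lib, model_cfg):
        wl_iso = isosbestic_wavelength(lib)
        grid = np.sort(np.append(lib.wavelengths, wl_iso))
        lib2 = load_chromophores(grid=grid)
        j = int(np.argmin(np.abs(lib2.wavelengths - wl_iso)))
        v = np.full(6, 0.5)
        r1 = render_spectrum(PerfusionProfile(v, np.ones(6)), lib2, model_cfg)
        r0 = render_spectrum(PerfusionProfile(v, np.zeros(6)), lib2, model_cfg)
        assert abs(r1.remission[j] - r0.remission[j]) < 1e-6

    def test_output_range_and_reproducibility(self, lib, model_cfg, rng):
        for _ in range(20):
            p = PerfusionProfile(rng.uniform(0, 1, 6), rng.uniform(0, 1, 6))
            a = render_spectrum(p, lib, model_cfg)
            b = render_spectrum(p, lib, model_cfg)
            assert np.all((a.remission >= 0) & (a.remission <= 1))
            np.testing.assert_array_equal(a.remission, b.remission)

    def test_monotone_in_every_layer_at_hb_band(self, lib, model_cfg):
        i575 = int(np.argmin(np.abs(lib.wavelengths - 575)))
        for layer in range(6):
            prev = None
            for v in (0.0, 0.3, 0.6, 0.9):
                vv = np.full(6, 0.2)
                vv[layer] = v
                r = render_spectrum(
                    PerfusionProfile(vv, np.full(6, 0.5)), lib, model_cfg
                ).remission[i575]
                if prev is not None:
                    assert r <= prev + 1e-12
                prev = r


class TestProfileType:
    def test_zero_blood_layers_report_zero_saturation(self):
        p = PerfusionProfile(
            np.array([0.0, 0.5, 0, 0.5, 0, 0.5]),
            np.array([0.9, 0.9, 0.9, 0.9, 0.9, 0.9]),
        )
        np.testing.assert_array_equal(p.xhbo2[[0, 2, 4]], 0.0)
        np.testing.assert_array_equal(p.xhbo2[[1, 3, 5]], 0.9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PerfusionProfile(np.full(6, 1.2), np.zeros(6))
        with pytest.raises(ValueError):
            PerfusionProfile(np.zeros(5), np.zeros(5))


def test_spectrum_csv_round_trip(tmp_path, lib, model_cfg):
    p = PerfusionProfile(np.full(6, 0.4), np.full(6, 0.7))
    spec = render_spectrum(p, lib, model_cfg)
    path = tmp_path / "spec.csv"
    write_spectrum_csv(spec, path)
    back = read_spectrum_csv(path)
    np.testing.assert_allclose(back.remission, spec.remission, atol=1e-12)
    np.testing.assert_allclose(back.wavelengths, spec.wavelengths)


def test_remission_type_rejects_out_of_range():
    with pytest.raises(ValueError):
        RemissionSpectrum(np.array([450.0, 455.0]), np.array([0.5, 1.2]))
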