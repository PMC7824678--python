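"""Derivative spectrophotometry and partition-isotherm fitting."""

import numpy as np
import pytest

from drugmem import partition as pt
from drugmem import synthdata as sd


def make_spectrum(fn, lo=200.0, hi=300.0, step=1.0):
    wl = np.arange(lo, hi + step / 2, step)
    return pt.Spectrum(wl, fn(wl))


class TestThirdDerivative:
    def test_annihilates_quadratic(self):
        spec = make_spectrum(lambda x: 2.0 + 0.3 * x - 0.01 * x**2)
        d3 = pt.third_derivative(spec)
        interior = ~d3.edge_mask
        assert np.all(np.abs(d3.absorbance[interior]) < 1e-8)

    def test_cubic_gives_six_a3(self):
        a3 = 4e-4
        spec = make_spectrum(lambda x: 1.0 - 0.02 * x + a3 * (x - 250.0) ** 3)
        d3 = pt.third_derivative(spec)
        assert np.allclose(d3.absorbance[~d3.edge_mask], 6 * a3, rtol=1e-8)

    def test_gaussian_matches_analytic(self):
        # fwhm 30 nm band; compare pointwise against the closed-form third
        # derivative, relative to its extremum.
        sigma, center, amp = 30.0 / 2.355, 250.0, 1.0
        spec = make_spectrum(
            lambda x: amp * np.exp(-((x - center) ** 2) / (2 * sigma**2))
        )
        u = spec.wavelengths - center
        analytic = (
            amp
            * (3 * u / sigma**4 - u**3 / sigma**6)
            * np.exp(-(u**2) / (2 * sigma**2))
        )
        d3 = pt.third_derivative(spec, window_points=9, poly_order=5)
        interior = ~d3.edge_mask
        scale = np.max(np.abs(analytic))
        assert np.all(
            np.abs(d3.absorbance[interior] - analytic[interior]) < 0.01 * scale
        )

    @pytest.mark.parametrize(
        "window,poly,err",
        [(8, 4, "odd"), (5, 5, "odd"), (9, 2, "poly_order")],
    )
    def test_bad_smoothing_params_rejected(self, window, poly, err):
        spec = make_spectrum(lambda x: x)
        with pytest.raises(ValueError, match=err):
            pt.third_derivative(spec, window_points=window, poly_order=poly)

    def test_short_spectrum_rejected(self):
        spec = make_spectrum(lambda x: x, lo=200, hi=207)
        with pytest.raises(ValueError, match="shorter"):
            pt.third_derivative(spec, window_points=11)

    def test_nonuniform_grid_rejected(self):
        wl = np.array([200.0, 201.0, 202.0, 204.0, 205.0, 206.0, 207.0])
        with pytest.raises(ValueError, match="uniform"):
            pt.Spectrum(wl, np.zeros(7))


class TestExtractSeries:
    def make_titration(self, fn, concs=(0.0, 1e-4, 5e-4, 1e-3)):
        spectra = [make_spectrum(fn, 200, 400) for _ in concs]
        return pt.SpectraTitration(
            drug_conc=5e-6, lipid_concs=np.array(concs), spectra=spectra
        )

    def test_identical_spectra_give_constant_series(self):
        tit = self.make_titration(lambda x: np.sin(x / 20.0))
        series = pt.extract_series(tit, 300.0)
        assert np.allclose(series.d3_values, series.d3_values[0])

    def test_on_grid_wavelength_exact(self):
        tit = self.make_titration(lambda x: np.exp(-((x - 320) ** 2) / 200))
        series = pt.extract_series(tit, 321.0)
        d3 = pt.third_derivative(tit.spectra[0])
        idx = int(np.where(d3.wavelengths == 321.0)[0][0])
        assert series.d3_values[0] == d3.absorbance[idx]

    def test_edge_and_out_of_range_rejected(self):
        tit = self.make_titration(lambda x: x * 0.001)
        with pytest.raises(ValueError, match="edge"):
            pt.extract_series(tit, 200.0)
        with pytest.raises(ValueError, match="outside"):
            pt.extract_series(tit, 450.0)

    def test_matches_isotherm_shape_on_simulated_data(self):
        # noise-free simulated titration follows D_W + b*f_bound within 0.5%
        config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.0)
        tit = sd.simulate_spectra_titration(config)
        series = pt.extract_series(tit, 213.0)
        dw, b = tit.truth["dw_true"], tit.truth["b_true"]
        f_bound = config.kp_true * series.lipid_concs / (
            1 + config.kp_true * series.lipid_concs
        )
        expected = dw + b * f_bound
        assert np.all(np.abs(series.d3_values - expected) <= 0.005 * abs(b))


def grid_search_sse(L, y, kp_grid, b_grid):
    """Brute-force oracle: best SSE over a (Kp, b) grid, D_W profiled out."""
    best = np.inf
    for kp in kp_grid:
        f = kp * L / (1 + kp * L)
        for b in b_grid:
            dw = np.mean(y - b * f)
            sse = float(np.sum((y - dw - b * f) ** 2))
            best = min(best, sse)
    return best


class TestFitPartitionModel:
    def test_noise_free_recovery_and_grid_oracle(self):
        L = np.linspace(0, 2e-3, 12)
        dw, b, kp = -1.0, 0.8, 1000.0
        y = pt.partition_model(L, dw, b, kp)
        fit = pt.fit_partition_model(pt.DerivativeSeries(213.0, L, y))
        assert fit.converged
        assert abs(fit.kp - kp) / kp < 1e-3
        assert abs(fit.b - b) / abs(b) < 1e-3
        assert abs(fit.dw - dw) / abs(dw) < 1e-3
        oracle = grid_search_sse(
            L, y, np.geomspace(100, 10000, 200), np.linspace(0.4, 1.2, 200)
        )
        assert fit.residual_sse <= oracle + 1e-12

    def test_flat_series_unidentifiable(self):
        L = np.linspace(0, 2e-3, 8)
        fit = pt.fit_partition_model(pt.DerivativeSeries(213.0, L, np.ones(8)))
        assert not fit.converged
        assert np.isnan(fit.kp)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            pt.fit_partition_model(
                pt.DerivativeSeries(213.0, np.array([0, 1e-4, 2e-4]), np.zeros(3))
            )

    def test_mean_kp_unbiased_under_noise(self):
        # 2% noise on b, 200 seeds: mean recovered Kp within 5% of truth
        L = np.linspace(0, 2e-3, 12)
        dw, b, kp = -1.0, 0.8, 1000.0
        clean = pt.partition_model(L, dw, b, kp)
        rng = np.random.default_rng(42)
        kps = []
        for _ in range(200):
            y = clean + rng.normal(0, 0.02 * abs(b), L.size)
            fit = pt.fit_partition_model(pt.DerivativeSeries(213.0, L, y))
            if fit.converged:
                kps.append(fit.kp)
        assert abs(np.mean(kps) - kp) / kp < 0.05

    def test_logd_invariant_under_series_rescaling(self):
        config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.0)
        tit = sd.simulate_spectra_titration(config)
        series = pt.extract_series(tit, 213.0)
        fit1 = pt.fit_partition_model(series)
        scaled = pt.DerivativeSeries(
            213.0, series.lipid_concs, 7.5 * series.d3_values
        )
        fit2 = pt.fit_partition_model(scaled)
        assert np.isclose(fit1.kp, fit2.kp, rtol=1e-6)


class TestIsothermProperties:
    @pytest.mark.parametrize("b", [0.8, -0.5])
    def test_model_limits_and_monotonicity(self, b):
        L = np.linspace(0, 1.0, 200)
        y = pt.partition_model(L, dw=0.3, b=b, kp=50.0)
        assert y[0] == 0.3  # D_T(0) = D_W exactly
        diffs = np.diff(y)
        assert np.all(diffs > 0) if b > 0 else np.all(diffs < 0)
        assert abs(pt.partition_model(1e9, 0.3, b, 50.0) - (0.3 + b)) < 1e-6


class TestLogD:
    def test_registered_system_examples(self):
        assert pt.logd_from_kp(756.0, pt.LIPID_SYSTEMS["POPC"]) == pytest.approx(
            3.000, abs=1e-9
        )
        assert pt.logd_from_kp(
            6.87, pt.LIPID_SYSTEMS["POPC:PI (85:15)"]
        ) == pytest.approx(1.000, abs=1e-9)

    def test_unit_ratio_is_zero(self):
        system = pt.LIPID_SYSTEMS["POPC"]
        assert pt.logd_from_kp(system.v_phi, system) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_kp_rejected(self):
        with pytest.raises(ValueError):
            pt.logd_from_kp(0.0, pt.LIPID_SYSTEMS["POPC"])


class TestMixtureMolarVolume:
    def test_midpoint_and_single_component(self):
        assert pt.mixture_molar_volume([(0.5, 0.7), (0.5, 0.9)]) == pytest.approx(0.8)
        assert pt.mixture_molar_volume([(1.0, 0.756)]) == pytest.approx(0.756)

    def test_popc_chol_registry_consistency(self):
        v = pt.mixture_molar_volume(
            [
                (0.8, pt.COMPONENT_MOLAR_VOLUMES["POPC"]),
                (0.2, pt.COMPONENT_MOLAR_VOLUMES["CHOL"]),
            ]
        )
        assert v == pytest.approx(
            pt.LIPID_SYSTEMS["POPC:CHOL (80:20)"].v_phi, abs=1e-3
        )

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            pt.mixture_molar_volume([(0.5, 0.7), (0.4, 0.9)])


class TestEstimatePartition:
    def test_zero_noise_logd_exact_to_three_decimals(self):
        config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.0)
        tit = sd.simulate_spectra_titration(config)
        fit = pt.estimate_partition(tit)
        assert fit.converged
        assert fit.logd == pytest.approx(tit.truth["logd_true"], abs=1e-3)
        assert fit.v_phi == 0.756

    def test_default_wavelength_per_drug(self):
        config = sd.reference_spectra_config("DIC", "POPC:TMCL (85:15)", noise_frac=0.0)
        tit = sd.simulate_spectra_titration(config)
        explicit = pt.estimate_partition(tit, wavelength=321.0)
        default = pt.estimate_partition(tit)
        assert default.kp == explicit.kp

    def test_unknown_drug_without_wavelength_rejected(self):
        config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.0)
        tit = sd.simulate_spectra_titration(config)
        tit.drug = None
        with pytest.raises(ValueError, match="wavelength"):
            pt.estimate_partition(tit)


def test_titration_text_round_trip(tmp_path):
    config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.02, seed=3)
    tit = sd.simulate_spectra_titration(config)
    path = tmp_path / "titration.tsv"
    pt.write_titration(path, tit)
    back = pt.read_titration(
        path, drug_conc=tit.drug_conc, lipid_system=tit.lipid_system, drug="NAP"
    )
    assert np.allclose(back.lipid_concs, tit.lipid_concs)
    for a, b in zip(back.spectra, tit.spectra):
        assert np.allclose(a.absorbance, b.absorbance)


def test_scan_wavelengths_finds_informative_region():
    config = sd.reference_spectra_config("NAP", "POPC", noise_frac=0.0)
    tit = sd.simulate_spectra_titration(config)
    scan = pt.scan_wavelengths(tit)
    best = scan.loc[scan.abs_b_estimate.idxmax(), "wavelength"]
    assert 205 <= best <= 220  # near the NAP band, where |b| is largest
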