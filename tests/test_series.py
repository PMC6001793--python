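"""Arrayed-spectra diagnostics: tracking, temperature, phase deviation,
integration, binning, alignment."""

import numpy as np
import pytest

from nmrkit.core import FidSet
from nmrkit.processing import fourier_transform, phase
from nmrkit.series import (
    HDO_COEFF_PPM_PER_K,
    TSP_COEFF_PPM_PER_K,
    IntegralRegion,
    TemperatureCalibration,
    align_spectra,
    bin_spectra,
    estimate_phase_deviation,
    estimate_temperature_change,
    integrate,
    track_peak,
)
from nmrkit.simulate import LineSpec, make_fid


def stacked_spectra(line_lists, n_points=4096, dwell=2.5e-4):
    rows = [make_fid(lines, n_points, dwell).data[0] for lines in line_lists]
    return fourier_transform(FidSet(np.vstack(rows), dwell, 500.0))


class TestTrackPeak:
    def test_lorentzian_width_within_interpolation_error(self):
        spec = stacked_spectra([[LineSpec(0.3, 1.0, 2.0)]], n_points=16384)
        tr = track_peak(spec)
        assert tr["fwhm_hz"][0] == pytest.approx(2.0, rel=0.02)

    def test_amplitude_scales_linearly(self):
        a = stacked_spectra([[LineSpec(0.3, 1.0, 2.0)]])
        b = stacked_spectra([[LineSpec(0.3, 3.5, 2.0)]])
        ra, rb = track_peak(a), track_peak(b)
        assert rb["amplitude"][0] == pytest.approx(3.5 * ra["amplitude"][0], rel=1e-9)

    def test_drifting_line_positions(self):
        drift = 0.001
        spec = stacked_spectra(
            [[LineSpec(0.3 + drift * i, 1.0, 2.0)] for i in range(5)], n_points=16384
        )
        tr = track_peak(spec)
        steps = np.diff(tr["position_ppm"])
        assert np.allclose(steps, drift, atol=5e-6)

    def test_missing_peak_recorded_as_nan(self):
        spec = stacked_spectra([[LineSpec(0.3, 1.0, 2.0)], [LineSpec(0.3, 0.01, 2.0)]])
        tr = track_peak(spec, threshold=0.1 * spec.data[0].real.max())
        assert np.isfinite(tr["position_ppm"][0])
        assert np.isnan(tr["position_ppm"][1])


class TestTemperature:
    def test_tsp_coefficient_inverts_to_one_kelvin(self):
        cal = TemperatureCalibration("tsp")
        dT = estimate_temperature_change(
            np.array([0.0, TSP_COEFF_PPM_PER_K]), cal
        )
        assert dT[1] == pytest.approx(1.0, rel=1e-12)

    def test_hdo_coefficient_inverts_to_one_kelvin(self):
        cal = TemperatureCalibration("hdo")
        dT = estimate_temperature_change(
            np.array([4.7, 4.7 + HDO_COEFF_PPM_PER_K]), cal
        )
        assert dT[1] == pytest.approx(1.0, rel=1e-12)

    def test_zero_shift_gives_zero(self):
        cal = TemperatureCalibration("hdo")
        assert np.all(estimate_temperature_change(np.full(4, 4.7), cal) == 0.0)

    def test_exactly_linear_in_displacement(self):
        cal = TemperatureCalibration("tsp")
        d = np.array([0.0, 1e-3, 2e-3])
        assert np.allclose(
            estimate_temperature_change(3.0 * d, cal),
            3.0 * estimate_temperature_change(d, cal),
            rtol=1e-14,
        )


@pytest.fixture(scope="module")
def broad_line():
    return fourier_transform(
        make_fid([LineSpec(0.0, 1.0, 20.0)], n_points=16384, dwell=2.5e-4)
    )


class TestPhaseDeviation:
    def test_zero_misphase_reads_zero(self, broad_line):
        est = estimate_phase_deviation(broad_line)
        assert abs(est[0]) < 0.01

    @pytest.mark.parametrize("phi", [2.0, 5.0, 10.0])
    def test_injected_misphase_recovered(self, broad_line, phi):
        est = estimate_phase_deviation(phase(broad_line, phi, 0.0))
        assert est[0] == pytest.approx(phi, abs=0.5)

    def test_estimator_is_odd(self, broad_line):
        plus = estimate_phase_deviation(phase(broad_line, 7.0, 0.0))[0]
        minus = estimate_phase_deviation(phase(broad_line, -7.0, 0.0))[0]
        assert plus == pytest.approx(-minus, abs=0.02)

    def test_agrees_with_brute_force_tabulation(self, broad_line):
        """Oracle: simulate each misphase, measure the excursion ratio on
        the closed-form Lorentzian directly, tabulate and compare."""
        from nmrkit.series import _lorentz_excursion_ratio
        from scipy.optimize import brentq

        for phi in np.arange(-20.0, 20.1, 5.0):
            est = estimate_phase_deviation(phase(broad_line, phi, 0.0))[0]
            # brute-force inversion of the tabulated closed form
            rho = _lorentz_excursion_ratio(phi)
            phi_oracle = brentq(
                lambda p: _lorentz_excursion_ratio(p) - rho, -44.9, 44.9
            )
            assert est == pytest.approx(phi_oracle, abs=0.2)


class TestIntegrate:
    def test_pure_linear_baseline_integrates_to_zero_with_tilt(self):
        spec = stacked_spectra([[LineSpec(1.5, 1e-9, 2.0)]], n_points=1024)
        spec.data = (np.linspace(-3.0, 5.0, spec.fn) + 0j)[None, :]
        table = integrate(spec, [IntegralRegion(-0.5, 0.5)], tilt_correction=True)
        assert abs(table[0, 0]) < 1e-10

    def test_lorentzian_integral_closed_form(self):
        # total spectral integral in ppm units = x(0) / (2 * dwell * sfrq);
        # a +/-20-linewidth region captures 2/pi*atan(40) of it
        spec = stacked_spectra([[LineSpec(0.0, 1.0, 2.0)]], n_points=32768)
        width = 20 * 2.0 / 500.0
        table = integrate(spec, [IntegralRegion(-width, width)])
        expected = 1.0 / (2 * 2.5e-4 * 500.0) * (2 / np.pi) * np.arctan(40.0)
        assert table[0, 0] == pytest.approx(expected, rel=0.01)

    def test_normalisation_sets_anchor_region(self):
        spec = stacked_spectra(
            [[LineSpec(-0.5, 1.0, 2.0), LineSpec(0.5, 0.25, 2.0)]], n_points=8192
        )
        regions = [
            IntegralRegion(-0.6, -0.4, normalize_to=100.0),
            IntegralRegion(0.4, 0.6),
        ]
        table = integrate(spec, regions, normalize=True)
        assert table[0, 0] == pytest.approx(100.0)
        assert table[0, 1] == pytest.approx(25.0, rel=0.02)


class TestBinning:
    def test_total_intensity_conserved(self, single_line_spec):
        binned, centres = bin_spectra(single_line_spec, 0.05)
        assert binned.sum() == pytest.approx(
            single_line_spec.data.real.sum(), abs=1e-8
        )

    def test_full_width_bin_is_total_sum(self, single_line_spec):
        binned, centres = bin_spectra(single_line_spec, 1e6)
        assert binned.shape[1] == 1
        assert binned[0, 0] == pytest.approx(single_line_spec.data.real.sum())

    def test_halving_width_doubles_bins(self, single_line_spec):
        n1 = bin_spectra(single_line_spec, 0.08)[0].shape[1]
        n2 = bin_spectra(single_line_spec, 0.04)[0].shape[1]
        assert abs(n2 - 2 * n1) <= 1


class TestAlignment:
    def series(self):
        return stacked_spectra([[LineSpec(0.3, 1.0, 4.0)]] * 3, n_points=4096)

    def test_zero_shifts_identity(self):
        spec = self.series()
        out = align_spectra(spec, shifts=[0, 0, 0])
        assert np.array_equal(out.data, spec.data)

    def test_auto_alignment_undoes_known_shifts(self):
        spec = self.series()
        shifted = align_spectra(spec, shifts=[0, 4, -3])
        aligned = align_spectra(shifted, intervals=[(0.1, 0.5)], max_shift=6)
        peaks = [int(np.argmax(aligned.data[i].real)) for i in range(3)]
        # all rows agree (the injected shifts are undone); the common
        # position matches the original to within one point (median target)
        assert len(set(peaks)) == 1
        assert abs(peaks[0] - int(np.argmax(spec.data[0].real))) <= 1

    def test_alignment_reduces_rms_deviation(self):
        spec = self.series()
        shifted = align_spectra(spec, shifts=[0, 4, -3])
        aligned = align_spectra(shifted, intervals=[(0.1, 0.5)], max_shift=6)

        def rms(s):
            med = np.median(s.data.real, axis=0)
            return np.sqrt(np.mean((s.data.real - med) ** 2))

        assert rms(aligned) < rms(shifted)

    def test_manual_shift_zero_fills_edges(self):
        spec = self.series()
        out = align_spectra(spec, shifts=[5, 0, 0])
        assert np.all(out.data[0, :5] == 0)
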