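"""FT conventions, apodisation closed forms, phasing, baseline, referencing."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmrkit.core import ApodisationParams, SpectrumSet
from nmrkit.processing import (
    apodise,
    autophase,
    baseline_correct,
    fourier_transform,
    phase,
    set_reference,
    spectrum_to_fid,
    zero_fill,
)
from nmrkit.simulate import LineSpec, make_fid

from helpers import measured_fwhm_hz


@pytest.fixture
def flat_fid():
    """Constant (non-decaying) FID: a delta line at the carrier."""
    from nmrkit.core import FidSet

    return FidSet(np.ones((1, 8192), complex), 2.5e-4, 500.0)


class TestZeroFill:
    def test_same_fn_is_identity(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=256)
        assert np.array_equal(zero_fill(fid, 256).data, fid.data)

    def test_padding_appends_exact_zeros(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=256)
        out = zero_fill(fid, 512)
        assert np.array_equal(out.data[:, :256], fid.data)
        assert np.all(out.data[:, 256:] == 0)

    def test_truncation_shows_sinc_wiggles(self):
        """Truncating a slowly-decaying line spreads energy into sinc
        sidelobes: the first sidelobe exceeds the untruncated baseline."""
        fid = make_fid([LineSpec(0.0, 1.0, 0.2)], n_points=8192, dwell=2.5e-4)
        full = fourier_transform(fid)
        trunc = fourier_transform(zero_fill(fid, 1024), 8192)
        i_full = int(np.argmax(full.data[0].real))
        off = slice(i_full + 40, i_full + 400)
        assert np.abs(trunc.data[0].real[off]).max() > 5 * np.abs(
            full.data[0].real[off]
        ).max()


class TestApodise:
    def test_zero_params_identity(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=256)
        out = apodise(fid, ApodisationParams(0.0, 0.0))
        assert np.array_equal(out.data, fid.data)

    def test_weight_is_one_at_t_zero(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=64)
        out = apodise(fid, ApodisationParams(5.0, 3.0))
        assert out.data[0, 0] == fid.data[0, 0]

    @pytest.mark.parametrize("lw,gw", [(2.0, 0.0), (0.0, 2.0)])
    def test_delta_fid_acquires_stated_fwhm(self, flat_fid, lw, gw):
        out = apodise(flat_fid, ApodisationParams(lw, gw))
        spec = fourier_transform(out)
        grid = abs(spec.axis_hz[1] - spec.axis_hz[0])
        assert measured_fwhm_hz(spec) == pytest.approx(2.0, abs=grid)

    @given(a=st.floats(0.0, 5.0), b=st.floats(0.0, 5.0))
    def test_lorentzian_additivity(self, a, b):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=128)
        twice = apodise(apodise(fid, ApodisationParams(a)), ApodisationParams(b))
        once = apodise(fid, ApodisationParams(a + b))
        assert np.allclose(twice.data, once.data, rtol=1e-12, atol=1e-300)


class TestFourierTransform:
    def test_pure_tone_hits_single_bin(self):
        # frequency exactly on the grid: all energy in one bin
        fid = make_fid([LineSpec(0.0, 1.0, 0.0)], n_points=1024, dwell=5e-4)
        f0 = 125.0  # = 64 * df with df = 1/(1024*5e-4)
        fid.data[0] = np.exp(2j * np.pi * f0 * fid.times)
        spec = fourier_transform(fid)
        i = int(np.argmax(np.abs(spec.data[0])))
        assert spec.axis_hz[i] == pytest.approx(f0)
        # every other bin carries only the flat -x0/2 first-point offset
        others = np.abs(spec.data[0] + 0.5).copy()
        others[i] = 0
        assert others.max() < 1e-9 * np.abs(spec.data[0, i])

    def test_all_zero_fid(self):
        from nmrkit.core import FidSet

        spec = fourier_transform(FidSet(np.zeros((1, 64), complex), 1e-3, 500.0))
        assert np.all(spec.data == 0)

    def test_linearity(self):
        a = make_fid([LineSpec(0.2, 1.0, 3.0)], n_points=256)
        b = make_fid([LineSpec(-0.3, 0.5, 1.0)], n_points=256)
        summed = a.copy()
        summed.data = a.data + b.data
        lhs = fourier_transform(summed).data
        rhs = fourier_transform(a).data + fourier_transform(b).data
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_parseval_with_first_point_correction(self):
        fid = make_fid([LineSpec(0.2, 1.0, 3.0)], n_points=512)
        spec = fourier_transform(fid)
        halved = fid.data[0].copy()
        halved[0] *= 0.5
        energy_t = np.sum(np.abs(halved) ** 2) * spec.fn
        energy_f = np.sum(np.abs(spec.data[0]) ** 2)
        assert energy_f == pytest.approx(energy_t, rel=1e-10)

    def test_round_trip_exact(self):
        fid = make_fid([LineSpec(0.2, 1.0, 3.0)], n_points=512)
        back = spectrum_to_fid(fourier_transform(fid))
        assert np.allclose(back.data, fid.data, rtol=1e-12, atol=1e-14)


class TestPhase:
    def test_zero_phase_identity(self, single_line_spec):
        out = phase(single_line_spec, 0.0, 0.0)
        assert np.allclose(out.data, single_line_spec.data, rtol=1e-15)

    def test_pivot_point_untouched_by_ph1(self, single_line_spec):
        spec = single_line_spec
        i = int(np.argmax(spec.data[0].real))
        pivot = spec.axis_hz[i]
        out = phase(spec, 0.0, 170.0, pivot_hz=pivot)
        assert out.data[0, i] == pytest.approx(spec.data[0, i], rel=1e-12)

    def test_ninety_degrees_turns_dispersion_into_absorption(self):
        fid = make_fid([LineSpec(0.0, 1.0, 4.0, phase_deg=-90.0)],
                       n_points=8192, dwell=2.5e-4)
        spec = phase(fourier_transform(fid), 90.0, 0.0)
        r = spec.data[0].real
        i = int(np.argmax(r))
        w = 200
        asym = np.abs(r[i - w : i] - r[i + w : i : -1]).max() / r[i]
        assert asym < 1e-8

    def test_individual_mode_per_increment(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=256)
        from nmrkit.core import FidSet

        arr = FidSet(np.vstack([fid.data[0]] * 3), fid.dwell, fid.sfrq)
        spec = fourier_transform(arr)
        out = phase(spec, [0.0, 90.0, 180.0], 0.0, mode="individual")
        assert np.allclose(out.data[0], spec.data[0])
        assert np.allclose(out.data[2], -spec.data[0], rtol=1e-12)


class TestAutophase:
    def test_already_phased_returns_near_zero(self, three_lines):
        spec = fourier_transform(make_fid(three_lines, n_points=4096, dwell=5e-4))
        spec.pivot_hz = spec.axis_hz[int(np.argmax(np.abs(spec.data[0])))]
        p0, p1 = autophase(spec)
        assert abs(p0[0]) <= 1.0 and abs(p1[0]) <= 1.0

    def test_recovers_injected_misphase(self, three_lines):
        spec = fourier_transform(make_fid(three_lines, n_points=4096, dwell=5e-4))
        spec.pivot_hz = spec.axis_hz[int(np.argmax(np.abs(spec.data[0])))]
        mis = phase(spec, 30.0, 40.0)
        p0, p1 = autophase(mis)
        assert p0[0] == pytest.approx(-30.0, abs=1.0)
        assert p1[0] == pytest.approx(-40.0, abs=1.0)

    def test_global_mode_identical_across_increments(self, three_lines):
        fid = make_fid(three_lines, n_points=2048, dwell=5e-4)
        from nmrkit.core import FidSet

        arr = FidSet(np.vstack([fid.data[0]] * 4), fid.dwell, fid.sfrq)
        spec = phase(fourier_transform(arr), 25.0, 0.0)
        p0, p1 = autophase(spec)
        assert np.all(p0 == p0[0]) and np.all(p1 == p1[0])

    def test_all_noise_warns_and_returns_zero(self):
        rng = np.random.default_rng(7)
        spec = SpectrumSet(
            data=rng.standard_normal((1, 512)) + 1j * rng.standard_normal((1, 512)),
            axis_hz=np.linspace(250.0, -250.0, 512),
            sfrq=500.0,
            dwell=1 / 500.0,
        )
        with pytest.warns(UserWarning):
            p0, p1 = autophase(spec)
        assert p0[0] == 0.0 and p1[0] == 0.0


class TestBaseline:
    def make_offset_spectrum(self, coeffs=(3.0, -2.0, 1.5)):
        # fully decayed Gaussian line: absorption tails vanish, so the
        # baseline is exactly the added polynomial
        fid = make_fid([LineSpec(0.3, 1.0, 0.0, 2.0)], n_points=8192, dwell=2.5e-4)
        spec = fourier_transform(fid)
        x = np.linspace(-1, 1, spec.fn)
        spec.data = spec.data + np.polynomial.polynomial.polyval(x, coeffs)
        return spec

    def test_zero_baseline_unchanged(self):
        spec = self.make_offset_spectrum(coeffs=(0.0,))
        out = baseline_correct(spec, signal_regions=[(0.2, 0.4)], order=2)
        scale = np.abs(spec.data.real).max()
        assert np.abs(out.data.real - spec.data.real).max() < 1e-12 * scale

    def test_quadratic_baseline_removed_exactly(self):
        spec = self.make_offset_spectrum()
        out = baseline_correct(spec, signal_regions=[(0.2, 0.4)], order=2)
        far = np.abs(spec.axis_ppm - 0.3) > 0.3
        base = self.make_offset_spectrum(coeffs=(0.0,))  # no offset reference
        resid = out.data[0].real[far] - base.data[0].real[far]
        assert np.abs(resid).max() < 1e-8

    def test_auto_matches_manual(self):
        spec = self.make_offset_spectrum()
        manual = baseline_correct(spec, signal_regions=[(0.2, 0.4)], order=2)
        auto = baseline_correct(spec, order=2)
        far = np.abs(spec.axis_ppm - 0.3) > 0.3
        dev = np.abs(manual.data[0].real[far] - auto.data[0].real[far]).max()
        assert dev < 1e-3 * np.abs(spec.data[0].real).max()

    def test_idempotent_on_own_output(self):
        spec = self.make_offset_spectrum()
        once = baseline_correct(spec, order=2)
        twice = baseline_correct(once, order=2)
        scale = np.abs(once.data.real).max()
        assert np.abs(twice.data.real - once.data.real).max() < 1e-3 * scale

    def test_order_exceeding_points_rejected(self):
        spec = self.make_offset_spectrum()
        span = (float(spec.axis_ppm.min()) + 1e-6, float(spec.axis_ppm.max()) - 1e-6)
        with pytest.raises(ValueError):
            baseline_correct(spec, signal_regions=[span], order=50)


class TestSetReference:
    def test_assign_current_position_is_identity(self, single_line_spec):
        out = set_reference(single_line_spec, 0.3, 0.3)
        assert np.allclose(out.axis_ppm, single_line_spec.axis_ppm)

    def test_assign_zero_moves_peak_to_zero(self, single_line_spec):
        spec = single_line_spec
        i = int(np.argmax(spec.data[0].real))
        observed = spec.axis_ppm[i]
        out = set_reference(spec, observed, 0.0)
        assert out.axis_ppm[i] == pytest.approx(0.0, abs=1e-12)

    def test_composition_equals_single_referencing(self, single_line_spec):
        a = set_reference(set_reference(single_line_spec, 0.3, 0.5), 0.5, 0.1)
        b = set_reference(single_line_spec, 0.3, 0.1)
        assert np.allclose(a.axis_ppm, b.axis_ppm, atol=1e-12)
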