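"""The synthetic-data generators satisfy their defining closed forms."""

import numpy as np
import pytest

from nmrkit.core import DiffusionEncoding, RelaxationEncoding
from nmrkit.processing import fourier_transform
from nmrkit.pure_shift import PureShiftParams, reconstruct
from nmrkit.simulate import (
    LineSpec,
    decoupled_fid_samples,
    distort_lineshape,
    gradient_array,
    make_diffusion_set,
    make_fid,
    make_pureshift_raw,
    make_reaction_cube,
    make_relaxation_set,
)


from helpers import measured_fwhm_hz


class TestMakeFid:
    def test_lorentzian_fwhm_matches_lw(self):
        fid = make_fid([LineSpec(0.0, 1.0, 1.0)], n_points=32768, dwell=2.5e-4)
        spec = fourier_transform(fid)
        grid = abs(spec.axis_hz[1] - spec.axis_hz[0])
        assert measured_fwhm_hz(spec) == pytest.approx(1.0, abs=grid)

    def test_zero_amplitude_gives_zero_fid(self):
        fid = make_fid([LineSpec(0.2, 0.0, 1.0)], n_points=64)
        assert np.all(fid.data == 0)

    def test_same_seed_bit_identical(self):
        a = make_fid([LineSpec(0.1)], noise_sigma=0.1, seed=42)
        b = make_fid([LineSpec(0.1)], noise_sigma=0.1, seed=42)
        assert np.array_equal(a.data, b.data)
        c = make_fid([LineSpec(0.1)], noise_sigma=0.1, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_line_outside_sweep_rejected(self):
        with pytest.raises(ValueError):
            make_fid([LineSpec(5.0)], n_points=64, dwell=1e-3, sfrq=500.0)

    def test_noise_free_closed_form(self):
        line = LineSpec(0.25, 0.8, 2.0, 1.5, phase_deg=30.0)
        fid = make_fid([line], n_points=256, dwell=5e-4)
        t = fid.times
        f = 0.25 * 500.0
        expected = (
            0.8
            * np.exp(1j * (2 * np.pi * f * t + np.deg2rad(30.0)))
            * np.exp(-np.pi * 2.0 * t)
            * np.exp(-((np.pi * 1.5 * t / (2 * np.sqrt(np.log(2)))) ** 2))
        )
        assert np.allclose(fid.data[0], expected, rtol=1e-12, atol=1e-15)


class TestDiffusionSet:
    def test_zero_gradient_equals_plain_fid(self):
        lines = [LineSpec(0.2, 1.0, 2.0, D=3e-10)]
        enc = DiffusionEncoding(g=np.array([0.0, 0.2, 0.4]))
        fid, _ = make_diffusion_set(lines, encoding=enc, n_points=128, dwell=5e-4)
        plain = make_fid(lines, n_points=128, dwell=5e-4)
        assert np.allclose(fid.data[0], plain.data[0], rtol=1e-12)

    def test_unit_exponent_attenuation(self):
        lines = [LineSpec(0.0, 1.0, 0.0, D=1.0)]  # D chosen so X*D = 1 below
        gamma, delta, Dp = 1.0, 1.0, 1.0
        enc = DiffusionEncoding(g=np.array([0.0, 1.0]), gamma=gamma, delta=delta,
                                big_delta_prime=Dp)
        fid, _ = make_diffusion_set(lines, encoding=enc, n_points=128, dwell=5e-4)
        ratio = fid.data[1, 0] / fid.data[0, 0]
        assert abs(ratio - np.exp(-1.0)) < 1e-12

    def test_equal_g2_spacing(self):
        g = gradient_array(8, 0.5, 0.1, "equal_g2")
        assert np.allclose(np.diff(g**2), np.diff(g**2)[0])
        g2 = gradient_array(8, 0.5, 0.1, "equal_g")
        assert np.allclose(np.diff(g2), np.diff(g2)[0])


class TestRelaxationSet:
    def test_ir_long_tau_approaches_amplitude(self):
        lines = [LineSpec(0.0, 2.0, 1.0, t1=0.5)]
        enc = RelaxationEncoding(np.array([0.01, 50.0]), mode="inversion_recovery")
        fid, _ = make_relaxation_set(lines, enc, n_points=64)
        assert abs(fid.data[1, 0] - 2.0) < 1e-6

    def test_ir_null_point(self):
        t1 = 0.8
        lines = [LineSpec(0.0, 1.0, 1.0, t1=t1)]
        enc = RelaxationEncoding(np.array([t1 * np.log(2.0), 5.0]),
                                 mode="inversion_recovery")
        fid, _ = make_relaxation_set(lines, enc, n_points=64)
        assert abs(fid.data[0, 0]) < 1e-12

    def test_t2_decay_at_t2(self):
        t2 = 0.4
        lines = [LineSpec(0.0, 1.0, 1.0, t2=t2)]
        enc = RelaxationEncoding(np.array([t2, 10 * t2]), mode="t2_decay")
        fid, _ = make_relaxation_set(lines, enc, n_points=64)
        assert abs(fid.data[0, 0] - np.exp(-1.0)) < 1e-12


class TestReactionCube:
    def enc(self):
        return DiffusionEncoding(g=gradient_array(8, 0.5, 0.05, "equal_g2"))

    def test_rank_one_cube_has_single_singular_value(self):
        lines = [LineSpec(0.0, 1.0, 3.0, component_id=0, D=5e-10)]
        conc = np.linspace(1.0, 0.2, 6)[:, None]
        cube, _ = make_reaction_cube(lines, self.enc(), conc, n_freq=64)
        for mode in range(3):
            m = np.moveaxis(cube, mode, 0).reshape(cube.shape[mode], -1)
            s = np.linalg.svd(m, compute_uv=False)
            assert s[1] / s[0] < 1e-12

    def test_zero_concentration_gives_zero_slab(self):
        lines = [LineSpec(0.0, 1.0, 3.0, component_id=0, D=5e-10)]
        conc = np.array([[1.0], [0.0], [0.5]])
        cube, _ = make_reaction_cube(lines, self.enc(), conc, n_freq=32)
        assert np.all(cube[1] == 0)

    def test_trilinear_by_construction(self):
        lines = [
            LineSpec(-0.3, 1.0, 3.0, component_id=0, D=5e-10),
            LineSpec(0.3, 0.7, 3.0, component_id=1, D=1e-10),
        ]
        tg = np.linspace(0, 1, 5)
        conc = np.column_stack([np.exp(-tg), 1 - np.exp(-tg)])
        cube, freq = make_reaction_cube(lines, self.enc(), conc, n_freq=64)
        X = self.enc().exponent_scale
        from nmrkit.simulate import lorentzian_spectrum

        expected = np.zeros_like(cube)
        for k, cid in enumerate((0, 1)):
            spec_k = lorentzian_spectrum(
                [ln for ln in lines if ln.component_id == cid], freq
            )
            D_k = 5e-10 if cid == 0 else 1e-10
            expected += (
                conc[:, k][:, None, None]
                * np.exp(-X * D_k)[None, :, None]
                * spec_k[None, None, :]
            )
        assert np.allclose(cube, expected, rtol=1e-12)


class TestDistortLineshape:
    def test_unit_envelope_is_identity(self):
        fid = make_fid([LineSpec(0.1, 1.0, 2.0)], n_points=128)
        out = distort_lineshape(fid, np.ones(128, dtype=complex))
        assert np.array_equal(out.data, fid.data)

    def test_lorentzian_envelope_adds_linewidth(self):
        beta = 2.0
        fid = make_fid([LineSpec(0.0, 1.0, 1.0)], n_points=32768, dwell=2.5e-4)
        env = np.exp(-np.pi * beta * fid.times)
        wide = fourier_transform(distort_lineshape(fid, env))
        grid = abs(wide.axis_hz[1] - wide.axis_hz[0])
        assert measured_fwhm_hz(wide) == pytest.approx(1.0 + beta, abs=2 * grid)

    def test_common_envelope_applied_to_all_increments(self):
        lines = [LineSpec(0.1, 1.0, 2.0, D=5e-10)]
        fid, _ = make_diffusion_set(lines, n_increments=4, n_points=128, dwell=5e-4)
        env = np.exp(-0.5j * np.arange(128) / 128.0)
        out = distort_lineshape(fid, env)
        for i in range(4):
            assert np.allclose(out.data[i], fid.data[i] * env, rtol=1e-14)


class TestPureShiftRaw:
    def test_single_chunk_is_head_of_decoupled_fid(self):
        lines = [LineSpec(0.2, 1.0, 2.0)]
        raw = make_pureshift_raw(lines, chunks=1, chunk_points=32, first_chunk=24,
                                 drop_points=0, dwell=5e-4)
        rec = reconstruct(raw, PureShiftParams(1, 32, 24, 0))
        target = decoupled_fid_samples(lines, np.arange(24), 5e-4, 500.0)
        assert np.allclose(rec.data[0], target, rtol=1e-13)

    def test_drop_points_extend_each_increment(self):
        lines = [LineSpec(0.2, 1.0, 2.0)]
        raw = make_pureshift_raw(lines, chunks=4, chunk_points=16, drop_points=2,
                                 dwell=5e-4)
        assert raw.n_points == 2 + 16
        assert raw.meta["pureshift"]["drop_points"] == 2
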