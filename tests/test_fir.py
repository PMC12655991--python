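"""FIR design, quantization, and the per-channel vs time-multiplexed application paths."""

import numpy as np
import pytest

from szdet import fir
from szdet.exceptions import ConfigurationError, DesignError
from szdet.fir import (
    apply,
    apply_tdm,
    design_lowpass,
    passband_ripple_db,
    quantize,
    stopband_attenuation_db,
)
from szdet.signals_io import Recording

FS = 256.0


class TestDesign:
    def test_meets_stopband_spec_with_symmetric_taps(self, filt256_float):
        spec = filt256_float
        assert len(spec.coefficients) == 65
        np.testing.assert_array_equal(spec.coefficients, spec.coefficients[::-1])
        assert stopband_attenuation_db(spec.coefficients, FS, 50.0) >= 60.0
        assert passband_ripple_db(spec.coefficients, FS, 40.0) <= 1.0

    def test_dc_gain_close_to_unity(self, filt256_float):
        s = np.sum(filt256_float.coefficients)
        assert 0.99 <= s <= 1.01

    def test_infeasible_order_reports_achieved_attenuation(self):
        with pytest.raises(DesignError) as err:
            design_lowpass(FS, order=2, f_stop=50.0, min_stop_atten_db=60.0)
        assert err.value.achieved_atten_db is not None
        assert err.value.achieved_atten_db < 60.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f_stop": 200.0},  # beyond Nyquist
            {"f_stop": 50.0, "f_pass": 55.0},  # pass edge above stop edge
            {"order": 63},  # odd order
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            design_lowpass(FS, **{"order": 64, **kwargs})

    def test_json_round_trip(self, tmp_path, filt256):
        filt256.to_json(tmp_path / "f.json")
        back = fir.FilterSpec.from_json(tmp_path / "f.json")
        np.testing.assert_array_equal(back.coefficients, filt256.coefficients)
        assert back.quant_bits == 16


class TestQuantize:
    def test_16bit_preserves_stopband_and_symmetry(self, filt256_float):
        q = quantize(filt256_float, 16)
        assert q.achieved_atten_db >= 60.0
        np.testing.assert_array_equal(q.coefficients, q.coefficients[::-1])

    def test_fine_quantization_limit(self, filt256_float):
        q = quantize(filt256_float, 32)
        assert np.max(np.abs(q.coefficients - filt256_float.coefficients)) <= 2.0**-30

    def test_idempotent_at_same_wordlength(self, filt256):
        again = quantize(filt256, 16)
        np.testing.assert_array_equal(again.coefficients, filt256.coefficients)

    def test_coefficients_are_fixed_point_representable(self, filt256):
        c = filt256.coefficients
        m = np.max(np.abs(c))
        frac_bits = 0
        while round(m * 2 ** (frac_bits + 1)) <= 2**15 - 1:
            frac_bits += 1
        scaled = c * 2**frac_bits
        np.testing.assert_array_equal(scaled, np.round(scaled))


class TestApply:
    def test_unit_impulse_reproduces_coefficients(self, filt256):
        x = np.zeros((2, 100))
        x[0, 0] = 1.0
        y = apply(filt256, Recording(x, fs=FS)).samples
        np.testing.assert_array_equal(y[0, :65], filt256.coefficients)
        assert not y[1].any()

    def test_dc_steady_state_equals_dc_gain(self, filt256):
        v = 7.5
        y = apply(filt256, Recording(np.full((1, 300), v), fs=FS)).samples[0]
        np.testing.assert_allclose(y[65:], v * np.sum(filt256.coefficients), rtol=1e-12)

    def test_60hz_sine_attenuated_60db(self, filt256):
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)[None, :]
        y = apply(filt256, Recording(x, fs=FS)).samples[0]
        steady = y[65:]
        out_rms = np.sqrt(np.mean(steady**2))
        in_rms = np.sqrt(0.5)
        assert 20 * np.log10(out_rms / in_rms) <= -60.0

    def test_linearity(self, filt256, rng):
        x = rng.normal(size=(3, 500))
        y = rng.normal(size=(3, 500))
        lhs = apply(filt256, Recording(2.5 * x - 1.5 * y, fs=FS)).samples
        rhs = (
            2.5 * apply(filt256, Recording(x, fs=FS)).samples
            - 1.5 * apply(filt256, Recording(y, fs=FS)).samples
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_group_delay_compensation_shifts_output(self, filt256, rng):
        x = rng.normal(size=(1, 400))
        rec = Recording(x, fs=FS)
        causal = apply(filt256, rec).samples
        shifted = apply(filt256, rec, compensate_delay=True).samples
        d = filt256.group_delay_samples
        np.testing.assert_array_equal(shifted[:, : 400 - d], causal[:, d:])
        assert not shifted[:, 400 - d :].any()

    def test_fs_mismatch_rejected(self, filt256):
        with pytest.raises(ConfigurationError):
            apply(filt256, Recording(np.zeros((1, 100)), fs=512.0))

    def test_linear_phase_over_passband(self, filt256):
        # symmetric taps: H(w) * exp(j*w*order/2) must be purely real
        from scipy.signal import freqz

        w, h = freqz(filt256.coefficients, worN=2048)
        rotated = h * np.exp(1j * w * filt256.order / 2)
        passband = w < 2 * np.pi * 40.0 / FS
        assert np.max(np.abs(rotated[passband].imag)) < 1e-12


class TestTdmEquivalence:
    def test_matches_per_channel_filtering_bit_exactly(self, filt256, rng):
        for _ in range(5):
            rec = Recording(rng.normal(size=(4, 700)), fs=FS)
            np.testing.assert_array_equal(
                apply_tdm(filt256, rec).samples, apply(filt256, rec).samples
            )

    def test_single_channel_trivial(self, filt256, rng):
        rec = Recording(rng.normal(size=(1, 300)), fs=FS)
        np.testing.assert_array_equal(
            apply_tdm(filt256, rec).samples, apply(filt256, rec).samples
        )

    def test_no_cross_channel_leakage_under_permutation(self, filt256, rng):
        x = rng.normal(size=(5, 400))
        perm = np.array([3, 0, 4, 1, 2])
        y = apply_tdm(filt256, Recording(x, fs=FS)).samples
        y_perm = apply_tdm(filt256, Recording(x[perm], fs=FS)).samples
        np.testing.assert_array_equal(y_perm, y[perm])

    def test_interleave_deinterleave_inverse(self, rng):
        x = rng.normal(size=(6, 123))
        np.testing.assert_array_equal(fir.deinterleave(fir.interleave(x), 6), x)

    def test_stream_mac_oracle_on_integer_signal(self, rng):
        """Dual route: an explicit shared-MAC delay-line simulation of the TDM
        stream reproduces the implementation on integer-valued input."""
        taps = np.array([0.5, 0.25, 0.125, 0.25, 0.5])
        spec = fir.FilterSpec(taps, order=4, fs=FS, f_stop=50, min_stop_atten_db=0)
        x = rng.integers(-50, 50, size=(3, 40)).astype(float)
        rec = Recording(x, fs=FS)
        nch, t = x.shape
        stream = fir.interleave(x)
        delay = np.zeros((nch, 5))
        out = np.zeros_like(stream)
        for k, sample in enumerate(stream):  # one shared MAC, per-channel state bank
            ch = k % nch
            delay[ch] = np.roll(delay[ch], 1)
            delay[ch, 0] = sample
            out[k] = np.dot(taps, delay[ch])
        expected = fir.deinterleave(out, nch)
        np.testing.assert_allclose(apply_tdm(spec, rec).samples, expected, atol=1e-9)
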