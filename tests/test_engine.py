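"""Coincidence-detection engine: noise sampling, weights, output functions."""

import numpy as np
import pytest

import sbftiming as sbf
from sbftiming import (
    ConfigurationError, CosineBank, NoiseSpec, OscillatorBankSpec,
    closed_form_output, make_frequency_grid, memory_noise_output,
    output_function, reference_weights, running_weights, sample_multipliers,
)


def direct_noiseless_sum(spec, c, t):
    """Brute-force double-sum oracle for the noiseless cosine output."""
    freqs = make_frequency_grid(spec)
    t = np.atleast_1d(np.asarray(t, float))
    return (np.cos(2 * np.pi * np.outer(t, freqs))
            * np.cos(2 * np.pi * freqs * c)).sum(axis=1)


class TestSampleMultipliers:
    def test_none_family_is_exactly_one(self):
        out = sample_multipliers(NoiseSpec("none", 0.0, 7, 1))
        np.testing.assert_array_equal(out, np.ones(7))

    @pytest.mark.parametrize("family", ["normal", "uniform"])
    def test_large_sample_statistics(self, family):
        noise = NoiseSpec(family, 0.1, 100_000, seed=42)
        x = sample_multipliers(noise) - 1.0
        assert abs(x.mean()) < 0.002
        assert 0.099 <= x.std() <= 0.101
        if family == "uniform":
            half = 0.1 * np.sqrt(3.0)
            assert x.min() >= -half and x.max() <= half

    def test_seeded_reproducibility(self):
        noise = NoiseSpec("normal", 0.05, 1000, seed=7)
        np.testing.assert_array_equal(sample_multipliers(noise),
                                      sample_multipliers(noise))

    @pytest.mark.parametrize("kwargs", [
        dict(family="weird", level=0.1), dict(family="normal", level=-0.1),
        dict(family="none", level=0.1), dict(family="normal", level=0.0),
        dict(family="normal", level=0.1, n_samples=0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            NoiseSpec(**{"n_samples": 10, **kwargs})


class TestReferenceWeights:
    def test_integer_periods_give_unit_weights(self):
        # grid {2, 3, 4} Hz at c = 1 s: every state is cos(2*pi*k) = 1
        bank = CosineBank(OscillatorBankSpec(1.0, 4.0, 3))
        ref = reference_weights(bank, 1.0)
        np.testing.assert_allclose(ref.weights, [1.0, 1.0, 1.0], atol=1e-12)
        assert ref.norm == pytest.approx(1.0)

    def test_nonpositive_maximum_normalisation(self):
        # grid {1.25, 1.5} Hz at c = 1 s: raw states (0, -1); the signed
        # maximum is 0, so the magnitude convention kicks in
        bank = CosineBank(OscillatorBankSpec(1.0, 1.5, 2))
        ref = reference_weights(bank, 1.0)
        np.testing.assert_allclose(ref.weights, [0.0, -1.0], atol=1e-12)
        assert ref.norm == pytest.approx(1.0)
        pos = reference_weights(bank, 1.0, mode="positive")
        np.testing.assert_allclose(pos.weights, [0.5, 0.0], atol=1e-12)

    def test_weights_bounded_and_continuous_in_level(self, band_spec):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 200))
        base = reference_weights(bank, 30.0).weights
        for level in (1e-3, 1e-4, 1e-5):
            ref = reference_weights(
                bank, 30.0, NoiseSpec("normal", level, 500, seed=1))
            assert np.all(np.abs(ref.weights) <= 1.0 + 1e-12)
        tight = reference_weights(
            bank, 30.0, NoiseSpec("normal", 1e-6, 500, seed=1)).weights
        assert np.max(np.abs(tight - base)) < 1e-3

    def test_norm_bounded_by_sample_count(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 50))
        ref = reference_weights(bank, 30.0, NoiseSpec("uniform", 0.05, 200, 3))
        assert ref.norm <= 200.0

    def test_nonpositive_criterion_rejected(self):
        bank = CosineBank(OscillatorBankSpec(1.0, 2.0, 2))
        with pytest.raises(ConfigurationError):
            reference_weights(bank, 0.0)


class TestRunningWeights:
    def test_reset_coherence_at_time_zero(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 40))
        run = running_weights(bank, 0.0)
        np.testing.assert_allclose(run.weights, 1.0, atol=1e-12)

    def test_matches_reference_at_criterion_without_noise(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 40))
        run = running_weights(bank, 17.0)
        ref = reference_weights(bank, 17.0)
        np.testing.assert_allclose(run.weights, ref.weights, atol=1e-12)

    def test_frequency_noise_average_converges_to_noiseless(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 40))
        base = running_weights(bank, 3.0).weights
        prev_err = np.inf
        for level in (1e-2, 1e-4):
            avg = running_weights(
                bank, 3.0, NoiseSpec("normal", level, 50, seed=5)).weights
            err = np.max(np.abs(avg - base))
            assert err < prev_err
            prev_err = err
        assert prev_err < 1e-2


class TestOutputFunction:
    def test_single_oscillator_product(self):
        # one oscillator: the noiseless output is the plain state product,
        # maximal in magnitude at t=c when f*c is an integer
        spec = OscillatorBankSpec(1.0, 2.0, 1)
        t = np.linspace(0.5, 3.0, 501)
        tr = closed_form_output(spec, 1.0, t)
        np.testing.assert_allclose(
            tr.value,
            np.cos(2 * np.pi * 2.0 * 1.0) * np.cos(2 * np.pi * 2.0 * t),
            atol=1e-9)

    @pytest.mark.filterwarnings("ignore:time grid coarser")
    def test_dot_output_at_reset_equals_weight_sum(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 30))
        ref = reference_weights(bank, 12.0)
        t = np.array([1e-9, 0.5, 1.0])
        tr = output_function(bank, 12.0, t)
        assert tr.value[0] == pytest.approx(ref.weights.sum(), rel=1e-6)

    def test_closed_form_matches_direct_sum_on_small_banks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            f1 = rng.uniform(0.5, 5)
            spec = OscillatorBankSpec(f1, f1 + rng.uniform(0.5, 5),
                                      int(rng.integers(2, 12)))
            c = rng.uniform(1, 20)
            t = np.sort(rng.uniform(0, 30, 64))
            np.testing.assert_allclose(closed_form_output(spec, c, t).value,
                                       direct_noiseless_sum(spec, c, t),
                                       atol=1e-8)

    def test_closed_form_finite_at_criterion_and_mirror_symmetric(self):
        spec = OscillatorBankSpec(2.0, 4.0, 7)
        c = 5.0
        tr = closed_form_output(spec, c, np.array([c]))
        assert np.isfinite(tr.value[0])
        tau = np.linspace(-0.5, 0.5, 101)
        near_plus = closed_form_output(spec, c, c + tau).value
        near_minus = closed_form_output(spec, c, -c + tau).value
        np.testing.assert_allclose(near_plus, near_minus[::-1], atol=1e-8)

    def test_cosine_angle_bounded_and_unity_at_criterion(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 100))
        c = 9.0
        t = np.linspace(5.0, 13.0, 2001)
        t[1000] = c
        tr = output_function(bank, c, t, similarity="cosine_angle")
        assert np.all((tr.value >= 0) & (tr.value <= 1 + 1e-12))
        assert tr.value[1000] == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_limit_converges_pointwise(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 100))
        t = np.linspace(9.0, 11.0, 401)
        base = output_function(bank, 10.0, t).value
        errs = []
        for level in (1e-3, 1e-5):
            noisy = output_function(
                bank, 10.0, t,
                mem_noise=NoiseSpec("uniform", level, 200, seed=2)).value
            errs.append(np.max(np.abs(noisy - base)))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05 * np.max(np.abs(base))

    def test_seeded_outputs_bit_identical(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 60))
        t = np.linspace(8.0, 12.0, 301)
        kwargs = dict(mem_noise=NoiseSpec("normal", 0.02, 100, seed=11),
                      freq_noise=NoiseSpec("uniform", 0.01, 5, seed=12))
        a = output_function(bank, 10.0, t, **kwargs)
        b = output_function(bank, 10.0, t, **kwargs)
        np.testing.assert_array_equal(a.value, b.value)

    def test_coarse_grid_warns(self):
        bank = CosineBank(OscillatorBankSpec(5.5, 11.5, 10))
        with pytest.warns(UserWarning, match="coarser"):
            output_function(bank, 5.0, np.linspace(4.0, 6.0, 10))


class TestMemoryNoiseOutput:
    def test_single_sample_at_criterion_reduces_to_retained_branch(self):
        spec = OscillatorBankSpec(2.0, 4.0, 7)
        t = np.linspace(4.0, 6.0, 501)
        # level ~ 0 draw: the sampled criterion is within 1e-12 of c
        noisy = memory_noise_output(spec, 5.0, t,
                                    sbf.NoiseSpec("normal", 1e-13, 1, seed=0))
        retained = sbf.dirichlet_kernel(t - 5.0, spec)
        np.testing.assert_allclose(noisy.value, retained, atol=1e-6)

    def test_three_sample_enumerated_oracle(self):
        spec = OscillatorBankSpec(2.0, 4.0, 5)
        c, t = 5.0, np.linspace(3.0, 7.0, 401)
        noise = NoiseSpec("uniform", 0.05, 3, seed=9)
        samples = c * sample_multipliers(noise)
        tr = memory_noise_output(spec, c, t, noise)
        # oracle: per-sample direct cosine sums, retained branch only
        freqs = make_frequency_grid(spec)
        oracle = np.zeros_like(t)
        for cj in samples:
            oracle += 0.5 * np.cos(2 * np.pi * np.outer(t - cj, freqs)).sum(axis=1)
        np.testing.assert_allclose(tr.value, oracle, atol=1e-10)

    @pytest.mark.parametrize("family", ["normal", "uniform"])
    def test_single_peak_near_criterion(self, family):
        spec = OscillatorBankSpec(5.5, 11.5, 400)
        c = 30.0
        t = sbf.simulation_grid(spec, c, 0.01)
        tr = memory_noise_output(spec, c, t,
                                 NoiseSpec(family, 0.01, 300, seed=4))
        # peak envelope within the criterion-noise spread of c
        assert abs(t[np.argmax(np.abs(tr.value))] - c) < 3 * 0.01 * c

    def test_noiseless_spec_rejected(self):
        spec = OscillatorBankSpec(2.0, 4.0, 5)
        with pytest.raises(ConfigurationError):
            memory_noise_output(spec, 5.0, np.linspace(4, 6, 10), NoiseSpec())
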