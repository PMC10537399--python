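"""Degradation operators, MAE metric, cutoff sweep and breakpoint detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from backres.degrade import (
    CutoffAboveNyquistError,
    DegradeParams,
    ErrorCurve,
    ToleranceUnreachableError,
    add_noise,
    downsample_random,
    find_breakpoint,
    lowpass_profile,
    lowpass_stack,
    quantize_depth,
    shape_mae,
    sweep_cutoffs,
)
from backres.spectrum import profile_spectrum
from conftest import make_profile, sinusoid_profile, stack_from_profiles


def fitted_amplitude(profile, freq):
    """Least-squares amplitude of the sinusoid at ``freq`` over the central
    half of the profile (avoids filter edge transients)."""
    n = profile.n
    sl = slice(n // 4, 3 * n // 4)
    x, z = profile.x[sl], profile.z[sl]
    c, s = np.cos(2 * np.pi * freq * x), np.sin(2 * np.pi * freq * x)
    A = np.column_stack([c, s])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return float(np.hypot(*coef))


def zero_phase_gain(f, fc, order):
    """Analytic amplitude gain of a forward-backward Butterworth filter."""
    return 1.0 / (1.0 + (f / fc) ** (2 * order))


class TestLowpass:
    def test_passband_identity_one_decade_below(self):
        prof = sinusoid_profile(freq=0.02, amplitude=1.0, n=2048, dx=0.5)
        out = lowpass_profile(prof, fc=0.2, order=4)
        gain = fitted_amplitude(out, 0.02) / fitted_amplitude(prof, 0.02)
        assert gain == pytest.approx(zero_phase_gain(0.02, 0.2, 4), abs=1e-3)
        assert abs(gain - 1.0) <= 0.01

    def test_stopband_attenuation_one_decade_above(self):
        prof = sinusoid_profile(freq=0.2, amplitude=1.0, n=2048, dx=0.5)
        out = lowpass_profile(prof, fc=0.02, order=4)
        gain = fitted_amplitude(out, 0.2) / fitted_amplitude(prof, 0.2)
        # zero-phase filtering applies the squared magnitude response
        assert gain <= 1e-3
        assert gain <= zero_phase_gain(0.2, 0.02, 4) * 10 + 1e-9

    def test_transition_band_matches_analytic_gain(self):
        for f in (0.05, 0.1, 0.15):
            prof = sinusoid_profile(freq=f, amplitude=2.0, n=4096, dx=0.5)
            out = lowpass_profile(prof, fc=0.1, order=4)
            gain = fitted_amplitude(out, f) / 2.0
            assert gain == pytest.approx(zero_phase_gain(f, 0.1, 4), abs=0.01)

    def test_constant_profile_unchanged(self):
        prof = make_profile(np.full(256, 12.3), dx=0.5)
        out = lowpass_profile(prof, fc=0.1, order=4)
        np.testing.assert_allclose(out.z, prof.z, atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        prof = sinusoid_profile(0.05, dx=0.5)
        with pytest.raises(CutoffAboveNyquistError, match="Nyquist"):
            lowpass_profile(prof, fc=1.0, order=4)

    def test_grid_and_mask_unchanged(self):
        prof = sinusoid_profile(0.05, n=300, dx=0.5, x0=10.0)
        out = lowpass_profile(prof, fc=0.1)
        assert out.x0 == prof.x0 and out.dx == prof.dx and out.n == prof.n
        assert not out.missing.any()


class TestDownsample:
    def test_keep_all_is_identity(self):
        prof = sinusoid_profile(0.05, n=100)
        out = downsample_random(prof, 1.0, seed=5)
        np.testing.assert_array_equal(out.z, prof.z)
        assert not out.missing.any()

    def test_exact_survivor_count(self):
        prof = sinusoid_profile(0.05, n=100)
        out = downsample_random(prof, 0.25, seed=1)
        assert out.n_valid == 25

    def test_seed_determinism(self):
        prof = sinusoid_profile(0.05, n=200)
        a = downsample_random(prof, 0.5, seed=11)
        b = downsample_random(prof, 0.5, seed=11)
        c = downsample_random(prof, 0.5, seed=12)
        np.testing.assert_array_equal(a.missing, b.missing)
        assert not np.array_equal(a.missing, c.missing)

    def test_too_aggressive_rejected(self):
        prof = sinusoid_profile(0.05, n=100)
        with pytest.raises(ValueError):
            downsample_random(prof, 0.01, seed=0)


class TestQuantize:
    def test_rounding_examples(self):
        prof = make_profile([0.4, 0.6, -0.4, -0.6])
        out = quantize_depth(prof, 1.0)
        np.testing.assert_allclose(out.z, [0.0, 1.0, 0.0, -1.0])

    def test_zero_step_identity(self):
        prof = sinusoid_profile(0.05)
        out = quantize_depth(prof, 0.0)
        np.testing.assert_array_equal(out.z, prof.z)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(step=st.floats(1e-3, 10.0),
           seed=st.integers(0, 2**16))
    def test_error_bounded_by_half_step(self, step, seed):
        rng = np.random.default_rng(seed)
        prof = make_profile(rng.uniform(-50, 50, size=64))
        out = quantize_depth(prof, step)
        assert np.max(np.abs(out.z - prof.z)) <= step / 2 + 1e-12

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            quantize_depth(sinusoid_profile(0.05), -1.0)


class TestNoise:
    def test_zero_amplitude_identity(self):
        prof = sinusoid_profile(0.05)
        out = add_noise(prof, "uniform", DegradeParams(noise_amplitude=0.0))
        np.testing.assert_array_equal(out.z, prof.z)

    def test_uniform_noise_statistics(self):
        prof = make_profile(np.zeros(10_000), dx=0.5)
        out = add_noise(prof, "uniform",
                        DegradeParams(noise_amplitude=1.0, seed=3))
        added = out.z - prof.z
        assert abs(added.mean()) < 0.05
        assert np.max(np.abs(added)) <= 1.0

    def test_sinusoidal_noise_visible_in_spectrum(self):
        # n * dx * f integer -> the sine sits exactly on a DFT bin
        prof = make_profile(np.zeros(4000), dx=0.5)
        out = add_noise(prof, "sinusoidal",
                        DegradeParams(sine_amplitude=2.0, sine_frequency=0.05))
        spec = profile_spectrum(out, detrend="mean")
        k = int(np.argmax(spec.magnitudes))
        assert spec.frequencies[k] == pytest.approx(0.05, abs=spec.df)
        assert spec.magnitudes[k] == pytest.approx(2.0, rel=0.02)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            add_noise(sinusoid_profile(0.05), "gaussian")


class TestShapeMAE:
    def _random_stack(self, rng, n_slices=4, n=50, with_mask=False):
        profs = []
        for i in range(n_slices):
            missing = None
            if with_mask:
                missing = rng.uniform(size=n) < 0.2
            profs.append(make_profile(rng.normal(size=n), dx=1.0,
                                      y_center=10.0 * i, missing=missing))
        return stack_from_profiles(profs)

    def test_identical_stacks_zero(self, small_back_stack):
        assert shape_mae(small_back_stack, small_back_stack) == 0.0

    def test_constant_offset(self, small_back_stack):
        shifted = stack_from_profiles(
            [s.copy_with(z=s.z + 1.0) for s in small_back_stack.slices])
        assert shape_mae(small_back_stack, shifted) == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        a = self._random_stack(rng, with_mask=True)
        b = stack_from_profiles(
            [s.copy_with(z=s.z + rng.normal(size=s.n),
                         missing=rng.uniform(size=s.n) < 0.2)
             for s in a.slices])
        total, count = 0.0, 0
        for sa, sb in zip(a.slices, b.slices):
            for i in range(sa.n):
                if not sa.missing[i] and not sb.missing[i]:
                    total += abs(sa.z[i] - sb.z[i])
                    count += 1
        assert shape_mae(a, b) == pytest.approx(total / count, rel=1e-12)

    def test_symmetric(self, rng):
        a = self._random_stack(rng)
        b = stack_from_profiles(
            [s.copy_with(z=s.z + rng.normal(size=s.n)) for s in a.slices])
        assert shape_mae(a, b) == pytest.approx(shape_mae(b, a))

    def test_mismatched_grids_rejected(self, rng):
        a = self._random_stack(rng)
        b = stack_from_profiles(
            [make_profile(rng.normal(size=60), dx=1.0, y_center=10.0 * i)
             for i in range(4)])
        with pytest.raises(ValueError):
            shape_mae(a, b)


class TestSweep:
    def test_passband_content_survives(self):
        # stack band-limited below 0.02 mm^-1: both cutoffs in the passband
        profs = [sinusoid_profile(0.01, amplitude=5.0, n=1024, dx=0.5,
                                  phase=0.3 * i) for i in range(3)]
        for i, p in enumerate(profs):
            p.y_center = 10.0 * i
        curve = sweep_cutoffs([stack_from_profiles(profs)], [0.1, 0.05])
        assert np.all(curve.errors < 0.05)

    def test_removed_sinusoid_error_is_two_a_over_pi(self):
        # a pure sinusoid at 0.08: cutoff 0.2 keeps it, cutoff 0.01 removes it
        # leaving MAE ~ mean|A sin| = 2A/pi
        A = 3.0
        prof = sinusoid_profile(0.08, amplitude=A, n=4096, dx=0.5)
        curve = sweep_cutoffs([stack_from_profiles([prof])], [0.2, 0.01])
        assert curve.errors[0] < 0.01 * curve.errors[1]
        assert curve.errors[1] == pytest.approx(2 * A / np.pi, rel=0.05)

    def test_single_stack_single_cutoff(self, small_back_stack):
        curve = sweep_cutoffs([small_back_stack], [0.1])
        assert curve.cutoffs.shape == (1,) and curve.errors.shape == (1,)
        assert curve.per_subject_errors.shape == (1, 1)

    def test_error_curve_monotone_on_band_limited_stack(self, small_back_stack):
        cutoffs = [0.2, 0.1, 0.05, 0.02, 0.01, 0.005]
        curve = sweep_cutoffs([small_back_stack], cutoffs)
        assert np.all(np.diff(curve.errors) >= -1e-9)
        # content is below f_max=0.05: generous cutoffs are nearly lossless
        assert curve.errors[0] < 0.05

    def test_mean_over_subjects(self, small_back_stack):
        doubled = stack_from_profiles(
            [s.copy_with(z=2 * s.z) for s in small_back_stack.slices])
        curve = sweep_cutoffs([small_back_stack, doubled], [0.02])
        expected = curve.per_subject_errors.mean(axis=0)
        np.testing.assert_allclose(curve.errors, expected)

    def test_ascending_cutoffs_rejected(self, small_back_stack):
        with pytest.raises(ValueError):
            sweep_cutoffs([small_back_stack], [0.01, 0.05])


class TestBreakpoint:
    def test_direct_threshold_with_band(self):
        curve = ErrorCurve(np.array([0.1, 0.05, 0.02]),
                           np.array([0.01, 0.02, 5.0]))
        bp = find_breakpoint(curve, 0.5)
        assert bp.cutoff == pytest.approx(0.05)
        assert bp.band == pytest.approx((0.02, 0.05))

    def test_all_within_tolerance_degenerate_band(self):
        curve = ErrorCurve(np.array([0.1, 0.05]), np.array([0.01, 0.02]))
        bp = find_breakpoint(curve, 0.5)
        assert bp.cutoff == pytest.approx(0.05)
        assert bp.band == pytest.approx((0.05, 0.05))

    def test_analytic_inversion_on_monotone_curve(self):
        # e(fc) = 0.001/fc crosses tolerance 0.02 at fc = 0.05 exactly
        cutoffs = np.round(np.arange(0.10, 0.009, -0.01), 10)
        curve = ErrorCurve(cutoffs, 0.001 / cutoffs)
        bp = find_breakpoint(curve, 0.02)
        assert bp.cutoff == pytest.approx(0.05)

    def test_unreachable_tolerance_raises(self):
        curve = ErrorCurve(np.array([0.1, 0.05]), np.array([1.0, 2.0]))
        with pytest.raises(ToleranceUnreachableError, match="unreachable"):
            find_breakpoint(curve, 0.5)

    def test_invalid_tolerance(self):
        curve = ErrorCurve(np.array([0.1]), np.array([0.0]))
        with pytest.raises(ValueError):
            find_breakpoint(curve, 0.0)


class TestStackFilter:
    def test_lowpass_stack_preserves_structure(self, small_back_stack):
        out = lowpass_stack(small_back_stack, 0.05)
        assert len(out) == len(small_back_stack)
        np.testing.assert_array_equal(out.y_centers,
                                      small_back_stack.y_centers)
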