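"""Corruption simulators against Fourier-theorem and brute-force oracles."""

import warnings

import numpy as np
import pytest

from jointmri.corruption import (
    CorruptionConfig,
    MotionTrajectory,
    add_complex_gaussian_noise,
    apply_mask,
    apply_rigid_transform,
    make_sampling_mask,
    sample_motion_trajectory,
    simulate_motion_corruption,
    simulate_task,
    translation_phase_ramp,
    rotation_in_kspace,
)
from jointmri.fourier import fft2c, ifft2c
from jointmri.phantom import PhantomSpec, generate_phantom


def _cfg(**kw):
    return CorruptionConfig(**{"task": "motion", **kw})


class TestMotionTrajectory:
    def test_zero_rate_gives_identity_trajectory(self, rng):
        traj = sample_motion_trajectory(64, _cfg(gamma_m=0.0), rng)
        assert traj.change_lines.size == 0
        assert np.all(traj.per_line == 0)

    def test_change_point_count_rounds_up(self, rng):
        traj = sample_motion_trajectory(256, _cfg(gamma_m=0.03), rng)
        assert traj.change_lines.size == 8  # ceil(0.03 * 256)

    def test_same_seed_reproduces_trajectory(self):
        a = sample_motion_trajectory(64, _cfg(), np.random.default_rng(5))
        b = sample_motion_trajectory(64, _cfg(), np.random.default_rng(5))
        assert np.array_equal(a.per_line, b.per_line)
        assert np.array_equal(a.change_lines, b.change_lines)

    def test_parameters_piecewise_constant_within_ranges(self, rng):
        traj = sample_motion_trajectory(256, _cfg(gamma_m=0.05), rng)
        assert np.all(np.abs(traj.per_line[:, :2]) <= 8.0)
        assert np.all(np.abs(traj.per_line[:, 2]) <= 11.0)
        # identity before the first change point
        assert np.all(traj.per_line[: traj.change_lines[0]] == 0)
        # constant between consecutive change points
        bounds = list(traj.change_lines) + [256]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = traj.per_line[lo:hi]
            assert np.all(seg == seg[0])

    def test_sub_unit_expected_count_warns_and_is_identity(self, rng):
        with pytest.warns(UserWarning):
            traj = sample_motion_trajectory(16, _cfg(gamma_m=0.01), rng)
        assert traj.change_lines.size == 0


class TestRigidTransform:
    def test_identity_is_bit_exact(self, small_phantom):
        out = apply_rigid_transform(small_phantom, 0, 0, 0)
        assert np.array_equal(out.values, small_phantom.values)

    def test_integer_translation_equals_array_shift(self, rng):
        img = np.zeros((32, 32), complex)
        img[12:20, 12:20] = rng.normal(size=(8, 8)) + 1j
        out = apply_rigid_transform(img, 3, -2, 0).values
        assert np.abs(out - np.roll(img, (3, -2), axis=(0, 1))).max() < 1e-12

    def test_quarter_turn_matches_exact_grid_rotation(self):
        # odd size: the rotation center (H//2, W//2) is a grid point with
        # an exact quarter-turn image, so bilinear interpolation is exact
        phantom = generate_phantom(PhantomSpec(size=33), np.random.default_rng(3))
        out = apply_rigid_transform(phantom, 0, 0, 90.0).values
        assert np.abs(out - np.rot90(phantom.values, k=-1)).max() < 1e-6


class TestMotionSimulation:
    def test_identity_trajectory_reproduces_clean_kspace(self, small_phantom):
        traj = MotionTrajectory(np.zeros((32, 3)), np.array([], dtype=int))
        out = simulate_motion_corruption(small_phantom, traj)
        assert np.array_equal(out.values, fft2c(small_phantom.values))

    def test_global_integer_translation_matches_phase_ramp(self, random_complex_grid):
        # Fourier shift theorem oracle, circular-shift convention
        img = random_complex_grid(16, 16)
        traj = MotionTrajectory(np.tile([3.0, 5.0, 0.0], (16, 1)), np.array([0]))
        sim = simulate_motion_corruption(img, traj, wrap=True).values
        oracle = translation_phase_ramp(fft2c(img), 3, 5).values
        assert np.abs(sim - oracle).max() < 1e-8

    def test_each_line_matches_per_state_dft_brute_force(self, small_phantom):
        per_line = np.zeros((32, 3))
        per_line[10:22] = [2.0, -1.5, 7.0]
        per_line[22:] = [-3.0, 0.5, -4.0]
        traj = MotionTrajectory(per_line, np.array([10, 22]))
        sim = simulate_motion_corruption(small_phantom, traj).values
        for ky in range(32):
            moved = apply_rigid_transform(small_phantom, *per_line[ky])
            expected = fft2c(moved.values)[:, ky]
            assert np.abs(sim[:, ky] - expected).max() < 1e-12

    def test_line_count_mismatch_raises(self, small_phantom):
        traj = MotionTrajectory(np.zeros((16, 3)), np.array([], dtype=int))
        with pytest.raises(ValueError):
            simulate_motion_corruption(small_phantom, traj)


class TestPhaseRamp:
    def test_zero_shift_is_identity(self, random_complex_grid):
        k = random_complex_grid()
        assert np.array_equal(translation_phase_ramp(k, 0, 0).values, k)

    def test_pure_phase_preserves_modulus(self, random_complex_grid):
        k = random_complex_grid()
        out = translation_phase_ramp(k, 2.7, -1.3).values
        assert np.abs(np.abs(out) - np.abs(k)).max() < 1e-12

    def test_full_period_shift_is_identity(self, random_complex_grid):
        k = random_complex_grid(16, 16)
        out = translation_phase_ramp(k, 16, 0).values
        assert np.abs(out - k).max() < 1e-10


class TestRotationInKspace:
    def test_zero_angle_identity(self, random_complex_grid):
        k = random_complex_grid()
        assert np.array_equal(rotation_in_kspace(k, 0.0).values, k)

    def test_quarter_turn_matches_grid_rotation(self):
        k = fft2c(generate_phantom(PhantomSpec(size=33), np.random.default_rng(3)).values)
        out = rotation_in_kspace(k, 90.0).values
        assert np.abs(out - np.rot90(k, k=-1)).max() < 1e-6

    def test_rotation_theorem_cross_check(self):
        # rotating in k-space must reproduce the rotated image; validated
        # on a centered anisotropic Gaussian whose rotation is known in
        # closed form (bilinear k-space resampling limits the tolerance)
        n, sig, phi = 65, 4.0, 20.0
        c = n // 2
        y, x = np.indices((n, n))

        def gauss(angle_deg):
            rad = np.deg2rad(angle_deg)
            co, s = np.cos(rad), np.sin(rad)
            xr = (x - c) * co - (y - c) * s
            yr = (x - c) * s + (y - c) * co
            return np.exp(-((xr / sig) ** 2 + (yr / (sig * 1.5)) ** 2))

        img = gauss(0).astype(complex)
        via_k = np.abs(ifft2c(rotation_in_kspace(fft2c(img), phi).values))
        via_img = np.abs(apply_rigid_transform(img, 0, 0, phi).values)
        exact = gauss(-phi)  # output(p) = input(R p): pattern turns by -phi
        m = n // 5
        inner = (slice(m, n - m), slice(m, n - m))
        assert np.abs(via_k[inner] - exact[inner]).max() < 0.02
        assert np.abs(via_img[inner] - exact[inner]).max() < 0.02


class TestNoise:
    def test_zero_sigma_identity(self, random_complex_grid, rng):
        k = random_complex_grid()
        assert np.array_equal(add_complex_gaussian_noise(k, 0.0, rng).values, k)

    def test_negative_sigma_rejected(self, random_complex_grid, rng):
        with pytest.raises(ValueError):
            add_complex_gaussian_noise(random_complex_grid(), -1.0, rng)

    def test_power_matches_complex_gaussian_moments(self, rng):
        k = np.zeros((256, 256), complex)
        out = add_complex_gaussian_noise(k, 1.0, rng).values
        power = np.mean(np.abs(out) ** 2)
        assert abs(power - 2.0) / 2.0 < 0.05  # E|e1 + i e2|^2 = 2 sigma^2

    def test_fixed_seed_reproducible(self, random_complex_grid):
        k = random_complex_grid()
        a = add_complex_gaussian_noise(k, 0.5, np.random.default_rng(1)).values
        b = add_complex_gaussian_noise(k, 0.5, np.random.default_rng(1)).values
        assert np.array_equal(a, b)

    def test_mean_over_seeds_approaches_clean_kspace(self, random_complex_grid):
        k = random_complex_grid(8, 8)
        sigma = 0.3
        acc = np.zeros_like(k)
        n_seeds = 1000
        for s in range(n_seeds):
            acc += add_complex_gaussian_noise(k, sigma, np.random.default_rng(s)).values
        err = np.abs(acc / n_seeds - k)
        assert err.max() < 3 * sigma / np.sqrt(n_seeds) * 3  # 3-sigma slack per part


class TestSamplingMasks:
    def test_random_scheme_keeps_exact_fraction(self, rng):
        m = make_sampling_mask(256, "random", rng, gamma_s=0.25)
        assert m.n_kept == 64

    def test_equispaced_4x_keeps_full_central_band(self, rng):
        m = make_sampling_mask(256, "equispaced_4x_center8", rng)
        assert np.all(m.line_kept[118:138])  # 20-line band (8% of 256, even)

    def test_equispaced_8x_center_band(self, rng):
        m = make_sampling_mask(256, "equispaced_8x_center4", rng)
        assert np.all(m.line_kept[123:133])  # 10-line band
        outer = m.line_kept.copy()
        outer[123:133] = False
        assert np.all(np.nonzero(outer)[0] % 8 == 0)

    def test_motion_combo_reaches_quarter_sampling_with_full_center(self, rng):
        m = make_sampling_mask(256, "motion_combo_4x", rng)
        assert m.n_kept == 64
        assert np.all(m.line_kept[118:138])

    def test_same_seed_same_mask(self):
        a = make_sampling_mask(64, "random", np.random.default_rng(3))
        b = make_sampling_mask(64, "random", np.random.default_rng(3))
        assert np.array_equal(a.line_kept, b.line_kept)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError):
            make_sampling_mask(64, "spiral", rng)


class TestApplyMask:
    def test_all_kept_identity_and_all_dropped_zero(self, random_complex_grid, rng):
        k = random_complex_grid()
        m = make_sampling_mask(16, "random", rng, gamma_s=0.5)
        m.line_kept[:] = True
        assert np.array_equal(apply_mask(k, m).values, k)
        m.line_kept[:] = False
        assert np.abs(apply_mask(k, m).values).max() == 0

    def test_nonzero_column_count_matches_kept_lines(self, random_complex_grid, rng):
        k = random_complex_grid()
        m = make_sampling_mask(16, "random", rng, gamma_s=0.5)
        out = apply_mask(k, m).values
        assert (np.abs(out).sum(axis=0) > 0).sum() == m.n_kept

    def test_idempotent(self, random_complex_grid, rng):
        k = random_complex_grid()
        m = make_sampling_mask(16, "random", rng, gamma_s=0.5)
        once = apply_mask(k, m).values
        twice = apply_mask(once, m).values
        assert np.array_equal(once, twice)

    def test_width_mismatch_raises(self, random_complex_grid, rng):
        m = make_sampling_mask(8, "random", rng)
        with pytest.raises(ValueError):
            apply_mask(np.zeros((16, 16), complex), m)


class TestSimulateTask:
    def test_noiseless_noise_task_reduces_to_clean_dft(self, small_phantom, rng):
        corrupted, target, mask = simulate_task(
            small_phantom, CorruptionConfig(task="noise", noise_sigma=0.0), rng
        )
        assert mask is None
        assert np.abs(corrupted.values - fft2c(target.values)).max() < 1e-12

    def test_normalized_corrupted_image_peaks_at_one(self, small_phantom, rng):
        corrupted, _, _ = simulate_task(
            small_phantom, CorruptionConfig(task="motion"), rng
        )
        assert np.isclose(np.abs(ifft2c(corrupted.values)).max(), 1.0)

    def test_combined_task_degenerates_without_motion(self, small_phantom, rng):
        # gamma_m = 0 leaves only the undersampling mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrupted, target, mask = simulate_task(
                small_phantom,
                CorruptionConfig(task="motion+undersample", gamma_m=0.0),
                rng,
            )
        clean = fft2c(target.values)
        kept = mask.line_kept
        assert np.abs(corrupted.values[:, kept] - clean[:, kept]).max() < 1e-12
        assert np.abs(corrupted.values[:, ~kept]).max() == 0

    def test_undersample_task_returns_mask(self, small_phantom, rng):
        _, _, mask = simulate_task(
            small_phantom, CorruptionConfig(task="undersample"), rng
        )
        assert mask is not None and mask.n_kept == 8  # 0.25 * 32
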