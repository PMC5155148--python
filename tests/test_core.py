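"""Core subspace algorithm: eigenimages, projections, indicator, stitching."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musical_sr import (
    ImageStack,
    ProjectionPair,
    compute_eigenimages,
    extract_window_matrix,
    indicator,
    make_pair_scene,
    make_soft_window,
    project_psf,
    run_musical,
    sample_psf_vector,
    simulate_stack,
    split_subspaces,
    threshold_map,
)
from musical_sr.core import IndicatorMap
from musical_sr.profiles import measure_fwhm, sample_line_profile
from musical_sr.simulate import SyntheticScene, Emitter


def brute_force_indicator(frames_window, steering, sigma0, alpha):
    """Independent oracle: explicit covariance eigendecomposition + projectors.

    Builds G*G^T for the N x K window matrix, eigendecomposes it densely,
    forms the signal projector from eigenvectors with sqrt(eigenvalue) >=
    sigma0 and the null projector as its complement, and evaluates
    (||P_S a|| / ||P_N a||) ** alpha directly.
    """
    G = frames_window
    R = G @ G.T
    eigvals, eigvecs = np.linalg.eigh(R)
    sigmas = np.sqrt(np.clip(eigvals, 0.0, None))
    signal = eigvecs[:, sigmas >= sigma0]
    P_S = signal @ signal.T
    P_N = np.eye(G.shape[0]) - P_S
    d_pr = np.linalg.norm(P_S @ steering)
    d_pn = max(np.linalg.norm(P_N @ steering), 1e-12)
    return (d_pr / d_pn) ** alpha


class TestWindowMatrix:
    def test_shape_and_weighting(self, psf593):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.poisson(20.0, (49, 9, 9)).astype(float), 65.0)
        window = make_soft_window((4, 4), 7)
        G = extract_window_matrix(stack, window)
        assert G.shape == (49, 49)
        # column k reproduces frame k's window, row-major
        frame0 = stack.data[0, 1:8, 1:8].ravel()
        assert np.allclose(G[:, 0], frame0 * window.weights)

    def test_constant_frame_gives_constant_column(self):
        stack = ImageStack(np.full((3, 7, 7), 5.0), 65.0)
        G = extract_window_matrix(stack, make_soft_window((3, 3), 7))
        assert np.allclose(G, 5.0)

    def test_frame_permutation_permutes_columns(self):
        rng = np.random.default_rng(1)
        data = rng.random((10, 7, 7))
        perm = rng.permutation(10)
        w = make_soft_window((3, 3), 7)
        G = extract_window_matrix(ImageStack(data, 65.0), w)
        Gp = extract_window_matrix(ImageStack(data[perm], 65.0), w)
        assert np.allclose(Gp, G[:, perm])

    def test_out_of_bounds_window_rejected(self):
        stack = ImageStack(np.ones((3, 7, 7)), 65.0)
        with pytest.raises(ValueError):
            extract_window_matrix(stack, make_soft_window((1, 1), 7))

    def test_empty_frame_range_rejected(self):
        stack = ImageStack(np.ones((3, 7, 7)), 65.0)
        with pytest.raises(ValueError):
            extract_window_matrix(stack, make_soft_window((3, 3), 7), slice(2, 2))


class TestEigenimages:
    def test_repeated_frame_is_rank_one(self):
        frame = np.random.default_rng(2).random(25)
        G = np.tile(frame[:, None], (1, 12))
        d = compute_eigenimages(G)
        assert np.sum(d.singular_values > 1e-10 * d.singular_values[0]) == 1
        u0 = d.eigenimages[:, 0]
        assert np.allclose(np.abs(u0 @ frame), np.linalg.norm(frame))

    @pytest.mark.parametrize("N,K", [(25, 10), (25, 25), (25, 60)])
    def test_rank_bound_and_orthonormal_basis(self, N, K):
        G = np.random.default_rng(N + K).random((N, K))
        d = compute_eigenimages(G)
        assert np.sum(d.singular_values > 1e-10) <= min(N, K)
        gram = d.eigenimages.T @ d.eigenimages
        assert np.max(np.abs(gram - np.eye(N))) < 1e-8
        assert np.all(np.diff(d.singular_values) <= 1e-12)

    def test_reconstruction(self):
        G = np.random.default_rng(3).random((16, 30))
        d = compute_eigenimages(G)
        r = min(16, 30)
        approx = d.eigenimages[:, :r] @ np.diag(d.singular_values[:r]) @ d.frame_vectors
        assert np.linalg.norm(approx - G) / np.linalg.norm(G) < 1e-10

    def test_singular_values_match_covariance_eigenvalues(self):
        """sigma^2 equals eigenvalues of G G^T from an independent eigensolver."""
        for seed in range(5):
            G = np.random.default_rng(seed).normal(size=(10, 10))
            d = compute_eigenimages(G)
            eigvals = np.sort(np.linalg.eigvalsh(G @ G.T))[::-1]
            assert np.allclose(d.singular_values**2, eigvals, atol=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_eigenimages(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestSubspaceSplit:
    def test_threshold_above_sigma_max(self):
        d = compute_eigenimages(np.random.default_rng(4).random((9, 9)))
        d = split_subspaces(d, ("abs", d.singular_values[0] * 2))
        assert len(d.signal_indices) == 0
        assert len(d.null_indices) == 9

    def test_zero_threshold_puts_all_in_signal(self):
        d = compute_eigenimages(np.random.default_rng(5).random((9, 9)))
        d = split_subspaces(d, "abs:0")
        assert len(d.signal_indices) == 9

    def test_single_blinking_emitter_has_signal_dimension_one(self, psf593):
        """Noise-free lone emitter: rank-1 structure at any inner threshold."""
        scene = SyntheticScene((Emitter((5.0, 5.0), 80.0, 0.5),), (11, 11), 0.0, psf593)
        sim = simulate_stack(scene, 40, noise="none", seed=6)
        G = extract_window_matrix(sim.stack, make_soft_window((5, 5), 7))
        d = split_subspaces(compute_eigenimages(G), "rel:0.5")
        assert len(d.signal_indices) == 1


class TestProjections:
    def _decomp(self, seed=7, N=49, K=60, rule="rel:0.1"):
        G = np.random.default_rng(seed).random((N, K))
        return split_subspaces(compute_eigenimages(G), rule)

    def test_signal_eigenimage_projects_fully_on_range(self):
        d = self._decomp()
        steering = d.eigenimages[:, d.signal_indices[0]]
        p = project_psf(d, steering)
        assert p.d_PR == pytest.approx(1.0, abs=1e-9)
        assert p.d_PN == pytest.approx(0.0, abs=1e-9)

    def test_pythagoras_with_full_basis(self):
        d = self._decomp(seed=8)
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(size=49)
            a /= np.linalg.norm(a)
            p = project_psf(d, a)
            assert p.d_PR**2 + p.d_PN**2 == pytest.approx(1.0, abs=1e-9)

    def test_true_emitter_position_lies_in_range(self, psf593):
        """Noise-free single emitter: steering at the true position has
        a negligible null component."""
        scene = SyntheticScene((Emitter((5.0, 5.0), 80.0, 0.5),), (11, 11), 0.0, psf593)
        sim = simulate_stack(scene, 60, noise="none", seed=10)
        window = make_soft_window((5, 5), 7)
        G = extract_window_matrix(sim.stack, window)
        d = split_subspaces(compute_eigenimages(G), "rel:0.5")
        steering = sample_psf_vector(psf593, (5.0, 5.0), window.pixel_list)
        assert project_psf(d, steering).d_PN < 1e-6

    def test_length_mismatch_rejected(self):
        d = self._decomp(seed=11)
        with pytest.raises(ValueError):
            project_psf(d, np.ones(10))


class TestIndicator:
    @settings(deadline=None, derandomize=True)
    @given(
        d=st.floats(min_value=1e-6, max_value=1.0),
        alpha=st.floats(min_value=0.1, max_value=8.0),
    )
    def test_equal_projections_give_one(self, d, alpha):
        assert indicator(ProjectionPair(d, d), alpha) == pytest.approx(1.0)

    def test_ratio_two_alpha_two_gives_four(self):
        assert indicator(ProjectionPair(0.8, 0.4), 2.0) == pytest.approx(4.0)

    def test_traditional_music_mode(self):
        p = ProjectionPair(0.6, 0.25)
        assert indicator(p, 1.0, traditional_music=True) == pytest.approx(4.0)

    def test_floor_prevents_infinity(self):
        value = indicator(ProjectionPair(1.0, 0.0), 2.0)
        assert np.isfinite(value) and value == pytest.approx(1e24)

    def test_non_positive_alpha_rejected(self):
        with pytest.raises(ValueError):
            indicator(ProjectionPair(1.0, 1.0), 0.0)


class TestRunMusical:
    def test_oracle_equivalence_on_random_stacks(self, psf593):
        """Indicator values match the dense-projector oracle to < 1e-8."""
        rng = np.random.default_rng(20)
        window = make_soft_window((2, 2), 5)
        for trial in range(20):
            data = rng.poisson(30.0, (12, 5, 5)).astype(float)
            stack = ImageStack(data, 65.0)
            G = extract_window_matrix(stack, window)
            ref = compute_eigenimages(G)
            # threshold chosen in a spectral gap of the oracle's own values
            sigmas = np.sqrt(np.clip(np.sort(np.linalg.eigvalsh(G @ G.T))[::-1], 0, None))
            sigma0 = (sigmas[1] + sigmas[2]) / 2
            d = split_subspaces(ref, ("abs", sigma0))
            for point in [(2.0, 2.0), (1.3, 2.7), (3.9, 0.4)]:
                steering = sample_psf_vector(psf593, point, window.pixel_list)
                ours = indicator(project_psf(d, steering), 4.0)
                expected = brute_force_indicator(G, steering, sigma0, 4.0)
                assert abs(ours - expected) / expected < 1e-8

    def test_single_window_stitching_identity(self, psf593):
        """An N_w-sized image has one window; stitching is a one-term sum."""
        scene = SyntheticScene((Emitter((3.0, 3.0), 80.0, 0.5),), (7, 7), 0.0, psf593)
        sim = simulate_stack(scene, 60, noise="none", seed=21)
        map_ = run_musical(sim.stack, psf593, n_w=7, subpixel_factor=5,
                           sigma0_rule="rel:0.5")
        window = make_soft_window((3, 3), 7)
        G = extract_window_matrix(sim.stack, window)
        d = split_subspaces(compute_eigenimages(G), "rel:0.5")
        # spot-check a few test points against the scalar path
        for gy, gx in [(17, 17), (5, 30), (22, 9)]:
            point = (-0.5 + (gy + 0.5) / 5, -0.5 + (gx + 0.5) / 5)
            steering = sample_psf_vector(psf593, point, window.pixel_list)
            expected = indicator(project_psf(d, steering), 4.0)
            assert map_.grid[gy, gx] == pytest.approx(expected, rel=1e-10)

    def test_all_zero_stack_yields_zero_map(self, psf593):
        stack = ImageStack(np.zeros((10, 9, 9)), 65.0)
        map_ = run_musical(stack, psf593, subpixel_factor=4)
        assert np.all(map_.grid == 0.0)

    def test_warns_when_fewer_frames_than_window_pixels(self, psf593):
        stack = ImageStack(np.random.default_rng(22).random((20, 9, 9)), 65.0)
        with pytest.warns(UserWarning, match="K=20"):
            run_musical(stack, psf593, n_w=7, subpixel_factor=2)

    def test_frame_permutation_invariance(self, pair_scene_50nm, psf593):
        sim = simulate_stack(pair_scene_50nm, 80, noise="poisson", seed=23)
        perm = np.random.default_rng(24).permutation(80)
        kwargs = dict(n_w=7, subpixel_factor=4, sigma0_rule="rel:0.1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_musical(ImageStack(sim.stack.data, 65.0), psf593, **kwargs)
            b = run_musical(ImageStack(sim.stack.data[perm], 65.0), psf593, **kwargs)
        assert np.allclose(a.grid, b.grid, rtol=1e-8, atol=1e-12)

    def test_intensity_scale_invariance_with_relative_rule(self, pair_scene_50nm, psf593):
        sim = simulate_stack(pair_scene_50nm, 100, noise="poisson", seed=25)
        kwargs = dict(n_w=7, subpixel_factor=4, sigma0_rule="rel:0.1")
        a = run_musical(sim.stack, psf593, **kwargs)
        b = run_musical(ImageStack(sim.stack.data * 3.7, 65.0), psf593, **kwargs)
        assert np.allclose(a.grid, b.grid, rtol=1e-8)

    def test_alpha_monotonically_sharpens_peak(self, psf593):
        """Peak FWHM is non-increasing in alpha on a lone-emitter scene."""
        scene = SyntheticScene((Emitter((4.0, 4.0), 80.0, 0.5),), (9, 9), 0.0, psf593)
        sim = simulate_stack(scene, 60, noise="none", seed=26)
        widths = []
        for alpha in (1.0, 2.0, 4.0, 8.0):
            map_ = run_musical(sim.stack, psf593, alpha=alpha, subpixel_factor=10,
                               sigma0_rule="rel:0.5")
            row = int(np.unravel_index(np.argmax(map_.grid), map_.grid.shape)[0])
            prof = sample_line_profile(map_, (row, 10), (row, 79), 300)
            widths.append(measure_fwhm(prof).fwhm)
        assert all(b <= a + 1e-9 for a, b in zip(widths, widths[1:]))

    def test_indicator_contrast_between_emitter_and_empty_space(self, psf593):
        """Noise-free scene: indicator at a true emitter dominates any point
        two PSF widths away by at least 1e3."""
        emitters = (
            Emitter((9.0, 7.0), 80.0, 0.5),
            Emitter((9.0, 11.0), 80.0, 0.5),
        )
        scene = SyntheticScene(emitters, (19, 19), 0.0, psf593)
        sim = simulate_stack(scene, 100, noise="none", seed=27)
        map_ = run_musical(sim.stack, psf593, subpixel_factor=10,
                           sigma0_rule="rel:0.5")
        s = 10
        at_emitter = min(
            map_.grid[
                int((y + 0.5) * s - 1) : int((y + 0.5) * s + 1),
                int((x + 0.5) * s - 1) : int((x + 0.5) * s + 1),
            ].max()
            for y, x in [(9.0, 7.0), (9.0, 11.0)]
        )
        # 2 FWHM ~ 410 nm ~ 6.3 px away from both emitters
        far = map_.grid[int((3.0 + 0.5) * s), int((9.0 + 0.5) * s)]
        assert at_emitter > 1e3 * max(far, 1e-300)

    def test_superresolves_below_diffraction_limit(self, psf593):
        """At half the diffraction FWHM the mean image is unimodal but the
        reconstruction shows two maxima with a dip."""
        from musical_sr import calibrate_brightness
        from musical_sr.profiles import local_maxima_1d

        sep_nm = 0.5 * 204.8  # half the Airy FWHM at 593 nm / NA 1.49
        scene = calibrate_brightness(
            make_pair_scene(sep_nm, psf593, (15, 15), p_on=0.3, background=5.0),
            50.0,
        )
        sim = simulate_stack(scene, 200, noise="poisson", seed=28)
        mean_row = sim.stack.data.mean(axis=0)[7, 4:11]
        assert len(local_maxima_1d(mean_row)) <= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            map_ = run_musical(sim.stack, psf593, subpixel_factor=10)
        from conftest import pair_peak_errors

        errors, contrast = pair_peak_errors(map_, scene)
        assert errors is not None and contrast > 0.0

    def test_too_small_stack_rejected(self, psf593):
        with pytest.raises(ValueError):
            run_musical(ImageStack(np.ones((5, 5, 5)), 65.0), psf593, n_w=7)


class TestThresholdMap:
    def _map(self, values):
        return IndicatorMap(np.asarray(values, dtype=float), 6.5, {})

    def test_zero_fraction_is_identity(self):
        m = self._map(np.arange(1.0, 101.0).reshape(10, 10))
        out = threshold_map(m, fraction=0.0)
        assert np.array_equal(out.grid, m.grid)

    def test_constant_map_unchanged(self):
        m = self._map(np.full((5, 5), 2.0))
        out = threshold_map(m, fraction=0.9, percentile=99.9)
        assert np.array_equal(out.grid, m.grid)

    def test_enumeration_half_of_max(self):
        """Values 1..100 at fraction 0.5 of the max: exactly 51 survive."""
        m = self._map(np.arange(1.0, 101.0).reshape(10, 10))
        out = threshold_map(m, fraction=0.5, percentile=100.0)
        assert np.count_nonzero(out.grid) == 51
        assert out.grid.min() == 0.0
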