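"""Core model operations: PReLU, Gaussian map, forward prediction, restoration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convrf.model import (
    ConvRFModel,
    GaussianMap,
    OutputNonlinearity,
    PReLUParam,
    SpatioTemporalFilter,
    StimulusEnsemble,
    count_parameters,
    forward_predict,
    linear_predict,
    load_model,
    map_weights,
    output_nonlinearity_apply,
    prelu_apply,
    restoration,
    save_model,
    subunit_drive,
)
from conftest import small_model


class TestPrelu:
    @pytest.mark.parametrize(
        "x, alpha, expected",
        [(2.0, 0.5, 2.0), (-2.0, 0.5, -1.0), (-3.0, 0.0, 0.0), (0.0, 0.7, 0.0)],
    )
    def test_scalar_values(self, x, alpha, expected):
        assert prelu_apply(x, alpha) == pytest.approx(expected)

    def test_alpha_one_is_identity(self, rng):
        x = rng.normal(size=100)
        assert np.allclose(prelu_apply(x, 1.0), x)

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        alpha=st.floats(-2, 2, allow_nan=False),
    )
    def test_linear_plus_rectifier_decomposition(self, x, alpha):
        """prelu(x, a) == ((1+a)/2) x + ((1-a)/2) |x| exactly."""
        lhs = prelu_apply(x, alpha)
        rhs = 0.5 * (1 + alpha) * x + 0.5 * (1 - alpha) * abs(x)
        # identity is exact in reals; allow cancellation-level fp error
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6 * (1 + abs(x)))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="index"):
            prelu_apply(np.array([1.0, np.nan, 2.0]), 0.5)


class TestMapWeights:
    def test_centered_isotropic_symmetry(self):
        g = GaussianMap(7.5, 7.5, np.eye(2) * 4.0)
        w = map_weights(g, 16)
        assert np.allclose(w, w[::-1, :])
        assert np.allclose(w, w[:, ::-1])
        assert np.allclose(w, w.T)

    def test_peak_at_pixel_center_equals_beta(self):
        g = GaussianMap(5.0, 3.0, np.eye(2) * 2.0, beta=1.7)
        w = map_weights(g, 10)
        assert w[3, 5] == pytest.approx(1.7)
        assert w.max() == pytest.approx(1.7)

    def test_beta_scales_linearly(self):
        g1 = GaussianMap(4.0, 4.0, np.eye(2) * 3.0, beta=1.0)
        g2 = GaussianMap(4.0, 4.0, np.eye(2) * 3.0, beta=2.0)
        assert np.allclose(2 * map_weights(g1, 9), map_weights(g2, 9))

    def test_sum_matches_dense_quadrature(self):
        """Pixel-center sum approximates the continuous Gaussian integral."""
        sigma = 2.0
        g = GaussianMap(7.5, 7.5, np.eye(2) * sigma**2)
        w = map_weights(g, 16)
        # dense-quadrature oracle on a 10x-refined grid over the same support
        fine = 10
        yy, xx = (np.mgrid[0 : 16 * fine, 0 : 16 * fine] + 0.5) / fine - 0.5
        q = ((xx - 7.5) ** 2 + (yy - 7.5) ** 2) / sigma**2
        integral = np.exp(-0.5 * q).sum() / fine**2
        assert w.sum() == pytest.approx(integral, rel=0.01)

    def test_rejects_non_positive_definite(self):
        with pytest.raises(ValueError):
            GaussianMap(0, 0, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestOutputNonlinearity:
    @pytest.mark.parametrize(
        "x, gain, expo, expected",
        [(2.0, 1.0, 1.0, 2.0), (-3.0, 2.0, 1.5, 0.0), (2.0, 1.5, 2.0, 6.0)],
    )
    def test_power_law(self, x, gain, expo, expected):
        nl = OutputNonlinearity(gain, expo, stage1_mode=False)
        assert output_nonlinearity_apply(x, nl) == pytest.approx(expected)

    def test_stage1_is_rectifier(self):
        nl = OutputNonlinearity(stage1_mode=True)
        assert np.allclose(
            output_nonlinearity_apply(np.array([-1.0, 0.0, 2.0]), nl), [0, 0, 2]
        )

    def test_rejects_non_positive_exponent(self):
        with pytest.raises(ValueError):
            OutputNonlinearity(1.0, -1.0, stage1_mode=False)


class TestForwardPredict:
    def test_zero_filter_gives_zero_response(self, stimulus):
        model = small_model()
        model.filter.weights[:] = 0.0
        assert np.allclose(forward_predict(model, stimulus), 0.0)

    def test_alpha_one_collapses_to_linear_restoration(self, rng):
        """With the identity PReLU the cascade equals a single LN filter
        whose kernel is the restoration (filter * map, full convolution)."""
        for seed in range(5):
            model = small_model(alpha=1.0, seed=seed, bias=0.1)
            frames = np.random.default_rng(100 + seed).normal(size=(25, 8, 8))
            stim = StimulusEnsemble(frames, 75.0, 0.1)
            pred = forward_predict(model, stim)
            oracle = np.maximum(linear_predict(restoration(model), frames, 0.1), 0.0)
            assert np.allclose(pred, oracle, rtol=1e-6, atol=1e-9)

    def test_alpha_zero_point_map_is_single_subunit(self, rng):
        """Mass at one map pixel with alpha = 0 reduces to one half-wave
        rectified LN subunit at that location (direct window computation)."""
        model = small_model(alpha=0.0, input_size=6, k=3, n_lags=2)
        # concentrate the map on pixel (row 1, col 2) with a tiny sigma
        model.map = GaussianMap(2.0, 1.0, np.eye(2) * 1e-4)
        frames = rng.normal(size=(12, 6, 6))
        stim = StimulusEnsemble(frames, 75.0, 0.1)
        pred = forward_predict(model, stim)
        pad = np.concatenate([np.zeros((1, 6, 6)), frames])
        w = model.filter.weights
        expected = []
        for t in range(12):
            u = sum(
                np.sum(pad[t + 1 - tau, 1 : 1 + 3, 2 : 2 + 3] * w[tau])
                for tau in range(2)
            )
            expected.append(max(max(u, 0.0), 0.0))
        assert np.allclose(pred, expected, atol=1e-8)

    def test_output_is_nonnegative(self, rng):
        model = small_model(alpha=-0.7, bias=-0.5)
        stim = StimulusEnsemble(rng.normal(size=(40, 8, 8)), 75.0, 0.1)
        assert np.all(forward_predict(model, stim) >= 0)

    def test_rejects_size_mismatch(self, rng):
        model = small_model(input_size=8)
        stim = StimulusEnsemble(rng.normal(size=(10, 12, 12)), 75.0, 0.1)
        with pytest.raises(ValueError, match="12"):
            forward_predict(model, stim)


class TestRestoration:
    @pytest.mark.parametrize("input_size, k, expected_map, expected_rest",
                             [(30, 15, 16, 30), (30, 11, 20, 30), (8, 3, 6, 8)])
    def test_dimension_identities(self, input_size, k, expected_map, expected_rest):
        model = small_model(input_size=input_size, k=k)
        assert model.map_grid_side == expected_map
        assert restoration(model).shape == (model.filter.n_lags, expected_rest, expected_rest)

    def test_delta_map_translates_filter(self):
        model = small_model(input_size=8, k=3, n_lags=2)
        model.map = GaussianMap(2.0, 3.0, np.eye(2) * 1e-6)
        rest = restoration(model)
        # map is a delta at (row 3, col 2): filter lands at that offset
        expected = np.zeros_like(rest)
        expected[:, 3 : 3 + 3, 2 : 2 + 3] = model.filter.weights
        assert np.allclose(rest, expected, atol=1e-8)


class TestCountParameters:
    @pytest.mark.parametrize("k, n_lags, expected", [(11, 7, 855), (15, 7, 1583), (1, 1, 9)])
    def test_published_counts(self, k, n_lags, expected):
        assert count_parameters(k, n_lags) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            count_parameters(0, 7)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        model = small_model(alpha=-0.3, bias=0.7)
        model.out_nl = OutputNonlinearity(1.4, 1.8, stage1_mode=False)
        model.crop_window = (10, 20, 120)
        model.meta = {"seed": 7}
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert np.allclose(loaded.filter.weights, model.filter.weights)
        assert loaded.prelu.alpha == model.prelu.alpha
        assert np.allclose(loaded.map.cov, model.map.cov)
        assert loaded.out_nl.gain == model.out_nl.gain
        assert loaded.out_nl.exponent == model.out_nl.exponent
        assert loaded.crop_window == model.crop_window
        assert loaded.bias == model.bias
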