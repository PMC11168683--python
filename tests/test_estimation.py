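"""Fitting machinery: cropping, initialization, gradients, training stages."""

import numpy as np
import pytest

from convrf.fitting import (
    TrainingConfig,
    _Adam,
    _EnsembleCache,
    _chunk_caches,
    _loss_and_grads,
    _make_caches,
    _theta_from_model,
    auto_crop_window,
    downsample_and_crop,
    fit_model,
    fit_stage1,
    fit_stage2,
    initialize_model,
)
from convrf.model import (
    ConvRFModel,
    GaussianMap,
    StimulusEnsemble,
    forward_predict,
    subunit_drive,
)
from convrf.evaluation import raw_vaf
from convrf.synth import Dataset, build_experiment
from conftest import gabor_neuron_spec, small_model, tiny_design


def quick_config(**overrides):
    defaults = dict(
        learning_rate=0.005,
        patience=40,
        max_epochs=250,
        filter_sizes=(7,),
        min_crop_px=16,
        input_size=16,
        n_lags=7,
        passes=1,
        seed=0,
        batch_frames=512,
        chunk_len=128,
    )
    defaults.update(overrides)
    return TrainingConfig(**defaults)


class TestDownsampleAndCrop:
    def test_constant_frame_is_mean_preserved(self):
        ens = StimulusEnsemble(np.full((3, 60, 60), 4.2), 75.0, 0.1)
        out = downsample_and_crop(ens, (0, 0, 60), 30)
        assert out.side == 30
        assert np.allclose(out.frames, 4.2)

    def test_deg_per_pixel_bookkeeping(self):
        ens = StimulusEnsemble(np.zeros((2, 480, 480)), 75.0, 0.1)
        out = downsample_and_crop(ens, (100, 100, 240), 30)
        assert out.deg_per_pixel == pytest.approx(0.1 * 240 / 30)

    def test_block_average_of_split_field(self):
        frame = np.zeros((1, 30, 30))
        frame[:, :, 15:] = 8.0
        out = downsample_and_crop(StimulusEnsemble(frame, 75.0, 0.1), (0, 0, 30), 30)
        assert np.allclose(out.frames[0, :, :15], 0.0)
        assert np.allclose(out.frames[0, :, 15:], 8.0)

    def test_window_outside_image_rejected(self):
        ens = StimulusEnsemble(np.zeros((2, 60, 60)), 75.0, 0.1)
        with pytest.raises(ValueError, match="outside"):
            downsample_and_crop(ens, (40, 40, 30), 30)


class TestInitializeModel:
    def test_deterministic_given_seed(self):
        cfg = quick_config()
        a = initialize_model(cfg, 7, seed=3)
        b = initialize_model(cfg, 7, seed=3)
        assert np.array_equal(a.filter.weights, b.filter.weights)

    def test_alpha_initialized_at_half(self):
        assert initialize_model(quick_config(), 7, 0).prelu.alpha == 0.5

    def test_taper_suppresses_corners(self):
        model = initialize_model(quick_config(), 11, 0)
        w = np.abs(model.filter.weights).mean(axis=0)
        center = w[5, 5]
        assert w[0, 0] <= 0.1 * max(center, 1e-12)

    def test_map_starts_centered_and_broad(self):
        cfg = quick_config(input_size=30, min_crop_px=30)
        model = initialize_model(cfg, 11, 0)
        assert model.map.mu_x == pytest.approx((model.map_grid_side - 1) / 2)
        assert model.map.cov[0, 0] == pytest.approx(30.0**2)


class TestGradients:
    def test_analytic_gradients_match_numerical(self, rng):
        """Backprop through conv, PReLU, Gaussian map and power law agrees
        with central finite differences on a small random problem."""
        cfg = TrainingConfig(input_size=10, n_lags=3, min_crop_px=10, filter_sizes=(5,))
        model = initialize_model(cfg, 5, 0)
        pairs = [(rng.normal(size=(25, 10, 10)), rng.normal(size=25) ** 2)]
        for stage2 in (False, True):
            caches = _make_caches(pairs, 3, dtype=np.float64)
            theta = _theta_from_model(model, stage2)
            theta["alpha"] = np.array(0.4)
            theta["bias"] = np.array(0.15)
            if stage2:
                theta["g_raw"] = np.array(0.8)
                theta["exp_raw"] = np.array(0.9)
            _, grads = _loss_and_grads(theta, caches, stage2, 0.01)
            eps = 1e-6
            for key, val in theta.items():
                arr = np.atleast_1d(np.asarray(val, float))
                for idx in [0, arr.size - 1]:
                    def perturbed(sign):
                        tp = {k: np.array(v, copy=True) for k, v in theta.items()}
                        flat = np.atleast_1d(np.asarray(tp[key], float))
                        flat.flat[idx] += sign * eps
                        tp[key] = flat.reshape(np.shape(val)) if np.ndim(val) else np.array(flat[0])
                        return _loss_and_grads(tp, caches, stage2, 0.01)[0]

                    numeric = (perturbed(+1) - perturbed(-1)) / (2 * eps)
                    analytic = np.atleast_1d(np.asarray(grads[key], float)).flat[idx]
                    assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), key

    def test_cached_drive_matches_reference(self, rng):
        """The FFT-cached subunit drive equals the direct scipy correlation."""
        frames = rng.normal(size=(40, 12, 12))
        weights = rng.normal(size=(4, 5, 5))
        cache = _EnsembleCache(frames, np.zeros(40), 4, dtype=np.float64)
        assert np.allclose(cache.drive(weights), subunit_drive(frames, weights), atol=1e-10)

    def test_chunked_caches_preserve_history(self, rng):
        """Chunked minibatch caches reproduce the full-ensemble drive exactly
        (each chunk carries its true stimulus history)."""
        frames = rng.normal(size=(50, 12, 12))
        weights = rng.normal(size=(4, 5, 5))
        full = subunit_drive(frames, weights)
        chunks = _chunk_caches([(frames, np.zeros(50))], 4, chunk_len=16, dtype=np.float64)
        stitched = np.concatenate([ch.drive(weights) for ch in chunks])
        assert np.allclose(stitched, full, atol=1e-10)


class TestFitStage1:
    def make_ln_dataset(self, n_frames=1500, seed=0):
        spec = gabor_neuron_spec(1.0, seed=seed, reliability=1.0, k=7, input_size=16)
        design = tiny_design(n_train=3, n_reg=1, n_test=1, frames=n_frames // 3, leadin=4)
        return spec, build_experiment(spec, design, seed=seed + 50)

    def test_recovers_noise_free_ln_neuron(self):
        """Stage 1 on a noise-free LN (alpha = 1) neuron predicts held-out
        responses with raw VAF above 80%."""
        spec, ds = self.make_ln_dataset()
        cfg = quick_config(max_epochs=400, patience=60)
        model, report = fit_model(ds, cfg)
        ens, resp = ds.split("test")[0]
        small = downsample_and_crop(ens, (0, 0, 32), 16)
        vaf = raw_vaf(forward_predict(model, small), resp.mean_rate())
        assert vaf > 80.0

    def test_constant_response_degenerates_to_bias(self):
        spec, ds = self.make_ln_dataset(n_frames=300)
        flat = Dataset(
            stimuli=ds.stimuli,
            responses={
                split: [type(r)(np.full_like(r.rates, 5.0), r.frame_rate_hz) for r in lst]
                for split, lst in ds.responses.items()
            },
            meta=ds.meta,
        )
        init = initialize_model(quick_config(), 7, 0)
        pairs = lambda split: [
            (downsample_and_crop(e, (0, 0, 32), 16).frames, r.mean_rate())
            for e, r in flat.split(split)
        ]
        cfg = quick_config(max_epochs=500, patience=500)
        fitted, _ = fit_stage1(init, pairs("train"), pairs("reg"), cfg)
        pred = forward_predict(
            fitted, downsample_and_crop(flat.stimuli["test"][0], (0, 0, 32), 16)
        )
        # predictions flatten toward the constant target as L2 drains the filter
        assert np.std(pred) < 0.2 * 5.0
        assert np.linalg.norm(fitted.filter.weights) < np.linalg.norm(init.filter.weights)

    def test_patience_bounds_training_length(self):
        spec, ds = self.make_ln_dataset(n_frames=300)
        init = initialize_model(quick_config(), 7, 0)
        pairs = lambda split: [
            (downsample_and_crop(e, (0, 0, 32), 16).frames, r.mean_rate())
            for e, r in ds.split(split)
        ]
        cfg = quick_config(max_epochs=500, patience=15)
        _, traces = fit_stage1(init, pairs("train"), pairs("reg"), cfg)
        best_epoch = int(np.argmin(traces["reg"]))
        assert len(traces["train"]) <= best_epoch + cfg.patience


class TestFitStage2:
    def test_exponent_recovery(self):
        """A generator with a squaring output nonlinearity: stage 2 recovers
        an exponent well away from the stage-1 value of 1."""
        spec = gabor_neuron_spec(1.0, seed=21, reliability=1.0, k=7, input_size=16, out_exp=2.0)
        design = tiny_design(n_train=4, n_reg=1, n_test=1, frames=1000, leadin=4)
        ds = build_experiment(spec, design, seed=77)
        cfg = quick_config(learning_rate=0.01, max_epochs=800, patience=200)
        model, _ = fit_model(ds, cfg)
        assert 1.5 <= model.out_nl.exponent <= 2.5

    def test_stage2_never_worse_than_its_best_epoch(self):
        spec = gabor_neuron_spec(1.0, seed=22, reliability=0.8, k=7, input_size=16)
        design = tiny_design(n_train=2, n_reg=1, n_test=1, frames=250, leadin=4)
        ds = build_experiment(spec, design, seed=78)
        pairs = lambda split: [
            (downsample_and_crop(e, (0, 0, 32), 16).frames, r.mean_rate())
            for e, r in ds.split(split)
        ]
        cfg = quick_config(max_epochs=120, patience=120)
        m1, _ = fit_stage1(initialize_model(cfg, 7, 0), pairs("train"), pairs("reg"), cfg)
        m2, traces = fit_stage2(m1, pairs("train"), pairs("reg"), cfg)
        # returned parameters are the best-on-regularization checkpoint
        final_reg = traces["reg"][-1]
        assert min(traces["reg"]) <= final_reg + 1e-9
        # and stage 2 does not degrade the stage-1 regularization loss by more
        # than a sliver (it starts at an exact reproduction of stage 1)
        assert min(traces["reg"]) <= traces["reg"][0] * 1.05


class TestAutoCropWindow:
    def make_fitted_model(self, mu, sigma, input_size=30, k=15, window=(0, 0, 480)):
        model = small_model(input_size=input_size, k=k)
        model.map = GaussianMap(mu[0], mu[1], np.eye(2) * sigma**2)
        model.crop_window = window
        return model

    def test_window_centers_on_map_mean(self):
        # map mean at map-grid (3, 13) -> downsampled (10, 20) -> original (168, 328)
        model = self.make_fitted_model((3.0, 13.0), sigma=1.0)
        cfg = TrainingConfig(min_crop_px=120, input_size=30)
        r0, c0, side = auto_crop_window(model, 1, cfg, 480)[:3]
        assert side == 120
        assert r0 <= 328 - 1 <= r0 + side  # row = mu_y-derived
        assert c0 <= 168 - 1 <= c0 + side

    def test_tiny_rf_floors_at_min_crop(self):
        model = self.make_fitted_model((7.5, 7.5), sigma=1e-3)
        cfg = TrainingConfig(min_crop_px=120, input_size=30)
        assert auto_crop_window(model, 1, cfg, 480)[2] == 120

    def test_huge_rf_clamps_to_image(self):
        model = self.make_fitted_model((7.5, 7.5), sigma=30.0)
        cfg = TrainingConfig(min_crop_px=120, input_size=30)
        window = auto_crop_window(model, 1, cfg, 480)
        assert window[:3] == (0, 0, 480)

    def test_mean_outside_window_falls_back_to_center(self):
        model = self.make_fitted_model((200.0, 200.0), sigma=1.0)
        cfg = TrainingConfig(min_crop_px=120, input_size=30)
        out = auto_crop_window(model, 1, cfg, 480)
        assert len(out) == 4 and out[3] == "center-fallback"


class TestFitModel:
    def test_deterministic_and_test_split_untouched(self):
        spec = gabor_neuron_spec(1.0, seed=30, reliability=0.9, k=7, input_size=16)
        design = tiny_design(n_train=2, n_reg=1, n_test=1, frames=200, leadin=4)
        ds = build_experiment(spec, design, seed=90)
        cfg = quick_config(max_epochs=60, patience=60)
        m1, _ = fit_model(ds, cfg)
        # identical rerun
        m2, _ = fit_model(build_experiment(spec, design, seed=90), cfg)
        assert np.array_equal(m1.filter.weights, m2.filter.weights)
        # removing the test split changes nothing
        no_test = Dataset(
            stimuli={k: v for k, v in ds.stimuli.items() if k != "test"},
            responses={k: v for k, v in ds.responses.items() if k != "test"},
            meta=ds.meta,
        )
        m3, _ = fit_model(no_test, cfg)
        assert np.array_equal(m1.filter.weights, m3.filter.weights)

    def test_l2_shrinks_filter_norm(self):
        spec = gabor_neuron_spec(1.0, seed=31, reliability=0.9, k=7, input_size=16)
        design = tiny_design(n_train=2, n_reg=1, n_test=1, frames=250, leadin=4)
        ds = build_experiment(spec, design, seed=91)
        norms = []
        for l2 in (0.01, 1.0):
            cfg = quick_config(max_epochs=120, patience=120, l2_filter=l2)
            model, _ = fit_model(ds, cfg)
            norms.append(np.linalg.norm(model.filter.weights))
        assert norms[1] < norms[0]

    def test_multipass_cropping_improves_prediction(self):
        """For a small RF inside a large image, the crop windows shrink
        across passes and held-out VAF does not get worse from pass 1 to the
        final pass."""
        from convrf.evaluation import evaluate_model

        spec = gabor_neuron_spec(
            1.0, seed=33, reliability=0.9, k=7, input_size=16
        )
        spec.crop_window = (16, 16, 32)  # true RF occupies ~1/4 of the image
        design = tiny_design(n_train=4, n_reg=1, n_test=1, frames=300, leadin=4)
        ds = build_experiment(spec, design, seed=93, side=64)
        cfg = quick_config(max_epochs=400, patience=60, passes=3)
        model, report = fit_model(ds, cfg)
        sides = [w[2] for w in report.crop_windows]
        assert sides[0] == 64
        assert sides == sorted(sides, reverse=True)
        if len(report.pass_models) > 1:
            first = evaluate_model(report.pass_models[0], ds, "test").raw_vaf
            final = evaluate_model(report.pass_models[-1], ds, "test").raw_vaf
            assert final >= first - 5.0

    def test_full_field_rf_stops_after_one_pass(self):
        """When the fitted map covers the whole (already minimal) image the
        window cannot shrink and the multi-pass loop terminates."""
        spec = gabor_neuron_spec(1.0, seed=32, reliability=0.9, k=7, input_size=16)
        design = tiny_design(n_train=2, n_reg=1, n_test=1, frames=200, leadin=4)
        ds = build_experiment(spec, design, seed=92)
        cfg = quick_config(max_epochs=50, patience=50, passes=3)
        _, report = fit_model(ds, cfg)
        assert len(report.crop_windows) == 1
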