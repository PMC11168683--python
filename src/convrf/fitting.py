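"""Gradient-descent estimation of the convolutional RF model.

All parameters are fitted jointly by full-batch Adam on the mean-square error
between the trial-averaged measured response and the model prediction, with an
L2 penalty on the filter weights only.  Training is in two stages: stage 1
holds the output nonlinearity at a plain half-wave rectifier; stage 2 reloads
the stage-1 weights and re-trains with the rectified power law (gain and
exponent trainable).  Early stopping monitors the regularization split with a
patience counter and restores the best epoch's parameters.

Unconstrained reparameterizations keep the covariance positive-definite
(log sigmas + tanh correlation) and gain/exponent positive (softplus); the
gradients are derived analytically and checked against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.fft as sfft

from .model import (
    ConvRFModel,
    GaussianMap,
    OutputNonlinearity,
    PReLUParam,
    SpatioTemporalFilter,
    StimulusEnsemble,
    map_weights,
)

Pairs = List[Tuple[np.ndarray, np.ndarray]]  # [(frames (T,S,S), mean response (T,))]


@dataclass
class TrainingConfig:
    """Hyperparameters of the fitting procedure.

    learning_rate/max_epochs govern the Adam loop; patience is the number of
    epochs the regularization loss may fail to improve before stopping;
    l2_filter penalizes the filter weights only.  filter_sizes lists the
    candidate spatial filter sizes compared on the regularization split;
    min_crop_px floors the automatic cropping window.
    """

    learning_rate: float = 1e-3
    patience: int = 50
    l2_filter: float = 0.01
    max_epochs: int = 2000
    seed: int = 0
    filter_sizes: Sequence[int] = (11, 15)
    min_crop_px: int = 120
    input_size: int = 30
    n_lags: int = 7
    passes: int = 3
    crop_sigma_factor: float = 6.0  # window side = factor * max sigma (i.e. +/- 3 sigma)
    clip_norm: float = 1.0  # stage-2 global gradient-norm clip
    init_filter_scale: Optional[float] = None  # default: He-style 1/sqrt(fan-in)
    batch_frames: Optional[int] = 512  # frames per Adam update; None = full batch
    chunk_len: int = 128  # frames per history-carrying stimulus chunk

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.l2_filter < 0:
            raise ValueError("l2_filter must be >= 0")
        if self.min_crop_px < self.input_size:
            raise ValueError("min_crop_px must be >= input_size")


@dataclass
class FitReport:
    """Bookkeeping from a fit: per-pass windows, loss traces, chosen size."""

    crop_windows: List[Tuple[int, int, int]] = field(default_factory=list)
    stage1_losses: List[List[float]] = field(default_factory=list)
    stage2_losses: List[List[float]] = field(default_factory=list)
    epochs_run: List[int] = field(default_factory=list)
    reg_vaf: float = np.nan
    chosen_filter_size: int = 0
    pass_models: List[ConvRFModel] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# cropping / downsampling


def downsample_and_crop(
    ensemble: StimulusEnsemble,
    window: Tuple[int, int, int],
    target_side: int,
) -> StimulusEnsemble:
    """Crop each frame to a square window, then block-average to target_side.

    window is (row0, col0, side) in the ensemble's pixel coordinates; side
    must be a multiple of target_side so the reduction is an exact block mean
    (mean-preserving on constant images).
    """
    r0, c0, side = window
    img = ensemble.side
    if r0 < 0 or c0 < 0 or r0 + side > img or c0 + side > img:
        raise ValueError(f"window {window} outside image bounds (side {img})")
    if side % target_side != 0:
        raise ValueError(
            f"window side {side} must be a multiple of target side {target_side}"
        )
    b = side // target_side
    sub = ensemble.frames[:, r0 : r0 + side, c0 : c0 + side]
    t = sub.shape[0]
    out = sub.reshape(t, target_side, b, target_side, b).mean(axis=(2, 4))
    return StimulusEnsemble(
        frames=out,
        frame_rate_hz=ensemble.frame_rate_hz,
        deg_per_pixel=ensemble.deg_per_pixel * b,
        ensemble_id=ensemble.ensemble_id,
    )


def auto_crop_window(
    model: ConvRFModel,
    pass_index: int,
    config: TrainingConfig,
    image_side: int,
) -> Tuple[int, int, int]:
    """Next-pass crop window centered on the fitted map mean.

    The fitted map mean (map-grid coordinates) is mapped back through the
    current crop/downsample geometry into original-image pixels; the window
    side is config.crop_sigma_factor times the largest map sigma (also mapped
    back), floored at min_crop_px, snapped to a multiple of input_size, and
    clamped inside the image.
    """
    win = model.crop_window or (0, 0, image_side)
    r0, c0, side = win
    scale = side / model.input_size  # original px per downsampled px
    half_k = (model.filter.k - 1) / 2.0
    # subunit at map-grid (x, y) is centered at downsampled pixel (x + half_k)
    ds_col = model.map.mu_x + half_k
    ds_row = model.map.mu_y + half_k
    center_col = c0 + (ds_col + 0.5) * scale
    center_row = r0 + (ds_row + 0.5) * scale
    flagged = False
    if not (r0 <= center_row < r0 + side and c0 <= center_col < c0 + side):
        center_row = r0 + side / 2.0
        center_col = c0 + side / 2.0
        flagged = True
    max_sigma = float(np.sqrt(np.max(np.linalg.eigvalsh(model.map.cov)))) * scale
    new_side = max(config.min_crop_px, config.crop_sigma_factor * max_sigma)
    new_side = int(np.ceil(new_side / config.input_size)) * config.input_size
    new_side = min(new_side, (image_side // config.input_size) * config.input_size)
    nr0 = int(round(center_row - new_side / 2.0))
    nc0 = int(round(center_col - new_side / 2.0))
    nr0 = int(np.clip(nr0, 0, image_side - new_side))
    nc0 = int(np.clip(nc0, 0, image_side - new_side))
    window = (nr0, nc0, new_side)
    if flagged:
        return window + ("center-fallback",)  # type: ignore[return-value]
    return window


# --------------------------------------------------------------------------
# parameter vector <-> model


def _softplus(x: float) -> float:
    return float(np.log1p(np.exp(-abs(x))) + max(x, 0.0))


def _softplus_inv(y: float) -> float:
    if y <= 0:
        raise ValueError("softplus inverse requires positive input")
    return float(np.log(np.expm1(y)))


def _theta_from_model(model: ConvRFModel, stage2: bool) -> Dict[str, np.ndarray]:
    cov = model.map.cov
    s1 = np.sqrt(cov[0, 0])
    s2 = np.sqrt(cov[1, 1])
    rho = np.clip(cov[0, 1] / (s1 * s2), -0.999, 0.999)
    theta = {
        "c": model.filter.weights.copy(),
        "alpha": np.array(model.prelu.alpha, dtype=float),
        "mu": np.array([model.map.mu_x, model.map.mu_y], dtype=float),
        "log_s": np.log([s1, s2]),
        "rho_raw": np.array(np.arctanh(rho), dtype=float),
        "bias": np.array(model.bias, dtype=float),
    }
    if stage2:
        theta["g_raw"] = np.array(_softplus_inv(max(model.out_nl.gain, 1e-6)))
        theta["exp_raw"] = np.array(_softplus_inv(max(model.out_nl.exponent, 1e-6)))
    return theta


def _model_from_theta(
    theta: Dict[str, np.ndarray], template: ConvRFModel, stage2: bool
) -> ConvRFModel:
    s1, s2 = np.exp(theta["log_s"])
    rho = np.tanh(float(theta["rho_raw"]))
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    if stage2:
        nl = OutputNonlinearity(
            gain=_softplus(float(theta["g_raw"])),
            exponent=_softplus(float(theta["exp_raw"])),
            stage1_mode=False,
        )
    else:
        nl = OutputNonlinearity(stage1_mode=True)
    return ConvRFModel(
        filter=SpatioTemporalFilter(theta["c"].copy()),
        prelu=PReLUParam(float(theta["alpha"])),
        map=GaussianMap(float(theta["mu"][0]), float(theta["mu"][1]), cov),
        out_nl=nl,
        bias=float(theta["bias"]),
        input_size=template.input_size,
        crop_window=template.crop_window,
        meta=dict(template.meta),
    )


def _map_image_and_grads(theta: Dict[str, np.ndarray], m: int):
    """Map-weight image and its partials w.r.t. the 5 unconstrained map params."""
    mu_x, mu_y = theta["mu"]
    s1, s2 = np.exp(theta["log_s"])
    rho = np.tanh(float(theta["rho_raw"]))
    det = (s1 * s2) ** 2 * (1 - rho**2)
    p00 = s2**2 / det
    p11 = s1**2 / det
    p01 = -rho * s1 * s2 / det
    yy, xx = np.mgrid[0:m, 0:m]
    dx = xx - mu_x
    dy = yy - mu_y
    q = p00 * dx**2 + 2 * p01 * dx * dy + p11 * dy**2
    w = np.exp(-0.5 * q)
    e0 = p00 * dx + p01 * dy
    e1 = p01 * dx + p11 * dy
    grads = {
        "mu_x": w * e0,
        "mu_y": w * e1,
        "log_s1": w * (s1**2 * e0**2 + rho * s1 * s2 * e0 * e1),
        "log_s2": w * (s2**2 * e1**2 + rho * s1 * s2 * e0 * e1),
        "rho_raw": w * (1 - rho**2) * s1 * s2 * e0 * e1,
    }
    return w, grads


class _EnsembleCache:
    """Precomputed spatial FFT of one (zero-history-padded) stimulus ensemble.

    The stimulus never changes across epochs, so its rfft2 is computed once;
    each epoch then costs one inverse transform for the subunit drive and one
    forward transform of the upstream gradient for the filter gradient.
    Valid-region slicing avoids circular wrap because the kernel never
    exceeds the image side.
    """

    def __init__(
        self,
        frames: np.ndarray,
        y: np.ndarray,
        n_lags: int,
        dtype=np.float32,
        history: Optional[np.ndarray] = None,
    ):
        t, s, _ = frames.shape
        self.T, self.S, self.n_lags = t, s, n_lags
        if n_lags > 1:
            lead = history if history is not None else np.zeros((n_lags - 1, s, s))
            pad = np.concatenate([lead, frames])
        else:
            pad = frames
        self.SF = sfft.rfft2(pad.astype(dtype))
        self.y = np.asarray(y, dtype=np.float64)
        self.dtype = dtype


    def drive(self, c: np.ndarray) -> np.ndarray:
        """Subunit drive u (T, m, m): valid spatiotemporal correlation."""
        n_lags, k, _ = c.shape
        s, t = self.S, self.T
        kf = sfft.rfft2(c[:, ::-1, ::-1].astype(self.dtype), s=(s, s))
        uf = np.zeros((t, s, s // 2 + 1), dtype=np.complex64 if self.dtype == np.float32 else complex)
        for tau in range(n_lags):
            uf += self.SF[n_lags - 1 - tau : n_lags - 1 - tau + t] * kf[tau]
        return sfft.irfft2(uf, s=(s, s))[:, k - 1 :, k - 1 :]

    def filter_grad(self, gu: np.ndarray, k: int) -> np.ndarray:
        """d(loss)/d(filter) given the upstream drive gradient gu (T, m, m)."""
        s, t, n_lags = self.S, self.T, self.n_lags
        m = s - k + 1
        gf = sfft.rfft2(gu[:, ::-1, ::-1].astype(self.dtype), s=(s, s))
        df = np.zeros((n_lags, s, s // 2 + 1), dtype=np.complex64 if self.dtype == np.float32 else complex)
        for tau in range(n_lags):
            df[tau] = np.einsum(
                "tij,tij->ij", self.SF[n_lags - 1 - tau : n_lags - 1 - tau + t], gf
            )
        return sfft.irfft2(df, s=(s, s))[:, m - 1 :, m - 1 :].astype(np.float64)


def _make_caches(pairs: Pairs, n_lags: int, dtype=np.float32) -> List[_EnsembleCache]:
    return [_EnsembleCache(frames, y, n_lags, dtype) for frames, y in pairs]


def _chunk_caches(
    pairs: Pairs, n_lags: int, chunk_len: int, dtype=np.float32
) -> List[_EnsembleCache]:
    """Chunked caches for minibatch updates.

    Each chunk carries the exact n_lags - 1 frames of preceding stimulus
    history (zeros at an ensemble start), so chunked training optimizes the
    same loss as full-batch training, just in smaller pieces.
    """
    out: List[_EnsembleCache] = []
    for frames, y in pairs:
        t, s, _ = frames.shape
        y = np.asarray(y, float)
        for start in range(0, t, chunk_len):
            stop = min(start + chunk_len, t)
            if n_lags > 1:
                if start >= n_lags - 1:
                    hist = frames[start - (n_lags - 1) : start]
                else:
                    hist = np.concatenate(
                        [np.zeros((n_lags - 1 - start, s, s)), frames[:start]]
                    )
            else:
                hist = None
            out.append(
                _EnsembleCache(frames[start:stop], y[start:stop], n_lags, dtype, history=hist)
            )
    return out


def _loss_and_grads(
    theta: Dict[str, np.ndarray],
    caches: List[_EnsembleCache],
    stage2: bool,
    l2_filter: float,
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Full-batch MSE loss (plus filter L2) and analytic gradients."""
    c = np.asarray(theta["c"], dtype=np.float64)
    alpha = float(theta["alpha"])
    bias = float(theta["bias"])
    n_lags, k, _ = c.shape
    m = caches[0].S - k + 1
    w, wgrads = _map_image_and_grads(theta, m)
    if stage2:
        g = _softplus(float(theta["g_raw"]))
        expo = _softplus(float(theta["exp_raw"]))
        sig_g = 1.0 / (1.0 + np.exp(-float(theta["g_raw"])))
        sig_e = 1.0 / (1.0 + np.exp(-float(theta["exp_raw"])))

    n_total = sum(cache.y.size for cache in caches)
    loss = 0.0
    grads = {key: np.zeros_like(np.asarray(val, dtype=float)) for key, val in theta.items()}
    dw_total = np.zeros_like(w)

    for cache in caches:
        u = cache.drive(c)
        a = np.where(u > 0, u, alpha * u)
        z = np.tensordot(a, w, axes=([1, 2], [0, 1])) + bias
        if stage2:
            zp = np.maximum(z, 0.0)
            pow_z = np.where(zp > 0, np.power(np.maximum(zp, 1e-300), expo), 0.0)
            r = g * pow_z
        else:
            r = np.maximum(z, 0.0)
        resid = r - cache.y
        loss += float(np.sum(resid**2, dtype=np.float64))
        gr = 2.0 * resid / n_total
        if stage2:
            dr_dz = np.where(z > 0, g * expo * np.power(np.maximum(zp, 1e-12), expo - 1.0), 0.0)
            gz = gr * dr_dz
            grads["g_raw"] += np.sum(gr * pow_z) * sig_g
            safe_log = np.where(zp > 1e-12, np.log(np.maximum(zp, 1e-12)), 0.0)
            grads["exp_raw"] += np.sum(gr * g * pow_z * safe_log) * sig_e
        else:
            gz = gr * (z > 0)
        grads["bias"] += np.sum(gz)
        dw_total += np.tensordot(gz, a, axes=(0, 0))
        ga = gz[:, None, None] * w[None, :, :]
        gu = ga * np.where(u > 0, 1.0, alpha)
        grads["alpha"] += np.sum(ga * np.where(u <= 0, u, 0.0))
        grads["c"] += cache.filter_grad(gu, k)

    loss = loss / n_total + l2_filter * float(np.sum(c**2))
    grads["c"] += 2.0 * l2_filter * c
    grads["mu"] = np.array(
        [np.sum(dw_total * wgrads["mu_x"]), np.sum(dw_total * wgrads["mu_y"])]
    )
    grads["log_s"] = np.array(
        [np.sum(dw_total * wgrads["log_s1"]), np.sum(dw_total * wgrads["log_s2"])]
    )
    grads["rho_raw"] = np.array(np.sum(dw_total * wgrads["rho_raw"]))
    return loss, grads


def _predict_cached(theta: Dict[str, np.ndarray], cache: _EnsembleCache, stage2: bool) -> np.ndarray:
    c = np.asarray(theta["c"], dtype=np.float64)
    m = cache.S - c.shape[1] + 1
    w, _ = _map_image_and_grads(theta, m)
    u = cache.drive(c)
    a = np.where(u > 0, u, float(theta["alpha"]) * u)
    z = np.tensordot(a, w, axes=([1, 2], [0, 1])) + float(theta["bias"])
    if stage2:
        g = _softplus(float(theta["g_raw"]))
        expo = _softplus(float(theta["exp_raw"]))
        return np.where(z > 0, g * np.power(np.maximum(z, 0.0), expo), 0.0)
    return np.maximum(z, 0.0)


def _reg_loss(theta: Dict[str, np.ndarray], caches: List[_EnsembleCache], stage2: bool) -> float:
    sse, n = 0.0, 0
    for cache in caches:
        r = _predict_cached(theta, cache, stage2)
        sse += float(np.sum((r - cache.y) ** 2, dtype=np.float64))
        n += cache.y.size
    return sse / n


class _Adam:
    """Plain Adam on a dict of arrays."""

    def __init__(self, theta: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(np.asarray(v, float)) for k, v in theta.items()}
        self.v = {k: np.zeros_like(np.asarray(v, float)) for k, v in theta.items()}
        self.t = 0

    def step(self, theta: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for key in theta:
            gkey = grads[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * gkey
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * gkey**2
            theta[key] = theta[key] - self.lr * (self.m[key] / bc1) / (
                np.sqrt(self.v[key] / bc2) + self.eps
            )


def _clip_global_norm(grads: Dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(np.asarray(grad) ** 2)) for grad in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for key in grads:
            grads[key] = grads[key] * scale


def _train(
    theta: Dict[str, np.ndarray],
    train_pairs: Pairs,
    reg_pairs: Pairs,
    config: TrainingConfig,
    stage2: bool,
) -> Tuple[Dict[str, np.ndarray], Dict[str, List[float]]]:
    """Adam loop with minibatch updates and reg-split early stopping.

    Minibatches are chunks of stimulus frames carrying exact convolution
    history, so the optimized objective matches full-batch training.  The
    epoch's regularization loss drives patience-based early stopping and the
    best-epoch parameters are restored on exit.
    """
    n_lags = theta["c"].shape[0]
    if config.batch_frames:
        chunks = _chunk_caches(train_pairs, n_lags, config.chunk_len)
        per_batch = max(1, int(round(config.batch_frames / config.chunk_len)))
    else:
        chunks = _make_caches(train_pairs, n_lags)
        per_batch = len(chunks)
    reg_caches = _make_caches(reg_pairs, n_lags)
    rng = np.random.default_rng(config.seed * 2 + (1 if stage2 else 0))
    opt = _Adam(theta, config.learning_rate)
    best = {k: np.array(v, copy=True) for k, v in theta.items()}
    best_loss = _reg_loss(theta, reg_caches, stage2)
    best_epoch = 0
    traces: Dict[str, List[float]] = {"train": [], "reg": [best_loss]}
    aborted = False
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(chunks)) if config.batch_frames else np.arange(len(chunks))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), per_batch):
            batch = [chunks[i] for i in order[start : start + per_batch]]
            loss, grads = _loss_and_grads(theta, batch, stage2, config.l2_filter)
            if not np.isfinite(loss):
                warnings.warn(
                    f"non-finite training loss at epoch {epoch}; "
                    "returning best parameters so far"
                )
                aborted = True
                break
            if stage2:
                _clip_global_norm(grads, config.clip_norm)
            opt.step(theta, grads)
            epoch_loss += loss
            n_batches += 1
        if aborted:
            break
        rl = _reg_loss(theta, reg_caches, stage2)
        traces["train"].append(epoch_loss / max(n_batches, 1))
        traces["reg"].append(rl)
        if rl < best_loss:
            best_loss = rl
            best = {k: np.array(v, copy=True) for k, v in theta.items()}
            best_epoch = epoch
        if epoch - best_epoch >= config.patience:
            break
    return best, traces


# --------------------------------------------------------------------------
# public fitting API


def initialize_model(config: TrainingConfig, k: int, seed: int) -> ConvRFModel:
    """Fresh model: tapered random filter, alpha = 0.5, centered broad map.

    The filter is He-style random noise multiplied by a radial raised-cosine
    taper that weights the center and vanishes at the corners; the map starts
    at the grid center with isotropic sigma equal to the input side, so early
    epochs see the whole image.
    """
    rng = np.random.default_rng(seed)
    n_lags = config.n_lags
    scale = config.init_filter_scale
    if scale is None:
        scale = np.sqrt(2.0 / (k * k * n_lags))
    weights = rng.normal(0.0, scale, size=(n_lags, k, k))
    center = (k - 1) / 2.0
    yy, xx = np.mgrid[0:k, 0:k]
    r = np.sqrt((xx - center) ** 2 + (yy - center) ** 2) / max(k / 2.0, 1.0)
    taper = 0.5 * (1 + np.cos(np.pi * np.minimum(r, 1.0)))
    weights *= taper[None, :, :]
    m = config.input_size - k + 1
    sigma = float(config.input_size)
    gmap = GaussianMap((m - 1) / 2.0, (m - 1) / 2.0, np.eye(2) * sigma**2)
    return ConvRFModel(
        filter=SpatioTemporalFilter(weights),
        prelu=PReLUParam(0.5),
        map=gmap,
        out_nl=OutputNonlinearity(stage1_mode=True),
        bias=0.0,
        input_size=config.input_size,
        meta={"seed": seed},
    )


def fit_stage1(
    model: ConvRFModel,
    train_pairs: Pairs,
    reg_pairs: Pairs,
    config: TrainingConfig,
) -> Tuple[ConvRFModel, Dict[str, List[float]]]:
    """Stage-1 fit: output nonlinearity fixed to a half-wave rectifier."""
    theta = _theta_from_model(model, stage2=False)
    best, traces = _train(theta, train_pairs, reg_pairs, config, stage2=False)
    return _model_from_theta(best, model, stage2=False), traces


def fit_stage2(
    model: ConvRFModel,
    train_pairs: Pairs,
    reg_pairs: Pairs,
    config: TrainingConfig,
) -> Tuple[ConvRFModel, Dict[str, List[float]]]:
    """Stage-2 fit: rectified power law with trainable gain and exponent.

    Starts from the stage-1 weights with gain = exponent = 1 (so the initial
    stage-2 model reproduces the stage-1 predictions exactly on positive
    drive); gradients are clipped at a global norm to tame the power law.
    """
    theta = _theta_from_model(model, stage2=True)
    theta["g_raw"] = np.array(_softplus_inv(1.0))
    theta["exp_raw"] = np.array(_softplus_inv(1.0))
    best, traces = _train(theta, train_pairs, reg_pairs, config, stage2=True)
    return _model_from_theta(best, model, stage2=True), traces


def _mean_pairs(split) -> Pairs:
    """(ensemble, responses) list -> (frames, repetition-averaged response)."""
    return [(ens.frames, resp.mean_rate()) for ens, resp in split]


def fit_model(dataset, config: TrainingConfig):
    """Full estimation: multi-pass crop/downsample, two training stages,
    filter-size selection on the regularization split.

    dataset must expose .split(name) -> list of (StimulusEnsemble,
    TrialResponses) for names 'train' and 'reg'; the test split is never
    read here.  Returns (ConvRFModel, FitReport).
    """
    from .evaluation import raw_vaf

    train = dataset.split("train")
    reg = dataset.split("reg")
    if not train or not reg:
        raise ValueError("dataset must have non-empty train and reg splits")
    image_side = train[0][0].side
    n_units = (image_side // config.input_size) * config.input_size
    window = (
        (image_side - n_units) // 2,
        (image_side - n_units) // 2,
        n_units,
    )
    report = FitReport()
    seed = config.seed
    model = None
    k0 = config.filter_sizes[0]

    def _pairs_for(window):
        tr = [
            (downsample_and_crop(ens, window, config.input_size).frames, resp.mean_rate())
            for ens, resp in train
        ]
        rg = [
            (downsample_and_crop(ens, window, config.input_size).frames, resp.mean_rate())
            for ens, resp in reg
        ]
        return tr, rg

    n_passes = max(1, config.passes)
    for pass_index in range(1, n_passes + 1):
        report.crop_windows.append(window)
        tr_pairs, rg_pairs = _pairs_for(window)
        final = pass_index == n_passes
        if final:
            candidates = list(config.filter_sizes)
        else:
            candidates = [k0]
        best_model, best_vaf, best_tr = None, -np.inf, None
        for k in candidates:
            init = initialize_model(config, k, seed + pass_index)
            init = replace(init, crop_window=window)
            m1, tr1 = fit_stage1(init, tr_pairs, rg_pairs, config)
            m2, tr2 = fit_stage2(m1, tr_pairs, rg_pairs, config)
            theta2 = _theta_from_model(m2, stage2=True)
            rg_caches = _make_caches(rg_pairs, config.n_lags)
            pred = np.concatenate(
                [_predict_cached(theta2, cache, True) for cache in rg_caches]
            )
            meas = np.concatenate([cache.y for cache in rg_caches])
            vaf = raw_vaf(pred, meas) if np.std(pred) > 0 and np.std(meas) > 0 else 0.0
            if vaf > best_vaf:
                best_model, best_vaf, best_tr = m2, vaf, (tr1, tr2, k)
        model = best_model
        tr1, tr2, chosen_k = best_tr
        report.stage1_losses.append(tr1["train"])
        report.stage2_losses.append(tr2["train"])
        report.epochs_run.append(len(tr1["train"]) + len(tr2["train"]))
        report.pass_models.append(model)
        report.reg_vaf = best_vaf
        report.chosen_filter_size = chosen_k
        if final:
            break
        nxt = auto_crop_window(model, pass_index, config, image_side)
        if len(nxt) == 4:
            report.flags.append(f"pass {pass_index}: {nxt[3]}")
            nxt = nxt[:3]
        if nxt[2] >= window[2]:
            # window stopped shrinking: current fit already covers the RF
            break
        window = nxt
    return model, report

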