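"""Core model: parameter containers and the deterministic forward computation.

The model predicts a neuron's firing rate from a grayscale stimulus clip in
four stages:

1. a spatiotemporal filter ``c`` (n_lags x k x k) is swept over the stimulus
   (valid cross-correlation in space, causal in time), producing for each
   frame a "subunit drive" image on the map grid;
2. each subunit drive passes through a parameterized rectified linear unit
   (PReLU) with negative-branch slope ``alpha`` -- ``alpha = 1`` makes the
   cascade linear (simple-cell / LN regime), ``alpha <= 0`` gives rectified
   subunits (complex-cell regime);
3. the rectified drives are weighted by a 2-D Gaussian "map" (the receptive
   field envelope) and summed, plus a scalar bias;
4. a final output nonlinearity: a plain half-wave rectifier during stage-1
   training, or a rectified power law ``g * x**exp`` in the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal


# --------------------------------------------------------------------------
# containers


@dataclass
class StimulusEnsemble:
    """A sequence of square grayscale frames in mean-subtracted units.

    frames has shape (time, height, width) with height == width.
    """

    frames: np.ndarray
    frame_rate_hz: float
    deg_per_pixel: float
    ensemble_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, height, width); got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if h != w:
            raise ValueError(f"frames must be square; got height {h} != width {w}")
        if not np.all(np.isfinite(self.frames)):
            bad = np.argwhere(~np.isfinite(self.frames))[0]
            raise ValueError(f"non-finite stimulus value at index {tuple(bad)}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def side(self) -> int:
        return self.frames.shape[1]


@dataclass
class TrialResponses:
    """Per-trial firing rates (trials x time bins) aligned to one ensemble."""

    rates: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def mean_rate(self) -> np.ndarray:
        """Across-trial average response, one value per time bin."""
        return self.rates.mean(axis=0)


@dataclass
class SpatioTemporalFilter:
    """Subunit filter weights, shape (n_lags, k, k).

    Lag 0 is the current frame; lags increase into the past.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError(f"filter must be 3-D; got shape {self.weights.shape}")
        if self.weights.shape[1] != self.weights.shape[2]:
            raise ValueError(
                f"filter must be spatially square; got {self.weights.shape[1:]}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights contain non-finite values")

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def k(self) -> int:
        return self.weights.shape[1]


@dataclass
class PReLUParam:
    """Slope of the PReLU's negative branch.

    Fitted values are reported raw; the model does not clamp alpha to
    [-1, 1] even though fitted populations typically fall in that range.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


@dataclass
class GaussianMap:
    """2-D Gaussian receptive-field envelope on the map grid.

    Evaluated as the unnormalized exponential ``beta * exp(-q/2)`` with
    ``q`` the Mahalanobis form; ``beta`` is fixed at 1 so the five free
    parameters are the two means and the three covariance values -- overall
    scale is absorbed by the filter and output gain.
    """

    mu_x: float
    mu_y: float
    cov: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValueError(f"cov must be 2x2; got {self.cov.shape}")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        # positive-definiteness
        evals = np.linalg.eigvalsh(self.cov)
        if np.any(evals <= 0):
            raise ValueError(f"cov must be positive-definite; eigenvalues {evals}")


@dataclass
class OutputNonlinearity:
    """Final rectifying nonlinearity.

    In ``stage1_mode`` it is a plain half-wave rectifier (the form used during
    the first training stage); otherwise ``g * x**exp`` for positive x, zero
    for negative x.
    """

    gain: float = 1.0
    exponent: float = 1.0
    stage1_mode: bool = True

    def __post_init__(self) -> None:
        if not self.stage1_mode:
            if not (np.isfinite(self.gain) and self.gain > 0):
                raise ValueError(f"gain must be finite and positive; got {self.gain}")
            if not (np.isfinite(self.exponent) and self.exponent > 0):
                raise ValueError(
                    f"exponent must be finite and positive; got {self.exponent}"
                )


@dataclass
class ConvRFModel:
    """Full estimable model: filter, PReLU, Gaussian map, output nonlinearity."""

    filter: SpatioTemporalFilter
    prelu: PReLUParam
    map: GaussianMap
    out_nl: OutputNonlinearity
    bias: float = 0.0
    input_size: int = 30
    crop_window: Optional[Tuple[int, int, int]] = None  # (row0, col0, side) in original image
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.filter.k > self.input_size:
            raise ValueError(
                f"filter size {self.filter.k} exceeds input size {self.input_size}"
            )

    @property
    def map_grid_side(self) -> int:
        """Side of the map grid produced by valid convolution: input - k + 1."""
        return self.input_size - self.filter.k + 1

    def map_image(self) -> np.ndarray:
        return map_weights(self.map, self.map_grid_side)


# --------------------------------------------------------------------------
# operations


def prelu_apply(x, alpha: float):
    """Parameterized rectifier: x for x > 0, alpha * x otherwise.

    Continuous at 0; alpha = 0 is a half-wave rectifier, alpha = 1 the
    identity, alpha = -1 full-wave rectification up to sign.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(x)))[0]
        raise ValueError(f"non-finite input to prelu_apply at index {tuple(bad)}")
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    out = np.where(x > 0, x, alpha * x)
    return out if out.ndim else float(out)


def map_weights(gmap: GaussianMap, grid_side: int) -> np.ndarray:
    """Evaluate the Gaussian map at integer pixel centers of the grid.

    Returns a (grid_side, grid_side) image; rows index y, columns index x.
    The maximum equals beta when the mean lies on a pixel center.
    """
    if grid_side < 1:
        raise ValueError("grid_side must be >= 1")
    cov = np.asarray(gmap.cov, dtype=float)
    det = np.linalg.det(cov)
    if det <= 0 or np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("covariance must be positive-definite")
    prec = np.linalg.inv(cov)
    yy, xx = np.mgrid[0:grid_side, 0:grid_side]
    dx = xx - gmap.mu_x
    dy = yy - gmap.mu_y
    q = prec[0, 0] * dx**2 + 2 * prec[0, 1] * dx * dy + prec[1, 1] * dy**2
    return gmap.beta * np.exp(-0.5 * q)


def output_nonlinearity_apply(x, nl: OutputNonlinearity):
    """Apply the final rectifying nonlinearity elementwise."""
    x = np.asarray(x, dtype=float)
    if nl.stage1_mode:
        out = np.maximum(x, 0.0)
    else:
        if nl.exponent <= 0:
            raise ValueError(f"exponent must be positive; got {nl.exponent}")
        out = np.where(x > 0, nl.gain * np.power(np.maximum(x, 0.0), nl.exponent), 0.0)
    return out if out.ndim else float(out)


def subunit_drive(frames: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid spatiotemporal cross-correlation of the stimulus with the filter.

    Returns shape (T, m, m) with m = side - k + 1.  History for the first
    n_lags - 1 frames is zero-padded, so the output has one value per frame.
    """
    n_lags = weights.shape[0]
    t, s, _ = frames.shape
    if t < 1:
        raise ValueError("need at least one frame")
    pad = np.zeros((n_lags - 1, s, s), dtype=float)
    padded = np.concatenate([pad, frames]) if n_lags > 1 else frames
    # reverse the kernel in time so lag 0 multiplies the current frame
    return signal.correlate(padded, weights[::-1], mode="valid")


def forward_predict(model: ConvRFModel, stimulus: StimulusEnsemble) -> np.ndarray:
    """Predicted response series, one value per stimulus frame."""
    frames = stimulus.frames if isinstance(stimulus, StimulusEnsemble) else np.asarray(stimulus, float)
    if frames.shape[1] != model.input_size or frames.shape[2] != model.input_size:
        raise ValueError(
            f"stimulus spatial shape {frames.shape[1:]} does not match "
            f"model input size ({model.input_size}, {model.input_size})"
        )
    if frames.shape[0] < model.filter.n_lags:
        raise ValueError(
            f"need at least n_lags={model.filter.n_lags} frames; got {frames.shape[0]}"
        )
    u = subunit_drive(frames, model.filter.weights)
    a = np.where(u > 0, u, model.prelu.alpha * u)
    w = model.map_image()
    z = np.tensordot(a, w, axes=([1, 2], [0, 1])) + model.bias
    return output_nonlinearity_apply(z, model.out_nl)


def restoration(model: ConvRFModel) -> np.ndarray:
    """Linear restoration: per-lag full convolution of filter with map.

    Output shape (n_lags, input_size, input_size); for alpha = 1 this volume
    acts as the single equivalent linear filter of the collapsed LN cascade
    (the prediction is its framewise dot product with the stimulus history).
    """
    w = model.map_image()
    out = np.stack(
        [signal.fftconvolve(sl, w, mode="full") for sl in model.filter.weights]
    )
    assert out.shape[1] == model.input_size
    return out


def linear_predict(rest: np.ndarray, frames: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Dot product of a restoration volume with the stimulus history at each frame.

    Oracle path for the alpha = 1 collapse: equals the model's pre-rectifier
    output when the PReLU is the identity.
    """
    n_lags = rest.shape[0]
    t, s, _ = frames.shape
    pad = np.zeros((n_lags - 1, s, s))
    padded = np.concatenate([pad, frames]) if n_lags > 1 else frames
    out = np.empty(t)
    for i in range(t):
        hist = padded[i : i + n_lags][::-1]  # hist[tau] = frame at t - tau
        out[i] = np.sum(hist * rest)
    return out + bias


def count_parameters(k: int, n_lags: int) -> int:
    """Trainable parameter count: filter + 1 PReLU + 5 map + 2 output."""
    if k < 1 or n_lags < 1:
        raise ValueError(f"k and n_lags must be >= 1; got k={k}, n_lags={n_lags}")
    return k * k * n_lags + 1 + 5 + 2


# --------------------------------------------------------------------------
# serialization


def save_model(model: ConvRFModel, path) -> None:
    """Write the model to a single NPZ container."""
    np.savez(
        path,
        schema=np.array("convrf-model-1"),
        filter=model.filter.weights,
        alpha=np.array(model.prelu.alpha),
        mu=np.array([model.map.mu_x, model.map.mu_y]),
        cov=model.map.cov,
        beta=np.array(model.map.beta),
        gain=np.array(model.out_nl.gain),
        exponent=np.array(model.out_nl.exponent),
        stage1_mode=np.array(model.out_nl.stage1_mode),
        bias=np.array(model.bias),
        input_size=np.array(model.input_size),
        crop_window=np.array(model.crop_window if model.crop_window is not None else [-1, -1, -1]),
        meta_keys=np.array(sorted(model.meta.keys()), dtype=object) if model.meta else np.array([], dtype=object),
        meta_vals=np.array([model.meta[k] for k in sorted(model.meta.keys())], dtype=object) if model.meta else np.array([], dtype=object),
    )


def load_model(path) -> ConvRFModel:
    with np.load(path, allow_pickle=True) as f:
        if str(f["schema"]) != "convrf-model-1":
            raise ValueError(f"unknown model schema {f['schema']!r}")
        crop = f["crop_window"]
        crop_window = None if crop[0] < 0 else tuple(int(v) for v in crop)
        meta = {str(k): v for k, v in zip(f["meta_keys"], f["meta_vals"])}
        return ConvRFModel(
            filter=SpatioTemporalFilter(f["filter"]),
            prelu=PReLUParam(float(f["alpha"])),
            map=GaussianMap(float(f["mu"][0]), float(f["mu"][1]), f["cov"], float(f["beta"])),
            out_nl=OutputNonlinearity(
                float(f["gain"]), float(f["exponent"]), bool(f["stage1_mode"])
            ),
            bias=float(f["bias"]),
            input_size=int(f["input_size"]),
            crop_window=crop_window,
            meta=meta,
        )
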