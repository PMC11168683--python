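"""Synthetic experiments: natural-like stimuli and ground-truth model neurons.

The generator reproduces the study design the estimator expects: ensembles of
375 frames at 75 Hz, 20 training ensembles presented 5 times, 5 regularization
and 5 test ensembles presented 20 times each, preceded by a short blank
lead-in.  Natural images are emulated by 1/f-amplitude random-phase noise --
the broadband, spatially correlated statistic the estimator relies on --
mean-subtracted, RMS-equalized per frame and quantized to 256 levels the way
8-bit display stimuli are.

Ground-truth neurons are instances of the model itself: a spatial Gabor times
a damped-sine temporal kernel as the subunit filter, a chosen PReLU slope
(alpha_true = 1 simple/LN, alpha_true <= 0 complex-like), a Gaussian map and
a rectified power-law output.  Trial noise is parameterized by an operational
reliability r in (0, 1]: the expected single-trial noise ceiling R^2_neuron,
which makes synthetic noise levels directly comparable to recorded ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .characterize import damped_sine, gabor2d
from .model import (
    ConvRFModel,
    GaussianMap,
    OutputNonlinearity,
    PReLUParam,
    SpatioTemporalFilter,
    StimulusEnsemble,
    TrialResponses,
    forward_predict,
)
from .fitting import downsample_and_crop


@dataclass
class ExperimentDesign:
    """Counts and rates of the stimulus protocol."""

    n_train_ensembles: int = 20
    n_reg_ensembles: int = 5
    n_test_ensembles: int = 5
    frames_per_ensemble: int = 375
    repeats_train: int = 5
    repeats_reg: int = 20
    repeats_test: int = 20
    frame_rate_hz: float = 75.0
    blank_leadin_frames: int = 8  # ~100 ms of mean-luminance blank at 75 Hz

    def __post_init__(self) -> None:
        counts = (
            self.n_train_ensembles,
            self.n_reg_ensembles,
            self.n_test_ensembles,
            self.frames_per_ensemble,
            self.repeats_train,
            self.repeats_reg,
            self.repeats_test,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")

    def unique_frames(self, split: str) -> int:
        n = {
            "train": self.n_train_ensembles,
            "reg": self.n_reg_ensembles,
            "test": self.n_test_ensembles,
        }[split]
        return n * self.frames_per_ensemble

    def repeats(self, split: str) -> int:
        return {
            "train": self.repeats_train,
            "reg": self.repeats_reg,
            "test": self.repeats_test,
        }[split]


@dataclass
class SyntheticNeuronSpec:
    """Ground-truth generator parameters for one model neuron.

    gabor holds the spatial subunit parameters (keys of characterize.gabor2d,
    in pixel units via deg_per_pixel = 1 on the filter grid unless stated);
    temporal_kernel gives the n_lags damped-sine samples (lag 0 first).
    """

    gabor: Dict[str, float]
    temporal_kernel: np.ndarray
    alpha_true: float
    map: GaussianMap
    out_gain: float = 1.0
    out_exp: float = 1.0
    noise_model: str = "gaussian"  # or "poisson"
    reliability: float = 0.5
    seed: int = 0
    k: int = 11
    input_size: int = 30
    deg_per_pixel: float = 1.0
    crop_window: Optional[Tuple[int, int, int]] = None
    target_mean_rate: float = 10.0  # spikes/s

    def __post_init__(self) -> None:
        self.temporal_kernel = np.asarray(self.temporal_kernel, float)
        if not (0 < self.reliability <= 1):
            raise ValueError("reliability must be in (0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class Dataset:
    """Stimuli and responses per split, plus experiment metadata."""

    stimuli: Dict[str, List[StimulusEnsemble]]
    responses: Dict[str, List[TrialResponses]]
    meta: Dict = field(default_factory=dict)

    def split(self, name: str) -> List[Tuple[StimulusEnsemble, TrialResponses]]:
        return list(zip(self.stimuli[name], self.responses[name]))

    def validate(self) -> None:
        for name, ens_list in self.stimuli.items():
            resp_list = self.responses.get(name)
            if resp_list is None or len(resp_list) != len(ens_list):
                raise ValueError(f"responses missing or mismatched for split {name!r}")
            for i, (ens, resp) in enumerate(zip(ens_list, resp_list)):
                if resp.n_bins != ens.n_frames:
                    raise ValueError(
                        f"split {name!r} ensemble {i}: {resp.n_bins} response bins "
                        f"!= {ens.n_frames} stimulus frames"
                    )


def one_over_f_frame(side: int, rng: np.random.Generator) -> np.ndarray:
    """One natural-like frame: white noise shaped to a 1/f amplitude spectrum."""
    white = rng.standard_normal((side, side))
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    amp = np.zeros_like(radius)
    amp[radius > 0] = 1.0 / radius[radius > 0]
    frame = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    return frame


def _normalize_quantize(frame: np.ndarray, clip_sd: float = 4.0, levels: int = 256) -> np.ndarray:
    """Mean-subtract, equalize RMS to 1, clip and quantize to 8-bit-like levels."""
    frame = frame - frame.mean()
    rms = frame.std()
    if rms > 0:
        frame = frame / rms
    frame = np.clip(frame, -clip_sd, clip_sd)
    step = 2 * clip_sd / (levels - 1)
    return np.round(frame / step) * step


def generate_stimuli(
    design: ExperimentDesign,
    side: int,
    seed: int,
    deg_per_pixel: float = 0.1,
) -> Dict[str, List[StimulusEnsemble]]:
    """Disjoint 1/f-noise ensembles for the train/reg/test splits.

    Each ensemble is frames_per_ensemble unique images preceded by
    blank_leadin_frames of zeros (mean luminance in mean-subtracted units).
    Deterministic per seed; every frame across all splits is independent.
    """
    if side < 32:
        raise ValueError("side must be >= 32 for a meaningful 1/f spectrum")
    rng = np.random.default_rng(seed)
    out: Dict[str, List[StimulusEnsemble]] = {}
    counts = {
        "train": design.n_train_ensembles,
        "reg": design.n_reg_ensembles,
        "test": design.n_test_ensembles,
    }
    for split, n_ens in counts.items():
        ensembles = []
        for i in range(n_ens):
            frames = np.stack(
                [
                    _normalize_quantize(one_over_f_frame(side, rng))
                    for _ in range(design.frames_per_ensemble)
                ]
            )
            if design.blank_leadin_frames:
                blank = np.zeros((design.blank_leadin_frames, side, side))
                frames = np.concatenate([blank, frames])
            ensembles.append(
                StimulusEnsemble(
                    frames=frames,
                    frame_rate_hz=design.frame_rate_hz,
                    deg_per_pixel=deg_per_pixel,
                    ensemble_id=f"{split}-{i}",
                )
            )
        out[split] = ensembles
    return out


def make_ground_truth_neuron(spec: SyntheticNeuronSpec) -> ConvRFModel:
    """Instantiate the generator model from a neuron spec.

    The filter is the outer product of the spatial Gabor (evaluated on the
    k x k grid) and the temporal kernel; deterministic -- the spec seed only
    drives trial noise downstream.
    """
    if spec.temporal_kernel.ndim != 1:
        raise ValueError("temporal_kernel must be 1-D")
    gparams = dict(spec.gabor)
    spatial = gabor2d((spec.k, spec.k), 1.0, **gparams)
    # reject Gabors whose envelope spills off the filter grid
    cx, cy = gparams.get("x0", 0), gparams.get("y0", 0)
    for c, s in ((cx, gparams["sigma_xp"]), (cy, gparams["sigma_yp"])):
        if c - 2 * s < -0.5 or c + 2 * s > spec.k - 0.5:
            raise ValueError("Gabor envelope exceeds the filter grid")
    weights = spatial[None, :, :] * spec.temporal_kernel[:, None, None]
    return ConvRFModel(
        filter=SpatioTemporalFilter(weights),
        prelu=PReLUParam(spec.alpha_true),
        map=spec.map,
        out_nl=OutputNonlinearity(
            gain=spec.out_gain, exponent=spec.out_exp, stage1_mode=False
        ),
        bias=0.0,
        input_size=spec.input_size,
        crop_window=spec.crop_window,
        meta={"alpha_true": spec.alpha_true, "deg_per_pixel": spec.deg_per_pixel},
    )


def default_temporal_kernel(n_lags: int = 7, frame_rate_hz: float = 75.0,
                            tf_hz: float = 8.0, lam: float = 12.0) -> np.ndarray:
    """Biphasic damped-sine kernel sampled at the stimulus frame rate."""
    t = np.arange(n_lags) / frame_rate_hz
    return damped_sine(t, A=1.0, lam=lam, omega=2 * np.pi * tf_hz, phi=0.0)


def simulate_responses(
    model: ConvRFModel,
    ensembles: List[StimulusEnsemble],
    repeats: int,
    noise_model: str,
    seed: int,
    reliability: float = 0.5,
    target_mean_rate: float = 10.0,
) -> List[TrialResponses]:
    """Noisy trial responses of a generator model to a list of ensembles.

    The noiseless prediction is scaled to target_mean_rate spikes/s; trial
    noise is then calibrated so the expected single-trial R^2_neuron is
    approximately `reliability`:

    - gaussian: additive iid noise with variance var(signal) * (1 - r) / r;
    - poisson: the rate is rescaled so the bin-count shot noise yields the
      requested reliability, then counts are drawn per bin.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    signals = []
    for ens in ensembles:
        if ens.side != model.input_size:
            ens = downsample_and_crop(
                ens, model.crop_window or (0, 0, ens.side), model.input_size
            )
        signals.append(forward_predict(model, ens))
    mean_rate = float(np.mean(np.concatenate(signals)))
    scale = target_mean_rate / mean_rate if mean_rate > 0 else 1.0
    signals = [s * scale for s in signals]
    all_sig = np.concatenate(signals)
    var_s = float(np.var(all_sig))
    dt = 1.0 / ensembles[0].frame_rate_hz
    out = []
    if noise_model == "gaussian":
        sigma = np.sqrt(var_s * (1 - reliability) / reliability) if reliability < 1 else 0.0
        for sig in signals:
            trials = sig[None, :] + rng.normal(0.0, sigma, size=(repeats, sig.size))
            out.append(TrialResponses(trials, ensembles[0].frame_rate_hz))
    else:  # poisson
        mbar = float(np.mean(all_sig))
        if reliability < 1 and var_s > 0:
            s2 = (reliability / (1 - reliability)) * (mbar / (var_s * dt))
        else:
            s2 = 1e6  # effectively noiseless
        for sig in signals:
            lam = np.maximum(sig * s2, 0.0) * dt
            counts = rng.poisson(lam[None, :].repeat(repeats, axis=0))
            out.append(TrialResponses(counts / (dt * s2), ensembles[0].frame_rate_hz))
    return out


def build_experiment(
    spec: SyntheticNeuronSpec,
    design: ExperimentDesign,
    seed: int,
    side: Optional[int] = None,
) -> Dataset:
    """Full synthetic experiment: stimuli, ground-truth responses, splits.

    side defaults to the neuron's input size scaled by its crop window (if
    any); pass a larger side to exercise the cropping machinery.
    """
    model = make_ground_truth_neuron(spec)
    if side is None:
        if spec.crop_window:
            side = spec.crop_window[2]
        else:
            # smallest multiple of input_size large enough for a 1/f spectrum
            side = spec.input_size * max(1, int(np.ceil(32 / spec.input_size)))
    stimuli = generate_stimuli(design, side, seed, deg_per_pixel=spec.deg_per_pixel)
    responses = {}
    for i, split in enumerate(("train", "reg", "test")):
        responses[split] = simulate_responses(
            model,
            stimuli[split],
            repeats=design.repeats(split),
            noise_model=spec.noise_model,
            seed=seed + 1000 * (i + 1),
            reliability=spec.reliability,
            target_mean_rate=spec.target_mean_rate,
        )
    ds = Dataset(
        stimuli=stimuli,
        responses=responses,
        meta={
            "seed": seed,
            "blank_leadin_frames": design.blank_leadin_frames,
            "frame_rate_hz": design.frame_rate_hz,
            "alpha_true": spec.alpha_true,
            "reliability": spec.reliability,
            "side": side,
        },
    )
    ds.validate()
    return ds
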