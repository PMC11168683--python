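import numpy as np
import pytest

from convrf.characterize import damped_sine
from convrf.model import (
    ConvRFModel,
    GaussianMap,
    OutputNonlinearity,
    PReLUParam,
    SpatioTemporalFilter,
    StimulusEnsemble,
)
from convrf.synth import ExperimentDesign, SyntheticNeuronSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_model(
    alpha: float = 1.0,
    input_size: int = 8,
    k: int = 3,
    n_lags: int = 2,
    seed: int = 0,
    stage1: bool = True,
    bias: float = 0.0,
) -> ConvRFModel:
    """A tiny random-but-fixed model for oracle comparisons."""
    rng = np.random.default_rng(seed)
    m = input_size - k + 1
    return ConvRFModel(
        filter=SpatioTemporalFilter(rng.normal(size=(n_lags, k, k))),
        prelu=PReLUParam(alpha),
        map=GaussianMap((m - 1) / 2.0, (m - 1) / 2.0, np.eye(2) * (m / 3.0) ** 2),
        out_nl=OutputNonlinearity(stage1_mode=stage1),
        bias=bias,
        input_size=input_size,
    )


def gabor_neuron_spec(
    alpha_true: float,
    seed: int = 0,
    reliability: float = 0.5,
    k: int = 11,
    input_size: int = 30,
    out_exp: float = 1.0,
) -> SyntheticNeuronSpec:
    """A ground-truth neuron with a randomized oriented Gabor subunit."""
    rng = np.random.default_rng(seed)
    m = input_size - k + 1
    gabor = dict(
        A=1.0,
        f=0.12 + 0.05 * rng.random(),
        theta=rng.uniform(0.0, 180.0),
        phi=rng.uniform(0.0, 2 * np.pi),
        sigma_xp=k / 6.0,
        sigma_yp=k / 4.25,
        x0=(k - 1) / 2.0,
        y0=(k - 1) / 2.0,
    )
    temporal = damped_sine(np.arange(7) / 75.0, A=1.0, lam=12.0, omega=2 * np.pi * 8, phi=0.0)
    return SyntheticNeuronSpec(
        gabor=gabor,
        temporal_kernel=temporal,
        alpha_true=alpha_true,
        map=GaussianMap((m - 1) / 2.0, (m - 1) / 2.0, np.eye(2) * 1.5**2),
        out_exp=out_exp,
        reliability=reliability,
        seed=seed,
        k=k,
        input_size=input_size,
    )


def tiny_design(
    n_train: int = 2,
    n_reg: int = 1,
    n_test: int = 1,
    frames: int = 120,
    leadin: int = 4,
) -> ExperimentDesign:
    return ExperimentDesign(
        n_train_ensembles=n_train,
        n_reg_ensembles=n_reg,
        n_test_ensembles=n_test,
        frames_per_ensemble=frames,
        repeats_train=5,
        repeats_reg=10,
        repeats_test=10,
        blank_leadin_frames=leadin,
    )


@pytest.fixture
def stimulus(rng):
    return StimulusEnsemble(rng.normal(size=(30, 8, 8)), 75.0, 0.1, "fixture")
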