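"""Generate a synthetic natural-image experiment with a ground-truth neuron.

The default design mirrors the standard protocol: 375-frame ensembles at
75 Hz; 20 training ensembles x 5 repeats, 5 regularization and 5 test
ensembles x 20 repeats.  Here we use a scaled-down design so the script runs
in seconds, and check that the injected trial noise hits its target
reliability (the expected single-trial noise ceiling R^2_neuron).
"""

import numpy as np

from convrf import ExperimentDesign, build_experiment, r2_neuron
from convrf.characterize import damped_sine
from convrf.model import GaussianMap
from convrf.synth import SyntheticNeuronSpec

full = ExperimentDesign()
print(f"full design: {full.unique_frames('train')} unique training frames, "
      f"{full.unique_frames('test')} test frames at {full.frame_rate_hz:g} Hz")

design = ExperimentDesign(
    n_train_ensembles=3, n_reg_ensembles=1, n_test_ensembles=1,
    frames_per_ensemble=250, repeats_train=5, repeats_reg=20, repeats_test=20,
    blank_leadin_frames=8,
)
k, input_size = 11, 30
m = input_size - k + 1
spec = SyntheticNeuronSpec(
    gabor=dict(A=1.0, f=0.15, theta=40.0, phi=0.0, sigma_xp=k / 6, sigma_yp=k / 4.25,
               x0=(k - 1) / 2, y0=(k - 1) / 2),
    temporal_kernel=damped_sine(np.arange(7) / 75.0, A=1.0, lam=12.0,
                                omega=2 * np.pi * 8, phi=0.0),
    alpha_true=0.0,  # complex-like: half-wave rectified subunits
    map=GaussianMap((m - 1) / 2, (m - 1) / 2, np.eye(2) * 1.5**2),
    reliability=0.3,
    k=k, input_size=input_size,
)
ds = build_experiment(spec, design, seed=1)
ceiling, _ = r2_neuron(ds.responses["test"][0])
print(f"target reliability 30% -> measured R^2_neuron {ceiling:.1f}% on 20 test repeats")
print("R^2_neuron is the noise ceiling: the upper bound a perfect model could reach per trial")
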