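"""Build a convolutional RF model by hand and run its forward prediction.

The model chain: spatiotemporal filter -> PReLU -> Gaussian map -> rectified
power law.  Shows the structural identities (map grid = input - k + 1,
restoration side = input) and the trainable parameter count.
"""

import numpy as np

from convrf import (
    ConvRFModel,
    GaussianMap,
    OutputNonlinearity,
    PReLUParam,
    SpatioTemporalFilter,
    StimulusEnsemble,
    count_parameters,
    forward_predict,
    restoration,
)

rng = np.random.default_rng(0)
model = ConvRFModel(
    filter=SpatioTemporalFilter(rng.normal(0, 0.05, size=(7, 15, 15))),
    prelu=PReLUParam(0.5),
    map=GaussianMap(mu_x=7.5, mu_y=7.5, cov=np.eye(2) * 2.0**2),
    out_nl=OutputNonlinearity(gain=1.0, exponent=1.2, stage1_mode=False),
    input_size=30,
)
print(f"map grid side: {model.map_grid_side} (30x30 input, 15x15 filter)")
print(f"restoration shape: {restoration(model).shape} (lags x 30 x 30)")
print(f"trainable parameters: {count_parameters(15, 7)} (k=15), {count_parameters(11, 7)} (k=11)")

stim = StimulusEnsemble(rng.normal(size=(75, 30, 30)), frame_rate_hz=75.0, deg_per_pixel=0.1)
rates = forward_predict(model, stim)
print(f"predicted 1 s of response: mean {rates.mean():.3f}, max {rates.max():.3f} (model units)")
print("each value is the model's firing rate for one 13.3 ms stimulus frame")
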