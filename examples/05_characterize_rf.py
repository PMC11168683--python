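"""Characterize a receptive field: Gabor fit, bandwidth indices, dynamics.

The linear restoration (filter convolved with the map) is the model's
first-order picture of the RF.  At the lag of maximal variance we fit a 2-D
Gabor (optimal spatial frequency, orientation, envelope) and from the 3x3
peak-region lag profile a damped sine (optimal temporal frequency).
"""

import numpy as np

from convrf import (
    bandwidth_indices,
    fit_damped_sine,
    fit_gabor,
    optimal_time_lag,
    restoration,
    temporal_profile,
)
from convrf.characterize import damped_sine
from convrf.model import GaussianMap
from convrf.synth import SyntheticNeuronSpec, make_ground_truth_neuron

k, input_size = 11, 30
m = input_size - k + 1
true_f_cpd = 0.15
model = make_ground_truth_neuron(SyntheticNeuronSpec(
    gabor=dict(A=1.0, f=true_f_cpd, theta=40.0, phi=0.3, sigma_xp=k / 6, sigma_yp=k / 4.25,
               x0=(k - 1) / 2, y0=(k - 1) / 2),
    temporal_kernel=damped_sine(np.arange(7) / 75.0, 1.0, 12.0, 2 * np.pi * 8, 0.0),
    alpha_true=0.8,
    map=GaussianMap((m - 1) / 2, (m - 1) / 2, np.eye(2) * 1.5**2),
    k=k, input_size=input_size, deg_per_pixel=1.0,
))

volume = restoration(model)
lag = optimal_time_lag(volume)
print(f"optimal time lag: {lag} ({lag / 75 * 1000:.0f} ms before the response)")

gfit = fit_gabor(volume[lag], deg_per_pixel=1.0)
bw = bandwidth_indices(gfit)
print(f"Gabor fit: f {gfit.f:.3f} c/deg (subunit {true_f_cpd}; map smoothing biases it "
      f"slightly low), theta {gfit.theta:.0f} deg, FVU {gfit.fvu:.3f}")
print(f"bandwidth indices nx {bw.nx:.2f}, ny {bw.ny:.2f}; RF size {bw.rf_size:.2f} deg")

profile, _ = temporal_profile(volume)
tfit = fit_damped_sine(profile, 1 / 75.0)
print(f"damped-sine fit: optimal TF {tfit.optimal_tf:.1f} Hz (generator kernel 8 Hz), "
      f"FVU {tfit.fvu:.3f}")
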