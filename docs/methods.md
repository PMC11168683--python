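# Methods

## Model

The package estimates a compact convolutional model of an early visual
cortical neuron. A stimulus clip `s[t, y, x]` (square grayscale frames in
mean-subtracted units) is cross-correlated with a spatiotemporal filter
`c[τ, i, j]` over a valid spatial window, giving a subunit drive
`u[t, y, x]` on a map grid of side `input_size − k + 1` (lag 0 is the
current frame; lags increase into the past, with zero-padded history for the
first `n_lags − 1` frames — the synthetic protocol likewise leads every
ensemble with a blank screen, so early bins are near-silent either way).
Each drive passes through a PReLU with negative-branch slope α, is weighted
by a 2-D Gaussian map and summed with a scalar bias, and the result passes
through a rectified power law `N(z) = g·z^exp` for `z > 0` (a plain
half-wave rectifier during stage-1 training).

Conventions worth stating:

- The Gaussian map is the *unnormalized* exponential with its scale β fixed
  at 1; overall response scale is carried by the filter and the output gain.
  The map therefore contributes exactly 5 trainable parameters (2 means + 3
  covariance values), giving the 855/1583 totals for k = 11/15 at 7 lags.
- Coordinates are 0-based row-major pixels; the Gaussian is evaluated at
  integer pixel centers; `mu_x` indexes columns and `mu_y` rows.
- The linear *restoration* is the per-lag **full** convolution of the filter
  with the map image, side = `input_size`. For α = 1 the whole cascade
  collapses exactly to this single linear filter (rectified at the output);
  the test suite asserts the identity at 1e-6 relative tolerance against a
  brute-force oracle.
- α is left unconstrained during fitting and reported raw.
- Fitted values of the PReLU slope obey a positive-scale symmetry
  (`prelu(s·u, α) = s·prelu(u, α)` for `s > 0`), so response scale cannot
  leak into α.

## Estimation

All parameters are fitted jointly by minimizing the mean-squared error
between the model prediction and the trial-averaged measured rate, with an
L2 penalty (default 0.01) on the filter weights only. Optimization is Adam
with analytic gradients; the covariance is parameterized as
(log σ₁, log σ₂, tanh-correlation) so it stays positive-definite, and the
stage-2 gain and exponent as softplus of raw parameters so they stay
positive. Stage 1 fixes the output nonlinearity to a half-wave rectifier;
stage 2 reloads the stage-1 weights and retrains everything with the power
law (g, exp initialized at 1), under a global gradient-norm clip of 1.0 that
tames the power law's gradients. Early stopping watches the regularization
split with a patience counter (default 50 epochs) and restores the best
epoch.

Updates are minibatched: each ensemble is cut into chunks (default 128
frames) that carry their exact `n_lags − 1` frames of stimulus history, so
the chunked objective is identical to the full-batch one; chunks are
shuffled per epoch (seeded) and grouped into ~512-frame batches. Because the
stimulus never changes across epochs, each chunk's spatial FFT is computed
once and cached; one epoch then costs roughly one inverse FFT (forward) and
one forward FFT (filter gradient) per chunk, in float32. A float64 reference
path (`model.subunit_drive`, direct scipy correlation) is kept and the test
suite asserts the two agree; analytic gradients are checked against central
finite differences.

Defaults follow the standard recipe (learning rate 1e-3, up to 2000 epochs).
The desk-scale studies in the tests and examples use learning rate 5e-3,
≤ 900 epochs and ~2400 training frames per neuron — problem sizes chosen so
a full 10-neuron population study runs in minutes on one CPU. At these sizes,
minibatch updates are what make complex-cell (α ≤ 0) fits converge; pure
full-batch Adam crawls along a plateau for thousands of epochs before
finding the rectified-subunit solution.

Cropping: receptive fields much smaller than the image are handled by up to
three passes of crop → block-average to 30×30 → refit. The next window is
centered on the fitted map mean mapped back through the crop geometry, with
side = 6 × (largest map σ, in original pixels), floored at 120 original
pixels, snapped to a multiple of the input size (so block averaging stays
exact) and clamped inside the image; if the mean falls outside the current
window the update recenters on the window middle and flags the report. The
filter size (11 vs 15) is chosen by regularization-set VAF on the final
pass. Intermediate passes train stage 1 only — the window update depends
only on the fitted map, which stage 1 already estimates. One caveat found
during development and left documented rather than patched: for α ≈ 1
neurons the filter/map factorization is a degenerate ridge (any split with
the same restoration predicts identically), so the fitted map σ — and hence
the automatic window — is only weakly determined; the window-update geometry
is therefore unit-tested directly, and the window never grows across passes.

## Synthetic experiments

The generator reproduces the study protocol: ensembles of 375 frames at
75 Hz; 20 training ensembles × 5 repeats; 5 regularization and 5 test
ensembles × 20 repeats; ~100 ms of blank lead-in per ensemble. Natural
images are emulated by 1/f-amplitude random-phase noise — broadband and
spatially correlated, which is the statistic that makes natural-image system
identification hard — mean-subtracted, RMS-equalized per frame, clipped at
±4 SD and quantized to 256 levels like an 8-bit display. What this does
*not* emulate: sparse structure, edges and higher-order statistics of real
photographs, eye movements, or per-neuron contrast adjustments (a single
global RMS contrast is used). Passing recovery tests on this ensemble shows
the estimator handles correlated broadband input, not that it has been
validated on photographs.

Ground-truth neurons are instances of the model itself: a spatial Gabor
(σs a few pixels, centered on the filter grid) times a damped-sine temporal
kernel as the filter, a chosen α_true, a Gaussian map with σ = 1.5 map
pixels (fitted envelopes in practice span a few pixels; much broader maps
would low-pass the subunit carrier out of the restoration), and a rectified
power-law output. Trial noise is parameterized by an operational
reliability r ∈ (0, 1]: the expected single-trial R²_neuron. Gaussian mode
adds iid noise with variance `var(signal)·(1−r)/r`; Poisson mode rescales
the mean rate so bin-count shot noise yields the same target. The measured
ceiling runs slightly below r (the mean-of-19-others reference is itself
noisy); the calibration tests allow for this. Noiseless rates are scaled to
a 10 spikes/s mean; Gaussian-mode trials are real-valued rate residuals and
may dip below zero.

## Evaluation

All accuracies are percentages built on Pearson correlations of rate series
at frame-bin (13.3 ms) resolution, with blank lead-in bins excluded. Raw
VAF uses the across-repetition mean of the test response. R²_neuron
correlates each repetition with the mean of the others and averages;
R²_model correlates each repetition with the prediction. Explainable VAF =
100·R²_model/R²_neuron is reported unclipped (sampling error can push it
past 100). The inclusion screen drops units with R²_neuron ≤ 1% on either
held-out split, explainable VAF < 1%, or evoked − blank rate
< 0.5 spikes/s.

## Gratings and phase sensitivity

Drifting sinewave gratings are rendered under a circular raised-cosine
aperture on a blank (zero) background, with a Nyquist guard on the spatial
frequency. Tuning curves are time-mean responses after discarding the
`n_lags`-frame onset transient, normalized to the curve maximum. The AC/DC
ratio uses F1 = 2|X(tf)|/n evaluated at the exact drift frequency over an
integer number of cycles (the series is trimmed accordingly) and F0 = mean;
AC/DC < 1 classifies a cell as complex. The model's final rectification
keeps F0 positive for any responsive model; a zero-mean response is reported
as undefined rather than infinite.

## RF characterization

Spatial properties are measured on the restoration at the lag of maximal
spatial variance (ties to the smaller lag). The 2-D Gabor is
`A·exp(−(x′/2σ_x′)² − (y′/2σ_y′)²)·cos(2πf·x′ + φ) + d` in a frame rotated
by θ (counterclockwise from +x; x′ along the modulation direction); fits are
nonlinear least squares with multi-starts over four phases and two
orientations seeded from the slice's dominant Fourier component, FVU =
1 − R² against the slice's own variance. A flag switches fitting to the raw
filter slice, whose frequency estimates run slightly higher than
restoration-based ones (the map's Gaussian smoothing attenuates the
carrier). Temporal properties come from the 3×3 neighborhood of the
strongest pixel (truncated and flagged at borders), averaged per lag and fit
with `A·e^{−λt}cos(ωt + φ)` using an ω multi-start grid up to the lag-rate
Nyquist; optimal temporal frequency is ω/2π. FVU is reported for both fits;
no FVU-based exclusion is applied — that is left to the caller.

## Known limitations

- Single-filter architecture: no cross-orientation suppression, surround
  suppression or gain control, by design.
- The exponent/gain/filter-scale triple is only weakly identifiable from
  natural-image responses over a limited drive range; exponent recovery in
  tests needs a few thousand noise-free frames and converges slowly.
- The automated crop window inherits the map-σ identifiability caveat above.
- Desk-scale study sizes (2–5k training frames, one filter size, one pass)
  are deliberately small; population-level findings here are directional
  checks, not quantitative reproductions of in-vivo numbers.
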