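"""Receptive-field characterization: Gabor and damped-sinusoid fits.

Spatial structure is read from the linear restoration (filter convolved with
the Gaussian map) at the time lag of maximal spatial variance.  The slice is
fit with a 2-D Gabor -- a sinusoid under a rotated Gaussian envelope -- whose
parameters give the optimal spatial frequency, orientation, envelope sigmas,
and hence RF size and the dimensionless bandwidth indices n_x = sigma_x' * f
and n_y = sigma_y' * f.  Temporal structure is the lag profile of the 3x3
region around the strongest pixel, fit with a damped sine whose angular
frequency estimates the optimal temporal frequency.

Goodness of fit is the fraction of variance unexplained, FVU = 1 - R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize


@dataclass
class GaborFit:
    """Best-fit 2-D Gabor; lengths in degrees, f in cycles/degree."""

    A: float
    f: float
    theta: float  # orientation of the sinusoid, degrees CCW from +x
    phi: float  # phase, radians
    sigma_xp: float  # envelope SD along the modulation direction (width)
    sigma_yp: float  # envelope SD along the envelope length
    x0: float
    y0: float
    d: float
    fvu: float
    converged: bool = True


@dataclass
class DampedSineFit:
    A: float
    lam: float  # decay constant, 1/s
    omega: float  # angular frequency, rad/s
    phi: float
    fvu: float
    converged: bool = True

    @property
    def optimal_tf(self) -> float:
        """Optimal temporal frequency in Hz."""
        return self.omega / (2 * np.pi)


@dataclass
class BandwidthIndices:
    nx: float
    ny: float
    rf_size: float  # sqrt(sigma_xp^2 + sigma_yp^2), degrees


def gabor2d(
    shape: Tuple[int, int],
    deg_per_pixel: float,
    A: float,
    f: float,
    theta: float,
    phi: float,
    sigma_xp: float,
    sigma_yp: float,
    x0: float,
    y0: float,
    d: float = 0.0,
) -> np.ndarray:
    """Evaluate the Gabor on a pixel grid; (x0, y0) and sigmas in degrees.

    The envelope is exp(-(x'/(2 sigma_x'))^2 - (y'/(2 sigma_y'))^2) with the
    rotated frame x' along the sinusoid's modulation direction.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols] * deg_per_pixel
    th = np.deg2rad(theta)
    xp = (xx - x0) * np.cos(th) + (yy - y0) * np.sin(th)
    yp = -(xx - x0) * np.sin(th) + (yy - y0) * np.cos(th)
    env = np.exp(-((xp / (2 * sigma_xp)) ** 2) - ((yp / (2 * sigma_yp)) ** 2))
    return A * env * np.cos(2 * np.pi * f * xp + phi) + d


def damped_sine(t: np.ndarray, A: float, lam: float, omega: float, phi: float) -> np.ndarray:
    """A * exp(-lam t) * cos(omega t + phi)."""
    return A * np.exp(-lam * t) * np.cos(omega * t + phi)


def optimal_time_lag(rf_volume: np.ndarray) -> int:
    """Lag index with maximal spatial variance; ties go to the smaller lag."""
    rf_volume = np.asarray(rf_volume, float)
    var = rf_volume.reshape(rf_volume.shape[0], -1).var(axis=1)
    if np.all(var == 0):
        warnings.warn("all-zero restoration volume; returning lag 0")
        return 0
    return int(np.argmax(var))  # argmax returns the first (smallest) maximizer


def _dominant_orientation_and_freq(
    rf_slice: np.ndarray, deg_per_pixel: float
) -> Tuple[float, float]:
    """Initial guesses for orientation (deg) and spatial frequency (cpd)
    from the peak of the amplitude spectrum (DC excluded)."""
    n = rf_slice.shape[0]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(rf_slice - rf_slice.mean())))
    center = n // 2
    spec[center, center] = 0.0
    iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
    fy = (iy - center) / (n * deg_per_pixel)
    fx = (ix - center) / (n * deg_per_pixel)
    f = float(np.hypot(fx, fy))
    theta = float(np.rad2deg(np.arctan2(fy, fx))) % 180.0
    return theta, max(f, 1e-3)


def fit_gabor(rf_slice: np.ndarray, deg_per_pixel: float) -> GaborFit:
    """Least-squares 2-D Gabor fit with multi-start over phase.

    Initial center and envelope sigmas come from the energy centroid and
    second moments; orientation and frequency from the dominant Fourier
    component.  Starts are taken over four phases (0, pi/2, pi, 3pi/2) and
    the two orientations theta, theta + 90; the lowest-SSE fit wins.
    """
    rf_slice = np.asarray(rf_slice, float)
    if np.std(rf_slice) == 0:
        raise ValueError("cannot fit a Gabor to a constant slice")
    rows, cols = rf_slice.shape
    yy, xx = np.mgrid[0:rows, 0:cols] * deg_per_pixel
    energy = (rf_slice - rf_slice.mean()) ** 2
    wsum = energy.sum()
    x0 = float((xx * energy).sum() / wsum)
    y0 = float((yy * energy).sum() / wsum)
    sx = float(np.sqrt(((xx - x0) ** 2 * energy).sum() / wsum))
    sy = float(np.sqrt(((yy - y0) ** 2 * energy).sum() / wsum))
    sig0 = max(0.5 * (sx + sy), deg_per_pixel)
    theta0, f0 = _dominant_orientation_and_freq(rf_slice, deg_per_pixel)
    amp0 = float(np.max(np.abs(rf_slice - rf_slice.mean())))
    d0 = float(rf_slice.mean())
    data = rf_slice.ravel()
    ss_tot = float(np.sum((data - data.mean()) ** 2))

    def residuals(p):
        A, f, th, phi, sxp, syp, px0, py0, d = p
        return (
            gabor2d(rf_slice.shape, deg_per_pixel, A, f, th, phi, sxp, syp, px0, py0, d).ravel()
            - data
        )

    lo = [-np.inf, 0.0, -np.inf, -np.inf, 1e-4, 1e-4, -np.inf, -np.inf, -np.inf]
    hi = [np.inf] * 9
    best, best_sse = None, np.inf
    for th_start in (theta0, theta0 + 90.0):
        for phi_start in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            p0 = [amp0, f0, th_start, phi_start, sig0, sig0, x0, y0, d0]
            try:
                res = optimize.least_squares(residuals, p0, bounds=(lo, hi), max_nfev=2000)
            except Exception:
                continue
            sse = 2 * res.cost
            if sse < best_sse:
                best, best_sse = res, sse
    if best is None:
        return GaborFit(*([np.nan] * 9), fvu=np.nan, converged=False)
    A, f, th, phi, sxp, syp, px0, py0, d = best.x
    # canonical form: positive sigmas, orientation folded into [0, 180)
    fvu = best_sse / ss_tot if ss_tot > 0 else np.nan
    return GaborFit(
        A=float(A),
        f=float(f),
        theta=float(th % 180.0),
        phi=float(np.mod(phi, 2 * np.pi)),
        sigma_xp=float(abs(sxp)),
        sigma_yp=float(abs(syp)),
        x0=float(px0),
        y0=float(py0),
        d=float(d),
        fvu=float(min(max(fvu, 0.0), 1.0)),
    )


def bandwidth_indices(fit: GaborFit) -> BandwidthIndices:
    """Dimensionless bandwidth indices and RF size from a Gabor fit.

    n_x = sigma_x' * f and n_y = sigma_y' * f count cycles of the optimal
    spatial frequency under the envelope; larger values mean narrower tuning.
    RF size is the Euclidean norm of the two envelope sigmas, in degrees.
    """
    return BandwidthIndices(
        nx=fit.sigma_xp * fit.f,
        ny=fit.sigma_yp * fit.f,
        rf_size=float(np.hypot(fit.sigma_xp, fit.sigma_yp)),
    )


def temporal_profile(rf_volume: np.ndarray) -> Tuple[np.ndarray, dict]:
    """Lag profile of the 3x3 region around the strongest pixel.

    At the optimal-lag slice, locate the pixel of maximum absolute value and
    average its 3x3 neighborhood (truncated at borders) at every lag.
    Returns (profile, info) where info notes the peak location and whether
    the neighborhood was truncated.
    """
    rf_volume = np.asarray(rf_volume, float)
    n_lags, rows, cols = rf_volume.shape
    if n_lags < 2 or rows < 3 or cols < 3:
        raise ValueError("need n_lags >= 2 and spatial side >= 3")
    lag = optimal_time_lag(rf_volume)
    sl = rf_volume[lag]
    r, c = np.unravel_index(np.argmax(np.abs(sl)), sl.shape)
    r0, r1 = max(r - 1, 0), min(r + 2, rows)
    c0, c1 = max(c - 1, 0), min(c + 2, cols)
    profile = rf_volume[:, r0:r1, c0:c1].mean(axis=(1, 2))
    truncated = (r1 - r0) * (c1 - c0) < 9
    return profile, {"peak": (int(r), int(c)), "lag": lag, "truncated": truncated}


def fit_damped_sine(profile: np.ndarray, lag_spacing_s: float) -> DampedSineFit:
    """Least-squares damped-sine fit with a multi-start grid over omega.

    The omega grid spans zero to the Nyquist rate of the lag spacing
    (pi / spacing rad/s); lambda is constrained nonnegative.
    """
    profile = np.asarray(profile, float)
    if profile.size < 4:
        raise ValueError("need at least 4 points for a damped-sine fit")
    t = np.arange(profile.size) * lag_spacing_s
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))

    def residuals(p):
        return damped_sine(t, *p) - profile

    amp0 = float(np.max(np.abs(profile))) or 1.0
    nyq = np.pi / lag_spacing_s
    best, best_sse = None, np.inf
    for omega0 in np.linspace(0.0, nyq, 13):
        for lam0 in (0.0, 1.0 / (profile.size * lag_spacing_s)):
            p0 = [amp0, lam0, omega0, 0.0]
            try:
                res = optimize.least_squares(
                    residuals,
                    p0,
                    bounds=([-np.inf, 0.0, 0.0, -np.inf], [np.inf, np.inf, 1.5 * nyq, np.inf]),
                    max_nfev=1000,
                )
            except Exception:
                continue
            if 2 * res.cost < best_sse:
                best, best_sse = res, 2 * res.cost
    if best is None:
        return DampedSineFit(np.nan, np.nan, np.nan, np.nan, fvu=np.nan, converged=False)
    A, lam, omega, phi = best.x
    fvu = best_sse / ss_tot if ss_tot > 0 else np.nan
    return DampedSineFit(
        A=float(A),
        lam=float(lam),
        omega=float(omega),
        phi=float(np.mod(phi, 2 * np.pi)),
        fvu=float(min(max(fvu, 0.0), 1.0)),
    )


def characterize_model(model, use_filter: bool = False) -> dict:
    """One-stop RF summary for a fitted model.

    By default Gabor fitting operates on the restoration; use_filter=True
    switches to the raw filter slice (frequencies there run slightly higher,
    since the map's Gaussian smoothing lowers restoration-based estimates).
    """
    from .model import restoration

    volume = model.filter.weights if use_filter else restoration(model)
    deg = model.meta.get("deg_per_pixel", 1.0)
    lag = optimal_time_lag(volume)
    gfit = fit_gabor(volume[lag], deg)
    bw = bandwidth_indices(gfit)
    profile, info = temporal_profile(volume)
    frame_rate = model.meta.get("frame_rate_hz", 75.0)
    tfit = fit_damped_sine(profile, 1.0 / frame_rate)
    return {
        "optimal_lag": lag,
        "gabor": gfit,
        "bandwidth": bw,
        "temporal_profile": profile,
        "temporal_fit": tfit,
        "peak_info": info,
    }
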