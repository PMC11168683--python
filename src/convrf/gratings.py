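"""Drifting-grating synthesis, tuning-curve prediction and phase sensitivity.

The AC/DC ratio -- the response's first harmonic at the grating's temporal
frequency divided by its mean -- is the classical phase-sensitivity index:
values below 1 mark complex (phase-invariant) cells, values at or above 1
simple (phase-sensitive) cells.  The F1 amplitude uses the 2|DFT|/n
convention evaluated at the exact drift frequency over an integer number of
cycles, after discarding the model's n_lags-frame onset transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .model import ConvRFModel, StimulusEnsemble, forward_predict


@dataclass
class GratingParams:
    """One drifting sinewave grating under a circular cosine-taper aperture."""

    spatial_frequency: float  # cycles/degree
    temporal_frequency: float  # Hz
    orientation: float = 0.0  # degrees CCW from +x
    contrast: float = 1.0  # fraction of full scale
    duration_s: float = 1.0
    frame_rate_hz: float = 75.0
    aperture_radius_frac: float = 0.5  # radius as fraction of image side
    taper_frac: float = 0.4  # outer fraction of the radius that ramps to 0

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0 or self.temporal_frequency <= 0:
            raise ValueError("spatial and temporal frequency must be positive")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")


@dataclass
class TuningCurve:
    """Mean response per abscissa value, normalized to its maximum."""

    abscissa: np.ndarray
    response: np.ndarray
    raw_response: np.ndarray = field(default_factory=lambda: np.array([]))
    unresponsive: bool = False


def make_drifting_grating(
    p: GratingParams, side_px: int, deg_per_pixel: float
) -> StimulusEnsemble:
    """Frames of a drifting sinewave grating, blank (0) outside the aperture."""
    wavelength_px = 1.0 / (p.spatial_frequency * deg_per_pixel)
    if wavelength_px < 2.0:
        limit = 1.0 / (2.0 * deg_per_pixel)
        raise ValueError(
            f"spatial frequency {p.spatial_frequency} cpd exceeds the Nyquist "
            f"limit {limit} cpd at {deg_per_pixel} deg/px"
        )
    n_frames = int(round(p.duration_s * p.frame_rate_hz))
    yy, xx = np.mgrid[0:side_px, 0:side_px] * deg_per_pixel
    center = (side_px - 1) / 2.0 * deg_per_pixel
    th = np.deg2rad(p.orientation)
    xp = (xx - center) * np.cos(th) + (yy - center) * np.sin(th)
    radius = np.hypot(xx - center, yy - center)
    r_out = p.aperture_radius_frac * side_px * deg_per_pixel
    r_in = (1 - p.taper_frac) * r_out
    aperture = np.ones_like(radius)
    ramp = (radius > r_in) & (radius <= r_out)
    aperture[ramp] = 0.5 * (1 + np.cos(np.pi * (radius[ramp] - r_in) / (r_out - r_in)))
    aperture[radius > r_out] = 0.0
    t = np.arange(n_frames) / p.frame_rate_hz
    frames = (
        p.contrast
        * np.sin(
            2 * np.pi * p.spatial_frequency * xp[None, :, :]
            - 2 * np.pi * p.temporal_frequency * t[:, None, None]
        )
        * aperture[None, :, :]
    )
    return StimulusEnsemble(
        frames=frames,
        frame_rate_hz=p.frame_rate_hz,
        deg_per_pixel=deg_per_pixel,
        ensemble_id=f"grating-sf{p.spatial_frequency}-tf{p.temporal_frequency}-or{p.orientation}",
    )


def simulate_grating_response(
    model: ConvRFModel, p: GratingParams, deg_per_pixel: Optional[float] = None
) -> np.ndarray:
    """Model response to one grating, onset transient (n_lags frames) removed."""
    deg = deg_per_pixel or model.meta.get("deg_per_pixel", 1.0)
    ens = make_drifting_grating(p, model.input_size, deg)
    r = forward_predict(model, ens)
    return r[model.filter.n_lags :]


def predict_tuning_curve(
    model: ConvRFModel,
    sweep: Sequence[GratingParams],
    deg_per_pixel: Optional[float] = None,
) -> TuningCurve:
    """Time-mean response across a grating parameter sweep, normalized to max.

    The abscissa is the parameter that varies across the sweep (spatial
    frequency unless orientation varies instead).
    """
    means = np.array(
        [float(np.mean(simulate_grating_response(model, p, deg_per_pixel))) for p in sweep]
    )
    sfs = np.array([p.spatial_frequency for p in sweep])
    oris = np.array([p.orientation for p in sweep])
    abscissa = sfs if np.unique(sfs).size >= np.unique(oris).size else oris
    peak = means.max()
    if peak <= 0:
        return TuningCurve(abscissa, np.zeros_like(means), means, unresponsive=True)
    return TuningCurve(abscissa, means / peak, means)


def ac_dc_ratio(response: np.ndarray, tf: float, frame_rate: float) -> float:
    """First harmonic over mean: F1/F0 with F1 = 2|X(tf)|/n.

    The series is trimmed to an integer number of drift cycles so the
    projection onto the tf component is exact.
    """
    response = np.asarray(response, float)
    dt = 1.0 / frame_rate
    frames_per_cycle = frame_rate / tf
    n_cycles = int(np.floor(response.size / frames_per_cycle))
    if n_cycles < 1:
        raise ValueError(
            f"response covers {response.size * dt:.3f} s, less than one cycle at {tf} Hz"
        )
    n = int(round(n_cycles * frames_per_cycle))
    r = response[:n]
    f0 = float(np.mean(r))
    if f0 <= 0:
        raise ValueError("AC/DC undefined: mean response is not positive")
    t = np.arange(n) * dt
    f1 = 2.0 * abs(np.sum(r * np.exp(-2j * np.pi * tf * t))) / n
    return f1 / f0


def classify_simple_complex(acdc: float) -> str:
    """AC/DC < 1 -> 'complex'; otherwise 'simple'."""
    if acdc < 0:
        raise ValueError("AC/DC ratio must be nonnegative")
    return "complex" if acdc < 1.0 else "simple"


def tuning_vaf(predicted: TuningCurve, measured: TuningCurve) -> float:
    """Percent VAF (squared Pearson correlation) between two tuning curves."""
    if predicted.abscissa.size < 3:
        raise ValueError("need at least 3 tuning points")
    if not np.allclose(predicted.abscissa, measured.abscissa):
        raise ValueError("tuning curves must share the same abscissa")
    c = np.corrcoef(predicted.response, measured.response)[0, 1]
    return 100.0 * float(c) ** 2


def default_sf_sweep(
    sfs: Sequence[float],
    tf: float = 2.0,
    orientation: float = 0.0,
    contrast: float = 1.0,
    duration_s: float = 1.0,
    frame_rate_hz: float = 75.0,
) -> List[GratingParams]:
    """A spatial-frequency sweep at fixed orientation and temporal frequency."""
    return [
        GratingParams(
            spatial_frequency=sf,
            temporal_frequency=tf,
            orientation=orientation,
            contrast=contrast,
            duration_s=duration_s,
            frame_rate_hz=frame_rate_hz,
        )
        for sf in sfs
    ]
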