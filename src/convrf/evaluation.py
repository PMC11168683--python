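"""Predictive-accuracy metrics and the unit-inclusion screen.

All quantities are percentages in [0, 100] built on squared Pearson
correlations of rate series at stimulus-frame resolution:

- raw VAF: correlation^2 between the prediction and the repetition-averaged
  measured response;
- R^2_neuron ("noise ceiling"): for each repetition, correlation^2 between
  that trial and the mean of all other repetitions, averaged over
  repetitions -- an upper bound on the explainable variance;
- R^2_model: per-repetition correlation^2 between each single trial and the
  prediction, averaged over repetitions;
- explainable VAF: 100 * R^2_model / R^2_neuron, the fraction of reliable
  response variance the model captures (may exceed 100 by sampling error;
  reported unclipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import TrialResponses


@dataclass
class EvaluationResult:
    raw_vaf: float
    r2_model: float
    r2_neuron: float
    explainable_vaf: float
    per_rep_r2_model: np.ndarray = field(default_factory=lambda: np.array([]))
    per_rep_r2_neuron: np.ndarray = field(default_factory=lambda: np.array([]))
    skipped_reps: int = 0


def _corr2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation as a percentage."""
    return 100.0 * float(np.corrcoef(a, b)[0, 1]) ** 2


def raw_vaf(predicted: np.ndarray, measured_mean: np.ndarray) -> float:
    """Percent variance accounted for against the repetition-averaged response."""
    predicted = np.asarray(predicted, float)
    measured_mean = np.asarray(measured_mean, float)
    if predicted.shape != measured_mean.shape or predicted.size < 3:
        raise ValueError(
            f"series must have equal length >= 3; got {predicted.shape} vs {measured_mean.shape}"
        )
    if np.std(predicted) == 0 or np.std(measured_mean) == 0:
        raise ValueError("raw_vaf undefined for zero-variance input")
    return _corr2(predicted, measured_mean)


def r2_neuron(trials: TrialResponses) -> Tuple[float, Dict]:
    """Noise ceiling: mean over repetitions of R^2(trial_i, mean of others).

    Returns (percent, diagnostics); zero-variance repetitions are skipped and
    counted in diagnostics['skipped'].
    """
    rates = trials.rates if isinstance(trials, TrialResponses) else np.atleast_2d(trials)
    n_rep = rates.shape[0]
    if n_rep < 2:
        raise ValueError("r2_neuron requires >= 2 repetitions")
    vals: List[float] = []
    skipped = 0
    total = rates.sum(axis=0)
    for i in range(n_rep):
        others = (total - rates[i]) / (n_rep - 1)
        if np.std(rates[i]) == 0 or np.std(others) == 0:
            skipped += 1
            continue
        vals.append(_corr2(rates[i], others))
    if not vals:
        raise ValueError("all repetitions have zero variance")
    return float(np.mean(vals)), {"skipped": skipped, "per_rep": np.array(vals)}


def r2_model(predicted: np.ndarray, trials: TrialResponses) -> Tuple[float, Dict]:
    """Mean over repetitions of R^2(trial_i, prediction), as a percentage."""
    rates = trials.rates if isinstance(trials, TrialResponses) else np.atleast_2d(trials)
    predicted = np.asarray(predicted, float)
    if rates.shape[1] != predicted.size:
        raise ValueError(
            f"prediction length {predicted.size} != trial bins {rates.shape[1]}"
        )
    if np.std(predicted) == 0:
        raise ValueError("r2_model undefined for zero-variance prediction")
    vals: List[float] = []
    skipped = 0
    for i in range(rates.shape[0]):
        if np.std(rates[i]) == 0:
            skipped += 1
            continue
        vals.append(_corr2(rates[i], predicted))
    if not vals:
        raise ValueError("all repetitions have zero variance")
    return float(np.mean(vals)), {"skipped": skipped, "per_rep": np.array(vals)}


def explainable_vaf(r2_model_pct: float, r2_neuron_pct: float) -> float:
    """Noise-ceiling-corrected performance, 100 * R^2_model / R^2_neuron."""
    if r2_neuron_pct <= 0:
        raise ValueError("explainable VAF undefined for r2_neuron <= 0")
    return 100.0 * r2_model_pct / r2_neuron_pct


def evaluate_model(model, dataset, split: str = "test") -> EvaluationResult:
    """Convenience: all metrics for one model on one dataset split.

    Predictions and responses from all ensembles of the split are
    concatenated; blank lead-in bins (dataset.meta['blank_leadin_frames'])
    are excluded from every metric.
    """
    from .fitting import downsample_and_crop
    from .model import forward_predict

    leadin = int(dataset.meta.get("blank_leadin_frames", 0))
    preds, trial_blocks = [], []
    for ens, resp in dataset.split(split):
        if ens.side != model.input_size:
            window = model.crop_window or (0, 0, ens.side)
            ens = downsample_and_crop(ens, window, model.input_size)
        p = forward_predict(model, ens)[leadin:]
        preds.append(p)
        trial_blocks.append(resp.rates[:, leadin:])
    predicted = np.concatenate(preds)
    rates = np.concatenate(trial_blocks, axis=1)
    trials = TrialResponses(rates, dataset.split(split)[0][1].frame_rate_hz)
    rv = raw_vaf(predicted, trials.mean_rate())
    rn, dn = r2_neuron(trials)
    rm, dm = r2_model(predicted, trials)
    return EvaluationResult(
        raw_vaf=rv,
        r2_model=rm,
        r2_neuron=rn,
        explainable_vaf=explainable_vaf(rm, rn),
        per_rep_r2_model=dm["per_rep"],
        per_rep_r2_neuron=dn["per_rep"],
        skipped_reps=dn["skipped"] + dm["skipped"],
    )


@dataclass
class ScreenThresholds:
    """Inclusion screen: minimum reliability, explainable VAF and evoked rate."""

    min_r2_neuron: float = 1.0  # percent, on both regularization and test sets
    min_explainable_vaf: float = 1.0  # percent
    min_evoked_minus_blank: float = 0.5  # spikes/s


def screen_units(
    units: Sequence[Dict], thresholds: Optional[ScreenThresholds] = None
) -> Tuple[List[Dict], List[Tuple[Dict, str]]]:
    """Partition per-unit metric dicts into included and (excluded, reason).

    Each unit dict needs keys: r2_neuron_reg, r2_neuron_test,
    explainable_vaf, evoked_rate, blank_rate.
    """
    th = thresholds or ScreenThresholds()
    required = ("r2_neuron_reg", "r2_neuron_test", "explainable_vaf", "evoked_rate", "blank_rate")
    included, excluded = [], []
    for unit in units:
        if any(key not in unit or unit[key] is None for key in required):
            excluded.append((unit, "incomplete"))
            continue
        if unit["r2_neuron_reg"] <= th.min_r2_neuron or unit["r2_neuron_test"] <= th.min_r2_neuron:
            excluded.append((unit, "unreliable (r2_neuron)"))
        elif unit["explainable_vaf"] < th.min_explainable_vaf:
            excluded.append((unit, "low explainable VAF"))
        elif unit["evoked_rate"] - unit["blank_rate"] < th.min_evoked_minus_blank:
            excluded.append((unit, "weak evoked response"))
        else:
            included.append(unit)
    return included, excluded
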