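"""End-to-end pipeline: simulate -> fit -> evaluate -> characterize -> gratings.

Each stage writes one artifact and is resumable: an existing artifact is
reused unless force=True.  Stage failures raise with the stage name after
earlier artifacts have been persisted.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .characterize import characterize_model
from .evaluation import evaluate_model
from .fitting import TrainingConfig, fit_model
from .gratings import ac_dc_ratio, classify_simple_complex, default_sf_sweep, predict_tuning_curve, simulate_grating_response
from .model import GaussianMap, load_model, save_model
from .synth import ExperimentDesign, SyntheticNeuronSpec, build_experiment, default_temporal_kernel

log = logging.getLogger("convrf")


def neuron_spec_from_config(neuron: Dict, design: ExperimentDesign) -> SyntheticNeuronSpec:
    """Build a SyntheticNeuronSpec from the (flat) neuron section of a config."""
    k = int(neuron.get("k", 11))
    input_size = int(neuron.get("input_size", 30))
    n_lags = int(neuron.get("n_lags", 7))
    m = input_size - k + 1
    gabor = {
        "A": 1.0,
        "f": float(neuron.get("sf_cycles_per_px", 0.15)),
        "theta": float(neuron.get("orientation_deg", 30.0)),
        "phi": float(neuron.get("phase_rad", 0.0)),
        "sigma_xp": float(neuron.get("sigma_x_px", k / 6.0)),
        "sigma_yp": float(neuron.get("sigma_y_px", k / 4.0)),
        "x0": (k - 1) / 2.0,
        "y0": (k - 1) / 2.0,
    }
    cov = np.eye(2) * float(neuron.get("map_sigma_px", 1.5)) ** 2
    return SyntheticNeuronSpec(
        gabor=gabor,
        temporal_kernel=default_temporal_kernel(
            n_lags, design.frame_rate_hz,
            tf_hz=float(neuron.get("tf_hz", 8.0)),
            lam=float(neuron.get("temporal_decay", 12.0)),
        ),
        alpha_true=float(neuron.get("alpha_true", 1.0)),
        map=GaussianMap((m - 1) / 2.0, (m - 1) / 2.0, cov),
        out_gain=float(neuron.get("out_gain", 1.0)),
        out_exp=float(neuron.get("out_exp", 1.0)),
        noise_model=str(neuron.get("noise_model", "gaussian")),
        reliability=float(neuron.get("reliability", 0.5)),
        k=k,
        input_size=input_size,
        deg_per_pixel=float(neuron.get("deg_per_pixel", 0.1)),
    )


def run_pipeline(config: Dict, force: bool = False) -> Dict[str, Path]:
    """Run all stages from a loaded run configuration; returns artifact paths."""
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    design: ExperimentDesign = config["design"]
    training: TrainingConfig = config["training"]
    artifacts = {
        "dataset": out_dir / "dataset.h5",
        "model": out_dir / "model.npz",
        "metrics": out_dir / "metrics.csv",
        "rf": out_dir / "rf_properties.csv",
        "tuning": out_dir / "tuning.csv",
    }

    def _stage(name, path, fn):
        if path.exists() and not force:
            log.info("stage=%s seed=%d status=skipped artifact=%s", name, seed, path)
            return
        t0 = time.perf_counter()
        try:
            fn(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info(
            "stage=%s seed=%d elapsed_s=%.1f artifact=%s",
            name, seed, time.perf_counter() - t0, path,
        )

    spec = neuron_spec_from_config(config.get("neuron", {}), design)

    def do_simulate(path):
        ds = build_experiment(spec, design, seed)
        cio.write_dataset(ds, path)

    def do_fit(path):
        ds = cio.read_dataset(artifacts["dataset"])
        model, report = fit_model(ds, dataclasses.replace(training, seed=seed))
        model.meta.update(
            {
                "deg_per_pixel": spec.deg_per_pixel,
                "frame_rate_hz": design.frame_rate_hz,
                "reg_vaf": report.reg_vaf,
                "chosen_filter_size": report.chosen_filter_size,
            }
        )
        save_model(model, path)

    def do_evaluate(path):
        ds = cio.read_dataset(artifacts["dataset"])
        model = load_model(artifacts["model"])
        res = evaluate_model(model, ds, "test")
        res_reg = evaluate_model(model, ds, "reg")
        pd.DataFrame(
            [
                {
                    "raw_vaf": res.raw_vaf,
                    "r2_model": res.r2_model,
                    "r2_neuron": res.r2_neuron,
                    "explainable_vaf": res.explainable_vaf,
                    "r2_neuron_reg": res_reg.r2_neuron,
                }
            ]
        ).to_csv(path, index=False)

    def do_characterize(path):
        model = load_model(artifacts["model"])
        summary = characterize_model(model)
        g, bw, tf = summary["gabor"], summary["bandwidth"], summary["temporal_fit"]
        pd.DataFrame(
            [
                {
                    "optimal_lag": summary["optimal_lag"],
                    "gabor_A": g.A, "gabor_f_cpd": g.f, "gabor_theta_deg": g.theta,
                    "gabor_phi_rad": g.phi, "gabor_sigma_xp_deg": g.sigma_xp,
                    "gabor_sigma_yp_deg": g.sigma_yp, "gabor_x0_deg": g.x0,
                    "gabor_y0_deg": g.y0, "fvu_spatial": g.fvu,
                    "rf_size_deg": bw.rf_size, "nx": bw.nx, "ny": bw.ny,
                    "optimal_tf_hz": tf.optimal_tf, "fvu_temporal": tf.fvu,
                }
            ]
        ).to_csv(path, index=False)

    def do_gratings(path):
        model = load_model(artifacts["model"])
        sweep_cfg = config.get("sweep", {}) or {}
        deg = model.meta.get("deg_per_pixel", spec.deg_per_pixel)
        sfs = sweep_cfg.get("spatial_frequencies")
        if sfs is None:
            nyq = 1.0 / (2 * deg)
            sfs = list(np.geomspace(nyq / 16, nyq / 1.5, 8))
        sweep = default_sf_sweep(
            sfs,
            tf=float(sweep_cfg.get("tf", 2.0)),
            orientation=float(sweep_cfg.get("orientation", 0.0)),
            contrast=float(sweep_cfg.get("contrast", 1.0)),
            frame_rate_hz=design.frame_rate_hz,
        )
        curve = predict_tuning_curve(model, sweep, deg)
        best = sweep[int(np.argmax(curve.response))]
        resp = simulate_grating_response(model, best, deg)
        try:
            acdc = ac_dc_ratio(resp, best.temporal_frequency, best.frame_rate_hz)
            label = classify_simple_complex(acdc)
        except ValueError:
            acdc, label = np.nan, "undefined"
        df = pd.DataFrame(
            {"spatial_frequency_cpd": curve.abscissa, "normalized_response": curve.response}
        )
        df["acdc_at_peak"] = acdc
        df["classification"] = label
        df.to_csv(path, index=False)

    _stage("simulate", artifacts["dataset"], do_simulate)
    _stage("fit", artifacts["model"], do_fit)
    _stage("evaluate", artifacts["metrics"], do_evaluate)
    _stage("characterize", artifacts["rf"], do_characterize)
    _stage("predict-gratings", artifacts["tuning"], do_gratings)
    return artifacts
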