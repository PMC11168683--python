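"""Dataset container I/O (HDF5 primary, NPZ fallback) and run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Dict

import h5py
import numpy as np
import yaml

from .fitting import TrainingConfig
from .model import StimulusEnsemble, TrialResponses
from .synth import Dataset, ExperimentDesign

SCHEMA = "convrf-dataset-1"
SPLITS = ("train", "reg", "test")


def write_dataset(dataset: Dataset, path) -> None:
    """Lossless round trip of all arrays and metadata; format by extension."""
    dataset.validate()
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(dataset, path)
    elif path.suffix == ".npz":
        _write_npz(dataset, path)
    else:
        raise ValueError(f"unsupported container extension {path.suffix!r}")


def read_dataset(path) -> Dataset:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        ds = _read_h5(path)
    elif path.suffix == ".npz":
        ds = _read_npz(path)
    else:
        raise ValueError(f"unsupported container extension {path.suffix!r}")
    ds.validate()
    return ds


def _write_h5(dataset: Dataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["meta"] = json.dumps(dataset.meta, default=float)
        for split, ens_list in dataset.stimuli.items():
            grp = f.create_group(f"stimuli/{split}")
            for i, ens in enumerate(ens_list):
                d = grp.create_dataset(f"ens{i}", data=ens.frames)
                d.attrs["frame_rate_hz"] = ens.frame_rate_hz
                d.attrs["deg_per_pixel"] = ens.deg_per_pixel
                d.attrs["ensemble_id"] = ens.ensemble_id
        for split, resp_list in dataset.responses.items():
            grp = f.create_group(f"responses/{split}")
            for i, resp in enumerate(resp_list):
                d = grp.create_dataset(f"ens{i}", data=resp.rates)
                d.attrs["frame_rate_hz"] = resp.frame_rate_hz


def _read_h5(path: Path) -> Dataset:
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema")
        if schema != SCHEMA:
            raise ValueError(f"schema mismatch: file has {schema!r}, reader expects {SCHEMA!r}")
        for group in ("stimuli", "responses"):
            if group not in f:
                raise ValueError(f"container missing required group {group!r}")
        meta = json.loads(f.attrs["meta"])
        stimuli, responses = {}, {}
        for split in f["stimuli"]:
            ens_list = []
            grp = f[f"stimuli/{split}"]
            for name in sorted(grp, key=lambda s: int(s[3:])):
                d = grp[name]
                ens_list.append(
                    StimulusEnsemble(
                        frames=d[()],
                        frame_rate_hz=float(d.attrs["frame_rate_hz"]),
                        deg_per_pixel=float(d.attrs["deg_per_pixel"]),
                        ensemble_id=str(d.attrs["ensemble_id"]),
                    )
                )
            stimuli[split] = ens_list
        for split in f["responses"]:
            grp = f[f"responses/{split}"]
            responses[split] = [
                TrialResponses(grp[name][()], float(grp[name].attrs["frame_rate_hz"]))
                for name in sorted(grp, key=lambda s: int(s[3:]))
            ]
    return Dataset(stimuli=stimuli, responses=responses, meta=meta)


def _write_npz(dataset: Dataset, path: Path) -> None:
    arrays = {"schema": np.array(SCHEMA), "meta": np.array(json.dumps(dataset.meta, default=float))}
    for split, ens_list in dataset.stimuli.items():
        for i, ens in enumerate(ens_list):
            arrays[f"stim_{split}_{i}"] = ens.frames
            arrays[f"stimmeta_{split}_{i}"] = np.array(
                [ens.frame_rate_hz, ens.deg_per_pixel]
            )
            arrays[f"stimid_{split}_{i}"] = np.array(ens.ensemble_id)
    for split, resp_list in dataset.responses.items():
        for i, resp in enumerate(resp_list):
            arrays[f"resp_{split}_{i}"] = resp.rates
            arrays[f"respmeta_{split}_{i}"] = np.array([resp.frame_rate_hz])
    np.savez(path, **arrays)


def _read_npz(path: Path) -> Dataset:
    with np.load(path, allow_pickle=False) as f:
        if "schema" not in f or str(f["schema"]) != SCHEMA:
            raise ValueError(f"schema mismatch reading {path}")
        if not any(key.startswith("resp_") for key in f.files):
            raise ValueError("container missing required group 'responses'")
        meta = json.loads(str(f["meta"]))
        stimuli: Dict[str, list] = {}
        responses: Dict[str, list] = {}
        for key in sorted(f.files):
            if key.startswith("stim_"):
                _, split, i = key.split("_")
                fr, dpp = f[f"stimmeta_{split}_{i}"]
                stimuli.setdefault(split, []).append(
                    StimulusEnsemble(f[key], float(fr), float(dpp), str(f[f"stimid_{split}_{i}"]))
                )
            elif key.startswith("resp_"):
                _, split, i = key.split("_")
                responses.setdefault(split, []).append(
                    TrialResponses(f[key], float(f[f"respmeta_{split}_{i}"][0]))
                )
    return Dataset(stimuli=stimuli, responses=responses, meta=meta)


# --------------------------------------------------------------------------
# run configuration

_DESIGN_KEYS = {f.name for f in fields(ExperimentDesign)}
_TRAIN_KEYS = {f.name for f in fields(TrainingConfig)}
_TOP_KEYS = {"design", "training", "sweep", "neuron", "seed", "out_dir"}


def load_run_config(path) -> Dict:
    """Load a YAML run configuration, rejecting unknown keys.

    Sections: design (ExperimentDesign fields), training (TrainingConfig
    fields), neuron (synthetic neuron parameters), sweep (grating sweep),
    plus top-level seed and out_dir.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for section, allowed in (("design", _DESIGN_KEYS), ("training", _TRAIN_KEYS)):
        extra = set(raw.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
    cfg = {
        "design": ExperimentDesign(**raw.get("design", {})),
        "training": TrainingConfig(**raw.get("training", {})),
        "neuron": raw.get("neuron", {}),
        "sweep": raw.get("sweep", {}),
        "seed": int(raw.get("seed", 0)),
        "out_dir": raw.get("out_dir", "."),
    }
    return cfg
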