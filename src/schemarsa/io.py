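"""HDF5/CSV data contracts tying the pipeline stages together.

One HDF5 bundle per experiment with groups ``/design``, ``/data``,
``/rdms``, ``/glm``, ``/stats``; flat CSV mirrors for human inspection.
Every simulated dataset carries its ground truth (effect weights, noise
scale, seed) in a ``ground_truth`` subgroup so outputs are reconstructible
from config + seeds alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import StimulusSet
from .glm import GlmSuiteResult
from .rdm import RDMSeries
from .stats import StatMap
from .synthetic import EegDataset, EegStudy, FmriDataset, GroundTruth


def _write_truth(group: h5py.Group, truth: GroundTruth, seed) -> None:
    g = group.require_group("ground_truth")
    for key, value in truth.as_dict()["weights"].items():
        g.attrs[f"weight_{key}"] = value
    for key in ("unique_weight", "noise_scale", "onset_ms", "peak_ms", "decay_ms"):
        g.attrs[key] = getattr(truth, key)
    g.attrs["seed"] = -1 if seed is None else int(seed)


def _read_truth(group: h5py.Group) -> tuple[GroundTruth, int | None]:
    g = group["ground_truth"]
    weights = {
        k[len("weight_"):]: float(v) for k, v in g.attrs.items() if k.startswith("weight_")
    }
    truth = GroundTruth(
        weights=weights,
        unique_weight=float(g.attrs["unique_weight"]),
        noise_scale=float(g.attrs["noise_scale"]),
        onset_ms=float(g.attrs["onset_ms"]),
        peak_ms=float(g.attrs["peak_ms"]),
        decay_ms=float(g.attrs["decay_ms"]),
    )
    seed = int(g.attrs["seed"])
    return truth, (None if seed == -1 else seed)


def write_design(f: h5py.File, stimulus_set: StimulusSet) -> None:
    g = f.require_group("design")
    for col in ("scene_id", "vertical", "horizontal"):
        g.create_dataset(col, data=getattr(stimulus_set, col))
    g.create_dataset(
        "scene_type", data=np.array(stimulus_set.scene_type, dtype="S16")
    )


def read_design(f: h5py.File) -> StimulusSet:
    g = f["design"]
    frame = pd.DataFrame(
        {
            "condition_index": np.arange(len(g["scene_id"])),
            "scene_id": g["scene_id"][:],
            "scene_type": [s.decode() for s in g["scene_type"][:]],
            "vertical": g["vertical"][:],
            "horizontal": g["horizontal"][:],
        }
    )
    return StimulusSet.from_frame(frame)


def write_fmri(f: h5py.File, dataset: FmriDataset) -> None:
    g = f.require_group(f"data/fmri/{dataset.roi}")
    g.create_dataset("patterns", data=dataset.data)
    g.attrs["n_reps_per_run"] = dataset.n_reps_per_run
    _write_truth(g, dataset.truth, dataset.seed)


def read_fmri(f: h5py.File, roi: str, stimulus_set: StimulusSet) -> FmriDataset:
    g = f[f"data/fmri/{roi}"]
    truth, seed = _read_truth(g)
    return FmriDataset(
        g["patterns"][:], stimulus_set, truth, seed=seed, roi=roi,
        n_reps_per_run=int(g.attrs["n_reps_per_run"]),
    )


def fmri_rois(f: h5py.File) -> list[str]:
    return sorted(f["data/fmri"].keys()) if "data/fmri" in f else []


def write_eeg(f: h5py.File, study: EegStudy) -> None:
    g = f.require_group("data/eeg")
    g.create_dataset("times", data=study.subjects[0].times)
    g.attrs["sfreq"] = study.subjects[0].sfreq
    g.attrs["channel_names"] = json.dumps(list(study.subjects[0].channel_names))
    for ds in study.subjects:
        sg = g.create_group(f"subject{ds.subject:03d}")
        sg.create_dataset("epochs", data=ds.epochs)
        sg.create_dataset("labels", data=ds.labels)
    _write_truth(g, study.truth, study.seed)


def read_eeg(f: h5py.File, stimulus_set: StimulusSet) -> EegStudy:
    g = f["data/eeg"]
    times = g["times"][:]
    sfreq = float(g.attrs["sfreq"])
    names = tuple(json.loads(g.attrs["channel_names"]))
    truth, seed = _read_truth(g)
    subjects = []
    for key in sorted(k for k in g.keys() if k.startswith("subject")):
        sg = g[key]
        subjects.append(
            EegDataset(sg["epochs"][:], sg["labels"][:], times.copy(), sfreq,
                       names, subject=int(key[len("subject"):]))
        )
    return EegStudy(subjects, stimulus_set, truth, seed=seed)


def write_rdm_stack(f: h5py.File, name: str, values: np.ndarray,
                    times: np.ndarray | None = None, kind: str = "") -> None:
    g = f.require_group("rdms")
    if name in g:
        del g[name]
    d = g.create_dataset(name, data=values)
    d.attrs["kind"] = kind
    if times is not None:
        d.attrs["times"] = times


def read_rdm_stack(f: h5py.File, name: str) -> tuple[np.ndarray, np.ndarray | None]:
    d = f[f"rdms/{name}"]
    times = d.attrs["times"][:] if "times" in d.attrs else None
    return d[:], times


def write_glm(f: h5py.File, name: str, result: GlmSuiteResult) -> None:
    g = f.require_group(f"glm/{name}")
    g.create_dataset("betas", data=result.betas)
    g.attrs["predictor_names"] = json.dumps(result.predictor_names)
    g.attrs["analysis"] = result.analysis
    g.attrs["n_pairs"] = result.n_pairs
    if result.units is not None:
        g.create_dataset("units", data=np.asarray(result.units, dtype=float))


def read_glm(f: h5py.File, name: str) -> GlmSuiteResult:
    g = f[f"glm/{name}"]
    return GlmSuiteResult(
        betas=g["betas"][:],
        predictor_names=json.loads(g.attrs["predictor_names"]),
        analysis=str(g.attrs["analysis"]),
        n_pairs=int(g.attrs["n_pairs"]),
        units=g["units"][:] if "units" in g else None,
    )


def write_statmap(f: h5py.File, name: str, stat: StatMap) -> None:
    g = f.require_group(f"stats/{name}")
    g.create_dataset("t", data=stat.t)
    g.create_dataset("p_uncorrected", data=stat.p_uncorrected)
    g.create_dataset("sig_mask", data=stat.sig_mask.astype(np.int8))
    if stat.tfce is not None:
        g.create_dataset("tfce", data=stat.tfce)
    if stat.z is not None:
        g.create_dataset("z", data=stat.z)
    if stat.times is not None:
        g.create_dataset("times", data=stat.times)
    for attr in ("onset_ms", "peak_ms", "peak_t"):
        value = getattr(stat, attr)
        if value is not None:
            g.attrs[attr] = value


# ---------------------------------------------------------------- CSV mirrors

def statmap_frame(stat: StatMap, unit_name: str = "time_ms") -> pd.DataFrame:
    axis = stat.times if stat.times is not None else np.arange(len(stat.t))
    frame = pd.DataFrame({unit_name: axis, "t": stat.t,
                          "p_uncorrected": stat.p_uncorrected,
                          "significant": stat.sig_mask.astype(int)})
    if stat.tfce is not None:
        frame["tfce"] = stat.tfce
    if stat.z is not None:
        frame["z"] = stat.z
    return frame


def glm_long_frame(result: GlmSuiteResult, unit_name: str = "unit") -> pd.DataFrame:
    """Long-format betas: subject, unit, predictor, beta."""
    S, U, P = result.betas.shape
    units = result.units if result.units is not None else np.arange(U)
    rows = []
    for s in range(S):
        for u in range(U):
            for p, pname in enumerate(result.predictor_names):
                rows.append({"subject": s, unit_name: units[u],
                             "predictor": pname, "beta": result.betas[s, u, p]})
    return pd.DataFrame(rows)


def write_rdm_csv(path: str | Path, values: np.ndarray) -> None:
    pd.DataFrame(values).to_csv(path, index=True)


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
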