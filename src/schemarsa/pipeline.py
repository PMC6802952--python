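"""End-to-end pipeline: simulate -> RDMs -> GLM suite -> statistics -> MDS.

A :class:`RunConfig` fully determines a run: every stochastic stage has an
explicit seed, and rerunning an identical config reproduces every output
bit for bit. Stages are exposed individually (the CLI subcommands call the
same functions), so running them one by one against a shared bundle path
equals one ``run_pipeline`` call.

The demo fMRI simulation plants ROI-specific structure mirroring the
qualitative findings the package is built to detect: vertical-location and
category structure in OPA, category structure in PPA, and only stimulus-
unique structure in V1.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import io as bundle_io
from .design import build_stimulus_set
from .eeg import POSTERIOR_17, decode_series, preprocess_epochs, select_channels
from .fmri import dataset_rdms
from .glm import run_glm_suite
from .rdm import RDMSeries
from .stats import PermutationScheme, bonferroni, group_ttest, sign_permutation_correct
from .synthetic import (
    EegDataset,
    EegStudy,
    FmriDataset,
    GroundTruth,
    simulate_eeg,
    simulate_features,
    simulate_fmri,
)
from .features import bank_rdms
from .viz import mds_movie


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending unit."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class DesignBlock:
    n_scenes_per_type: int = 3
    n_vertical: int = 3
    n_horizontal: int = 2


@dataclass
class SimulationBlock:
    modalities: tuple[str, ...] = ("fmri", "eeg")
    n_subjects_fmri: int = 6
    n_voxels: int = 60
    n_runs: int = 6
    n_subjects_eeg: int = 4
    n_channels: int = 17
    n_reps: int = 6
    time_start_ms: float = -100.0
    time_stop_ms: float = 300.0
    time_step_ms: float = 5.0
    weights: dict = field(
        default_factory=lambda: {"vertical": 1.0, "horizontal": 0.0, "category": 1.0}
    )
    unique_weight: float = 1.0
    noise_scale: float = 5.0
    onset_ms: float = 50.0
    peak_ms: float = 200.0
    seed_fmri: int | None = None
    seed_eeg: int | None = None
    seed_features: int | None = None
    n_layers: int = 18


@dataclass
class RdmBlock:
    tr_shift: int = 3
    channels: tuple[str, ...] | None = None  # None = all simulated channels
    shrinkage: float = 0.05


@dataclass
class GlmBlock:
    analyses: tuple[str, ...] = ("full",)
    zscore_criterion: bool = True


@dataclass
class StatsBlock:
    n_permutations: int = 1000
    threshold_z: float = 1.64
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_steps: int = 100
    seed: int | None = None


@dataclass
class RunConfig:
    output_dir: str = "schemarsa_out"
    design: DesignBlock = field(default_factory=DesignBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    rdm: RdmBlock = field(default_factory=RdmBlock)
    glm: GlmBlock = field(default_factory=GlmBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    make_movie: bool = False
    movie_fps: int = 20

    def validate(self) -> None:
        missing = []
        if "fmri" in self.simulation.modalities and self.simulation.seed_fmri is None:
            missing.append("simulation.seed_fmri")
        if "eeg" in self.simulation.modalities and self.simulation.seed_eeg is None:
            missing.append("simulation.seed_eeg")
        if any(a in ("dnn_resid", "combined") for a in self.glm.analyses):
            if self.simulation.seed_features is None:
                missing.append("simulation.seed_features")
        if self.stats.seed is None:
            missing.append("stats.seed")
        if missing:
            raise ValueError(f"config is missing explicit seeds: {missing}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        blocks = {
            "design": DesignBlock,
            "simulation": SimulationBlock,
            "rdm": RdmBlock,
            "glm": GlmBlock,
            "stats": StatsBlock,
        }
        kwargs = dict(payload)
        for name, block_cls in blocks.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                block = kwargs[name]
                for key in ("modalities", "analyses", "channels"):
                    if key in block and isinstance(block[key], list):
                        block[key] = tuple(block[key])
                kwargs[name] = block_cls(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


#: ROI-specific planted effects of the demo fMRI study
ROI_WEIGHTS = {
    "OPA": {"vertical": 1.0, "horizontal": 0.0, "category": 1.0},
    "PPA": {"vertical": 0.0, "horizontal": 0.0, "category": 1.0},
    "V1": {"vertical": 0.0, "horizontal": 0.0, "category": 0.0},
}


def _seeded(base: int, offset: int) -> int:
    return (int(base) * 1_000_003 + offset) % (2**31 - 1)


def _stable_hash(text: str) -> int:
    # hash() is salted per process; seeds must be reproducible across runs
    return int(hashlib.sha256(text.encode()).hexdigest()[:6], 16)


def subset_runs(dataset: FmriDataset, runs) -> FmriDataset:
    """Run subset (e.g. the first experiment half); empty selection errors."""
    runs = list(runs)
    if not runs:
        raise ValueError("run selection must not be empty")
    return FmriDataset(
        dataset.data[:, :, runs, :], dataset.stimulus_set, dataset.truth,
        seed=dataset.seed, roi=dataset.roi, n_reps_per_run=dataset.n_reps_per_run,
    )


def subset_trials(dataset: EegDataset, selector) -> EegDataset:
    """Trial subset by index array, boolean mask, or 'first_half'/'second_half'."""
    if isinstance(selector, str):
        half = dataset.n_trials // 2
        if selector == "first_half":
            idx = np.arange(half)
        elif selector == "second_half":
            idx = np.arange(half, dataset.n_trials)
        else:
            raise ValueError(f"unknown selector {selector!r}")
    else:
        idx = np.asarray(selector)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
    if len(idx) == 0:
        raise ValueError("trial selection must not be empty")
    return EegDataset(
        dataset.epochs[idx], dataset.labels[idx], dataset.times.copy(),
        dataset.sfreq, dataset.channel_names, dataset.subject,
    )


def subset_conditions(dataset, condition_indices):
    """Condition subset (e.g. vertical levels top+middle for pairwise contrasts).

    Works on FmriDataset and EegDataset; returns (subset dataset, subset
    stimulus set). Condition indices are renumbered consecutively.
    """
    idx = list(condition_indices)
    if not idx:
        raise ValueError("condition selection must not be empty")
    sset = dataset.stimulus_set.subset(idx) if hasattr(dataset, "stimulus_set") else None
    if isinstance(dataset, FmriDataset):
        return (
            FmriDataset(dataset.data[:, idx], sset, dataset.truth, seed=dataset.seed,
                        roi=dataset.roi, n_reps_per_run=dataset.n_reps_per_run),
            sset,
        )
    if isinstance(dataset, EegDataset):
        keep = np.isin(dataset.labels, idx)
        relabel = {c: k for k, c in enumerate(idx)}
        labels = np.array([relabel[c] for c in dataset.labels[keep]])
        return (
            EegDataset(dataset.epochs[keep], labels, dataset.times.copy(),
                       dataset.sfreq, dataset.channel_names, dataset.subject),
            None,
        )
    raise TypeError(f"cannot subset conditions of {type(dataset).__name__}")


# ------------------------------------------------------------------- stages

def stage_simulate(config: RunConfig, bundle: Path) -> None:
    sim = config.simulation
    sset = build_stimulus_set(
        config.design.n_scenes_per_type, config.design.n_vertical,
        config.design.n_horizontal,
    )
    with h5py.File(bundle, "w") as f:
        bundle_io.write_design(f, sset)
        if "fmri" in sim.modalities:
            for k, (roi, weights) in enumerate(ROI_WEIGHTS.items()):
                truth = GroundTruth(
                    weights=weights, unique_weight=sim.unique_weight,
                    noise_scale=sim.noise_scale, onset_ms=sim.onset_ms,
                    peak_ms=sim.peak_ms,
                )
                ds = simulate_fmri(
                    sset, sim.n_subjects_fmri, sim.n_voxels, sim.n_runs,
                    truth, seed=_seeded(sim.seed_fmri, k), roi=roi,
                )
                bundle_io.write_fmri(f, ds)
        if "eeg" in sim.modalities:
            truth = GroundTruth(
                weights=sim.weights, unique_weight=sim.unique_weight,
                noise_scale=sim.noise_scale, onset_ms=sim.onset_ms,
                peak_ms=sim.peak_ms,
            )
            names = POSTERIOR_17 if sim.n_channels == 17 else None
            study = simulate_eeg(
                sset, sim.n_subjects_eeg, sim.n_channels, sim.n_reps,
                times=np.arange(sim.time_start_ms, sim.time_stop_ms + 1e-9,
                                sim.time_step_ms),
                truth=truth, seed=sim.seed_eeg, channel_names=names,
            )
            bundle_io.write_eeg(f, study)


def stage_rdm_fmri(config: RunConfig, bundle: Path) -> None:
    with h5py.File(bundle, "a") as f:
        sset = bundle_io.read_design(f)
        for roi in bundle_io.fmri_rois(f):
            ds = bundle_io.read_fmri(f, roi, sset)
            bundle_io.write_rdm_stack(
                f, f"fmri_{roi}", dataset_rdms(ds), kind="crossval_corr_diff"
            )


def stage_rdm_eeg(config: RunConfig, bundle: Path) -> None:
    with h5py.File(bundle, "a") as f:
        sset = bundle_io.read_design(f)
        study = bundle_io.read_eeg(f, sset)
        stacks = []
        for ds in study.subjects:
            ds = preprocess_epochs(ds, (ds.times[0], 0.0))
            if config.rdm.channels:
                ds = select_channels(ds, list(config.rdm.channels))
            series = decode_series(ds, shrinkage=config.rdm.shrinkage)
            stacks.append(series.values)
        bundle_io.write_rdm_stack(
            f, "eeg", np.stack(stacks), times=series.times, kind="decoding_accuracy"
        )


def stage_glm(config: RunConfig, bundle: Path) -> None:
    with h5py.File(bundle, "a") as f:
        sset = bundle_io.read_design(f)
        covariates = None
        if any(a in ("dnn_resid", "combined") for a in config.glm.analyses):
            bank = simulate_features(
                sset, n_layers=config.simulation.n_layers,
                seed=config.simulation.seed_features,
            )
            covariates = bank_rdms(bank)
        for analysis in config.glm.analyses:
            cov = covariates if analysis in ("dnn_resid", "combined") else None
            for name in list(f["rdms"]):
                values, times = bundle_io.read_rdm_stack(f, name)
                if values.ndim == 4:  # (subjects, times, n, n)
                    neural = [
                        RDMSeries(values[s], times) for s in range(values.shape[0])
                    ]
                else:
                    neural = values
                result = run_glm_suite(
                    neural, sset, analysis=analysis, covariate_bank=cov,
                    zscore_criterion=config.glm.zscore_criterion,
                )
                key = f"{name}__{analysis}"
                if f"glm/{key}" in f:
                    del f[f"glm/{key}"]
                bundle_io.write_glm(f, key, result)


def stage_stats(config: RunConfig, bundle: Path) -> dict:
    summary = {}
    sb = config.stats
    with h5py.File(bundle, "a") as f:
        roi_records = {}
        for key in list(f["glm"]):
            result = bundle_io.read_glm(f, key)
            if result.units is None:  # ROI-style: one unit per stack
                roi_records.setdefault(result.analysis, []).append((key, result))
                continue
            for p, pname in enumerate(result.predictor_names):
                stat = sign_permutation_correct(
                    result.betas[:, :, p],
                    PermutationScheme(sb.n_permutations,
                                     seed=_seeded(sb.seed, _stable_hash(key + pname)),
                                     threshold_z=sb.threshold_z),
                    times=np.asarray(result.units, float),
                    e=sb.tfce_e, h=sb.tfce_h, n_steps=sb.tfce_steps,
                )
                name = f"{key}__{pname}"
                if f"stats/{name}" in f:
                    del f[f"stats/{name}"]
                bundle_io.write_statmap(f, name, stat)
                summary[name] = {
                    "onset_ms": stat.onset_ms, "peak_ms": stat.peak_ms,
                    "peak_t": stat.peak_t,
                }
        # fMRI: one-tailed t-tests, Bonferroni across the ROIs of each analysis
        for analysis, records in roi_records.items():
            names = records[0][1].predictor_names
            for p, pname in enumerate(names):
                betas = np.column_stack([r.betas[:, 0, p] for _, r in records])
                stat = group_ttest(betas)
                p_adj, sig = bonferroni(stat.p_uncorrected, m=len(records))
                for k, (key, _) in enumerate(records):
                    summary[f"{key}__{pname}"] = {
                        "t": float(stat.t[k]),
                        "p_uncorrected": float(stat.p_uncorrected[k]),
                        "p_bonferroni": float(p_adj[k]),
                        "significant": bool(sig[k]),
                    }
                    g = f.require_group(f"stats/{key}__{pname}")
                    for attr, value in summary[f"{key}__{pname}"].items():
                        g.attrs[attr] = value
    return summary


def stage_export_csv(config: RunConfig, bundle: Path, out_dir: Path) -> None:
    with h5py.File(bundle, "r") as f:
        sset = bundle_io.read_design(f)
        sset.to_frame().to_csv(out_dir / "stimulus_set.csv", index=False)
        for key in list(f.get("glm", [])):
            result = bundle_io.read_glm(f, key)
            unit = "time_ms" if result.units is not None else "unit"
            bundle_io.glm_long_frame(result, unit).to_csv(
                out_dir / f"glm_{key}.csv", index=False
            )


def stage_movie(config: RunConfig, bundle: Path, out_dir: Path) -> None:
    with h5py.File(bundle, "r") as f:
        sset = bundle_io.read_design(f)
        if "rdms/eeg" not in f:
            raise ValueError("no EEG RDM series in the bundle; run rdm-eeg first")
        values, times = bundle_io.read_rdm_stack(f, "eeg")
    series = RDMSeries(values.mean(axis=0), times)
    mds_movie(series, out_dir / "mds_movie.gif", stimulus_set=sset,
              fps=config.movie_fps, seed=config.stats.seed, smooth_ms=15.0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write the result bundle.

    Returns a summary dict (stat highlights plus file locations). Raises
    :class:`PipelineError` naming the failing stage.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = out_dir / "bundle.h5"
    collected: list[str] = []
    summary: dict = {}

    stages = [("simulate", lambda: stage_simulate(config, bundle))]
    if "fmri" in config.simulation.modalities:
        stages.append(("rdm-fmri", lambda: stage_rdm_fmri(config, bundle)))
    if "eeg" in config.simulation.modalities:
        stages.append(("rdm-eeg", lambda: stage_rdm_eeg(config, bundle)))
    stages.append(("glm", lambda: stage_glm(config, bundle)))

    for name, fn in stages:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fn()
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        collected.extend(f"{name}: {w.message}" for w in caught)

    try:
        summary["stats"] = stage_stats(config, bundle)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    stage_export_csv(config, bundle, out_dir)
    if config.make_movie and "eeg" in config.simulation.modalities:
        try:
            stage_movie(config, bundle, out_dir)
        except Exception as exc:
            raise PipelineError("mds", str(exc)) from exc

    import schemarsa

    bundle_io.write_manifest(
        out_dir / "provenance.json",
        {
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "package_version": schemarsa.__version__,
            "numpy_version": np.__version__,
        },
    )
    bundle_io.write_manifest(out_dir / "warnings.json", {"warnings": collected})
    summary["bundle"] = str(bundle)
    return summary
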