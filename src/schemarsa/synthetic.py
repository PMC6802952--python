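"""Synthetic fMRI-like, EEG-like and feature-model data with planted structure.

Every generator plants a known representational structure — shared
components for vertical level, horizontal level and scene category, plus a
condition-unique component — so each downstream stage (RDM construction,
GLM, group statistics) can be tested for recovery without recorded data.

Defaults mirror the study design: 30 fMRI subjects with 6 runs (each
condition measured in every run), 20 EEG subjects with 40 repetitions per
condition, 17 posterior channels, and epochs from -200 ms to 800 ms at
200 Hz. Component patterns/topographies are drawn independently per
subject, since the analysis is entirely within-subject.

Noise is i.i.d. Gaussian on runs (fMRI) or trials x channels x time (EEG);
an optional AR(1) flag adds temporal autocorrelation to the EEG noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from ._utils import rng_from_seed
from .design import InvalidDesignError, StimulusSet, build_category_rdm

PREDICTORS = ("vertical", "horizontal", "category")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effect sizes and noise model, recorded with every dataset.

    ``weights`` scales the shared component patterns per predictor
    (arbitrary pattern units; the component patterns themselves are unit
    i.i.d. Gaussian across voxels/channels). ``unique_weight`` scales a
    condition-specific pattern shared by no predictor. ``noise_scale`` is
    the SD of the additive measurement noise in the same units. For EEG,
    the effects are multiplied by a time course that is zero before
    ``onset_ms``, ramps linearly to 1 at ``peak_ms`` and then decays
    exponentially with time constant ``decay_ms``.
    """

    weights: Mapping[str, float] = field(
        default_factory=lambda: {"vertical": 1.0, "horizontal": 0.0, "category": 1.0}
    )
    unique_weight: float = 1.0
    noise_scale: float = 5.0
    onset_ms: float = 50.0
    peak_ms: float = 200.0
    decay_ms: float = 200.0
    timecourses: Mapping[str, np.ndarray] | None = None

    def weight(self, name: str) -> float:
        return float(self.weights.get(name, 0.0))

    def timecourse(self, name: str, times: np.ndarray) -> np.ndarray:
        """Effect time course over ``times`` (ms); in [0, 1], zero pre-stimulus."""
        if self.timecourses is not None and name in self.timecourses:
            tc = np.asarray(self.timecourses[name], dtype=float)
            if tc.shape != times.shape:
                raise ValueError("explicit time course must match the time axis")
            return tc
        return default_timecourse(times, self.onset_ms, self.peak_ms, self.decay_ms)

    def as_dict(self) -> dict:
        return {
            "weights": dict(self.weights),
            "unique_weight": self.unique_weight,
            "noise_scale": self.noise_scale,
            "onset_ms": self.onset_ms,
            "peak_ms": self.peak_ms,
            "decay_ms": self.decay_ms,
        }


def default_timecourse(
    times: np.ndarray, onset_ms: float, peak_ms: float, decay_ms: float
) -> np.ndarray:
    """Zero before onset, linear ramp to 1 at the peak, exponential decay after."""
    times = np.asarray(times, dtype=float)
    tc = np.zeros_like(times)
    rising = (times > onset_ms) & (times <= peak_ms)
    tc[rising] = (times[rising] - onset_ms) / max(peak_ms - onset_ms, 1e-9)
    after = times > peak_ms
    tc[after] = np.exp(-(times[after] - peak_ms) / decay_ms)
    return tc


@dataclass
class FmriDataset:
    """Condition x run x voxel activation patterns for every subject of one ROI."""

    data: np.ndarray  # (n_subjects, n_conditions, n_runs, n_voxels)
    stimulus_set: StimulusSet
    truth: GroundTruth
    seed: int | None = None
    roi: str = "ROI"
    n_reps_per_run: int = 4

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_runs(self) -> int:
        return self.data.shape[2]


@dataclass
class EegDataset:
    """Epoched trials for one subject: trial x channel x time, with labels."""

    epochs: np.ndarray  # (n_trials, n_channels, n_times)
    labels: np.ndarray  # (n_trials,) condition indices into the StimulusSet
    times: np.ndarray  # milliseconds, uniform
    sfreq: float  # Hz
    channel_names: tuple[str, ...]
    subject: int | None = None

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_conditions(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class EegStudy:
    """Multi-subject EEG dataset plus the ground truth it was generated from."""

    subjects: list[EegDataset]
    stimulus_set: StimulusSet
    truth: GroundTruth
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class FeatureBank:
    """Ordered per-layer activations over the full stimulus set."""

    layers: list[tuple[str, np.ndarray]]  # (layer id, condition x unit)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.layers]


def _condition_means(
    stimulus_set: StimulusSet, truth: GroundTruth, n_features: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-predictor condition x feature signal patterns for one subject."""
    n = len(stimulus_set)
    levels = {
        "vertical": stimulus_set.vertical,
        "horizontal": stimulus_set.horizontal,
        "category": stimulus_set.scene_id,
    }
    parts = {}
    for name in PREDICTORS:
        codes, inverse = np.unique(levels[name], return_inverse=True)
        components = rng.standard_normal((len(codes), n_features))
        parts[name] = truth.weight(name) * components[inverse]
    parts["unique"] = truth.unique_weight * rng.standard_normal((n, n_features))
    return parts


def simulate_fmri(
    stimulus_set: StimulusSet,
    n_subjects: int = 30,
    n_voxels: int = 100,
    n_runs: int = 6,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    roi: str = "ROI",
) -> FmriDataset:
    """Simulate run-wise voxel patterns with planted predictor structure.

    Each condition's mean pattern is a weighted sum of a per-vertical-level
    component, a per-horizontal-level component, a per-scene component and a
    condition-unique component (all subject-specific); each run adds i.i.d.
    Gaussian noise of SD ``truth.noise_scale``.
    """
    if n_runs < 2:
        raise InvalidDesignError("split-half cross-validation requires n_runs >= 2")
    truth = truth or GroundTruth()
    rng = rng_from_seed(seed)
    n = len(stimulus_set)
    data = np.empty((n_subjects, n, n_runs, n_voxels))
    for s in range(n_subjects):
        parts = _condition_means(stimulus_set, truth, n_voxels, rng)
        mean = sum(parts.values())
        noise = truth.noise_scale * rng.standard_normal((n, n_runs, n_voxels))
        data[s] = mean[:, None, :] + noise
    return FmriDataset(data, stimulus_set, truth, seed=seed, roi=roi)


def simulate_eeg(
    stimulus_set: StimulusSet,
    n_subjects: int = 20,
    n_channels: int = 17,
    n_reps: int = 40,
    times: np.ndarray | None = None,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    channel_names: Sequence[str] | None = None,
    ar_coefficient: float = 0.0,
) -> EegStudy:
    """Simulate epoched EEG with stimulus-locked planted structure.

    Condition topographies carrying vertical/horizontal/category structure
    are injected with the truth's effect time course (zero pre-stimulus),
    plus i.i.d. trial noise (optionally AR(1) over time via
    ``ar_coefficient``). The default time axis is -200..800 ms at 200 Hz.
    """
    if n_reps < 2:
        raise InvalidDesignError("leave-one-trial-out requires n_reps >= 2")
    truth = truth or GroundTruth()
    if times is None:
        times = np.arange(-200.0, 801.0, 5.0)
    times = np.asarray(times, dtype=float)
    if not (times < 0).any():
        raise InvalidDesignError(
            "time axis must include pre-stimulus samples (baseline correction)"
        )
    if channel_names is None:
        channel_names = tuple(f"CH{i + 1}" for i in range(n_channels))
    channel_names = tuple(channel_names)
    if len(channel_names) != n_channels:
        raise ValueError("channel_names length must equal n_channels")
    rng = rng_from_seed(seed)
    n = len(stimulus_set)
    labels = np.tile(np.arange(n), n_reps)
    n_trials = len(labels)
    sfreq = 1000.0 / float(np.diff(times)[0])
    subjects = []
    for s in range(n_subjects):
        parts = _condition_means(stimulus_set, truth, n_channels, rng)
        # condition x channel x time signal: each component has its own time course
        signal = np.zeros((n, n_channels, len(times)))
        for name, topo in parts.items():
            tc = truth.timecourse(name, times)
            signal += topo[:, :, None] * tc[None, None, :]
        noise = truth.noise_scale * rng.standard_normal(
            (n_trials, n_channels, len(times))
        )
        if ar_coefficient:
            for t in range(1, noise.shape[-1]):
                noise[..., t] += ar_coefficient * noise[..., t - 1]
        epochs = signal[labels] + noise
        subjects.append(
            EegDataset(epochs, labels.copy(), times.copy(), sfreq, channel_names, subject=s)
        )
    return EegStudy(subjects, stimulus_set, truth, seed=seed)


def simulate_features(
    stimulus_set: StimulusSet,
    n_layers: int = 18,
    layer_sizes: Sequence[int] | int = 100,
    category_gradient: float = 1.0,
    seed: int | None = None,
) -> FeatureBank:
    """Simulate a layered feature bank whose category structure grows with depth.

    Layer l's activations mix i.i.d. noise with per-scene prototype
    activations; the mixing coefficient increases linearly across layers up
    to ``category_gradient``, so with ``category_gradient=1`` the final
    layer is a pure function of the scene and its RDM is rank-equivalent to
    the category predictor.
    """
    if n_layers < 1:
        raise InvalidDesignError("n_layers must be >= 1")
    if not 0.0 <= category_gradient <= 1.0:
        raise ValueError("category_gradient must lie in [0, 1]")
    if np.isscalar(layer_sizes):
        layer_sizes = [int(layer_sizes)] * n_layers
    if len(layer_sizes) != n_layers:
        raise ValueError("layer_sizes must have one entry per layer")
    rng = rng_from_seed(seed)
    scene_ids = stimulus_set.scene_id
    scenes, inverse = np.unique(scene_ids, return_inverse=True)
    n = len(stimulus_set)
    layers = []
    for l, size in enumerate(layer_sizes):
        gamma = category_gradient * (l / (n_layers - 1) if n_layers > 1 else 1.0)
        prototypes = rng.standard_normal((len(scenes), size))
        noise = rng.standard_normal((n, size))
        activations = (1.0 - gamma) * noise + gamma * prototypes[inverse]
        layers.append((f"layer{l + 1:02d}", activations))
    return FeatureBank(layers)
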