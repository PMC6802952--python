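"""Time-resolved MDS visualization of RDM series and beta time courses.

The RDM series (typically group-averaged decoding RDMs) is smoothed with a
sliding boxcar window, each time point is embedded in two dimensions by
metric multidimensional scaling, and successive frames are rigidly aligned
(rotation/reflection via Procrustes; MDS solutions are rotation-
indeterminate) so the rendered movie is visually continuous. Condition
markers are colored by vertical level, with marker shape by scene type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.manifold import MDS

from .design import StimulusSet
from .rdm import RDMSeries


@dataclass
class MdsFrame:
    """2-D embedding of one RDM: centered coordinates, time stamp, stress."""

    coordinates: np.ndarray  # (n_conditions, 2)
    time: float
    stress: float


def smooth_series(series: RDMSeries, window_ms: float) -> RDMSeries:
    """Entrywise boxcar average over a centered window; truncated at edges.

    A window of one sample (window_ms <= time step) is the identity, and
    smoothing preserves the entrywise series mean up to edge truncation.
    """
    step = float(np.diff(series.times)[0]) if len(series) > 1 else window_ms
    if window_ms < step:
        raise ValueError(f"window ({window_ms} ms) must be >= the time step ({step} ms)")
    half = window_ms / 2.0
    values = np.empty_like(series.values)
    for k, t in enumerate(series.times):
        sel = np.abs(series.times - t) <= half + 1e-9
        values[k] = series.values[sel].mean(axis=0)
    return RDMSeries(values, series.times.copy(), kind=series.kind, subject=series.subject)


def _as_dissimilarity(values: np.ndarray) -> np.ndarray:
    """Nonnegative dissimilarities for MDS: shift by the minimum if negative.

    Cross-validated correlation RDMs can be negative under noise; decoding
    RDMs are used as-is. The diagonal is set to 0.
    """
    d = values.copy()
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(d.shape[0], dtype=bool)
    lo = d[off].min()
    if lo < 0:
        d[off] = d[off] - lo
    return d


def mds_frame(
    rdm_values: np.ndarray,
    n_dims: int = 2,
    seed: int | None = 0,
    time: float = 0.0,
    metric: bool = True,
) -> MdsFrame:
    """Metric (or non-metric) MDS embedding of one RDM; deterministic per seed."""
    d = _as_dissimilarity(np.asarray(rdm_values, dtype=float))
    if np.allclose(d, d[0, 1] * (~np.eye(len(d), dtype=bool))):
        warnings.warn("constant RDM; MDS configuration is degenerate",
                      RuntimeWarning, stacklevel=2)
    import inspect

    params = inspect.signature(MDS).parameters
    if "metric_mds" in params:  # sklearn >= 1.9 naming
        est = MDS(
            n_components=n_dims, metric="precomputed", metric_mds=metric,
            random_state=seed, normalized_stress=False, n_init=4, init="random",
        )
    else:
        est = MDS(
            n_components=n_dims, dissimilarity="precomputed", metric=metric,
            random_state=seed, normalized_stress=False, n_init=4,
        )
    coords = est.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    return MdsFrame(coords, time=float(time), stress=float(est.stress_))


def align_to(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly align centered coordinates to a reference (rotation/reflection).

    Pure orthogonal transform — within-frame pairwise distances are
    untouched.
    """
    R, _ = orthogonal_procrustes(coords, reference)
    return coords @ R


def mds_series(
    series: RDMSeries,
    seed: int | None = 0,
    smooth_ms: float | None = None,
    metric: bool = True,
) -> list[MdsFrame]:
    """MDS embedding per time point, chained-aligned for continuity."""
    if len(series) < 2:
        raise ValueError("an MDS movie needs >= 2 frames")
    if series.n_conditions < 2:
        raise ValueError("an MDS embedding needs >= 2 conditions")
    if smooth_ms is not None:
        series = smooth_series(series, smooth_ms)
    frames: list[MdsFrame] = []
    for k in range(len(series)):
        frame = mds_frame(series.values[k], seed=seed, time=series.times[k], metric=metric)
        if frames:
            frame.coordinates = align_to(frame.coordinates, frames[-1].coordinates)
        frames.append(frame)
    return frames


def frames_to_frame_table(frames: list[MdsFrame]) -> pd.DataFrame:
    rows = []
    for frame in frames:
        for c, (x, y) in enumerate(frame.coordinates):
            rows.append({"time_ms": frame.time, "condition_index": c,
                         "x": x, "y": y, "stress": frame.stress})
    return pd.DataFrame(rows)


def mds_movie(
    series: RDMSeries,
    out_path: str | Path,
    stimulus_set: StimulusSet | None = None,
    fps: int = 20,
    seed: int | None = 0,
    smooth_ms: float | None = 15.0,
    metric: bool = True,
) -> list[MdsFrame]:
    """Render the aligned MDS series to a GIF/MP4 plus a per-frame CSV.

    Returns the aligned frames so callers can quantify the embedding (e.g.
    within- vs between-vertical-level distances) without re-reading the file.
    """
    import imageio.v3 as iio
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = mds_series(series, seed=seed, smooth_ms=smooth_ms, metric=metric)
    out_path = Path(out_path)
    frames_to_frame_table(frames).to_csv(
        out_path.with_suffix("").with_name(out_path.stem + "_coords.csv"), index=False
    )

    colors = plt.get_cmap("viridis")
    lim = 1.05 * max(np.abs(f.coordinates).max() for f in frames)
    images = []
    for idx, frame in enumerate(frames):
        fig, ax = plt.subplots(figsize=(4, 4), dpi=80)
        try:
            for c in range(frame.coordinates.shape[0]):
                if stimulus_set is not None:
                    cond = stimulus_set[c]
                    n_levels = int(stimulus_set.vertical.max())
                    color = colors((cond.vertical - 1) / max(n_levels - 1, 1))
                    marker = "o" if cond.scene_type == "indoor" else "s"
                else:
                    color, marker = "C0", "o"
                ax.scatter(*frame.coordinates[c], color=color, marker=marker, s=60)
            ax.set_xlim(-lim, lim)
            ax.set_ylim(-lim, lim)
            ax.set_xticks([])
            ax.set_yticks([])
            ax.set_title(f"{frame.time:.0f} ms")
            fig.canvas.draw()
            buf = np.asarray(fig.canvas.buffer_rgba())[..., :3].copy()
        except Exception as exc:  # surface the failing frame
            plt.close(fig)
            raise RuntimeError(f"rendering frame {idx} ({frame.time} ms) failed") from exc
        plt.close(fig)
        images.append(buf)
    try:
        iio.imwrite(out_path, images, duration=1000 // fps, loop=0)
    except Exception as exc:
        raise RuntimeError(f"writing movie to {out_path} failed") from exc
    return frames
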