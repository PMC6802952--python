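"""Cross-validated correlation RDMs from run-wise fMRI voxel patterns.

The dissimilarity of two conditions is the split-half cross-validated
correlation difference: the data's runs are split into two equal halves,
patterns are averaged within each half, and within-condition correlations
(condition i in half A vs i in half B, likewise j) are compared against
between-condition correlations (i vs j across halves). All correlations
are Fisher-transformed before the subtraction

    d(i, j) = mean[z(r_ii), z(r_jj)] - mean[z(r_ij), z(r_ji)],

and the result is averaged over all possible equal splits of the runs
(10 unordered 3/3 partitions for 6 runs). Above-zero values indicate
discriminable conditions; pure noise gives an expected value of 0.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import FISHER_CLIP, corr_rows, fisher_z
from .rdm import NeuralRDM
from .synthetic import FmriDataset


def extract_trial_patterns(
    volume_series: np.ndarray,
    onsets: pd.DataFrame,
    tr_s: float,
    tr_shift: int = 3,
    n_conditions: int | None = None,
) -> np.ndarray:
    """Extract condition x run x voxel patterns from a volume time series.

    Each trial's pattern is the volume at the TR closest to its onset,
    shifted by ``tr_shift`` TRs (default 3, i.e. 6 s at TR = 2 s, to
    account for the hemodynamic delay; sweepable 0-5). Trials are averaged
    within condition x run. ``onsets`` needs columns ``run``,
    ``condition`` (0-based index into the stimulus set) and ``onset_s``.
    Trials whose shifted index falls beyond the series end are dropped
    with a warning.
    """
    if tr_shift < 0:
        raise ValueError("tr_shift must be >= 0")
    volume_series = np.asarray(volume_series, dtype=float)
    n_vols, n_voxels = volume_series.shape
    runs = np.unique(onsets["run"].to_numpy())
    conds = onsets["condition"].to_numpy(dtype=int)
    n_cond = n_conditions or int(conds.max()) + 1
    sums = np.zeros((n_cond, len(runs), n_voxels))
    counts = np.zeros((n_cond, len(runs)), dtype=int)
    run_index = {r: k for k, r in enumerate(runs)}
    n_dropped = 0
    for row in onsets.itertuples():
        idx = int(np.rint(row.onset_s / tr_s)) + tr_shift
        if idx >= n_vols:
            n_dropped += 1
            continue
        r = run_index[row.run]
        sums[int(row.condition), r] += volume_series[idx]
        counts[int(row.condition), r] += 1
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) whose shifted volume index fell "
            "beyond the series end",
            RuntimeWarning,
            stacklevel=2,
        )
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} condition-by-run cell(s) have no trials; "
            "their patterns are NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        patterns = sums / np.where(empty, np.nan, counts)[..., None]
    return patterns


def demean_by_run(patterns: np.ndarray) -> np.ndarray:
    """Subtract each voxel's mean across conditions, separately per run.

    Removes run-wise activation offsets; idempotent, and invariant to
    adding a constant to any single run.
    """
    patterns = np.asarray(patterns, dtype=float)
    return patterns - patterns.mean(axis=0, keepdims=True)


def half_splits(n_runs: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered equal partitions of the runs into two halves.

    For 2n runs there are C(2n, n)/2 such partitions (10 for 6 runs);
    run 0 is pinned to the first half so each partition appears once.
    """
    if n_runs % 2 or n_runs < 2:
        raise ValueError(f"split-half cross-validation needs an even run count >= 2, got {n_runs}")
    half = n_runs // 2
    splits = []
    rest = range(1, n_runs)
    for extra in combinations(rest, half - 1):
        first = (0,) + extra
        second = tuple(r for r in range(n_runs) if r not in first)
        splits.append((first, second))
    assert len(splits) == comb(n_runs, half) // 2
    return splits


class CrossValidatedRDM(BaseEstimator, TransformerMixin):
    """Transformer from condition x run x voxel patterns to a neural RDM.

    Parameters
    ----------
    demean : bool, default True
        Subtract the per-run mean across conditions before correlating.
    clip : float, default 1e-12
        Correlations are clipped to |r| <= 1 - clip before the Fisher
        transform so noise-free data stays finite.
    """

    def __init__(self, demean: bool = True, clip: float = FISHER_CLIP):
        self.demean = demean
        self.clip = clip

    def fit(self, X: np.ndarray, y=None) -> "CrossValidatedRDM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected condition x run x voxel patterns")
        if X.shape[1] % 2 or X.shape[1] < 2:
            raise ValueError(
                f"split-half cross-validation needs an even run count >= 2, got {X.shape[1]}"
            )
        self.n_conditions_ = X.shape[0]
        self.n_runs_ = X.shape[1]
        self.splits_ = half_splits(X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the (n_conditions, n_conditions) RDM with NaN diagonal."""
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if self.demean:
            X = demean_by_run(X)
        n = X.shape[0]
        acc = np.zeros((n, n))
        for first, second in self.splits_:
            a = X[:, first, :].mean(axis=1)
            b = X[:, second, :].mean(axis=1)
            z = fisher_z(corr_rows(a, b), clip=self.clip)
            within = 0.5 * (np.diag(z)[:, None] + np.diag(z)[None, :])
            between = 0.5 * (z + z.T)
            acc += within - between
        values = acc / len(self.splits_)
        values = 0.5 * (values + values.T)  # exact symmetry against fp noise
        np.fill_diagonal(values, np.nan)
        return values


def crossval_corr_rdm(
    patterns: np.ndarray,
    demean: bool = True,
    subject: int | None = None,
    unit: str | None = None,
) -> NeuralRDM:
    """Split-half cross-validated correlation RDM for one subject/ROI."""
    values = CrossValidatedRDM(demean=demean).transform(patterns)
    return NeuralRDM(values, kind="crossval_corr_diff", subject=subject, unit=unit)


def dataset_rdms(dataset: FmriDataset, demean: bool = True) -> np.ndarray:
    """Stack of cross-validated RDMs, one per subject: (n_subjects, n, n)."""
    est = CrossValidatedRDM(demean=demean)
    return np.stack([est.transform(dataset.data[s]) for s in range(dataset.n_subjects)])
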