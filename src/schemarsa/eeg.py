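"""Time-resolved pairwise decoding RDMs from epoched EEG.

Dissimilarity between two conditions at a time point is the accuracy of a
two-class linear discriminant analysis (LDA) classifier, trained and
tested with leave-one-trial-out cross-validation on the channel values at
that single time point. One trial of each condition is held out per fold,
the classifier is trained on the remainder, and accuracy is averaged
until every trial has been left out once. Chance level is 0.5.

The LDA uses the pooled within-class covariance with shrinkage toward a
scaled identity (default coefficient 0.05): with 17 channels and few
training trials the raw covariance can be singular. Decoding is
deterministic — there is no randomness anywhere in the procedure.

The implementation batches folds and condition pairs through rank-one
leave-one-out downdates of the class means and scatter matrices, so a
full RDM series is a handful of stacked 17 x 17 solves per time point
instead of millions of per-fold classifier fits.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import pair_indices
from .rdm import NeuralRDM, RDMSeries
from .synthetic import EegDataset

#: the 17 occipital and posterior sensors (10-10 system) used by default
POSTERIOR_17 = (
    "O1", "O2", "Oz", "PO3", "PO4", "PO7", "PO8", "POz",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "Pz",
)


def preprocess_epochs(
    data: EegDataset,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    target_rate: float | None = None,
) -> EegDataset:
    """Baseline-correct per trial and channel, then decimate to ``target_rate``.

    The baseline mean over ``baseline_window`` (ms, [start, end), within the
    pre-stimulus span) is subtracted from each trial and channel.
    Downsampling boxcar-averages consecutive samples; the original rate must
    be an integer multiple of the target (e.g. 1000 Hz -> 200 Hz, 5 ms step).
    """
    start, end = baseline_window
    if start >= end:
        raise ValueError("baseline window must have start < end")
    if start < data.times[0] or end > 0 + 1e-9:
        raise ValueError(
            "baseline window must lie within the pre-stimulus span "
            f"[{data.times[0]}, 0], got {baseline_window}"
        )
    in_window = (data.times >= start) & (data.times < end)
    if not in_window.any():
        raise ValueError("baseline window contains no samples")
    baseline = data.epochs[:, :, in_window].mean(axis=2, keepdims=True)
    epochs = data.epochs - baseline
    times = data.times
    sfreq = data.sfreq
    if target_rate is not None and target_rate != data.sfreq:
        factor = data.sfreq / target_rate
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"original rate {data.sfreq} Hz is not an integer multiple of "
                f"target rate {target_rate} Hz"
            )
        factor = int(round(factor))
        n_keep = (epochs.shape[2] // factor) * factor
        epochs = epochs[:, :, :n_keep].reshape(
            epochs.shape[0], epochs.shape[1], -1, factor
        ).mean(axis=3)
        times = times[:n_keep].reshape(-1, factor).mean(axis=1)
        sfreq = float(target_rate)
    return EegDataset(
        epochs, data.labels.copy(), times, sfreq, data.channel_names, data.subject
    )


def select_channels(data: EegDataset, names: list[str] | tuple[str, ...]) -> EegDataset:
    """Channel subset in the requested order (e.g. the 17 posterior sensors)."""
    if len(names) == 0:
        raise ValueError("channel selection must not be empty")
    missing = [n for n in names if n not in data.channel_names]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    idx = [data.channel_names.index(n) for n in names]
    return EegDataset(
        data.epochs[:, idx, :], data.labels.copy(), data.times.copy(),
        data.sfreq, tuple(names), data.subject,
    )


def _condition_stack(data: EegDataset, balance: bool) -> np.ndarray:
    """Group trials as (n_conditions, n_reps, n_channels, n_times)."""
    labels = data.labels
    conds = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in conds])
    if counts.min() < 2:
        raise ValueError("every condition needs >= 2 trials for leave-one-trial-out")
    if counts.min() != counts.max():
        if not balance:
            raise ValueError(
                "unequal trial counts per condition; pass balance=True to "
                "subsample each condition to the minimum count"
            )
        n_reps = int(counts.min())
    else:
        n_reps = int(counts[0])
    stack = np.stack([data.epochs[labels == c][:n_reps] for c in conds])
    return stack


def _loto_lda_accuracies(
    X: np.ndarray, shrinkage: float, chunk: int = 256
) -> np.ndarray:
    """Pairwise leave-one-trial-out LDA accuracy matrix at one time point.

    X: (n_conditions, n_reps, n_channels). Folds pair the k-th trial of
    each condition; the training covariance per fold is obtained by
    rank-one downdates of the full class scatter matrices.
    """
    n_cond, n, c = X.shape
    means = X.mean(axis=1)  # (cond, C)
    dev = X - means[:, None, :]
    scatter = np.einsum("kri,krj->kij", dev, dev)  # (cond, C, C)
    loo_means = (n * means[:, None, :] - X) / (n - 1)  # (cond, n, C)
    loo_scatter = scatter[:, None] - (n / (n - 1)) * np.einsum(
        "kri,krj->krij", dev, dev
    )  # (cond, n, C, C)
    df = max(2 * (n - 1) - 2, 1)

    ii, jj = pair_indices(n_cond)
    acc = np.zeros((n_cond, n_cond))
    eye = np.eye(c)
    for lo in range(0, len(ii), chunk):
        pi = ii[lo:lo + chunk]
        pj = jj[lo:lo + chunk]
        cov = (loo_scatter[pi] + loo_scatter[pj]) / df  # (P, n, C, C)
        scale = np.trace(cov, axis1=2, axis2=3) / c  # (P, n)
        degenerate = scale <= 0
        scale = np.where(degenerate, 1.0, scale)
        shrunk = (1.0 - shrinkage) * cov + (
            shrinkage * scale[..., None, None]
        ) * eye
        # fully degenerate training data (e.g. one trial per class) -> identity
        if degenerate.any():
            shrunk[degenerate] = eye
        delta = loo_means[pi] - loo_means[pj]  # (P, n, C)
        w = np.linalg.solve(shrunk, delta[..., None])[..., 0]  # (P, n, C)
        b = 0.5 * np.einsum("pnc,pnc->pn", w, loo_means[pi] + loo_means[pj])
        score_i = np.einsum("pnc,pnc->pn", w, X[pi]) - b
        score_j = np.einsum("pnc,pnc->pn", w, X[pj]) - b
        pair_acc = 0.5 * ((score_i > 0).mean(axis=1) + (score_j < 0).mean(axis=1))
        acc[pi, pj] = pair_acc
        acc[pj, pi] = pair_acc
    np.fill_diagonal(acc, np.nan)
    return acc


class PairwiseDecoder(BaseEstimator, TransformerMixin):
    """Transformer from an epoched EEG dataset to a time-resolved RDM series.

    Parameters
    ----------
    shrinkage : float, default 0.05
        Fixed shrinkage coefficient of the pooled covariance toward a
        scaled identity.
    balance : bool, default False
        Subsample each condition to the minimum trial count when counts
        are unequal (the study design has equal repetitions, so the
        default refuses unequal counts instead of silently rebalancing).
    """

    def __init__(self, shrinkage: float = 0.05, balance: bool = False):
        self.shrinkage = shrinkage
        self.balance = balance

    def fit(self, X: EegDataset, y=None) -> "PairwiseDecoder":
        stack = _condition_stack(X, self.balance)
        self.n_conditions_ = stack.shape[0]
        self.n_folds_ = stack.shape[1]
        return self

    def transform(self, X: EegDataset) -> RDMSeries:
        self.fit(X)
        stack = _condition_stack(X, self.balance)  # (cond, reps, C, T)
        values = np.stack(
            [
                _loto_lda_accuracies(stack[..., t], self.shrinkage)
                for t in range(stack.shape[-1])
            ]
        )
        return RDMSeries(values, X.times.copy(), kind="decoding_accuracy",
                         subject=X.subject)


def pairwise_decode_rdm(
    data: EegDataset, time_ms: float, shrinkage: float = 0.05, balance: bool = False
) -> NeuralRDM:
    """Pairwise LDA decoding RDM at the sample closest to ``time_ms``."""
    idx = int(np.argmin(np.abs(data.times - time_ms)))
    stack = _condition_stack(data, balance)
    values = _loto_lda_accuracies(stack[..., idx], shrinkage)
    return NeuralRDM(values, kind="decoding_accuracy", subject=data.subject,
                     unit=float(data.times[idx]))


def decode_series(
    data: EegDataset, shrinkage: float = 0.05, balance: bool = False
) -> RDMSeries:
    """One pairwise decoding RDM per sample across the whole epoch."""
    return PairwiseDecoder(shrinkage=shrinkage, balance=balance).transform(data)
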