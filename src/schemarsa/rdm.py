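"""Containers for measured (neural) dissimilarity matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import check_square_symmetric


@dataclass
class NeuralRDM:
    """Per-subject, per-unit neural dissimilarity matrix.

    ``kind`` is either ``crossval_corr_diff`` (fMRI; may be negative under
    noise, above-zero means discriminable) or ``decoding_accuracy`` (EEG;
    values in [0, 1], chance 0.5). The diagonal is NaN.
    """

    values: np.ndarray
    kind: str = "crossval_corr_diff"
    subject: int | str | None = None
    unit: float | str | None = None  # ROI name or time point (ms)

    def __post_init__(self) -> None:
        self.values = check_square_symmetric(self.values, "NeuralRDM")
        np.fill_diagonal(self.values, np.nan)
        off = ~np.eye(self.values.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.values[off])):
            raise ValueError("NeuralRDM off-diagonal values must be finite")
        if self.kind == "decoding_accuracy":
            lo, hi = np.nanmin(self.values), np.nanmax(self.values)
            if lo < 0 or hi > 1:
                raise ValueError(
                    f"decoding accuracies must lie in [0, 1], got [{lo}, {hi}]"
                )

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


@dataclass
class RDMSeries:
    """One RDM per time point on a uniform millisecond time axis.

    ``values`` has shape (n_times, n_conditions, n_conditions).
    """

    values: np.ndarray
    times: np.ndarray
    kind: str = "decoding_accuracy"
    subject: int | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(
                f"RDMSeries values must be (n_times, n, n), got {self.values.shape}"
            )
        if len(self.times) != self.values.shape[0]:
            raise ValueError("time axis length does not match the number of RDMs")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0]):
                raise ValueError("RDMSeries requires a uniform time step")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def at(self, time_ms: float) -> NeuralRDM:
        """RDM at the sample closest to ``time_ms``."""
        idx = int(np.argmin(np.abs(self.times - time_ms)))
        return NeuralRDM(
            self.values[idx].copy(), kind=self.kind, subject=self.subject,
            unit=float(self.times[idx]),
        )
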