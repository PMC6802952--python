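"""Model RDMs from feature activations (network layers, raw pixels).

These serve as control models/covariates: each layer of a feature bank
yields an RDM of 1 - Pearson correlation between condition activation
vectors, and the same metric applied to flattened pixel arrays gives a
low-level pixel-dissimilarity control. Activations can come from any
callable (e.g. a pretrained network adapter); the pipeline only consumes
the activation matrices.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from ._utils import corr_rows
from .design import ModelRDM
from .synthetic import FeatureBank


def layer_rdm(activations: np.ndarray, name: str = "layer") -> ModelRDM:
    """1 - Pearson correlation between condition activation vectors.

    Values lie in [0, 2]; zero-variance activation vectors correlate 0 by
    convention (dissimilarity 1, with a warning), matching the degenerate-
    correlation rule used for neural patterns.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.ndim != 2 or activations.shape[1] < 2:
        raise ValueError("activations must be condition x unit with >= 2 units")
    if not np.all(np.isfinite(activations)):
        raise ValueError("activations must be finite")
    values = 1.0 - corr_rows(activations, activations)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, np.nan)
    return ModelRDM(values, kind="custom", name=name)


def bank_rdms(bank: FeatureBank) -> list[ModelRDM]:
    """One RDM per layer, order preserved.

    Which layers populate the bank (e.g. the final layer of each residual
    block plus input and output, 18 in total) is the extractor adapter's
    business; this function consumes whatever the bank holds.
    """
    if len(bank) == 0:
        raise ValueError("feature bank is empty")
    return [layer_rdm(act, name=name) for name, act in bank.layers]


def pixel_rdm(images: np.ndarray, metric: str = "correlation") -> ModelRDM:
    """Low-level control RDM from raw pixel values.

    Images are flattened per condition; the default metric is 1 - Pearson
    correlation (consistent with layer RDMs), with ``metric="euclidean"``
    as an alternative.
    """
    images = np.asarray(images, dtype=float)
    flat = images.reshape(images.shape[0], -1)
    if metric == "correlation":
        return layer_rdm(flat, name="pixel")
    if metric == "euclidean":
        sq = np.sum(flat**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T, 0.0)
        values = np.sqrt(d2)
        np.fill_diagonal(values, np.nan)
        return ModelRDM(values, kind="custom", name="pixel_euclidean")
    raise ValueError(f"unknown metric {metric!r}")


def extract_feature_bank(
    images: np.ndarray,
    extractor: Callable[[np.ndarray], dict[str, np.ndarray] | Sequence[np.ndarray]],
    layer_names: Sequence[str] | None = None,
) -> FeatureBank:
    """Adapter: run any images -> per-layer-activations callable into a bank.

    ``extractor`` receives the image array and returns either a mapping of
    layer name to (condition x unit) activations or an ordered sequence of
    activation matrices.
    """
    out = extractor(images)
    if isinstance(out, dict):
        layers = [(str(k), np.asarray(v, dtype=float)) for k, v in out.items()]
    else:
        names = layer_names or [f"layer{i + 1:02d}" for i in range(len(out))]
        if len(names) != len(out):
            raise ValueError("layer_names must match the number of layers")
        layers = [(str(n), np.asarray(v, dtype=float)) for n, v in zip(names, out)]
    for name, act in layers:
        if act.shape[0] != images.shape[0]:
            raise ValueError(f"layer {name!r} does not cover all conditions")
    return FeatureBank(layers)
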