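"""Shared numerical helpers: pair indexing, correlations, Fisher transform."""

from __future__ import annotations

import warnings

import numpy as np

#: clip margin applied before arctanh so noise-free data (r = +/-1) stays finite
FISHER_CLIP = 1e-12


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the lower off-diagonal triangle, row-major.

    This fixed order (i from 1..n-1, j < i) is the canonical pair order used
    by every vectorized RDM in the package.
    """
    return np.tril_indices(n, -1)


def fisher_z(r: np.ndarray | float, clip: float = FISHER_CLIP) -> np.ndarray:
    """Fisher (arctanh) transform with clipping so |r| = 1 stays finite."""
    return np.arctanh(np.clip(r, -1.0 + clip, 1.0 - clip))


def corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Zero-variance rows yield correlation 0 (with a warning) rather than NaN,
    so degenerate patterns never crash a batch run.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt(np.einsum("ij,ij->i", ac, ac))
    nb = np.sqrt(np.einsum("ij,ij->i", bc, bc))
    bad_a = na == 0
    bad_b = nb == 0
    if bad_a.any() or bad_b.any():
        warnings.warn(
            "zero-variance pattern encountered; correlation set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    na = np.where(bad_a, 1.0, na)
    nb = np.where(bad_b, 1.0, nb)
    r = (ac @ bc.T) / np.outer(na, nb)
    r[bad_a, :] = 0.0
    r[:, bad_b] = 0.0
    return r


def check_square_symmetric(values: np.ndarray, name: str = "RDM") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {values.shape}")
    off = ~np.eye(values.shape[0], dtype=bool)
    if not np.allclose(values[off], values.T[off], equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return values


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
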