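"""Group-level inference on predictor betas.

fMRI-style units (ROIs): one-tailed one-sample t-tests against zero with
Bonferroni correction across ROIs. EEG-style units (time points):
threshold-free cluster enhancement (TFCE) of the group t-map, corrected by
a sign-permutation test — each iteration flips the sign of each subject's
whole beta time course at random, the maximum enhanced statistic per
iteration forms the null, and the observed enhanced map is converted to
z-values against that null and thresholded (default Z > 1.64, i.e.
p < 0.05 one-tailed). Onset is the first sample of the earliest
suprathreshold run; the peak is the time of the maximal group t. Latency
reliability comes from bootstrapping subjects with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.stats

from ._utils import rng_from_seed


@dataclass
class PermutationScheme:
    """Sign-permutation settings: iteration count, seed and z threshold."""

    n_iterations: int = 10_000
    seed: int | None = None
    threshold_z: float = 1.64

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class StatMap:
    """Group statistics per unit (ROI or time point)."""

    t: np.ndarray
    p_uncorrected: np.ndarray
    sig_mask: np.ndarray
    tfce: np.ndarray | None = None
    z: np.ndarray | None = None
    times: np.ndarray | None = None
    onset_ms: float | None = None
    peak_ms: float | None = None
    peak_t: float | None = None


def group_ttest(betas: np.ndarray, tail: str = "greater") -> StatMap:
    """Per-unit one-sample t-test of subject betas against zero.

    ``betas`` is (n_subjects, n_units). Zero across-subject variance with a
    nonzero mean yields an infinite t (flagged with a warning) and p = 0;
    an all-zero unit yields t = 0, p = 0.5.
    """
    if tail != "greater":
        raise ValueError("only the one-tailed 'greater' test is supported")
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    n = betas.shape[0]
    if n < 2:
        raise ValueError("group test requires >= 2 subjects")
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    degenerate = sd == 0
    if np.any(degenerate & (mean != 0)):
        warnings.warn(
            "zero across-subject variance with nonzero mean; t is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(
            degenerate, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t
        )
    p = scipy.stats.t.sf(t, df=n - 1)
    p = np.where(np.isposinf(t), 0.0, p)
    p = np.where(np.isneginf(t), 1.0, p)
    return StatMap(t=t, p_uncorrected=p, sig_mask=p < 0.05)


def bonferroni(pvals: np.ndarray, m: int | None = None, alpha: float = 0.05):
    """Bonferroni-adjusted p-values (capped at 1) and significance mask.

    ``m`` defaults to the number of tests; pass ``m=3`` when correcting a
    single predictor across the three ROIs.
    """
    pvals = np.asarray(pvals, dtype=float)
    m_eff = m if m is not None else pvals.size
    if m_eff < pvals.size:
        raise ValueError("m must be at least the number of tests")
    adjusted = np.minimum(1.0, m_eff * pvals)
    return adjusted, adjusted < alpha


def _run_extents(mask: np.ndarray) -> np.ndarray:
    """Length of the contiguous True run covering each position (batched rows).

    ``mask`` is (n_maps, n_times) boolean; runs never span rows.
    """
    starts = mask.copy()
    starts[:, 1:] &= ~mask[:, :-1]
    flat_mask = mask.ravel()
    run_id = np.cumsum(starts.ravel())  # 1-based inside runs
    lengths = np.bincount(run_id[flat_mask], minlength=run_id[-1] + 1 if run_id.size else 1)
    extents = np.zeros(flat_mask.shape, dtype=float)
    extents[flat_mask] = lengths[run_id[flat_mask]]
    return extents.reshape(mask.shape)


def tfce_batch(
    stat_maps: np.ndarray, e: float = 0.5, h: float = 2.0, n_steps: int = 100
) -> np.ndarray:
    """TFCE for a batch of 1-D maps (n_maps, n_times), one-tailed positive.

    Each map is integrated over ``n_steps`` thresholds from 0 to its own
    maximum (dh = max/n_steps); negative values contribute nothing.
    Adjacent-sample connectivity only.
    """
    stat_maps = np.atleast_2d(np.asarray(stat_maps, dtype=float))
    peaks = stat_maps.max(axis=1)
    dh = np.where(peaks > 0, peaks / n_steps, 0.0)  # per-map step
    out = np.zeros_like(stat_maps)
    active = peaks > 0
    if not active.any():
        return out
    maps = stat_maps[active]
    dh_a = dh[active]
    acc = np.zeros_like(maps)
    for k in range(1, n_steps + 1):
        thresh = k * dh_a
        mask = maps > thresh[:, None] - 1e-12 * dh_a[:, None]
        if not mask.any():
            continue
        extents = _run_extents(mask)
        acc += (extents**e) * (thresh[:, None] ** h) * dh_a[:, None] * mask
    out[active] = acc
    return out


def tfce_1d(
    stat_map: np.ndarray,
    e: float = 0.5,
    h: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of one 1-D statistic map.

    TFCE(t) = sum over thresholds h of extent(h, t)^E * h^H * dh, where the
    extent is the length of the suprathreshold run containing t. With the
    default ``dh=None`` the step is max(map)/n_steps; an explicit ``dh``
    integrates from dh up to the map maximum in steps of dh.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if dh is None:
        return tfce_batch(stat_map[None], e=e, h=h, n_steps=n_steps)[0]
    if dh <= 0:
        raise ValueError("dh must be positive")
    peak = stat_map.max()
    out = np.zeros_like(stat_map)
    if peak <= 0:
        return out
    thresh = dh
    while thresh <= peak + 1e-12 * dh:
        mask = stat_map > thresh - 1e-12 * dh
        extents = _run_extents(mask[None])[0]
        out += (extents**e) * thresh**h * dh * mask
        thresh += dh
    return out


def _t_map(betas: np.ndarray) -> np.ndarray:
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        return np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)


def _onset_peak(
    t: np.ndarray, sig: np.ndarray, times: np.ndarray | None
) -> tuple[float | None, float | None, float]:
    axis = times if times is not None else np.arange(len(t))
    onset = float(axis[int(np.argmax(sig))]) if sig.any() else None
    peak_idx = int(np.argmax(t))
    return onset, float(axis[peak_idx]), float(t[peak_idx])


def sign_permutation_correct(
    betas: np.ndarray,
    scheme: PermutationScheme | None = None,
    times: np.ndarray | None = None,
    e: float = 0.5,
    h: float = 2.0,
    n_steps: int = 100,
    method: str = "moment",
) -> StatMap:
    """TFCE + max-statistic sign-permutation correction across time.

    ``betas`` is (n_subjects, n_times). Each iteration flips the sign of
    every subject's whole time course independently, recomputes the group
    t-map and its TFCE, and records the maximum enhanced value. Observed
    TFCE values are converted to z-scores against that null — via the
    null's mean/SD (``method="moment"``, default) or via empirical
    quantiles mapped through the normal inverse CDF
    (``method="quantile"``) — and thresholded at ``scheme.threshold_z``.
    Deterministic given the scheme's seed.
    """
    scheme = scheme or PermutationScheme()
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 2:
        raise ValueError("betas must be (n_subjects >= 2, n_times)")
    n_sub, n_time = betas.shape
    tail_p = scipy.stats.norm.sf(scheme.threshold_z)
    if scheme.n_iterations * tail_p < 10:
        warnings.warn(
            f"{scheme.n_iterations} iterations resolve the Z>{scheme.threshold_z} "
            "tail poorly; consider more iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = rng_from_seed(scheme.seed)

    t_obs = _t_map(betas)
    tfce_obs = tfce_batch(t_obs[None], e=e, h=h, n_steps=n_steps)[0]

    # sign flips only change the mean; the per-subject squares are invariant,
    # so the permuted t-maps reduce to two matrix products
    flips = rng.choice([-1.0, 1.0], size=(scheme.n_iterations, n_sub))
    m2 = np.mean(betas**2, axis=0)  # (T,)
    means = flips @ betas / n_sub  # (I, T)
    var = (n_sub * (m2[None, :] - means**2)) / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n_sub)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=0.0, neginf=0.0)
    null_max = tfce_batch(t_null, e=e, h=h, n_steps=n_steps).max(axis=1)

    if method == "moment":
        mu, sd = null_max.mean(), null_max.std(ddof=1)
        z = (tfce_obs - mu) / sd if sd > 0 else np.where(tfce_obs > mu, np.inf, -np.inf)
        sig = z > scheme.threshold_z
    elif method == "quantile":
        exceed = (null_max[None, :] >= tfce_obs[:, None]).sum(axis=1)
        p_emp = (exceed + 1) / (scheme.n_iterations + 1)
        z = scipy.stats.norm.isf(p_emp)
        sig = p_emp < tail_p
    else:
        raise ValueError(f"unknown method {method!r}")

    p_unc = scipy.stats.t.sf(t_obs, df=n_sub - 1)
    onset, peak, peak_t = _onset_peak(t_obs, sig, times)
    return StatMap(
        t=t_obs, p_uncorrected=p_unc, sig_mask=sig, tfce=tfce_obs, z=z,
        times=times, onset_ms=onset, peak_ms=peak, peak_t=peak_t,
    )


def latency_bootstrap(
    betas: np.ndarray,
    sig_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    times: np.ndarray | None = None,
    ci: float = 95.0,
) -> dict:
    """Bootstrap distributions and CIs for onset and peak latencies.

    Subjects are resampled with replacement; for each draw significance is
    recomputed with ``sig_fn`` (betas -> boolean mask over time; defaults
    to TFCE + sign permutation at 1000 iterations seeded per draw), the
    onset is the first significant sample and the peak the argmax of the
    group t-map. Draws with no significant sample contribute an undefined
    onset, reported as a rate.
    """
    betas = np.asarray(betas, dtype=float)
    n_sub = betas.shape[0]
    if n_sub < 2:
        raise ValueError("bootstrap requires >= 2 subjects")
    rng = rng_from_seed(seed)
    axis = times if times is not None else np.arange(betas.shape[1])

    onsets = np.full(n_boot, np.nan)
    peaks = np.full(n_boot, np.nan)
    for b in range(n_boot):
        draw = betas[rng.integers(0, n_sub, size=n_sub)]
        if sig_fn is None:
            sig = sign_permutation_correct(
                draw,
                PermutationScheme(n_iterations=1000, seed=int(rng.integers(2**31))),
                times=times,
            ).sig_mask
        else:
            sig = np.asarray(sig_fn(draw), dtype=bool)
        t = _t_map(draw)
        peaks[b] = axis[int(np.argmax(t))]
        if sig.any():
            onsets[b] = axis[int(np.argmax(sig))]
    defined = ~np.isnan(onsets)
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    return {
        "onsets": onsets,
        "peaks": peaks,
        "onset_ci": (
            tuple(np.percentile(onsets[defined], [lo, hi])) if defined.any() else None
        ),
        "peak_ci": tuple(np.percentile(peaks, [lo, hi])),
        "undefined_onset_rate": float(1.0 - defined.mean()),
    }
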