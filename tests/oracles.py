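"""Independent brute-force implementations used as oracles in tests.

Everything here is written naively (explicit loops, scipy.stats helpers)
and independently of the package's vectorized code paths.
"""

from itertools import combinations, groupby

import numpy as np
import scipy.stats


def crossval_corr_rdm_oracle(patterns: np.ndarray) -> np.ndarray:
    """Split-half cross-validated correlation RDM, fold-by-fold with pearsonr."""
    n_cond, n_runs, _ = patterns.shape
    half = n_runs // 2
    # all unordered equal partitions
    splits = []
    for first in combinations(range(n_runs), half):
        second = tuple(r for r in range(n_runs) if r not in first)
        if first < second:
            splits.append((first, second))

    def z(r):
        r = min(max(r, -1 + 1e-12), 1 - 1e-12)
        return np.arctanh(r)

    rdm = np.full((n_cond, n_cond), np.nan)
    for i in range(n_cond):
        for j in range(n_cond):
            if i == j:
                continue
            vals = []
            for first, second in splits:
                a = patterns[:, list(first), :].mean(axis=1)
                b = patterns[:, list(second), :].mean(axis=1)
                within = (z(scipy.stats.pearsonr(a[i], b[i])[0])
                          + z(scipy.stats.pearsonr(a[j], b[j])[0])) / 2
                between = (z(scipy.stats.pearsonr(a[i], b[j])[0])
                           + z(scipy.stats.pearsonr(a[j], b[i])[0])) / 2
                vals.append(within - between)
            rdm[i, j] = np.mean(vals)
    return rdm


def lda_loto_accuracy_oracle(Xi: np.ndarray, Xj: np.ndarray, shrinkage: float) -> float:
    """Leave-one-trial-out two-class LDA accuracy, one explicit fold at a time.

    Fold k holds out trial k of each class; training uses pooled
    within-class covariance shrunk toward a scaled identity.
    """
    n, c = Xi.shape
    correct = []
    for k in range(n):
        tr_i = np.delete(Xi, k, axis=0)
        tr_j = np.delete(Xj, k, axis=0)
        mi, mj = tr_i.mean(axis=0), tr_j.mean(axis=0)
        si = (tr_i - mi).T @ (tr_i - mi)
        sj = (tr_j - mj).T @ (tr_j - mj)
        df = max(len(tr_i) + len(tr_j) - 2, 1)
        cov = (si + sj) / df
        scale = np.trace(cov) / c
        if scale <= 0:
            sigma = np.eye(c)
        else:
            sigma = (1 - shrinkage) * cov + shrinkage * scale * np.eye(c)
        w = np.linalg.solve(sigma, mi - mj)
        b = w @ (mi + mj) / 2
        correct.append(float(w @ Xi[k] > b))
        correct.append(float(w @ Xj[k] < b))
    return float(np.mean(correct))


def ols_betas_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form normal equations with an explicit intercept column."""
    design = np.column_stack([np.ones(len(y)), X])
    return np.linalg.inv(design.T @ design) @ design.T @ y


def residualize_oracle(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Two-step OLS: residuals of y on [1, C] via the normal equations."""
    design = np.column_stack([np.ones(len(y)), C])
    beta = np.linalg.inv(design.T @ design) @ design.T @ y
    return y - design @ beta


def tfce_oracle(stat_map: np.ndarray, e: float = 0.5, h: float = 2.0,
                n_steps: int = 100) -> np.ndarray:
    """Explicit threshold loop with run detection via groupby."""
    stat_map = np.asarray(stat_map, dtype=float)
    peak = stat_map.max()
    out = np.zeros_like(stat_map)
    if peak <= 0:
        return out
    dh = peak / n_steps
    for k in range(1, n_steps + 1):
        thresh = k * dh
        mask = stat_map > thresh - 1e-12 * dh
        pos = 0
        for value, group in groupby(mask):
            length = len(list(group))
            if value:
                out[pos:pos + length] += (length ** e) * (thresh ** h) * dh
            pos += length
    return out


def onesample_t_oracle(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    n = len(values)
    return values.mean() / (values.std(ddof=1) / np.sqrt(n))


def count_zero_pairs(stimulus_set, key) -> int:
    """Brute-force count of unordered pairs sharing the attribute ``key``."""
    conds = list(stimulus_set)
    return sum(
        1
        for a, b in combinations(conds, 2)
        if getattr(a, key) == getattr(b, key)
    )
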