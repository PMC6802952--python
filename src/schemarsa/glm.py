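"""Modelling vectorized neural RDMs as linear combinations of predictor RDMs.

Neural and predictor RDMs are vectorized by taking the lower off-diagonal
triangle in a fixed row-major pair order (630 pairs for 36 conditions);
masked analyses drop excluded pairs from criterion and predictors alike.
The criterion (neural) vector is z-scored (on the retained entries only)
and regressed on the binary predictors by ordinary least squares with an
intercept, yielding one beta per predictor per subject and unit.

Covariate control ("residualization") projects a bank of covariate RDMs
(e.g. network-layer RDMs) out of the analysis. By default both the
criterion and the predictors are residualized on the bank, which by the
Frisch-Waugh theorem equals fitting one joint GLM with the bank as
nuisance regressors; ``residualize_predictors=False`` residualizes the
criterion only. A predictor that the bank spans completely (its residual
is numerically zero) gets beta 0 with a warning — its structure has been
fully attributed to the covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from ._utils import pair_indices
from .design import ModelRDM, PairMask, StimulusSet, build_cross_type_mask, default_predictor_rdms
from .rdm import NeuralRDM, RDMSeries

#: relative norm below which a residualized predictor counts as annihilated
_ANNIHILATED_TOL = 1e-9


class CollinearPredictorsError(ValueError):
    """Raised when the predictor design is rank deficient."""


@dataclass
class RdmVector:
    """Vectorized RDM: one value per retained unordered condition pair."""

    values: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    name: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.values)


@dataclass
class GLMResult:
    """Per-subject, per-unit regression weights."""

    betas: dict[str, float]
    intercept: float
    n_pairs: int
    subject: int | str | None = None
    unit: float | str | None = None

    @property
    def predictor_names(self) -> list[str]:
        return list(self.betas)


@dataclass
class GlmSuiteResult:
    """Beta stack over subjects and units for one analysis variant."""

    betas: np.ndarray  # (n_subjects, n_units, n_predictors)
    predictor_names: list[str]
    analysis: str
    n_pairs: int
    units: np.ndarray | list | None = None  # time axis (ms) or ROI names

    def predictor(self, name: str) -> np.ndarray:
        """Subject x unit betas of one predictor."""
        return self.betas[:, :, self.predictor_names.index(name)]


def _rdm_values(rdm) -> np.ndarray:
    if isinstance(rdm, (ModelRDM, NeuralRDM)):
        return rdm.values
    return np.asarray(rdm, dtype=float)


def vectorize(rdm, mask: PairMask | np.ndarray | None = None, name: str = "") -> RdmVector:
    """Lower-triangle vectorization in canonical pair order; masked pairs dropped."""
    values = _rdm_values(rdm)
    n = values.shape[0]
    if values.shape != (n, n):
        raise ValueError("RDM must be square")
    rows, cols = pair_indices(n)
    if mask is not None:
        include = mask.include if isinstance(mask, PairMask) else np.asarray(mask, bool)
        if include.shape != (n, n):
            raise ValueError(
                f"mask shape {include.shape} does not match RDM size {n}"
            )
        keep = include[rows, cols]
        rows, cols = rows[keep], cols[keep]
    vec = values[rows, cols]
    if not isinstance(rdm, np.ndarray) and not name:
        name = getattr(rdm, "name", "") or getattr(rdm, "kind", "")
    return RdmVector(vec, rows, cols, name=name)


def _as_vector(x) -> np.ndarray:
    if isinstance(x, RdmVector):
        return x.values
    return np.asarray(x, dtype=float)


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score with sample SD; a zero-variance vector warns and maps to zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance criterion; z-scored vector set to 0",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


class RDMRegression(BaseEstimator, RegressorMixin):
    """OLS of a (z-scored) neural RDM vector on predictor RDM vectors.

    Parameters
    ----------
    zscore_criterion : bool, default True
        Z-score the criterion before fitting (the predictors stay in raw
        binary form). Rescales all betas by one positive factor; signs and
        t-statistics are unaffected.
    fit_intercept : bool, default True

    Attributes
    ----------
    coef_ : (n_predictors,) betas in predictor order
    intercept_ : float
    """

    def __init__(self, zscore_criterion: bool = True, fit_intercept: bool = True):
        self.zscore_criterion = zscore_criterion
        self.fit_intercept = fit_intercept

    def fit(self, X: np.ndarray, y: np.ndarray, predictor_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pairs, n_predictors) aligned with y")
        names = list(predictor_names or [f"x{i}" for i in range(X.shape[1])])
        if self.zscore_criterion:
            y = zscore(y)
            if not y.any():
                self.coef_ = np.zeros(X.shape[1])
                self.intercept_ = 0.0
                self.predictor_names_ = names
                return self
        design = np.column_stack([np.ones(len(y)), X]) if self.fit_intercept else X
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # QR with column pivoting: trailing pivots name the dependent columns
            _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
            n_dep = design.shape[1] - rank
            offset = 1 if self.fit_intercept else 0
            dep = sorted(
                names[p - offset] if p >= offset else "intercept"
                for p in piv[rank:][:n_dep]
            )
            raise CollinearPredictorsError(
                f"predictor design is rank deficient; dependent columns: {dep}"
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.predictor_names_ = names
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


def fit_rdm_glm(
    neural: RdmVector | np.ndarray,
    predictors: Mapping[str, RdmVector | np.ndarray],
    zscore_criterion: bool = True,
    subject=None,
    unit=None,
) -> GLMResult:
    """Fit one GLM: neural vector ~ intercept + predictor vectors."""
    y = _as_vector(neural)
    names = list(predictors)
    X = np.column_stack([_as_vector(predictors[n]) for n in names])
    est = RDMRegression(zscore_criterion=zscore_criterion).fit(X, y, names)
    return GLMResult(
        betas=dict(zip(names, est.coef_.tolist())),
        intercept=est.intercept_,
        n_pairs=len(y),
        subject=subject,
        unit=unit,
    )


class Residualizer(BaseEstimator, TransformerMixin):
    """Removes the span of a covariate matrix (plus intercept) from vectors.

    ``fit(X)`` learns an orthonormal basis of span{1, X};
    ``transform(Y)`` returns Y minus its orthogonal projection onto it.
    """

    def fit(self, X: np.ndarray, y=None) -> "Residualizer":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.column_stack([np.ones(X.shape[0]), X])
        q, r = np.linalg.qr(design)
        keep = np.abs(np.diag(r)) > 1e-12 * max(np.abs(np.diag(r)).max(), 1.0)
        self.basis_ = q[:, keep]
        self.n_samples_ = X.shape[0]
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if Y.shape[0] != self.n_samples_:
            raise ValueError("vector length does not match the fitted covariates")
        return Y - self.basis_ @ (self.basis_.T @ Y)


def residualize(
    neural: RdmVector | np.ndarray,
    covariates: Sequence[RdmVector | np.ndarray],
) -> RdmVector | np.ndarray:
    """Criterion minus its OLS projection onto the covariates (+ intercept)."""
    y = _as_vector(neural)
    C = np.column_stack([_as_vector(c) for c in covariates])
    resid = Residualizer().fit(C).transform(y)
    if isinstance(neural, RdmVector):
        return RdmVector(resid, neural.rows, neural.cols, name=neural.name)
    return resid


ANALYSES = ("full", "dnn_resid", "cross_type", "combined")


def _neural_stack(neural) -> tuple[np.ndarray, np.ndarray | None]:
    """Normalize neural input to (n_subjects, n_units, n, n) plus a unit axis."""
    if isinstance(neural, NeuralRDM):
        return neural.values[None, None], None
    if isinstance(neural, RDMSeries):
        return neural.values[None], neural.times
    if isinstance(neural, (list, tuple)) and neural and isinstance(neural[0], RDMSeries):
        times = neural[0].times
        for s in neural[1:]:
            if not np.array_equal(s.times, times):
                raise ValueError("all subjects must share one time axis")
        return np.stack([s.values for s in neural]), times
    arr = np.asarray(neural, dtype=float)
    if arr.ndim == 2:
        return arr[None, None], None
    if arr.ndim == 3:  # (n_subjects, n, n)
        return arr[:, None], None
    if arr.ndim == 4:
        return arr, None
    raise ValueError(f"cannot interpret neural input with shape {arr.shape}")


def run_glm_suite(
    neural,
    stimulus_set: StimulusSet,
    analysis: str = "full",
    covariate_bank: Sequence[ModelRDM | np.ndarray] | None = None,
    predictors: Mapping[str, ModelRDM] | None = None,
    mask: PairMask | None = None,
    zscore_criterion: bool = True,
    residualize_predictors: bool = True,
) -> GlmSuiteResult:
    """Run one of the four analysis variants over all subjects and units.

    Variants: ``full`` (three-predictor GLM), ``dnn_resid`` (covariate
    bank partialled out first), ``cross_type`` (pairs restricted to
    indoor-vs-outdoor comparisons; vertical + horizontal only, category
    cannot be modelled), ``combined`` (both restrictions).

    ``neural`` may be a single RDM, a subject stack (n_subjects, n, n), a
    full (n_subjects, n_units, n, n) array, an RDMSeries, or a list of
    per-subject RDMSeries.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; choose from {ANALYSES}")
    restricted = analysis in ("cross_type", "combined")
    residualized = analysis in ("dnn_resid", "combined")
    if residualized and not covariate_bank:
        raise ValueError(f"analysis {analysis!r} requires a covariate bank")

    if predictors is None:
        predictors = default_predictor_rdms(stimulus_set)
        if restricted:
            predictors = {k: predictors[k] for k in ("vertical", "horizontal")}
    if restricted and "category" in predictors:
        raise ValueError(
            "a category RDM cannot be constructed under the cross-scene-type "
            "restriction: all retained pairs stem from different scenes"
        )
    if restricted and mask is None:
        mask = build_cross_type_mask(stimulus_set)

    stack, units = _neural_stack(neural)
    n = len(stimulus_set)
    if stack.shape[-1] != n:
        raise ValueError("neural RDM size does not match the stimulus set")

    names = list(predictors)
    Xcols = [vectorize(predictors[k], mask).values for k in names]
    X = np.column_stack(Xcols)
    cov = None
    if residualized:
        cov = np.column_stack(
            [vectorize(_rdm_values(c), mask).values for c in covariate_bank]
        )
        projector = Residualizer().fit(cov)
        if residualize_predictors:
            X_res = projector.transform(X)
            norms = np.linalg.norm(X - X.mean(0), axis=0)
            res_norms = np.linalg.norm(X_res, axis=0)
            annihilated = res_norms <= _ANNIHILATED_TOL * np.maximum(norms, 1.0)
            if annihilated.any():
                dropped = [names[i] for i in np.flatnonzero(annihilated)]
                warnings.warn(
                    f"predictor(s) {dropped} lie in the covariate-bank span; "
                    "their betas are 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            X_fit = X_res[:, ~annihilated]
            kept = np.flatnonzero(~annihilated)
        else:
            X_fit, kept, annihilated = X, np.arange(len(names)), np.zeros(len(names), bool)
    else:
        X_fit, kept, annihilated = X, np.arange(len(names)), np.zeros(len(names), bool)

    rows, cols = vectorize(np.zeros((n, n)), mask).rows, vectorize(np.zeros((n, n)), mask).cols
    S, U = stack.shape[0], stack.shape[1]
    betas = np.zeros((S, U, len(names)))
    est = RDMRegression(zscore_criterion=zscore_criterion)
    kept_names = [names[i] for i in kept]
    for s in range(S):
        for u in range(U):
            y = stack[s, u][rows, cols]
            if residualized:
                y = projector.transform(y)
            est.fit(X_fit, y, kept_names)
            betas[s, u, kept] = est.coef_
    return GlmSuiteResult(
        betas=betas,
        predictor_names=names,
        analysis=analysis,
        n_pairs=len(rows),
        units=units,
    )
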