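"""Sparse prognostic shape score (LVAS): Cox-Lasso over PCA mode
coefficients with penalty selection by cross-validated partial
log-likelihood, and max-min normalised scoring of new patients.

Mode coefficients are standardized to unit variance inside the
penalised fit (lasso penalties are scale sensitive); learned weights
are reported back on the raw coefficient scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _coxlib
from .mesh import LVMesh
from .pca import ShapeModel, project


@dataclass
class LVASModel:
    """Sparse mode weights plus the frozen training normalisation."""

    weights: np.ndarray  # raw-coefficient scale; zeros outside the support
    selected_mode_indices: tuple[int, ...]
    lambda_selected: float
    cv_lambdas: np.ndarray
    cv_values: np.ndarray
    raw_score_min: float
    raw_score_max: float
    quartile_cutpoints: np.ndarray  # training quartiles of the normalised score

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.cv_lambdas = np.asarray(self.cv_lambdas, dtype=float)
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        self.quartile_cutpoints = np.asarray(self.quartile_cutpoints, dtype=float)
        if self.raw_score_min >= self.raw_score_max:
            raise ValueError("raw_score_min must be < raw_score_max")

    def raw_score(self, coefficients: np.ndarray) -> np.ndarray:
        C = np.atleast_2d(np.asarray(coefficients, dtype=float))
        return C @ self.weights

    def normalize(self, raw: np.ndarray, clip: bool = True) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        z = (raw - self.raw_score_min) / (self.raw_score_max - self.raw_score_min)
        if clip and np.any((z < 0) | (z > 1)):
            warnings.warn(
                "raw LVAS outside the training range; clipping to [0, 1]",
                stacklevel=2,
            )
            z = np.clip(z, 0.0, 1.0)
        return z


def _validate_survival(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if events.sum() == 0:
        raise ValueError("no events in the training data")
    return times, events


def cox_partial_loglik(beta, coefficients, times, events) -> float:
    """Efron-corrected Cox partial log-likelihood of mode coefficients."""
    times, events = _validate_survival(times, events)
    return _coxlib.partial_loglik(beta, coefficients, times, events)


def standardize(coefficients) -> tuple[np.ndarray, np.ndarray]:
    C = np.atleast_2d(np.asarray(coefficients, dtype=float))
    scale = C.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (C - C.mean(axis=0)) / scale, scale


def cox_lasso_path(coefficients, times, events, lambda_grid=None):
    """Sparse Cox-Lasso solution path over (already standardized) mode
    coefficients; warm starts along decreasing lambda, deterministic.

    Returns (lambdas, betas, converged flags)."""
    times, events = _validate_survival(times, events)
    return _coxlib.lasso_path(coefficients, times, events, lambdas=lambda_grid)


def cv_select(
    coefficients, times, events, n_folds: int = 10, seed: int = 0,
    lambda_grid=None, rule: str = "1se",
):
    """Penalty selection on the Verweij-van Houwelingen cross-validated
    partial log-likelihood curve.

    ``rule='max'`` takes the argmax (ties resolved toward the sparser,
    larger-lambda end).  The default ``'1se'`` takes the largest lambda
    whose CV value is within one standard error (across folds) of the
    maximum -- the plain argmax retains spurious modes on pure-noise
    data too often to be a usable default.  Returns
    (lambda, lambdas, cv_curve).
    """
    times, events = _validate_survival(times, events)
    X = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if lambda_grid is None:
        lambda_grid = _coxlib.default_lambda_grid(
            _coxlib.lambda_max(X, times, events)
        )
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    cv, _, per_fold = _coxlib.cv_partial_loglik(
        X, times, events, lambda_grid, n_folds=n_folds, seed=seed
    )
    order = np.argsort(-lambda_grid)
    best = None
    best_val = -np.inf
    for i in order:  # largest lambda first => sparser model wins ties
        if cv[i] > best_val + 1e-10:
            best_val = cv[i]
            best = i
    if rule == "max":
        return float(lambda_grid[best]), lambda_grid, cv
    if rule != "1se":
        raise ValueError(f"unknown selection rule: {rule!r}")
    se = per_fold.std(axis=0, ddof=1) * np.sqrt(per_fold.shape[0])
    threshold = cv[best] - se[best]
    for i in order:
        if cv[i] >= threshold:
            return float(lambda_grid[i]), lambda_grid, cv
    return float(lambda_grid[best]), lambda_grid, cv


def build_lvas(
    shape_model: ShapeModel,
    coefficients,
    times,
    events,
    n_folds: int = 10,
    seed: int = 0,
    lambda_grid=None,
) -> LVASModel:
    """Learn the sparse mode combination and freeze the training
    normalisation (max-min bounds and quartile cutpoints)."""
    times, events = _validate_survival(times, events)
    C = np.atleast_2d(np.asarray(coefficients, dtype=float))
    Cs, scale = standardize(C)
    lam, lambdas, cv = cv_select(
        Cs, times, events, n_folds=n_folds, seed=seed, lambda_grid=lambda_grid
    )
    beta_std, ok = _coxlib.lasso_fit(Cs, times, events, lam)
    if not ok:
        warnings.warn("Cox-Lasso did not fully converge at the selected lambda",
                      stacklevel=2)
    if np.all(beta_std == 0):
        raise ValueError("no prognostic shape signal at selected lambda")
    weights = beta_std / scale

    raw = C @ weights
    # orient so a higher score means higher hazard
    fit = _coxlib.newton_fit(raw[:, None], times, events)
    if fit.beta[0] < 0:
        weights = -weights
        raw = -raw
    lo, hi = float(raw.min()), float(raw.max())
    normalized = (raw - lo) / (hi - lo)
    cutpoints = np.quantile(normalized, [0.25, 0.5, 0.75])
    return LVASModel(
        weights=weights,
        selected_mode_indices=tuple(int(j) for j in np.nonzero(weights)[0]),
        lambda_selected=lam,
        cv_lambdas=lambdas,
        cv_values=cv,
        raw_score_min=lo,
        raw_score_max=hi,
        quartile_cutpoints=cutpoints,
    )


def score_patient(
    lvas_model: LVASModel, shape_model: ShapeModel, mesh: LVMesh
) -> float:
    """Normalised LVAS of one mesh: align (if a landmark is carried),
    project onto the shape model, weight, and map through the stored
    training bounds (clipping outside them)."""
    if mesh.topology.vector_length != shape_model.mean.size:
        raise ValueError("mesh topology does not match the shape model")
    if mesh.rv_point is not None:
        from .personalize import align_mesh

        mesh = align_mesh(mesh)
    c = project(shape_model, mesh.to_vector())
    raw = float(c @ lvas_model.weights[: c.size])
    return float(lvas_model.normalize(np.array([raw]))[0])


def quartile_code(scores, cutpoints) -> np.ndarray:
    """Quartile index 0-3 by training cutpoints; ties go to the lower
    quartile."""
    scores = np.asarray(scores, dtype=float)
    cutpoints = np.asarray(cutpoints, dtype=float)[:3]
    return np.searchsorted(cutpoints, scores, side="left").astype(int)
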