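"""PCA statistical shape model over aligned LV shape vectors.

Provides fitting (via SVD, equivalent to the N x N Gram trick when
D >> N), projection, reconstruction, mode exaggeration, and Spearman
mode-variable correlation tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mesh import LatticeTopology, LVMesh
from .metrics import cavity_volume


@dataclass
class ShapeModel:
    """Mean shape, orthonormal variation modes and per-mode variances.

    ``modes`` has shape (K, D) with orthonormal rows ordered by
    non-increasing variance; ``variances`` are the sample (ddof=1)
    variances of the training coefficients, mm^2.
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    n_retained: int
    n_train: int
    topology: LatticeTopology | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def fit_pca(
    shape_vectors: np.ndarray,
    n_retained: int = 10,
    topology: LatticeTopology | None = None,
) -> ShapeModel:
    """Eigendecomposition of the sample covariance of N x D shape
    vectors; deterministic up to sign, which is fixed by convention:
    a mode points in the direction of increasing cavity volume when a
    topology is available, otherwise its largest-magnitude component is
    made positive.
    """
    X = np.asarray(shape_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (N >= 3) x D matrix of shape vectors")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank == 0:
        raise ValueError("all shape vectors are identical; PCA rank is zero")
    k = min(rank, n - 1)
    modes = Vt[:k]
    variances = S[:k] ** 2 / (n - 1)

    signs = _mode_signs(mean, modes, variances, topology)
    modes = modes * signs[:, None]
    return ShapeModel(
        mean=mean,
        modes=modes,
        variances=variances,
        n_retained=min(n_retained, k),
        n_train=n,
        topology=topology,
    )


def _mode_signs(mean, modes, variances, topology) -> np.ndarray:
    signs = np.ones(len(modes))
    for j, mode in enumerate(modes):
        flipped = None
        if topology is not None:
            eps = np.sqrt(variances[j])
            try:
                v_plus = cavity_volume(LVMesh.from_vector(mean + eps * mode, topology))
                v_minus = cavity_volume(LVMesh.from_vector(mean - eps * mode, topology))
                dv = v_plus - v_minus
                if abs(dv) > 1e-9:
                    flipped = dv < 0
            except ValueError:
                flipped = None
        if flipped is None:  # fallback: largest-magnitude component positive
            flipped = mode[np.argmax(np.abs(mode))] < 0
        if flipped:
            signs[j] = -1.0
    return signs


def project(model: ShapeModel, shape_vector: np.ndarray) -> np.ndarray:
    """Coefficients c_j = M_j . (X - mean) for the retained modes.
    Accepts a single vector or an (N, D) matrix."""
    X = np.asarray(shape_vector, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"shape vector length {X.shape[1]} != model dimension {model.mean.size}"
        )
    C = (X - model.mean) @ model.modes[: model.n_retained].T
    return C[0] if single else C


def reconstruct(model: ShapeModel, coefficients: np.ndarray) -> np.ndarray:
    """mean + sum_j c_j M_j; accepts up to n_modes coefficients."""
    c = np.asarray(coefficients, dtype=float).ravel()
    if c.size > model.n_modes:
        raise ValueError(f"got {c.size} coefficients for {model.n_modes} modes")
    return model.mean + c @ model.modes[: c.size]


def variance_explained(model: ShapeModel, k: int) -> float:
    """Fraction of total variance captured by the first k modes.

    Note: when K was truncated at fit time the denominator only covers
    the retained spectrum; fit with full rank for exact fractions.
    """
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"k must be in [1, {model.n_modes}], got {k}")
    return float(model.variances[:k].sum() / model.variances.sum())


def exaggerate_mode(
    model: ShapeModel,
    direction: np.ndarray,
    n_sd: float,
    topology: LatticeTopology | None = None,
) -> LVMesh:
    """Mesh at mean + n_sd * sigma along a unit direction in mode space,
    where sigma is the training-sample sd of the projected score."""
    topo = topology or model.topology
    if topo is None:
        raise ValueError("a lattice topology is required to build a mesh")
    w = np.asarray(direction, dtype=float).ravel()
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise ValueError("direction must be a non-zero vector in mode space")
    w = w / norm
    if w.size > model.n_modes:
        raise ValueError("direction has more entries than model modes")
    sigma = float(np.sqrt(w**2 @ model.variances[: w.size]))
    vec = model.mean + (n_sd * sigma) * (w @ model.modes[: w.size])
    return LVMesh.from_vector(vec, topo)


# ---------------------------------------------------------------------------

def spearman_with_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho with two-sided significance from
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 df; pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xr = sps.rankdata(x[ok])
    yr = sps.rankdata(y[ok])
    if np.std(xr) == 0 or np.std(yr) == 0:
        return np.nan, np.nan, n
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p, n


def spearman_critical_rho(n: int, alpha: float = 0.05) -> float:
    """Smallest |rho| significant at level alpha under the t-test."""
    t_crit = sps.t.isf(alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def mode_variable_correlations(
    coefficients: np.ndarray,
    variables: pd.DataFrame,
    min_pairs: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (and p) between each retained mode's coefficients and
    each cohort variable, pairwise-complete.  Constant columns give NaN.
    """
    C = np.atleast_2d(np.asarray(coefficients, dtype=float))
    rho = pd.DataFrame(index=variables.columns, columns=range(C.shape[1]), dtype=float)
    pval = rho.copy()
    for col in variables.columns:
        y = pd.to_numeric(variables[col], errors="coerce").to_numpy(dtype=float)
        for j in range(C.shape[1]):
            r, p, n = spearman_with_t_test(C[:, j], y)
            if n < min_pairs:
                r, p = np.nan, np.nan
            rho.loc[col, j] = r
            pval.loc[col, j] = p
    return rho, pval
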