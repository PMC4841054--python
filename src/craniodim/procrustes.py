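"""Generalized Procrustes analysis and allometry/age adjustment.

Shape is extracted by full Procrustes superimposition: every
configuration is centered, scaled to unit centroid size, and rotated
(proper rotations only — reflections are never admitted, so chirality
is preserved) onto an iteratively re-estimated consensus.  The
superimposed coordinates are used directly as shape coordinates; no
tangent-space projection is applied, which at facial levels of shape
variation differs negligibly from projected coordinates.

Allometry and age effects are removed by per-coordinate least-squares
regression of the shape coordinates on centroid size and age, pooled
across sexes, keeping the residuals (plus the consensus) as adjusted
shape coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "ordinary_procrustes_align",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "generalized_procrustes",
    "GpaResult",
    "AllometryAgeAdjuster",
    "adjust_for_size_and_age",
    "AdjustedShapes",
]


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    points = np.asarray(config, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"expected an (k, 3) point set, got shape {points.shape}")
    return points


def centroid_size(config) -> float:
    """Root summed squared landmark distances from the centroid (mm)."""
    points = _as_points(config)
    centered = points - points.mean(axis=0)
    size = float(np.sqrt((centered ** 2).sum()))
    if size == 0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return size


def _normalize(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    size = np.sqrt((centered ** 2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / size


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target - moving @ R.T||_F.

    Reflections are excluded by flipping the sign of the smallest
    singular vector when the Kabsch cross-covariance has negative
    determinant (this also breaks degenerate-singular-value ties).
    """
    h = target.T @ moving
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    return u @ d @ vt


def ordinary_procrustes_align(moving, target) -> tuple[np.ndarray, float]:
    """Full ordinary Procrustes fit of ``moving`` onto ``target``.

    Both point sets are centered and scaled to unit centroid size; the
    optimal proper rotation is then applied to ``moving``.  Returns the
    aligned (unit-size, centered) copy of ``moving`` and the residual
    root-summed-squared distance to the normalized target.
    """
    a = _as_points(target)
    b = _as_points(moving)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if np.linalg.matrix_rank(a - a.mean(axis=0)) < 2 or np.linalg.matrix_rank(
        b - b.mean(axis=0)
    ) < 2:
        raise ValueError("degenerate point set: rank < 2")
    a_n = _normalize(a)
    b_n = _normalize(b)
    rotation = _optimal_rotation(b_n, a_n)
    aligned = b_n @ rotation.T
    residual = float(np.sqrt(((a_n - aligned) ** 2).sum()))
    return aligned, residual


def procrustes_distance(shape_a, shape_b, atol: float = 1e-6) -> float:
    """Procrustes distance between two centered, unit-size shapes.

    Root summed squared coordinate difference after optimally rotating
    ``shape_b`` onto ``shape_a`` (proper rotations only).  Inputs must
    already be normalized; pass raw configurations through
    :func:`ordinary_procrustes_align` or ``_normalize`` first.
    """
    a = _as_points(shape_a)
    b = _as_points(shape_b)
    for name, s in (("shape_a", a), ("shape_b", b)):
        if np.abs(s.mean(axis=0)).max() > atol or abs((s ** 2).sum() - 1.0) > atol:
            raise ValueError(
                f"{name} is not centered at unit centroid size; "
                "normalize shapes before computing Procrustes distance"
            )
    rotation = _optimal_rotation(b, a)
    return float(np.sqrt(((a - b @ rotation.T) ** 2).sum()))


@dataclass
class GpaResult:
    """Outcome of a generalized Procrustes superimposition."""

    subject_ids: list[str] | None
    shape_coords: np.ndarray  # (n, k, 3) unit-size superimposed shapes
    centroid_sizes: np.ndarray  # (n,) original sizes, mm
    consensus: np.ndarray  # (k, 3) mean shape, unit size
    iterations: int
    converged: bool


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes superimposition as a transformer.

    ``fit`` estimates the consensus from a stack of configurations;
    ``transform`` maps configurations (n, k, 3) or flattened (n, 3k) to
    superimposed unit-size shape coordinates aligned to that consensus.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-summed-squared change of the
        consensus between iterations.
    max_iter : int
        Iteration cap; non-convergence is flagged, not fatal.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def _stack(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], LandmarkConfiguration):
            X = np.stack([c.coords for c in X])
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # flattened (n, 3k)
            if X.shape[1] % 3:
                raise ValueError("flattened shape matrix width must be a multiple of 3")
            X = X.reshape(X.shape[0], -1, 3)
        if X.ndim != 3 or X.shape[2] != 3 or X.shape[0] < 2:
            raise ValueError(
                f"expected >= 2 configurations of (k, 3) points, got shape {X.shape}"
            )
        return X

    def fit(self, X, y=None):
        configs = self._stack(X)
        n = configs.shape[0]
        sizes = np.empty(n)
        normalized = np.empty_like(configs)
        for i, config in enumerate(configs):
            sizes[i] = centroid_size(config)
            normalized[i] = _normalize(config)

        consensus = normalized[0]
        aligned = normalized.copy()
        converged = False
        iteration = 0
        for iteration in range(1, self.max_iter + 1):
            for i in range(n):
                rotation = _optimal_rotation(normalized[i], consensus)
                aligned[i] = normalized[i] @ rotation.T
            new_consensus = _normalize(aligned.mean(axis=0))
            change = np.sqrt(((new_consensus - consensus) ** 2).sum())
            consensus = new_consensus
            if change < self.tol:
                converged = True
                break

        self.consensus_ = consensus
        self.n_iter_ = iteration
        self.converged_ = converged
        self.shape_coords_ = aligned
        self.centroid_sizes_ = sizes
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "consensus_")
        configs = self._stack(X) if not (
            isinstance(X, np.ndarray) and X.ndim == 3
        ) else np.asarray(X, dtype=float)
        out = np.empty_like(configs, dtype=float)
        for i, config in enumerate(configs):
            normalized = _normalize(np.asarray(config, dtype=float))
            rotation = _optimal_rotation(normalized, self.consensus_)
            out[i] = normalized @ rotation.T
        return out

    def result(self, subject_ids: list[str] | None = None) -> GpaResult:
        check_is_fitted(self, "consensus_")
        return GpaResult(
            subject_ids=subject_ids,
            shape_coords=self.shape_coords_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            iterations=self.n_iter_,
            converged=self.converged_,
        )


def generalized_procrustes(configs, subject_ids=None, tol=1e-10, max_iter=100) -> GpaResult:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    return GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(configs).result(subject_ids)


@dataclass
class AdjustedShapes:
    """Shape coordinates with size and age effects regressed out."""

    subject_ids: list[str] | None
    residuals: np.ndarray  # (n, k, 3) deviations around the fitted model
    consensus: np.ndarray  # (k, 3) superimposition consensus
    coefficients: np.ndarray  # (2, 3k): rows = centroid size, age slopes
    intercepts: np.ndarray  # (3k,)

    @property
    def adjusted_coords(self) -> np.ndarray:
        """Covariate-adjusted configurations: consensus + residuals."""
        return self.consensus[None, :, :] + self.residuals


class AllometryAgeAdjuster(BaseEstimator, TransformerMixin):
    """Remove allometry and age from shape coordinates by regression.

    Each of the 3k shape coordinates is regressed on centroid size and
    age (pooled across sexes); ``transform`` returns the residuals.  The
    pooled fit leaves any sex mean difference intact for testing.
    """

    def fit(self, X, covariates):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        flat = X.reshape(n, -1)
        cov = np.asarray(covariates, dtype=float)
        if cov.shape != (n, 2):
            raise ValueError(
                f"covariates must be (n, 2) [centroid size, age], got {cov.shape}"
            )
        if np.ptp(cov[:, 0]) == 0 or np.ptp(cov[:, 1]) == 0:
            raise ValueError("constant covariate: cannot adjust for size/age")
        design = np.column_stack([np.ones(n), cov])
        beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
        self.intercepts_ = beta[0]
        self.coefficients_ = beta[1:]
        self._shape = X.shape[1:]
        return self

    def transform(self, X, covariates) -> np.ndarray:
        check_is_fitted(self, "coefficients_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        flat = X.reshape(n, -1)
        cov = np.asarray(covariates, dtype=float)
        fitted = self.intercepts_[None, :] + cov @ self.coefficients_
        return (flat - fitted).reshape(X.shape)

    def fit_transform(self, X, covariates) -> np.ndarray:
        return self.fit(X, covariates).transform(X, covariates)


def adjust_for_size_and_age(gpa: GpaResult, sizes=None, ages=None) -> AdjustedShapes:
    """Regress superimposed shape coordinates on centroid size and age.

    ``sizes`` defaults to the GPA-recorded centroid sizes.  Returns the
    residual deviations together with the consensus, so adjusted
    configurations can be reconstituted as ``consensus + residuals``.
    """
    sizes = gpa.centroid_sizes if sizes is None else np.asarray(sizes, dtype=float)
    if ages is None:
        raise ValueError("ages are required to adjust for age")
    ages = np.asarray(ages, dtype=float)
    n = gpa.shape_coords.shape[0]
    if len(sizes) != n or len(ages) != n:
        raise ValueError("one centroid size and age per sample required")
    adjuster = AllometryAgeAdjuster()
    covariates = np.column_stack([sizes, ages])
    residuals = adjuster.fit_transform(gpa.shape_coords, covariates)
    return AdjustedShapes(
        subject_ids=gpa.subject_ids,
        residuals=residuals,
        consensus=gpa.consensus,
        coefficients=adjuster.coefficients_,
        intercepts=adjuster.intercepts_,
    )
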