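"""Post-superimposition statistics over homologized vertex coordinates.

The nearest-neighbor pairings stored by a superimposition run assign
every final-prototype vertex a matched point on each specimen.  Stacking
those matches gives a specimens-by-(3 * vertex-count) coordinate matrix —
the surface analogue of a landmark data matrix — on which standard
multivariate machinery applies: per-vertex variance heat maps, principal
component ordination, and regression of vertex coordinates onto
ordination scores for visualizing what a component means anatomically.

Vertex data are extremely high-dimensional (3V columns for a handful of
specimens), so the principal axes are computed through the N x N Gram
matrix of centered rows (specimen space) rather than the 3V x 3V
covariance; the two routes agree exactly up to per-axis sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .driver import GPSAResult

__all__ = [
    "HomologizedMatrix",
    "OrdinationResult",
    "homologize",
    "pointwise_variance",
    "ordinate",
    "vertex_regression",
    "extreme_projection_surfaces",
]


@dataclass
class HomologizedMatrix:
    """Specimens x (3 * prototype-vertex-count) coordinate matrix.

    Row ``i`` holds, for each final-prototype vertex ``v``, the x, y, z
    coordinates (interleaved) of specimen ``i``'s point matched as the
    nearest neighbor of ``v``.
    """

    matrix: np.ndarray
    specimen_labels: list

    @property
    def n_specimens(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[1] // 3


@dataclass
class OrdinationResult:
    """Principal axes of the homologized matrix, variance-ordered."""

    scores: np.ndarray  # (N, K) projections of centered rows
    axis_variances: np.ndarray  # (K,) descending
    mean: np.ndarray  # (3V,) row mean
    axes: np.ndarray  # (K, 3V) unit vectors


def homologize(result: GPSAResult) -> HomologizedMatrix:
    """Build the homologized coordinate matrix from stored pairings."""
    if result.pairings is None or result.pairings.size == 0:
        raise ValueError("superimposition result carries no pairings")
    rows = []
    for i, surf in enumerate(result.surfaces):
        rows.append(surf.points[result.pairings[:, i]].reshape(-1))
    return HomologizedMatrix(np.vstack(rows), list(result.labels))


def pointwise_variance(result: GPSAResult) -> np.ndarray:
    """Total variance of each prototype vertex's matched points.

    For every prototype vertex, the trace of the 3x3 covariance matrix
    (unbiased, N-1 divisor) of its nearest-neighbor matches across the
    sample — a rotation-invariant scalar in squared length units, ready
    for heat-map export.
    """
    n = len(result.surfaces)
    if n < 2:
        raise ValueError("pointwise variance needs at least 2 specimens")
    hm = homologize(result)
    coords = hm.matrix.reshape(n, -1, 3)  # (N, V, 3)
    return coords.var(axis=0, ddof=1).sum(axis=1)


def ordinate(matrix: HomologizedMatrix | np.ndarray, k: int | None = None) -> OrdinationResult:
    """Principal component ordination via the specimen-space route.

    Rows are centered; the N x N Gram matrix is eigendecomposed; the
    eigenvectors are mapped back to unit axes in coordinate space.
    Scores are the centered rows projected on those axes.  ``k`` defaults
    to ``min(N - 1, 10)`` and may not exceed ``N - 1``.  Axis signs are
    fixed so each axis's largest-magnitude coordinate is positive.
    """
    x = matrix.matrix if isinstance(matrix, HomologizedMatrix) else np.asarray(matrix)
    n = x.shape[0]
    if n < 2:
        raise ValueError("ordination needs at least 2 specimens")
    if k is None:
        k = min(n - 1, 10)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]; got {k}")
    mean = x.mean(axis=0)
    xc = x - mean
    gram = xc @ xc.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:k]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    axes = np.zeros((k, x.shape[1]))
    scores = np.zeros((n, k))
    for a in range(k):
        v = xc.T @ evecs[:, a]
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
        # deterministic sign: largest-|component| coordinate positive
        pivot = np.argmax(np.abs(v))
        if v[pivot] < 0:
            v = -v
        axes[a] = v
        scores[:, a] = xc @ v
    return OrdinationResult(
        scores=scores,
        axis_variances=evals / max(n - 1, 1),
        mean=mean,
        axes=axes,
    )


def vertex_regression(
    matrix: HomologizedMatrix | np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regress every vertex's coordinates onto one ordination axis.

    Ordinary least squares of each vertex coordinate (across specimens)
    on the score vector gives a per-vertex 3-vector slope: the direction
    and rate of vertex displacement per unit score.  The color scalar is
    the squared magnitude of that slope, min-max scaled across vertices
    to [0, 1] for heat-map rendering.
    """
    x = matrix.matrix if isinstance(matrix, HomologizedMatrix) else np.asarray(matrix)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(scores) != x.shape[0]:
        raise ValueError("one score per specimen is required")
    if x.shape[0] < 3:
        raise ValueError("vertex regression needs at least 3 specimens")
    sc = scores - scores.mean()
    ss = float(sc @ sc)
    if ss <= 0:
        raise ValueError("scores are constant; regression is undefined")
    xc = x - x.mean(axis=0)
    slopes = (xc.T @ sc) / ss  # (3V,)
    slopes = slopes.reshape(-1, 3)
    color = (slopes**2).sum(axis=1)
    lo, hi = color.min(), color.max()
    scaled = np.zeros_like(color) if hi == lo else (color - lo) / (hi - lo)
    return slopes, scaled


def extreme_projection_surfaces(
    result: GPSAResult, ordination: OrdinationResult, axis: int = 0
) -> tuple[tuple[str, float], tuple[str, float]]:
    """Specimens with the minimal and maximal score on one axis.

    Used to display the extremes of a shape-variation axis against the
    semi-transparent mean surface.  Ties resolve to the lowest specimen
    index.  Returns ``((min_label, min_score), (max_label, max_score))``.
    """
    if not 0 <= axis < ordination.scores.shape[1]:
        raise ValueError(
            f"axis {axis} out of range for {ordination.scores.shape[1]} axes"
        )
    col = ordination.scores[:, axis]
    labels = result.labels
    i_min, i_max = int(np.argmin(col)), int(np.argmax(col))
    return (labels[i_min], float(col[i_min])), (labels[i_max], float(col[i_max]))
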