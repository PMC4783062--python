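"""The Procrustes Surface Metric (PSM) and its landmark counterpart.

Surfaces lack the index homology of landmark configurations, so shape
distance is measured over nearest-neighbor pairings instead.  For surfaces
A and B with points ``p`` and nearest neighbors ``q``::

    D = sqrt( 1/(2 m_A) * sum_i ||p_A,i - q_B,i||^2
            + 1/(2 m_B) * sum_j ||p_B,j - q_A,j||^2 )

Each surface contributes half the squared distance, normalized by its own
point count, so the metric is symmetric in its arguments and insensitive
to how many points each scan contains.  It is an RMS-style quantity: for
two configurations of m landmarks whose nearest neighbors are exactly the
homologous points, D equals the Procrustes distance P divided by sqrt(m)
(see :func:`check_eq4`, which verifies the identity numerically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_index import build_index

__all__ = [
    "LandmarkConfig",
    "psm",
    "procrustes_distance",
    "check_eq4",
    "pairwise_psm_matrix",
]


@dataclass
class LandmarkConfig:
    """Ordered landmark configuration; homology is by index."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError("a landmark configuration needs >= 3 finite 3D points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self.points = pts


def _points_of(obj) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(getattr(obj, "points", obj), dtype=np.float64))
    if pts.size == 0:
        raise ValueError("empty surface")
    return pts


def psm(A, B, corr=None) -> float:
    """Procrustes Surface Metric between two surfaces as positioned.

    ``A`` and ``B`` may be :class:`~gpsa.mesh_io.Surface` objects or bare
    ``(n, 3)`` coordinate arrays.  If ``corr`` (a
    :class:`~gpsa.icp.CorrespondenceSet`) is omitted, fresh bidirectional
    nearest-neighbor pairings are computed.  Summation within each
    directed term runs in point order, so exchanging the arguments gives
    a bit-identical value.
    """
    pa, pb = _points_of(A), _points_of(B)
    if corr is None:
        _, d_ab = build_index(pb).all_nearest(pa)
        _, d_ba = build_index(pa).all_nearest(pb)
    else:
        d_ab = np.asarray(corr.a_to_b_distance, dtype=np.float64)
        d_ba = np.asarray(corr.b_to_a_distance, dtype=np.float64)
    term_a = (d_ab**2).sum() / (2.0 * len(pa))
    term_b = (d_ba**2).sum() / (2.0 * len(pb))
    return float(np.sqrt(term_a + term_b))


def procrustes_distance(X, Y, superimpose: bool = True) -> float:
    """Partial Procrustes distance between two landmark configurations.

    The root of summed squared distances between homologous points, after
    translating both configurations to a common centroid and rotating one
    onto the other by the optimal (SVD, reflection-corrected) rotation.
    No scaling is applied: scale both inputs to unit centroid size first
    to obtain the size-free distance.  With ``superimpose=False`` the
    configurations are measured exactly as given.
    """
    x = _points_of(X)
    y = _points_of(Y)
    if x.shape != y.shape:
        raise ValueError(
            f"landmark counts differ: {x.shape[0]} vs {y.shape[0]}"
        )
    if superimpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        u, _, vt = np.linalg.svd(xc.T @ yc)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt  # proper rotation mapping yc to xc
        x, y = xc, yc @ rot.T
    return float(np.sqrt(((x - y) ** 2).sum()))


def check_eq4(X, Y) -> tuple[float, float, float]:
    """Compare surface-metric and landmark-distance readings of one pair.

    Treats each configuration as a surface whose nearest-neighbor pairing
    is the index homology, computes the surface metric D under that
    pairing, the Procrustes distance P of the pair as positioned divided
    by sqrt(m), and returns ``(D, P/sqrt(m), |difference|)``.  When every
    point's nearest neighbor genuinely is its homologue the two values
    agree to floating-point precision.
    """
    x = _points_of(X)
    y = _points_of(Y)
    if x.shape != y.shape:
        raise ValueError("configurations must have equal landmark counts")
    m = len(x)
    d_pairs = np.linalg.norm(x - y, axis=1)
    d_val = float(np.sqrt((d_pairs**2).sum() / (2.0 * m) + (d_pairs**2).sum() / (2.0 * m)))
    p_scaled = procrustes_distance(x, y, superimpose=False) / np.sqrt(m)
    return d_val, float(p_scaled), abs(d_val - float(p_scaled))


def pairwise_psm_matrix(surfaces) -> pd.DataFrame:
    """Symmetric matrix of PSM values between superimposed surfaces.

    Assumes the surfaces already sit in a common frame (e.g. after a full
    superimposition run); each entry uses fresh bidirectional pairings
    between that pair of surfaces.
    """
    labels = [
        getattr(s, "label", "") or f"specimen_{i}" for i, s in enumerate(surfaces)
    ]
    n = len(surfaces)
    mat = np.zeros((n, n), dtype=np.float64)
    indexes = [build_index(_points_of(s)) for s in surfaces]
    for i in range(n):
        pi = _points_of(surfaces[i])
        for j in range(i + 1, n):
            pj = _points_of(surfaces[j])
            _, d_ij = indexes[j].all_nearest(pi)
            _, d_ji = indexes[i].all_nearest(pj)
            v = np.sqrt(
                (d_ij**2).sum() / (2.0 * len(pi)) + (d_ji**2).sum() / (2.0 * len(pj))
            )
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)
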