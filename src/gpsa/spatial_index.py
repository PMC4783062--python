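"""Exact nearest-neighbor queries between surfaces.

Nearest-neighbor pairing approximates point homology between surfaces, so
the index must be exact, not approximate: the symmetry of the surface
metric relies on true nearest neighbors.  A k-d tree provides the exact-NN
contract; ties (several source points at the same minimal distance) are
resolved deterministically in favor of the smallest source index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NeighborIndex", "build_index"]

# relative window within which a runner-up neighbor triggers exact
# tie resolution against squared distances
_TIE_RTOL = 1e-9


class NeighborIndex:
    """Spatial index over a fixed set of source points.

    Queries return the index of the exactly nearest source point under
    Euclidean distance, smallest index winning ties.
    """

    def __init__(self, points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if points.size == 0:
            raise ValueError("cannot build an index over an empty point set")
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError(f"source points must be (m, 3); got {points.shape}")
        self.points = points
        self._tree = cKDTree(points)

    def __len__(self) -> int:
        return len(self.points)

    def nearest(self, query: np.ndarray) -> tuple[int, float]:
        """Exact nearest neighbor of a single query point."""
        idx, dist = self.all_nearest(np.asarray(query, dtype=np.float64)[None, :])
        return int(idx[0]), float(dist[0])

    def all_nearest(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Exact nearest neighbors for a batch of query points.

        Returns ``(indices, distances)`` arrays aligned with ``queries``.
        Distances are recomputed from coordinates, so they agree with
        ``np.linalg.norm`` to the last ulp.
        """
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        if queries.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
        if len(self.points) == 1:
            idx = np.zeros(len(queries), dtype=np.int64)
        else:
            dd, jj = self._tree.query(queries, k=2)
            idx = jj[:, 0].astype(np.int64)
            # near-ties: re-examine candidates with exact squared distances
            close = dd[:, 1] <= dd[:, 0] * (1.0 + _TIE_RTOL) + 1e-300
            for i in np.nonzero(close)[0]:
                idx[i] = self._resolve_tie(queries[i], dd[i, 0])
        dist = np.linalg.norm(self.points[idx] - queries, axis=1)
        return idx, dist

    def _resolve_tie(self, query: np.ndarray, approx_dist: float) -> int:
        radius = approx_dist * (1.0 + _TIE_RTOL) + 1e-300
        cand = np.sort(np.asarray(self._tree.query_ball_point(query, radius)))
        if cand.size == 0:  # numerical guard; fall back to tree answer
            return int(self._tree.query(query)[1])
        sq = ((self.points[cand] - query) ** 2).sum(axis=1)
        return int(cand[np.argmin(sq)])


def build_index(points: np.ndarray) -> NeighborIndex:
    """Build an exact nearest-neighbor index over ``points``."""
    return NeighborIndex(points)
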