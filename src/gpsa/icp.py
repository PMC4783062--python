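"""Symmetric point-to-plane ICP superimposition of two surfaces.

Classic ICP is asymmetric: pairing points of A with their nearest
neighbors on B and minimizing gives a different relative configuration
than pairing B against A.  The cost used here takes both pairing
directions into account while remaining a function of a single rigid
transform, so the superimposition is (up to numerics) independent of
which surface moves::

    C = sum_i ( (p_A,i - (H q_B,i - t)) . n_A,i )^2
      + sum_j ( ((H p_B,j - t) - q_A,j) . n_B,j )^2

where ``q`` denotes nearest neighbors, ``n`` unit normals, and the
unknown motion ``y -> H y - t`` acts on surface B's points in both sums,
so the two directed terms pull the same relative alignment.  Each residual is the distance from a
point to the tangent plane of its paired point (point-to-plane), which
converges much faster than point-to-point on smooth surfaces.

The solve linearizes ``H ~ I + [r]x`` and minimizes a 6-unknown linear
least-squares problem in ``(r, t)``; the rotation is re-orthonormalized
through the axis-angle (Rodrigues) map, and the step is halved until the
exact cost at fixed correspondences does not increase.

Initialization aligns centroids and the two longest principal axes of
each surface under all four sign (reflection) combinations, keeping the
candidate with the lowest surface-metric value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import metric
from .mesh_io import Surface
from .spatial_index import NeighborIndex, build_index

__all__ = [
    "RigidTransform",
    "CorrespondenceSet",
    "ICPParams",
    "ICPResult",
    "DegenerateGeometryError",
    "principal_axes",
    "init_candidates",
    "select_init",
    "correspond",
    "solve_symmetric_step",
    "eq_cost",
    "icp_superimpose",
]

#: angular step (radians) above which the linearization is not trusted
_MAX_TRUSTED_STEP = 0.1


class DegenerateGeometryError(RuntimeError):
    """The geometry does not constrain a rigid transform (e.g. all normals
    parallel, or collinear points)."""


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        self.rotation, self.translation = r, t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec)).as_matrix(), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_to(self, surface: Surface) -> Surface:
        """Transform a surface; normals rotate, faces and label are kept."""
        return surface.with_points(
            self.apply(surface.points), surface.normals @ self.rotation.T
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )


@dataclass
class CorrespondenceSet:
    """Directed nearest-neighbor pairings between two surfaces."""

    a_to_b_index: np.ndarray
    a_to_b_distance: np.ndarray
    b_to_a_index: np.ndarray
    b_to_a_distance: np.ndarray


@dataclass
class ICPParams:
    """Iteration controls for :func:`icp_superimpose`."""

    max_iterations: int = 100
    tolerance: float = 1e-6
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ICPResult:
    transform: RigidTransform
    correspondences: CorrespondenceSet
    psm: float
    cost_trace: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# initialization


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and orthonormal principal axes ordered by decreasing variance.

    The third axis is the cross product of the first two, so the returned
    frame is always right-handed (this removes one of the three sign
    ambiguities of eigenvectors).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / max(len(pts) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1e-300):
        raise DegenerateGeometryError("principal axes undefined for collinear points")
    axes = np.empty((3, 3), dtype=np.float64)
    axes[0], axes[1] = evecs[:, 0], evecs[:, 1]
    axes[2] = np.cross(axes[0], axes[1])
    return centroid, axes


def init_candidates(A: Surface, B: Surface) -> list[RigidTransform]:
    """Four rigid initializations of A onto B's principal frame.

    Matches centroids and maps A's first/second axes onto B's under the
    four sign combinations (+,+), (+,-), (-,+), (-,-); the third axis is
    always the cross product, so every candidate is a proper rotation.
    """
    ca, axes_a = principal_axes(A.points)
    cb, axes_b = principal_axes(B.points)
    candidates = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        fa = np.empty((3, 3))
        fa[0], fa[1] = s1 * axes_a[0], s2 * axes_a[1]
        fa[2] = np.cross(fa[0], fa[1])
        rot = axes_b.T @ fa  # maps fa-frame onto axes_b-frame
        candidates.append(RigidTransform(rot, cb - rot @ ca))
    return candidates


def select_init(A: Surface, B: Surface, candidates: list[RigidTransform]) -> RigidTransform:
    """Candidate with the lowest surface metric after application to A.

    Ties are broken by candidate order.
    """
    if not candidates:
        raise ValueError("no initialization candidates supplied")
    index_b = build_index(B.points)
    index_needed = len(candidates) > 1
    best, best_val = None, np.inf
    for cand in candidates:
        moved = cand.apply(A.points)
        _, d_ab = index_b.all_nearest(moved)
        if index_needed:
            _, d_ba = build_index(moved).all_nearest(B.points)
        else:
            return cand
        val = np.sqrt(
            (d_ab**2).sum() / (2.0 * len(moved)) + (d_ba**2).sum() / (2.0 * len(B.points))
        )
        if val < best_val:
            best, best_val = cand, val
    return best


# ---------------------------------------------------------------------------
# correspondences and cost


def correspond(
    A: Surface | np.ndarray,
    B: Surface | np.ndarray,
    index_a: NeighborIndex | None = None,
    index_b: NeighborIndex | None = None,
) -> CorrespondenceSet:
    """Bidirectional nearest-neighbor pairings between A and B as positioned."""
    pa = np.asarray(getattr(A, "points", A), dtype=np.float64)
    pb = np.asarray(getattr(B, "points", B), dtype=np.float64)
    index_a = index_a or build_index(pa)
    index_b = index_b or build_index(pb)
    i_ab, d_ab = index_b.all_nearest(pa)
    i_ba, d_ba = index_a.all_nearest(pb)
    return CorrespondenceSet(i_ab, d_ab, i_ba, d_ba)


def eq_cost(
    A: Surface,
    B: Surface,
    corr: CorrespondenceSet,
    rotvec: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    symmetric: bool = True,
) -> float:
    """Exact point-to-plane cost at fixed correspondences.

    ``(rotvec, translation)`` parametrize a candidate relative motion;
    omitting them evaluates the cost of the current configuration.  In
    symmetric mode the motion is split half-and-half between the two
    surfaces, so the value is exactly invariant under exchanging A and B
    (with the motion negated) — the property the whole superimposition
    relies on.  With ``symmetric=False`` only the A-side sum is used and
    the full motion acts on B's points (``q -> H q - t``).
    """
    r = np.zeros(3) if rotvec is None else np.asarray(rotvec, dtype=np.float64)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=np.float64)
    qb = B.points[corr.a_to_b_index]
    if not symmetric:
        h = Rotation.from_rotvec(r).as_matrix()
        res_a = np.einsum("ij,ij->i", A.points - (qb @ h.T - t), A.normals)
        return float((res_a**2).sum())
    hh = Rotation.from_rotvec(r / 2.0).as_matrix()
    # A moves by (Rh^T, +t/2), B by (Rh, -t/2); composed = the full motion
    diff_a = A.points @ hh - qb @ hh.T + t
    res_a = np.einsum("ij,ij->i", diff_a, A.normals @ hh)
    qa = A.points[corr.b_to_a_index]
    diff_b = B.points @ hh.T - qa @ hh - t
    res_b = np.einsum("ij,ij->i", diff_b, B.normals @ hh.T)
    return float((res_a**2).sum() + (res_b**2).sum())


# ---------------------------------------------------------------------------
# linearized solve


def solve_symmetric_step(
    A: Surface,
    B: Surface,
    corr: CorrespondenceSet,
    symmetric: bool = True,
) -> RigidTransform:
    """One damped, linearized point-to-plane step, returned as A's motion.

    Builds the 6x6 normal equations of the linearized cost (rotation
    vector ``r`` and translation ``t``), solves, re-orthonormalizes the
    rotation through the Rodrigues map, and halves the step until the
    exact cost at these correspondences does not increase (and the
    angular step is below 0.1 rad, where the linearization is reliable).
    The solved motion acts on B; the inverse — the motion that moves A
    into alignment — is returned.
    """
    jac, rhs = _build_system(A, B, corr, symmetric)
    step, _ = _damped_step(A, B, corr, jac, rhs, symmetric)
    return step


def _build_system(A, B, corr, symmetric):
    qb = B.points[corr.a_to_b_index]
    na = A.normals
    if symmetric:
        # midpoint (swap-antisymmetric) linearization: exchanging the roles
        # of A and B maps the linear system onto its exact mirror, so the
        # two directions of superimposition follow mirrored trajectories
        # instead of diverging at second order in the step size
        mid_a = 0.5 * (A.points + qb)
        rows_a = np.hstack([-np.cross(mid_a, na), na])
        rhs_a = np.einsum("ij,ij->i", A.points - qb, na)
        qa = A.points[corr.b_to_a_index]
        nb = B.normals
        mid_b = 0.5 * (B.points + qa)
        rows_b = np.hstack([np.cross(mid_b, nb), -nb])
        rhs_b = np.einsum("ij,ij->i", B.points - qa, nb)
        jac = np.vstack([rows_a, rows_b])
        rhs = np.concatenate([rhs_a, rhs_b])
    else:
        # classic one-directional rows: residual = (p_A - q_B).n_A + t.n_A
        # - r.(q_B x n_A)
        jac = np.hstack([-np.cross(qb, na), na])
        rhs = np.einsum("ij,ij->i", A.points - qb, na)
    return jac, rhs


def _damped_step(A, B, corr, jac, rhs, symmetric):
    """Solve the 6x6 normal equations and damp; returns (step, exact cost)."""
    jtj = jac.T @ jac
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateGeometryError(
            f"normal equations ill-conditioned (condition number {cond:.3e}); "
            "the surfaces' geometry does not constrain a rigid motion"
        )
    x = np.linalg.solve(jtj, -jac.T @ rhs)
    r, t = x[:3], x[3:]

    current = eq_cost(A, B, corr, symmetric=symmetric)
    accepted = False
    for _ in range(60):
        trial = eq_cost(A, B, corr, r, t, symmetric=symmetric)
        if np.linalg.norm(r) <= _MAX_TRUSTED_STEP and trial <= current * (1 + 1e-12) + 1e-300:
            accepted = True
            break
        r, t = r / 2.0, t / 2.0
    if not accepted:
        return RigidTransform.identity(), current
    h = Rotation.from_rotvec(r).as_matrix()
    if symmetric:
        # the split parametrization composes to the motion (H, (H + I) t / 2)
        # acting on B; A's step is its inverse
        t_eff = 0.5 * (h @ t + t)
    else:
        t_eff = t
    return RigidTransform(h.T, h.T @ t_eff), trial


# ---------------------------------------------------------------------------
# driver


def icp_superimpose(
    A: Surface,
    B: Surface,
    params: ICPParams | None = None,
    init: RigidTransform | None = None,
) -> ICPResult:
    """Superimpose A onto B by iterated pairing and rigid solving.

    A moves; B stays fixed.  Without an explicit ``init``, the
    principal-axes/reflection search provides the starting pose.
    Iteration stops when the relative change of the cost falls below
    ``params.tolerance`` or ``params.max_iterations`` is reached.

    Returns the composed transform of A onto B, the final bidirectional
    correspondences, the final surface-metric value, and the per-iteration
    cost trace.
    """
    params = params or ICPParams()
    if init is None:
        init = select_init(A, B, init_candidates(A, B))
    current = init.apply_to(A)
    total = init
    index_b = build_index(B.points)

    trace: list[float] = []
    prev_cost: float | None = None
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        corr = correspond(current, B, index_b=index_b)
        cost_before = eq_cost(current, B, corr, symmetric=params.symmetric)
        if prev_cost is None:
            prev_cost = cost_before
        elif cost_before > prev_cost:
            # re-pairing no longer lowers the cost: we are at the optimum of
            # the discrete pairing landscape; stopping here also keeps the
            # recorded trace non-increasing
            converged = True
            break
        jac, rhs = _build_system(current, B, corr, params.symmetric)
        step, cost_after = _damped_step(
            current, B, corr, jac, rhs, params.symmetric
        )
        current = step.apply_to(current)
        total = step.compose(total)
        trace.append(cost_after)
        change = abs(prev_cost - cost_after) / max(prev_cost, cost_after, 1e-300)
        prev_cost = cost_after
        if change < params.tolerance:
            converged = True
            break

    final_corr = correspond(current, B, index_b=index_b)
    final_psm = metric.psm(current, B, corr=final_corr)
    return ICPResult(
        transform=total,
        correspondences=final_corr,
        psm=final_psm,
        cost_trace=trace,
        n_iterations=iterations,
        converged=converged,
    )
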