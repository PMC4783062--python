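"""Generalized superimposition of a surface sample to an evolving prototype.

The two-surface machinery only compares pairs.  To analyze a whole
sample, every surface is superimposed to a designated prototype (mean)
surface; each prototype vertex is then moved to the arithmetic mean of
its nearest-neighbor points, one per specimen, and vertices that received
identical nearest-neighbor sets are collapsed to a single point so no
region is overweighted.  The pass repeats until the prototype's shape
stops changing, as measured by the surface metric between successive
prototypes.

The prototype should be chosen by the researcher as the most complete,
least atypical specimen: with high sample variation, nearest-neighbor
homology degrades and the final mean becomes increasingly dependent on
that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import icp as _icp
from . import metric
from .mesh_io import Surface, scale_to_unit
from .spatial_index import build_index

__all__ = [
    "GPSAParams",
    "GPSAResult",
    "update_prototype",
    "remove_duplicates",
    "gpsa_run",
]


@dataclass
class GPSAParams:
    """Controls for :func:`gpsa_run`.

    ``tolerance`` is the surface-metric change between successive
    prototypes below which the outer loop stops; by default it is
    1e-4 times the prototype's bounding-box diagonal.
    """

    prototype: int | str = 0
    max_outer_iterations: int = 5
    tolerance: float | None = None
    scale_to_unit: bool = False
    icp: _icp.ICPParams = field(default_factory=_icp.ICPParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")
        if self.tolerance is not None and self.tolerance < 0:
            raise ValueError("tolerance must be nonnegative")


@dataclass
class GPSAResult:
    """Everything downstream statistics need from a superimposition run."""

    surfaces: list  # specimens in the common frame, input order
    prototype: Surface
    pairings: np.ndarray  # (V, N) specimen point index per prototype vertex
    psm_to_prototype: np.ndarray  # (N,)
    transforms: list  # composed RigidTransform per specimen
    iteration_log: list  # dicts: iteration, prototype_change, vertex counts
    converged: bool = False

    @property
    def labels(self) -> list:
        return [s.label for s in self.surfaces]


def update_prototype(prototype: Surface, surfaces) -> tuple[Surface, np.ndarray]:
    """Move each prototype vertex to the mean of its matches.

    For every prototype vertex the nearest-neighbor point on each
    specimen surface (all in a common frame) is found; the vertex moves
    to the arithmetic mean of those points.  Every specimen contributes —
    the entire nearest-neighbor set is used, with no exclusions.  Returns
    the updated surface (normals re-estimated from local neighborhoods)
    and the ``(V, N)`` matrix of matched specimen point indices, used for
    duplicate-point removal and for homologized statistics.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("specimen list is empty")
    nn_idx = np.empty((prototype.n_points, len(surfaces)), dtype=np.int64)
    acc = np.zeros_like(prototype.points)
    for k, surf in enumerate(surfaces):
        idx, _ = build_index(surf.points).all_nearest(prototype.points)
        nn_idx[:, k] = idx
        acc += surf.points[idx]
    new_points = acc / len(surfaces)
    updated = _make_prototype(
        new_points,
        None if prototype.faces is None else prototype.faces.copy(),
        prototype.label,
        fallback_normals=prototype.normals,
    )
    return updated, nn_idx


def _make_prototype(points, faces, label, fallback_normals=None) -> Surface:
    """Prototype surface with normals re-estimated from local neighborhoods.

    The prototype is treated as an oriented point cloud after averaging;
    faces are attached afterwards purely for visualization export.
    """
    if len(points) >= 10:
        surf = Surface(points=points, normals=None, faces=None, label=label)
    else:  # tiny prototypes cannot support neighborhood fitting
        surf = Surface(points=points, normals=fallback_normals, faces=None, label=label)
    surf.faces = faces
    return surf


def remove_duplicates(
    points: np.ndarray, nn_sets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop vertices whose nearest-neighbor sets are identical.

    After averaging, prototype vertices paired with the same specimen
    points across the whole sample land on the same location; keeping
    them would overweight that region.  Among each group of vertices with
    an identical matched-index tuple only the lowest-index one survives.
    Identity is exact integer-tuple equality, so no coordinate hashing
    tolerance is involved.

    Returns ``(kept_points, index_map)`` where ``index_map[old] = new``
    for survivors and ``-1`` for removed vertices.
    """
    points = np.asarray(points, dtype=np.float64)
    nn_sets = np.atleast_2d(np.asarray(nn_sets, dtype=np.int64))
    if len(nn_sets) != len(points):
        raise ValueError("nn_sets must align with points")
    _, first = np.unique(nn_sets, axis=0, return_index=True)
    keep = np.sort(first)
    index_map = np.full(len(points), -1, dtype=np.int64)
    index_map[keep] = np.arange(len(keep))
    return points[keep], index_map


def _remap_faces(faces: np.ndarray | None, index_map: np.ndarray) -> np.ndarray | None:
    """Keep faces whose three vertices all survived deduplication."""
    if faces is None:
        return None
    mapped = index_map[faces]
    ok = np.all(mapped >= 0, axis=1)
    mapped = mapped[ok]
    ok = (
        (mapped[:, 0] != mapped[:, 1])
        & (mapped[:, 1] != mapped[:, 2])
        & (mapped[:, 0] != mapped[:, 2])
    )
    out = mapped[ok]
    return out if len(out) else None


def _anchor_to_previous(old_points: np.ndarray, new_points: np.ndarray) -> np.ndarray:
    """Remove the rigid component of a prototype update.

    The averaging step is defined only up to a rigid motion of the whole
    configuration (the specimens re-align to wherever the prototype
    goes), so without anchoring the prototype can drift rigidly forever
    at a constant rate while its shape is unchanged.  Updated vertices
    correspond 1:1 to the old ones, so the optimal rigid alignment of
    the new prototype onto the old (Kabsch) fixes that gauge and leaves
    the shape change for the convergence test to measure.
    """
    mu_old = old_points.mean(axis=0)
    mu_new = new_points.mean(axis=0)
    xc = old_points - mu_old
    yc = new_points - mu_new
    u, _, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return yc @ rot.T + mu_old


def _resolve_prototype(surfaces, selector) -> int:
    if isinstance(selector, str):
        labels = [s.label for s in surfaces]
        if selector not in labels:
            raise ValueError(f"no specimen labelled {selector!r}")
        return labels.index(selector)
    idx = int(selector)
    if not 0 <= idx < len(surfaces):
        raise ValueError(
            f"prototype index {idx} out of range for {len(surfaces)} specimens"
        )
    return idx


def gpsa_run(surfaces, params: GPSAParams | None = None) -> GPSAResult:
    """Superimpose a sample of surfaces and estimate their mean surface.

    Steps: optional scaling of every specimen to unit centroid size;
    principal-axes initialization of each specimen to the starting
    prototype (a copy of the selected specimen); then an outer loop of
    per-specimen ICP superimposition followed by prototype averaging and
    duplicate removal, terminating when the surface metric between the
    old and new prototype drops below tolerance or the iteration budget
    is exhausted.  A final superimposition pass against the final
    prototype makes the stored pairings and per-specimen metric values
    mutually consistent.
    """
    surfaces = list(surfaces)
    params = params or GPSAParams()
    if len(surfaces) < 2:
        raise ValueError("generalized superimposition needs at least 2 surfaces")
    proto_idx = _resolve_prototype(surfaces, params.prototype)

    if params.scale_to_unit:
        surfaces = [scale_to_unit(s) for s in surfaces]

    prototype = surfaces[proto_idx].copy()
    tolerance = (
        params.tolerance
        if params.tolerance is not None
        else 1e-4 * prototype.bounding_box_diagonal
    )

    current: list[Surface] = []
    transforms: list[_icp.RigidTransform] = []
    for i, surf in enumerate(surfaces):
        try:
            init = _icp.select_init(surf, prototype, _icp.init_candidates(surf, prototype))
        except _icp.DegenerateGeometryError as exc:
            raise _icp.DegenerateGeometryError(
                f"specimen {surf.label or i}: {exc}"
            ) from exc
        current.append(init.apply_to(surf))
        transforms.append(init)

    log: list[dict] = []
    converged = False
    for outer in range(1, params.max_outer_iterations + 1):
        for i in range(len(current)):
            try:
                res = _icp.icp_superimpose(
                    current[i], prototype, params.icp, init=_icp.RigidTransform.identity()
                )
            except _icp.DegenerateGeometryError as exc:
                raise _icp.DegenerateGeometryError(
                    f"specimen {current[i].label or i}: {exc}"
                ) from exc
            current[i] = res.transform.apply_to(current[i])
            transforms[i] = res.transform.compose(transforms[i])

        averaged, nn_idx = update_prototype(prototype, current)
        anchored = _anchor_to_previous(prototype.points, averaged.points)
        points, index_map = remove_duplicates(anchored, nn_idx)
        new_prototype = _make_prototype(
            points,
            _remap_faces(averaged.faces, index_map),
            prototype.label,
            fallback_normals=averaged.normals[index_map >= 0],
        )
        change = metric.psm(prototype, new_prototype)
        log.append(
            {
                "iteration": outer,
                "prototype_change": float(change),
                "vertex_count": new_prototype.n_points,
            }
        )
        prototype = new_prototype
        if change < tolerance:
            converged = True
            break

    # final pass: pairings and metric values against the *final* prototype
    pairings = np.empty((prototype.n_points, len(current)), dtype=np.int64)
    psms = np.empty(len(current), dtype=np.float64)
    for i in range(len(current)):
        res = _icp.icp_superimpose(
            current[i], prototype, params.icp, init=_icp.RigidTransform.identity()
        )
        current[i] = res.transform.apply_to(current[i])
        transforms[i] = res.transform.compose(transforms[i])
        pairings[:, i] = res.correspondences.b_to_a_index
        psms[i] = res.psm

    return GPSAResult(
        surfaces=current,
        prototype=prototype,
        pairings=pairings,
        psm_to_prototype=psms,
        transforms=transforms,
        iteration_log=log,
        converged=converged,
    )
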