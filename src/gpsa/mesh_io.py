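"""Surface container, mesh I/O, normal estimation, and centroid-size scaling.

A :class:`Surface` is the atomic object of the whole pipeline: an oriented
point set (positions + unit normals), optionally carrying a triangulation.
All alignment and averaging operates on points and normals only; faces are
kept for visualization export.

Supported formats: PLY (ASCII and binary little-endian), OBJ and STL on
read; ASCII PLY on write, with an optional per-vertex float ``quality``
property and a blue-to-red color ramp for heat-map rendering.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree

__all__ = [
    "Surface",
    "SurfaceValidationError",
    "read_surface",
    "write_surface",
    "read_vertex_scalars",
    "read_landmarks",
    "compute_normals",
    "centroid_size",
    "scale_to_unit",
]

#: number of neighbors used for point-cloud normal estimation
_NORMAL_K = 12

#: absolute vertex-merge tolerance for STL facet soup
_STL_MERGE_TOL = 1e-8


class SurfaceValidationError(ValueError):
    """An input surface violates a structural invariant."""


@dataclass
class Surface:
    """Oriented 3D point set with optional triangulation.

    Parameters
    ----------
    points
        ``(n, 3)`` Cartesian coordinates, arbitrary length units.
    normals
        ``(n, 3)`` unit vectors, one per point.  If omitted they are
        estimated from faces (if present) or from local neighborhoods.
    faces
        Optional ``(m, 3)`` integer triangles, 0-based vertex indices.
    label
        Identifier used in tables and output file names.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    faces: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise SurfaceValidationError(
                f"points must be (n, 3); got shape {pts.shape}"
            )
        if len(pts) < 4:
            raise SurfaceValidationError(
                f"a surface needs at least 4 points; got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise SurfaceValidationError("points contain non-finite values")
        # principal-axes initialization needs a rank-2 point scatter
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-300):
            raise SurfaceValidationError("points are (numerically) collinear")
        self.points = pts

        if self.faces is not None:
            f = np.asarray(self.faces, dtype=np.int64)
            if f.size == 0:
                f = None
            else:
                if f.ndim != 2 or f.shape[1] != 3:
                    raise SurfaceValidationError("faces must be (m, 3) index triples")
                if f.min() < 0 or f.max() >= len(pts):
                    raise SurfaceValidationError("face index out of range")
            self.faces = f

        if self.normals is None:
            self.normals = _estimate_normals(self.points, self.faces)
        else:
            nrm = np.asarray(self.normals, dtype=np.float64)
            if nrm.shape != pts.shape:
                raise SurfaceValidationError("normals must match points in shape")
            lengths = np.linalg.norm(nrm, axis=1)
            if np.any(lengths < 1e-12):
                raise SurfaceValidationError("zero-length normal encountered")
            self.normals = nrm / lengths[:, None]

    # -- convenience ----------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def bounding_box_diagonal(self) -> float:
        extent = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(extent))

    def copy(self) -> "Surface":
        return replace(
            self,
            points=self.points.copy(),
            normals=self.normals.copy(),
            faces=None if self.faces is None else self.faces.copy(),
        )

    def with_points(self, points: np.ndarray, normals: np.ndarray) -> "Surface":
        """New surface with replaced geometry, same faces and label."""
        return replace(self, points=points, normals=normals)


# ---------------------------------------------------------------------------
# reading


def read_surface(path: str | Path, format: str = "auto") -> Surface:
    """Read a surface mesh or oriented point cloud from disk.

    ``format`` is one of ``ply``, ``obj``, ``stl`` or ``auto`` (from the
    file suffix).  Normals stored in PLY files are preserved (after
    renormalization); otherwise normals are computed.  STL facet soups are
    merged back to shared vertices within an absolute tolerance of 1e-8.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read surface file: {path}")
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format.lower()
    if fmt not in {"ply", "obj", "stl"}:
        raise SurfaceValidationError(f"unsupported mesh format: {fmt!r}")
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise IOError(f"failed to parse {path} as {fmt}: {exc}") from exc

    normals = None
    if isinstance(mesh, trimesh.points.PointCloud):
        points, faces = np.asarray(mesh.vertices, dtype=np.float64), None
    elif isinstance(mesh, trimesh.Trimesh):
        points = np.asarray(mesh.vertices, dtype=np.float64)
        faces = np.asarray(mesh.faces, dtype=np.int64)
    else:
        raise IOError(f"{path} did not contain a single mesh or point cloud")

    if fmt == "ply":
        normals = _ply_stored_normals(mesh)
    elif fmt == "stl":
        points, faces = _merge_vertices(points, faces, tol=_STL_MERGE_TOL)

    if len(points) < 4:
        raise SurfaceValidationError(
            f"{path}: a surface needs at least 4 vertices, found {len(points)}"
        )
    return Surface(points=points, normals=normals, faces=faces, label=path.stem)


def _ply_stored_normals(mesh) -> np.ndarray | None:
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is None:
        return None
    try:
        names = raw.keys() if isinstance(raw, dict) else raw.dtype.names
        if not {"nx", "ny", "nz"} <= set(names):
            return None
        cols = [np.asarray(raw[c], dtype=np.float64).ravel() for c in ("nx", "ny", "nz")]
    except Exception:  # noqa: BLE001 - metadata layout varies across trimesh versions
        return None
    normals = np.column_stack(cols)
    if np.any(np.linalg.norm(normals, axis=1) < 1e-12):
        return None
    return normals


def read_vertex_scalars(path: str | Path) -> np.ndarray | None:
    """Recover the per-vertex ``quality`` scalar channel from a PLY file."""
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is None:
        return None
    names = raw.keys() if isinstance(raw, dict) else raw.dtype.names
    if "quality" not in names:
        return None
    return np.asarray(raw["quality"], dtype=np.float64).ravel()


def read_landmarks(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited landmark table (x y z per row)."""
    table = np.atleast_2d(np.loadtxt(path, dtype=np.float64))
    if table.shape[1] != 3:
        raise SurfaceValidationError(
            f"{path}: landmark table must have 3 columns, found {table.shape[1]}"
        )
    return table


def _merge_vertices(points, faces, tol):
    """Collapse vertices that coincide within an absolute tolerance."""
    key = np.round(points / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    merged = points[np.sort(first)]
    remap = rank[inverse]
    if faces is not None:
        faces = remap[faces]
        # drop faces that collapsed to fewer than 3 distinct vertices
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[ok]
    return merged, faces


# ---------------------------------------------------------------------------
# writing


def write_surface(
    surface: Surface,
    path: str | Path,
    scalars: np.ndarray | None = None,
) -> None:
    """Write ``surface`` as ASCII PLY.

    When ``scalars`` is given (one value per vertex) it is stored verbatim
    as a double ``quality`` property and additionally mapped min-to-max
    onto a blue-to-red ramp stored as 8-bit vertex colors, producing a 3D
    heat map viewable in any mesh viewer.  A degenerate range (all values
    equal) maps every vertex to the ramp's low end (blue).
    """
    path = Path(path)
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float64).ravel()
        if len(scalars) != surface.n_points:
            raise SurfaceValidationError(
                "scalars must provide exactly one value per vertex"
            )
    lines = ["ply", "format ascii 1.0", f"element vertex {surface.n_points}"]
    for c in ("x", "y", "z", "nx", "ny", "nz"):
        lines.append(f"property double {c}")
    if scalars is not None:
        lines.append("property double quality")
        for c in ("red", "green", "blue"):
            lines.append(f"property uchar {c}")
    n_faces = 0 if surface.faces is None else len(surface.faces)
    if n_faces:
        lines.append(f"element face {n_faces}")
        lines.append("property list uchar int vertex_indices")
    lines.append("end_header")

    colors = None if scalars is None else scalar_ramp_colors(scalars)
    for i in range(surface.n_points):
        row = [
            *(repr(float(v)) for v in surface.points[i]),
            *(repr(float(v)) for v in surface.normals[i]),
        ]
        if scalars is not None:
            row.append(repr(float(scalars[i])))
            row.extend(str(int(v)) for v in colors[i])
        lines.append(" ".join(row))
    if n_faces:
        for tri in surface.faces:
            lines.append("3 " + " ".join(str(int(v)) for v in tri))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write surface to {path}: {exc}") from exc


def scalar_ramp_colors(scalars: np.ndarray) -> np.ndarray:
    """Map scalars min-to-max onto a blue (low) to red (high) RGB ramp."""
    scalars = np.asarray(scalars, dtype=np.float64)
    lo, hi = scalars.min(), scalars.max()
    t = np.zeros_like(scalars) if hi == lo else (scalars - lo) / (hi - lo)
    colors = np.zeros((len(scalars), 3), dtype=np.uint8)
    colors[:, 0] = np.round(255 * t)
    colors[:, 2] = np.round(255 * (1.0 - t))
    return colors


# ---------------------------------------------------------------------------
# normals


def compute_normals(surface: Surface) -> Surface:
    """Return a copy of ``surface`` with freshly computed unit normals.

    With faces: each vertex normal is the normalized sum of incident-face
    area-weighted normals (degenerate faces are skipped).  Without faces:
    a local plane is fit to the 12 nearest neighbors of every point and
    signs are made consistent by propagation along a spanning tree of the
    neighbor graph.  Closed shapes are finally oriented outward by a
    majority vote against the direction from the centroid.
    """
    normals = _estimate_normals(surface.points, surface.faces)
    return surface.with_points(surface.points.copy(), normals)


def _estimate_normals(points: np.ndarray, faces: np.ndarray | None) -> np.ndarray:
    if faces is not None and len(faces) > 0:
        normals = _face_vertex_normals(points, faces)
    else:
        if len(points) < max(4, _NORMAL_K - 2):
            raise SurfaceValidationError(
                "normal estimation without faces needs at least 10 points"
            )
        normals = _pointcloud_normals(points)
    # outward majority vote (no-op for balanced open patches)
    toward = points - points.mean(axis=0)
    votes = np.sign(np.einsum("ij,ij->i", normals, toward))
    if votes.sum() < 0:
        normals = -normals
    return normals


def _face_vertex_normals(points, faces):
    v0, v1, v2 = points[faces[:, 0]], points[faces[:, 1]], points[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * face area
    areas = np.linalg.norm(fn, axis=1)
    good = areas > 0
    if not np.any(good):
        raise SurfaceValidationError("all faces are degenerate (zero area)")
    acc = np.zeros_like(points)
    for k in range(3):
        np.add.at(acc, faces[good, k], fn[good])
    lengths = np.linalg.norm(acc, axis=1)
    missing = lengths < 1e-300
    if np.any(missing):
        if len(points) >= 10:
            acc[missing] = _pointcloud_normals(points)[missing]
            lengths = np.linalg.norm(acc, axis=1)
        else:
            raise SurfaceValidationError(
                "vertex with no non-degenerate incident face"
            )
    return acc / lengths[:, None]


def _pointcloud_normals(points):
    n = len(points)
    k = min(_NORMAL_K, n - 1)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)  # first neighbor is the point itself
    neigh = points[idx]  # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    return _propagate_orientation(points, normals, idx[:, 1:])


def _propagate_orientation(points, normals, neighbor_idx):
    """Flip normals to a consistent sign along an MST of the kNN graph."""
    n = len(points)
    rows = np.repeat(np.arange(n), neighbor_idx.shape[1])
    cols = neighbor_idx.ravel()
    # weight favors flipping across nearly-parallel neighborhoods first
    w = 1.0 + 1e-9 - np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    graph = coo_matrix((w, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    sym = mst + mst.T
    # seed: highest point, oriented away from the centroid side
    seed = int(np.argmax(points[:, 2]))
    order, pred = breadth_first_order(sym, seed, directed=False)
    out = normals.copy()
    if np.dot(out[seed], points[seed] - points.mean(axis=0)) < 0:
        out[seed] = -out[seed]
    for node in order[1:]:
        parent = pred[node]
        if parent >= 0 and np.dot(out[node], out[parent]) < 0:
            out[node] = -out[node]
    return out


# ---------------------------------------------------------------------------
# centroid size


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of points from their centroid."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(points) < 1:
        raise SurfaceValidationError("centroid size needs at least one point")
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def scale_to_unit(surface: Surface) -> Surface:
    """Center the surface and scale it to unit centroid size.

    Normals are unchanged: an isotropic scaling about the centroid
    preserves directions.
    """
    size = centroid_size(surface.points)
    if size <= 0:
        raise SurfaceValidationError("cannot scale a zero-size point set")
    pts = (surface.points - surface.points.mean(axis=0)) / size
    return surface.with_points(pts, surface.normals.copy())
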