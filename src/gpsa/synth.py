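"""Synthetic surface populations with known ground truth.

Real scan collections come with no ground truth, so every algorithmic
claim in this package is exercised on generated populations: a smooth
base shape (subdivided icosahedron mapped to an ellipsoid, with analytic
normals), per-specimen localized deformations (cosine-falloff bumps with
compact support, so "the deformed region" is crisply defined), isotropic
coordinate noise, optional holes (deleted spherical caps, emulating
incomplete scans), and known random rigid motions.  Everything is
reproducible from the seed, and the sampled transforms and amplitudes
are returned alongside the surfaces.

Default vertex counts are in the thousands — far below real scans, whose
point counts run to the hundreds of thousands — chosen so whole-pipeline
runs stay desk-scale; raise ``target_vertices`` to scale up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .mesh_io import Surface, write_surface

__all__ = ["BumpSpec", "HoleSpec", "PopulationSpec", "make_base", "make_population", "write_population"]

# icosphere vertex counts by subdivision level
_ICO_COUNTS = (12, 42, 162, 642, 2562, 10242, 40962)


@dataclass
class BumpSpec:
    """Localized outward deformation on a spherical cap.

    ``center`` is a direction on the unit parameter sphere; vertices
    whose parameter direction lies within ``angular_radius`` (radians)
    of it are displaced along the surface normal, smoothly and exactly
    zero outside the cap.  The amplitude is drawn per specimen,
    uniformly from ``[amp_low, amp_high]``.

    Two falloff profiles are available.  ``"raised"`` is the raised
    cosine ``(1 + cos(pi * angle / radius)) / 2`` — a smooth dome.
    ``"plateau"`` is flat (weight 1) out to 90% of the radius with a
    thin cosine skirt to zero, so the deformed region is nearly binary:
    use it when assertions need a crisp in-patch/out-of-patch contrast.

    With ``antipodal=True`` the same weight pattern is applied at
    ``-center`` with the same per-specimen amplitude; the two lobes'
    net displacements cancel by symmetry, so the planted variation has
    (almost) no rigid component and stays out of the superimposition.
    """

    center: tuple = (1.0, 1.0, 1.0)
    angular_radius: float = 0.8
    amp_low: float = 0.0
    amp_high: float = 0.4
    profile: str = "raised"
    antipodal: bool = False

    def direction(self) -> np.ndarray:
        d = np.asarray(self.center, dtype=np.float64)
        return d / np.linalg.norm(d)


@dataclass
class HoleSpec:
    """Spherical-cap hole cut from designated specimens."""

    center: tuple = (0.0, 0.0, 1.0)
    angular_radius: float = 0.35
    specimens: tuple = (0,)

    def direction(self) -> np.ndarray:
        d = np.asarray(self.center, dtype=np.float64)
        return d / np.linalg.norm(d)


@dataclass
class PopulationSpec:
    """Conditions defining one synthetic population."""

    semi_axes: tuple = (3.0, 2.0, 1.0)
    target_vertices: int = 600
    bumps: list = field(default_factory=lambda: [BumpSpec()])
    noise_sigma: float | None = None  # absolute; None = 0.2% of bbox diagonal
    max_rotation_deg: float = 20.0
    max_translation: float = 0.5
    hole: HoleSpec | None = None
    n_specimens: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_vertices < 100:
            raise ValueError("target_vertices must be >= 100")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")

    def resolved_noise_sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        diag = 2.0 * np.linalg.norm(self.semi_axes)
        return 0.002 * diag


def make_base(spec: PopulationSpec) -> Surface:
    """Quasi-uniform triangulated ellipsoid with exact analytic normals.

    The subdivision level is the smallest whose icosphere vertex count
    reaches ``target_vertices``.  For a point ``u`` on the unit sphere
    mapped to ``p = u * (a, b, c)``, the outward normal is the normalized
    gradient ``(p_x/a^2, p_y/b^2, p_z/c^2)``.
    """
    level = next(
        (lv for lv, n in enumerate(_ICO_COUNTS) if n >= spec.target_vertices),
        len(_ICO_COUNTS) - 1,
    )
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    u = np.asarray(ico.vertices, dtype=np.float64)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    axes = np.asarray(spec.semi_axes, dtype=np.float64)
    points = u * axes
    normals = _ellipsoid_normals(points, axes)
    return Surface(
        points=points,
        normals=normals,
        faces=np.asarray(ico.faces, dtype=np.int64),
        label="base",
    )


def _ellipsoid_normals(points: np.ndarray, axes: np.ndarray) -> np.ndarray:
    grad = points / axes**2
    return grad / np.linalg.norm(grad, axis=1, keepdims=True)


def _cap_weights(
    directions: np.ndarray, center: np.ndarray, radius: float, profile: str = "raised"
) -> np.ndarray:
    """Cosine-falloff weight per vertex; zero outside the cap."""
    angle = np.arccos(np.clip(directions @ center, -1.0, 1.0))
    w = np.zeros(len(directions))
    inside = angle < radius
    if profile == "raised":
        w[inside] = 0.5 * (1.0 + np.cos(np.pi * angle[inside] / radius))
    elif profile == "plateau":
        a = angle[inside] / radius
        w[inside] = np.where(
            a <= 0.9, 1.0, 0.5 * (1.0 + np.cos(np.pi * (a - 0.9) / 0.1))
        )
    else:
        raise ValueError(f"unknown bump profile {profile!r}")
    return w


def cap_vertex_mask(spec: PopulationSpec, center, angular_radius: float) -> np.ndarray:
    """Boolean mask of base vertices inside a cap — the ground-truth support."""
    base = make_base(spec)
    u = base.points / np.asarray(spec.semi_axes, dtype=np.float64)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    c = np.asarray(center, dtype=np.float64)
    c /= np.linalg.norm(c)
    return np.arccos(np.clip(u @ c, -1.0, 1.0)) < angular_radius


def make_population(spec: PopulationSpec):
    """Sample a population of deformed, noisy, rigidly moved surfaces.

    Returns ``(surfaces, ground_truth)``; ``ground_truth`` is a list of
    per-specimen dicts with the bump amplitudes, rotation matrix and
    translation actually applied.  Same seed, same output, bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    base = make_base(spec)
    axes = np.asarray(spec.semi_axes, dtype=np.float64)
    u = base.points / axes
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    sigma = spec.resolved_noise_sigma()

    surfaces: list[Surface] = []
    truth: list[dict] = []
    for i in range(spec.n_specimens):
        points = base.points.copy()
        amplitudes = []
        for bump in spec.bumps:
            amp = float(rng.uniform(bump.amp_low, bump.amp_high))
            amplitudes.append(amp)
            w = _cap_weights(u, bump.direction(), bump.angular_radius, bump.profile)
            if bump.antipodal:
                w = w + _cap_weights(
                    u, -bump.direction(), bump.angular_radius, bump.profile
                )
            points = points + (amp * w)[:, None] * base.normals
        if sigma > 0:
            points = points + rng.normal(0.0, sigma, size=points.shape)
        faces = base.faces.copy()
        normals = None  # re-estimated from the deformed geometry

        if spec.hole is not None and i in set(spec.hole.specimens):
            keep = ~(
                np.arccos(np.clip(u @ spec.hole.direction(), -1.0, 1.0))
                < spec.hole.angular_radius
            )
            index_map = np.full(len(points), -1, dtype=np.int64)
            index_map[keep] = np.arange(int(keep.sum()))
            points = points[keep]
            mapped = index_map[faces]
            faces = mapped[np.all(mapped >= 0, axis=1)]

        rotvec = _random_rotvec(rng, np.radians(spec.max_rotation_deg))
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        trans = _random_translation(rng, spec.max_translation)
        points = points @ rot.T + trans

        surf = Surface(points=points, normals=normals, faces=faces, label=f"specimen_{i:02d}")
        surfaces.append(surf)
        truth.append(
            {
                "label": surf.label,
                "amplitudes": amplitudes,
                "rotation": rot.tolist(),
                "translation": trans.tolist(),
                "has_hole": bool(
                    spec.hole is not None and i in set(spec.hole.specimens)
                ),
            }
        )
    return surfaces, truth


def _random_rotvec(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return axis * rng.uniform(0.0, max_angle)


def _random_translation(rng: np.random.Generator, max_norm: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return direction * rng.uniform(0.0, max_norm)


def write_population(spec: PopulationSpec, out_dir: str | Path) -> Path:
    """Write the population as PLY files plus a ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    surfaces, truth = make_population(spec)
    for surf in surfaces:
        write_surface(surf, out_dir / f"{surf.label}.ply")
    manifest = {
        "spec": _spec_dict(spec),
        "specimens": truth,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _spec_dict(spec: PopulationSpec) -> dict:
    d = asdict(spec)
    d["resolved_noise_sigma"] = spec.resolved_noise_sigma()
    return d
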