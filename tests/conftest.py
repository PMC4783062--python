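import numpy as np
import pytest

from gpsa.mesh_io import Surface
from gpsa.synth import BumpSpec, PopulationSpec, make_base, make_population


@pytest.fixture(scope="session")
def ellipsoid():
    """Quasi-uniform 642-vertex ellipsoid (3, 2, 1) with analytic normals."""
    return make_base(PopulationSpec())


@pytest.fixture(scope="session")
def bumped_ellipsoid():
    """Ellipsoid with a fixed off-axis bump breaking all mirror symmetries."""
    spec = PopulationSpec(
        noise_sigma=0.0,
        max_rotation_deg=0.0,
        max_translation=0.0,
        n_specimens=1,
        bumps=[BumpSpec(amp_low=0.35, amp_high=0.35)],
        seed=0,
    )
    return make_population(spec)[0][0]


@pytest.fixture(scope="session")
def asymmetric_pair():
    """Two distinct deformed ellipsoids in arbitrary poses.

    Fixed-amplitude features anchor the alignment (as anatomy does on a
    real scan); one varying bump differentiates the two shapes.
    """
    spec = PopulationSpec(
        noise_sigma=0.0,
        max_rotation_deg=10.0,
        max_translation=0.3,
        n_specimens=2,
        bumps=[
            BumpSpec(center=(1, 1, 1), amp_low=0.1, amp_high=0.4),
            BumpSpec(center=(1, 0, -0.5), angular_radius=0.5, amp_low=0.3, amp_high=0.3),
            BumpSpec(center=(-1, 0.6, 0), angular_radius=0.5, amp_low=0.25, amp_high=0.25),
            BumpSpec(center=(0, -1, 0.4), angular_radius=0.5, amp_low=0.3, amp_high=0.3),
        ],
        seed=5,
    )
    return make_population(spec)[0]


@pytest.fixture
def tetrahedron():
    pts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return Surface(points=pts, faces=faces, label="tet")
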