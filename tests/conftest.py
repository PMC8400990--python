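import logging

import numpy as np
import pytest

from cortexcad import (
    CohortSpec,
    PhantomSpec,
    compute_vertex_shapes,
    make_cohort,
    make_phantom,
    marching_cubes,
    select_isovalue,
)

logging.getLogger("cortexcad").setLevel(logging.ERROR)

BALL_RADIUS = 10.0


@pytest.fixture(scope="session")
def ball_phantom():
    """Partial-volume ball, R=10 mm on a 64³ unit-spacing grid (default conditions)."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def ball_mesh(ball_phantom):
    alpha = select_isovalue(ball_phantom.volume)
    return marching_cubes(ball_phantom.volume, alpha), alpha


@pytest.fixture(scope="session")
def ball_shapes(ball_mesh):
    mesh, _ = ball_mesh
    return compute_vertex_shapes(mesh)


@pytest.fixture(scope="session")
def slab_phantom():
    return make_phantom(PhantomSpec(shape="slab", grid_shape=(32, 32, 32),
                                    thickness=8.0, seed=0))


@pytest.fixture(scope="session")
def slab_face_shapes(slab_phantom):
    """Curvatures on the slab mesh plus a mask of face-interior vertices."""
    alpha = select_isovalue(slab_phantom.volume)
    mesh = marching_cubes(slab_phantom.volume, alpha)
    shapes = compute_vertex_shapes(mesh)
    c = mesh.vertices.mean(axis=0)
    rel = mesh.vertices - c
    on_face = (
        (np.abs(np.abs(rel[:, 2]) - slab_phantom.spec.thickness / 2) < 0.5)
        & (np.abs(rel[:, 0]) < 8)
        & (np.abs(rel[:, 1]) < 8)
    )
    return shapes, on_face


@pytest.fixture(scope="session")
def small_separable_cohort():
    """Quick two-group cohort with 3 planted regions out of 10."""
    spec = CohortSpec(n_per_group=(20, 25), n_regions=10,
                      affected_regions=(1, 2, 3), effect_size=3.0, seed=11)
    table, labels, truth = make_cohort(spec)
    return table, labels, truth


@pytest.fixture(scope="session")
def study_scale_cohort():
    """Cohort mirroring the 60 NC / 86 MCI two-group design, 76 regions."""
    spec = CohortSpec(seed=7)
    table, labels, truth = make_cohort(spec)
    return table, labels, truth
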