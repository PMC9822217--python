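import numpy as np
import pytest

import bonemap as bm


@pytest.fixture
def constant_volume():
    spec = bm.PhantomSpec(kind="constant", params={"hu": 250.0}, dims=(12, 12, 12))
    return bm.make_volume(spec)


AFFINE_COEFFS = (2.0, -1.0, 3.0, 7.0)


@pytest.fixture
def affine_spec():
    return bm.PhantomSpec(kind="affine", params={"coeffs": list(AFFINE_COEFFS)}, dims=(14, 14, 14))


@pytest.fixture
def affine_volume(affine_spec):
    return bm.make_volume(affine_spec)


def affine_hu(points):
    a, b, c, d = AFFINE_COEFFS
    pts = np.atleast_2d(points)
    return a * pts[:, 0] + b * pts[:, 1] + c * pts[:, 2] + d


@pytest.fixture
def shell_spec():
    return bm.PhantomSpec(
        kind="shell",
        params={
            "center": [10.0, 10.0, 10.0],
            "r_inner": 5.0,
            "r_outer": 8.0,
            "hu_shell": 1500.0,
            "hu_interior": 300.0,
            "hu_background": 0.0,
        },
        dims=(41, 41, 41),
        spacing=(0.5, 0.5, 0.5),
    )


@pytest.fixture
def shell_volume(shell_spec):
    return bm.make_volume(shell_spec)


@pytest.fixture(scope="session")
def conforming_shell_setup():
    """Cubic-shell phantom whose interfaces coincide with box-mesh faces.

    Returns (volume, mesh, shell_mask, interior_mask) where the masks
    classify element centroids by Chebyshev distance from the body center.
    """
    spec = bm.PhantomSpec(
        kind="shell",
        params={"center": [10.0, 10.0, 10.0], "r_inner": 4.0, "r_outer": 6.0,
                "hu_shell": 1500.0, "hu_interior": 300.0, "hu_background": 0.0,
                "norm": "linf"},
        dims=(41, 41, 41), spacing=(0.5, 0.5, 0.5),
    )
    vol = bm.make_volume(spec)
    mesh = bm.make_box_mesh((12, 12, 12), (12, 12, 12), origin=(4, 4, 4))
    cent = mesh.centroids()
    r = np.abs(cent - 10.0).max(axis=1)
    return vol, mesh, (r > 4.0), (r <= 4.0)


@pytest.fixture
def cube_mesh():
    """Six-tet unit cube, interior to the default phantom grids."""
    return bm.make_box_mesh((6.0, 6.0, 6.0), (1, 1, 1), origin=(3.0, 3.0, 3.0))


@pytest.fixture
def box_mesh():
    return bm.make_box_mesh((8.0, 8.0, 8.0), (3, 3, 3), origin=(2.0, 2.0, 2.0))


def uniform_assignment(mesh, E=5000.0):
    m = mesh.n_elements
    return bm.MaterialAssignment(
        elem_ids=mesh.elem_ids,
        hu_mean=np.zeros(m),
        rho=np.full(m, 1.0),
        young_modulus=np.full(m, float(E)),
        n_samples=np.ones(m, dtype=int),
        clamped_fraction=np.zeros(m),
    )


def assignment_with_moduli(mesh, moduli):
    m = mesh.n_elements
    return bm.MaterialAssignment(
        elem_ids=mesh.elem_ids,
        hu_mean=np.zeros(m),
        rho=np.full(m, 1.0),
        young_modulus=np.asarray(moduli, dtype=float),
        n_samples=np.ones(m, dtype=int),
        clamped_fraction=np.zeros(m),
    )
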