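"""Shared fixtures: small phantom cohorts, slices and a ray-casting oracle."""

import numpy as np
import pytest

from echosynth.phantoms import generate_phantom, generate_phantom_cohort
from echosynth.shape_model import align_cohort, fit_pdm
from echosynth.slicing import define_a4c_plane, slice_mesh

TASK = ("lv_endo", "lv_epi", "la")


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(0)


@pytest.fixture(scope="session")
def cohort():
    return generate_phantom_cohort(8, seed=7)


@pytest.fixture(scope="session")
def aligned(cohort):
    return align_cohort(cohort)


@pytest.fixture(scope="session")
def pdm(aligned):
    return fit_pdm(aligned, 0.90)


@pytest.fixture(scope="session")
def a4c_slice(phantom):
    return slice_mesh(phantom, define_a4c_plane(phantom), 128, 128, 1.2)


def ray_cast_contains(tm, pts, direction=(0.577350269, 0.577350269, 0.577350269)):
    """Brute-force even-odd point-in-mesh test (Moller-Trumbore ray casts).

    Independent of the production rasterizer: counts triangle crossings of a
    fixed oblique ray per query point.
    """
    d = np.asarray(direction, dtype=float)
    tri = np.asarray(tm.triangles)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(d, e2)
    a = np.einsum("fj,fj->f", e1, h)
    ok = np.abs(a) > 1e-12
    inv = np.zeros_like(a)
    inv[ok] = 1.0 / a[ok]
    out = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        s = p - v0
        u = np.einsum("fj,fj->f", s, h) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,fj->f", d, q) * inv
        t = np.einsum("fj,fj->f", e2, q) * inv
        hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        out[i] = hit.sum() % 2 == 1
    return out
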