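"""Shared fixtures: analytic meshes and small parametrized tube populations."""

from __future__ import annotations

import numpy as np
import pytest

from cavishape.geometry import Surface
from cavishape.parametrize import parametrize
from cavishape.preprocess import cut_boundary_holes
from cavishape.synthetic import make_template, nostril_seeds


def open_cylinder(n_u: int = 32, n_v: int = 24, radius: float = 10.0,
                  height: float = 20.0) -> Surface:
    """Right circular cylinder shell (no caps): 2 boundary loops, chi = 0."""
    alpha = 2 * np.pi * np.arange(n_u) / n_u
    z = np.linspace(0.0, height, n_v)
    verts = np.array(
        [[radius * np.cos(a), radius * np.sin(a), zz] for zz in z for a in alpha]
    )
    faces = []
    for j in range(n_v - 1):
        for i in range(n_u):
            a0 = j * n_u + i
            b0 = j * n_u + (i + 1) % n_u
            c0 = (j + 1) * n_u + i
            d0 = (j + 1) * n_u + (i + 1) % n_u
            faces.append([a0, b0, d0])
            faces.append([a0, d0, c0])
    return Surface(verts, np.array(faces))


def flat_patch(nx: int = 5, ny: int = 5, sx: float = 3.0, sy: float = 7.0):
    """Regular planar rectangle mesh plus its exact unrolled coordinates."""
    x, y = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny))
    verts = np.column_stack([x.ravel() * sx, y.ravel() * sy, 0 * x.ravel()])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = j * nx + i + 1
            c = (j + 1) * nx + i
            d = (j + 1) * nx + i + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return Surface(verts, np.array(faces)), x.ravel(), y.ravel()


@pytest.fixture(scope="session")
def cylinder_mesh():
    return open_cylinder()


@pytest.fixture(scope="session")
def bent_tube():
    """Closed bent-tube template (watertight, genus 0)."""
    return make_template(n_u=20, n_v=28, bend_angle=120, radius=8, length=80)


@pytest.fixture(scope="session")
def open_tube(bent_tube):
    """Bent tube with the two sampling holes cut (chi = 0, 2 loops)."""
    return cut_boundary_holes(bent_tube, nostril_seeds(bent_tube), radius=1.0)


@pytest.fixture(scope="session")
def open_tube_param(open_tube):
    return parametrize(open_tube, relax_passes=0)
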