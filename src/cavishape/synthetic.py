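"""Synthetic populations of tube-like genus-0 surfaces with planted shape modes.

The generator emulates the kind of population the shape model is built from:
a smooth U-bent tube (the idealization of a nasal cavity closed at the
post-nasal region) deformed by a small number of known, mutually orthogonal
linear displacement modes with stated standard deviations, with per-subject
covariates (age, sex) driving some of the coefficients.  Because the planted
modes and coefficients are returned, every downstream stage can be tested as
a parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Surface, _orient_consistently, enclosed_volume
from .preprocess import LabelVolume

__all__ = [
    "PopulationSpec",
    "make_template",
    "nostril_seeds",
    "make_mode_fields",
    "sample_population",
    "voxelize",
]


def make_template(
    n_u: int = 24,
    n_v: int = 32,
    bend_angle: float = 120.0,
    radius: float = 8.0,
    length: float = 80.0,
) -> Surface:
    """Watertight genus-0 tube: a circle swept along a circular-arc centerline.

    ``bend_angle`` (degrees) is the total turning of the centerline (0 gives
    a straight capped cylinder, 180 a U-tube); ``radius`` is the tube radius
    and ``length`` the centerline arc length, both in mm.  The two cap
    centres — the "nostril" positions where holes are cut for the
    parametrization — are the last two vertices (see :func:`nostril_seeds`).
    """
    if n_u < 8 or n_v < 8:
        raise ValueError("need n_u >= 8 and n_v >= 8")
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    theta = np.deg2rad(bend_angle)
    if theta > 0:
        r_center = length / theta
        if r_center <= 1.05 * radius:
            raise ValueError(
                "bend too extreme: centerline radius must exceed tube radius"
            )
    t = np.linspace(0.0, 1.0, n_v)
    if theta == 0:
        centers = np.column_stack([length * t, np.zeros(n_v), np.zeros(n_v)])
        e1 = np.tile([0.0, 0.0, 1.0], (n_v, 1))
    else:
        phi = theta * t
        centers = np.column_stack(
            [r_center * np.sin(phi), np.zeros(n_v), r_center * (1 - np.cos(phi))]
        )
        e1 = np.column_stack([np.sin(phi), np.zeros(n_v), -np.cos(phi)])
    e2 = np.tile([0.0, 1.0, 0.0], (n_v, 1))
    alpha = 2 * np.pi * np.arange(n_u) / n_u
    # rings: (n_v, n_u, 3)
    rings = (
        centers[:, None, :]
        + radius * np.cos(alpha)[None, :, None] * e1[:, None, :]
        + radius * np.sin(alpha)[None, :, None] * e2[:, None, :]
    )
    vertices = rings.reshape(-1, 3)
    faces = []
    for j in range(n_v - 1):
        for i in range(n_u):
            a = j * n_u + i
            b = j * n_u + (i + 1) % n_u
            c = (j + 1) * n_u + i
            d = (j + 1) * n_u + (i + 1) % n_u
            faces.append([a, b, d])
            faces.append([a, d, c])
    c0 = len(vertices)
    c1 = c0 + 1
    vertices = np.vstack([vertices, centers[0], centers[-1]])
    for i in range(n_u):
        faces.append([c0, (i + 1) % n_u, i])
        base = (n_v - 1) * n_u
        faces.append([c1, base + i, base + (i + 1) % n_u])
    surface = _orient_consistently(Surface(vertices, np.array(faces)))
    # cap centres must stay the last two vertices after orientation repair
    assert np.allclose(surface.vertices[-2], centers[0])
    return surface


def nostril_seeds(template: Surface) -> np.ndarray:
    """The two cap-centre points of a :func:`make_template` surface."""
    return template.vertices[-2:].copy()


def _axial_coordinate(template: Surface, n_v_hint: int | None = None) -> np.ndarray:
    """Approximate along-tube coordinate in [0, 1] from cap-centre distances."""
    a, b = nostril_seeds(template)
    da = np.linalg.norm(template.vertices - a, axis=1)
    db = np.linalg.norm(template.vertices - b, axis=1)
    s = da / (da + db)
    return s


def make_mode_fields(template: Surface, kinds=("bulge", "bend", "skew")) -> np.ndarray:
    """Smooth orthonormal displacement fields on the template vertices.

    kinds: any of
      - "bulge": radial inflation weighted by a Gaussian bump along the tube
        (local widening/narrowing);
      - "bend":  lateral in-plane displacement growing along the tube
        (global bending);
      - "skew":  left-right translation weighted along the tube — a
        mirror-antisymmetric mode, the synthetic analogue of asymmetry
        modes in a mirror-augmented model;
      - "scale": isotropic scaling about the centroid (for volume/area
        scaling-law checks).

    Fields are flattened, centred across vertices, Gram-Schmidt
    orthogonalized and normalized to unit Euclidean norm, so a coefficient
    of c mm-units displaces the shape by ||c|| in R^{3n} and planted
    coefficient variances are directly comparable with PCA eigenvalues.
    """
    v = template.vertices
    s = _axial_coordinate(template)
    centroid = v.mean(axis=0)
    radial = v - centroid
    fields = []
    for kind in kinds:
        if kind == "bulge":
            w = np.exp(-(((s - 0.5) / 0.18) ** 2))
            axis_pts = centroid  # radial direction about the centroid
            d = (v - axis_pts) * w[:, None]
        elif kind == "bend":
            d = np.column_stack([np.zeros_like(s), np.zeros_like(s), (s - 0.5) ** 2])
            d = d * np.sign(s - 0.5)[:, None]
        elif kind == "skew":
            d = np.column_stack(
                [np.zeros_like(s), np.sin(np.pi * s), np.zeros_like(s)]
            )
        elif kind == "scale":
            d = radial.copy()
        else:
            raise ValueError(f"unknown mode kind {kind!r}")
        fields.append(d.reshape(-1))
    # rigid-motion generators at the template: translations and linearized
    # rotations about the centroid.  Planted fields are projected out of
    # their span so Procrustes alignment does not absorb planted variance.
    rigid = []
    n_verts = len(v)
    for k3 in range(3):
        t = np.zeros((n_verts, 3))
        t[:, k3] = 1.0
        rigid.append(t.reshape(-1))
    for axis in np.eye(3):
        rigid.append(np.cross(np.broadcast_to(axis, radial.shape), radial).reshape(-1))
    rigid_q = []
    for g in rigid:
        for prev in rigid_q:
            g = g - (g @ prev) * prev
        nrm = np.linalg.norm(g)
        if nrm > 1e-12:
            rigid_q.append(g / nrm)

    if not fields:
        return np.zeros((0, 3 * n_verts))
    out = []
    for fvec in fields:
        for prev in rigid_q + out:
            fvec = fvec - (fvec @ prev) * prev
        nrm = np.linalg.norm(fvec)
        if nrm < 1e-12:
            raise ValueError("mode fields are linearly dependent")
        out.append(fvec / nrm)
    return np.array(out)  # (k, 3n_vertices) as per-vertex xyz interleaved


@dataclass
class PopulationSpec:
    """Study conditions for a synthetic population.

    Defaults mirror a clinical shape-modelling study at desk scale: 46
    subjects, ages uniform on [20, 80] years, three planted modes with
    standard deviations of a few mm-units, the first mode drifting linearly
    with age and the second shifted by sex.
    """

    n_subjects: int = 46
    template_kwargs: dict = field(default_factory=dict)
    mode_kinds: tuple = ("bulge", "bend", "skew")
    mode_sds: tuple = (2.0, 1.0, 0.5)
    age_range: tuple = (20.0, 80.0)
    age_slope_mode1: float = 0.05  # coefficient units per year on mode 1
    sex_effect_mode2: float = 0.0  # additive shift of mode-2 coefficient for males
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mode_sds) != len(self.mode_kinds):
            raise ValueError("one SD per mode kind")
        if any(sd <= 0 for sd in self.mode_sds):
            raise ValueError("mode SDs must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")


def sample_population(spec: PopulationSpec):
    """Draw a population: (surfaces, covariates DataFrame, true coefficients).

    Subject s is template + sum_i c_si * mode_i.  Mode-1 coefficients follow
    c_1 = slope * (age - mean age) + noise so that their total SD equals the
    planted SD; remaining modes are zero-mean Gaussian.  A redrawn subject
    cap guards against degenerate geometry (non-positive enclosed volume).
    """
    rng = np.random.default_rng(spec.seed)
    template = make_template(**spec.template_kwargs)
    modes = make_mode_fields(template, spec.mode_kinds)
    k = len(modes)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sexes = np.array(["F", "M"])[rng.integers(0, 2, size=spec.n_subjects)]
    coeffs = np.empty((spec.n_subjects, k))
    if k >= 1:
        age_centred = ages - np.mean(spec.age_range)
        var_age = (
            spec.age_slope_mode1**2
            * (spec.age_range[1] - spec.age_range[0]) ** 2
            / 12
        )
        resid_sd = np.sqrt(max(spec.mode_sds[0] ** 2 - var_age, 1e-12))
        coeffs[:, 0] = spec.age_slope_mode1 * age_centred + rng.normal(
            0, resid_sd, spec.n_subjects
        )
    for i in range(1, k):
        coeffs[:, i] = rng.normal(0, spec.mode_sds[i], spec.n_subjects)
    if k >= 2 and spec.sex_effect_mode2:
        coeffs[:, 1] += np.where(sexes == "M", spec.sex_effect_mode2, 0.0)

    surfaces = []
    base = template.vertices.reshape(-1)
    for s in range(spec.n_subjects):
        for attempt in range(10):
            disp = coeffs[s] @ modes
            verts = (base + disp).reshape(-1, 3)
            surf = Surface(verts, template.faces.copy())
            try:
                if enclosed_volume(surf) > 0.1:
                    break
            except Exception:
                pass
            coeffs[s] = rng.normal(0, spec.mode_sds, k)  # redraw
        else:
            raise RuntimeError(f"subject {s}: could not draw a valid geometry")
        surfaces.append(surf)
    covariates = pd.DataFrame(
        {"subject_id": np.arange(spec.n_subjects), "age": ages, "sex": sexes}
    )
    return surfaces, covariates, coeffs


def voxelize(surface: Surface, spacing: float) -> LabelVolume:
    """Rasterize a watertight surface: foreground voxel <=> centre inside.

    Scanline parity test along z: for every (x, y) voxel-centre column the
    crossing heights with the surface are collected and voxels between
    odd/even crossing pairs are set.  The grid is offset by a tiny irrational
    fraction of the spacing so rays avoid edges and vertices.
    """
    if not surface.is_watertight():
        raise ValueError("voxelize requires a watertight surface")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = surface.vertices.min(axis=0) - spacing
    hi = surface.vertices.max(axis=0) + spacing
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    if shape.max() > 2048:
        raise ValueError("spacing too fine for the object's extent")
    eps = spacing * 0.0137961
    origin = lo + 0.5 * spacing + eps
    nx, ny, nz = shape
    if nx < 1 or ny < 1 or nz < 1 or (shape < 1).any():
        raise ValueError("spacing larger than the object")
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs0 = origin[2]

    v = surface.vertices
    f = surface.faces
    tri = v[f]  # (m, 3, 3)
    crossings_col: list[np.ndarray] = []
    crossings_z: list[np.ndarray] = []
    for p0, p1, p2 in tri:
        xmin, ymin = np.minimum(np.minimum(p0, p1), p2)[:2]
        xmax, ymax = np.maximum(np.maximum(p0, p1), p2)[:2]
        i0 = np.searchsorted(xs, xmin, "left")
        i1 = np.searchsorted(xs, xmax, "right")
        j0 = np.searchsorted(ys, ymin, "left")
        j1 = np.searchsorted(ys, ymax, "right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        px, py = gx.ravel(), gy.ravel()
        d = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
        if abs(d) < 1e-30:
            continue
        w1 = ((px - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (py - p0[1])) / d
        w2 = ((p1[0] - p0[0]) * (py - p0[1]) - (px - p0[0]) * (p1[1] - p0[1])) / d
        inside = (w1 >= 0) & (w2 >= 0) & (w1 + w2 <= 1)
        if not inside.any():
            continue
        zhit = (
            p0[2]
            + w1[inside] * (p1[2] - p0[2])
            + w2[inside] * (p2[2] - p0[2])
        )
        gi, gj = np.meshgrid(
            np.arange(i0, i1), np.arange(j0, j1), indexing="ij"
        )
        crossings_col.append((gi * ny + gj).ravel()[inside])
        crossings_z.append(zhit)
    voxels = np.zeros((nx, ny, nz), dtype=bool)
    if crossings_col:
        cols = np.concatenate(crossings_col)
        zh = np.concatenate(crossings_z)
        order = np.lexsort((zh, cols))
        cols, zh = cols[order], zh[order]
        starts = np.flatnonzero(np.r_[True, cols[1:] != cols[:-1]])
        ends = np.r_[starts[1:], len(cols)]
        for a, b in zip(starts, ends):
            zlist = zh[a:b]
            if len(zlist) % 2:
                continue  # grazing ray; skip rather than corrupt parity
            col = cols[a]
            i, j = divmod(int(col), ny)
            for lo_z, hi_z in zip(zlist[0::2], zlist[1::2]):
                k0 = int(np.ceil((lo_z - zs0) / spacing))
                k1 = int(np.floor((hi_z - zs0) / spacing))
                if k1 >= k0:
                    voxels[i, j, max(k0, 0) : min(k1, nz - 1) + 1] = True
    if not voxels.any():
        raise ValueError("empty foreground: spacing too coarse for the object")
    return LabelVolume(voxels, np.full(3, spacing), origin)
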