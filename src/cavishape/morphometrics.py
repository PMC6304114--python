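"""Region morphometrics on shape-model instances.

The mean shape is partitioned into four anatomical regions — nasal valve +
vestibule (NVVR), olfactory (OR), post-nasal (PNR), each selected by an
axis-aligned box over triangle centroids, and the respiratory remainder (RR).
Labels are defined once on the template triangulation and transferred to any
synthesized instance by triangle index, so regions deform with the shape.
NVVR/OR/PNR are closed with planar caps to give volumes; the RR volume is
the total volume minus the three; areas come from the labelled faces only
(caps excluded).  Sweeping each mode over b = k sqrt(lambda_i),
k in {-2.5, -1.25, 0, 1.25, 2.5}, yields volume/area/SVR tables whose
variation coefficient (SD/mean over the five sweep values) summarizes how
strongly the mode drives each measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Surface, enclosed_volume, triangle_areas
from .model import matrix_to_points

__all__ = [
    "REGIONS",
    "RegionPartition",
    "grid_surface",
    "define_regions",
    "close_region",
    "region_measures",
    "morpho_table",
    "variation_coefficient",
    "cv_table",
    "DEFAULT_MULTIPLIERS",
]

REGIONS = ("NVVR", "OR", "PNR", "RR")
DEFAULT_MULTIPLIERS = (-2.5, -1.25, 0.0, 1.25, 2.5)


def grid_surface(points: np.ndarray, n_u: int, n_v: int) -> Surface:
    """Tube triangulation of an (n_u * n_v, 3) landmark grid.

    Landmark i * n_v + j is column i (periodic in i), row j; the result has
    two boundary loops (j = 0 and j = n_v - 1), matching the sampling
    convention of the cylindrical charts.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape != (n_u * n_v, 3):
        raise ValueError("points must be (n_u * n_v, 3)")
    faces = []
    for i in range(n_u):
        i2 = (i + 1) % n_u
        for j in range(n_v - 1):
            a = i * n_v + j
            b = i2 * n_v + j
            c = i * n_v + j + 1
            d = i2 * n_v + j + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return Surface(points, np.array(faces))


@dataclass
class RegionPartition:
    """Per-triangle region labels plus the boxes that defined them."""

    face_labels: np.ndarray  # array of region names, one per face
    boxes: dict  # region -> (min_xyz, max_xyz) in mm on the template

    def faces_of(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.face_labels == region)


def _boxes_overlap(b1, b2) -> bool:
    lo1, hi1 = np.asarray(b1[0]), np.asarray(b1[1])
    lo2, hi2 = np.asarray(b2[0]), np.asarray(b2[1])
    return bool(np.all(np.maximum(lo1, lo2) < np.minimum(hi1, hi2)))


def define_regions(template: Surface, boxes: dict) -> RegionPartition:
    """Label triangles whose centroid falls inside a region's box; rest is RR.

    ``boxes`` maps region names (subset of NVVR/OR/PNR) to (min_xyz,
    max_xyz); boxes must be pairwise disjoint.
    """
    names = list(boxes)
    for k, name in enumerate(names):
        if name not in REGIONS or name == "RR":
            raise ValueError(f"unknown boxed region {name!r}")
        for other in names[k + 1 :]:
            if _boxes_overlap(boxes[name], boxes[other]):
                raise ValueError(f"boxes {name} and {other} overlap")
    centroids = template.vertices[template.faces].mean(axis=1)
    labels = np.full(template.n_faces, "RR", dtype=object)
    for name, (lo, hi) in boxes.items():
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        inside = np.all((centroids >= lo) & (centroids <= hi), axis=1)
        labels[inside] = name
    return RegionPartition(np.asarray(labels), dict(boxes))


def _fit_plane(points: np.ndarray):
    """Least-squares plane: (centroid, unit normal, in-plane basis)."""
    c = points.mean(axis=0)
    q = points - c
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    return c, vt[2], vt[:2]


def close_region(surface: Surface, faces: np.ndarray) -> Surface:
    """Extract a set of faces and cap every boundary loop with a planar fan.

    Each loop is projected onto its least-squares plane; if the projected
    polygon self-intersects the loop is rejected.  The cap fans from the
    projected loop centroid with winding matched to the submesh, so the
    result is a closed, consistently oriented surface whose enclosed volume
    is well defined.
    """
    faces = np.asarray(faces)
    if faces.dtype == bool:
        faces = np.flatnonzero(faces)
    sub = surface.faces[faces]
    used = np.unique(sub)
    remap = np.full(surface.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = surface.vertices[used].copy()
    tris = remap[sub]
    piece = Surface(verts, tris)
    loops = piece.boundary_loops()
    if not loops:
        return piece
    # directed boundary edges as they appear in the faces
    directed = set()
    for a, b, c in tris:
        directed.update([(int(a), int(b)), (int(b), int(c)), (int(c), int(a))])
    new_faces = [tris]
    new_verts = [verts]
    next_id = len(verts)
    for li, loop in enumerate(loops):
        pts = verts[loop]
        centroid, normal, basis = _fit_plane(pts)
        uv = (pts - centroid) @ basis.T
        # The simplicity check guards the planar-cap construction, so it is
        # only meaningful for near-planar loops; strongly non-planar loops
        # (e.g. zigzag cuts through a deformed band) are capped by the
        # centroid fan regardless, which closes the cycle either way.
        # Consecutive points that project on top of each other (the two rows
        # of a zigzag) are dropped first.
        scale = max(np.ptp(uv, axis=0).max(), 1e-12)
        out_of_plane = np.abs((pts - centroid) @ normal)
        if out_of_plane.max() < 0.1 * scale:
            from shapely.geometry import LineString, Polygon

            ring = LineString(np.vstack([uv, uv[:1]])).simplify(0.02 * scale)
            coords = np.asarray(ring.coords)
            if len(coords) >= 5 and not Polygon(coords[:-1]).is_valid:
                raise ValueError(
                    f"boundary loop {li} self-intersects when projected to "
                    "its least-squares plane"
                )
        cap_centre = centroid
        cycle = [(int(loop[k]), int(loop[(k + 1) % len(loop)])) for k in range(len(loop))]
        fan = []
        for a, b in cycle:
            if (a, b) in directed:
                fan.append([b, a, next_id])
            else:
                fan.append([a, b, next_id])
        new_faces.append(np.array(fan, dtype=np.int64))
        new_verts.append(cap_centre[None, :])
        next_id += 1
    closed = Surface(np.vstack(new_verts), np.vstack(new_faces))
    if not closed.is_watertight():
        raise ValueError("capping failed to produce a watertight surface")
    return closed


def variation_coefficient(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean of the sweep values."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("variation coefficient undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def region_measures(
    model,
    partition: RegionPartition,
    mode: int,
    grid: tuple[int, int],
    multipliers=DEFAULT_MULTIPLIERS,
) -> pd.DataFrame:
    """Volume/area/SVR of every region along one mode's b-sweep.

    For each multiplier k the shape mean + k sqrt(lambda_mode) P_mode is
    synthesized (no clamping), the boxed regions are closed and measured,
    and the respiratory volume is obtained by subtracting the three boxed
    volumes from the total.  Areas exclude the caps.  Units: cm^3, cm^2,
    cm^-1.
    """
    if mode >= model.n_modes_:
        raise ValueError(f"mode {mode} not in model")
    n_u, n_v = grid
    sd = float(np.sqrt(model.variances_[mode]))
    rows = []
    for k in multipliers:
        b = np.zeros(model.n_modes_)
        b[mode] = k * sd
        x, _ = model.synthesize(b, clamp=False)
        surf = grid_surface(matrix_to_points(x), n_u, n_v)
        areas_mm2 = triangle_areas(surf)
        total_closed = close_region(surf, np.arange(surf.n_faces))
        total_vol = enclosed_volume(total_closed)
        boxed_vols = {}
        for name in ("NVVR", "OR", "PNR"):
            fsel = partition.faces_of(name)
            if len(fsel) == 0:
                boxed_vols[name] = 0.0
                continue
            closed = close_region(surf, fsel)
            boxed_vols[name] = enclosed_volume(closed)
        rr_vol = total_vol - sum(boxed_vols.values())
        vols = {**boxed_vols, "RR": rr_vol}
        for name in REGIONS:
            fsel = partition.faces_of(name)
            area = float(areas_mm2[fsel].sum()) / 100.0
            vol = vols[name]
            rows.append(
                {
                    "mode": mode,
                    "k": k,
                    "region": name,
                    "volume_cm3": vol,
                    "area_cm2": area,
                    "svr_invcm": area / vol if vol != 0 else np.nan,
                }
            )
        rows.append(
            {
                "mode": mode,
                "k": k,
                "region": "total",
                "volume_cm3": total_vol,
                "area_cm2": float(areas_mm2.sum()) / 100.0,
                "svr_invcm": float(areas_mm2.sum()) / 100.0 / total_vol,
            }
        )
    return pd.DataFrame(rows)


def morpho_table(
    model,
    partition: RegionPartition,
    grid: tuple[int, int],
    modes=None,
    multipliers=DEFAULT_MULTIPLIERS,
) -> pd.DataFrame:
    """Concatenated :func:`region_measures` over the first modes (default 10
    or all)."""
    if modes is None:
        modes = range(min(10, model.n_modes_))
    return pd.concat(
        [region_measures(model, partition, m, grid, multipliers) for m in modes],
        ignore_index=True,
    )


def cv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Variation coefficients per (mode, region, measure) over the b-sweep."""
    rows = []
    for (mode, region), grp in table[table.region != "total"].groupby(
        ["mode", "region"]
    ):
        for measure in ("volume_cm3", "area_cm2", "svr_invcm"):
            vals = grp[measure].to_numpy()
            cv = (
                variation_coefficient(vals)
                if np.isfinite(vals).all() and vals.mean() != 0
                else np.nan  # empty region: measure degenerate, CV undefined
            )
            rows.append(
                {"mode": mode, "region": region, "measure": measure, "cv": cv}
            )
    return pd.DataFrame(rows)
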