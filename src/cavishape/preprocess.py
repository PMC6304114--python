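"""From binary label volume to a smoothed open surface ready for parametrization.

The chain is: fill interior cavities and keep one connected component (so the
extracted surface is genus-0), crop along the axial direction, run marching
cubes in physical coordinates, smooth without shrinkage, and cut two small
holes that become the two cylinder boundaries of the parametrization.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import Surface, TopologyError, _orient_consistently

__all__ = [
    "LabelVolume",
    "read_label_volume",
    "fill_holes",
    "crop_axial",
    "extract_surface",
    "smooth_taubin",
    "cut_boundary_holes",
]


@dataclass
class LabelVolume:
    """Binary segmentation mask on a regular voxel grid.

    voxels: 3D boolean array; spacing: per-axis voxel size in mm; origin:
    physical position of voxel (0,0,0) in mm; axial_axis: array axis of the
    scan's axial direction.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.voxels.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing must be strictly positive")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError("axial_axis must be 0, 1 or 2")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def read_label_volume(path: str | Path, format: str | None = None) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) mask.

    Voxels are binarized (nonzero -> foreground); spacing and origin come
    from the header.  Direction cosines are not applied: the voxel lattice is
    treated as axis-aligned, which is what the synthetic fixtures produce.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    fmt = format
    if fmt is None:
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith((".mhd", ".mha")):
            fmt = "metaimage"
        else:
            raise ValueError(f"cannot infer label format from {path.name!r}")
    fmt = fmt.lower()
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
        origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T  # sitk is (z, y, x); store (x, y, z)
        spacing = np.asarray(img.GetSpacing(), dtype=np.float64)
        origin = np.asarray(img.GetOrigin(), dtype=np.float64)
    else:
        raise ValueError(f"unsupported label format: {fmt!r}")
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"label volume must be 3D, got {data.ndim}D")
    if (spacing <= 0).any():
        raise ValueError("missing or invalid spacing metadata; pass explicit spacing")
    return LabelVolume(data != 0, spacing, origin)


# 26-connectivity for foreground components, 6-connectivity (the scipy
# default cross structure) for background cavities: the standard
# complementary pairing that avoids topological paradoxes.
_FG_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def fill_holes(volume: LabelVolume) -> LabelVolume:
    """Fill interior cavities and keep the largest foreground component."""
    if volume.n_foreground == 0:
        raise ValueError("fill_holes: empty foreground")
    filled = ndimage.binary_fill_holes(volume.voxels)
    labels, n = ndimage.label(filled, structure=_FG_STRUCTURE)
    if n > 1:
        sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
        filled = labels == (1 + int(np.argmax(sizes)))
    return LabelVolume(filled, volume.spacing, volume.origin, volume.axial_axis)


def crop_axial(
    volume: LabelVolume, plane_index: int, side: str = "below"
) -> LabelVolume:
    """Clear voxels on one side of an axial slice plane.

    side='below' clears slices with index < plane_index; side='above' clears
    slices with index >= plane_index.
    """
    ax = volume.axial_axis
    extent = volume.voxels.shape[ax]
    if not 0 <= plane_index < extent:
        raise IndexError(f"plane_index {plane_index} outside axial extent {extent}")
    voxels = volume.voxels.copy()
    sl = [slice(None)] * 3
    if side == "below":
        sl[ax] = slice(0, plane_index)
    elif side == "above":
        sl[ax] = slice(plane_index, None)
    else:
        raise ValueError("side must be 'below' or 'above'")
    voxels[tuple(sl)] = False
    if not voxels.any():
        raise ValueError("crop plane removes all foreground")
    return LabelVolume(voxels, volume.spacing, volume.origin, volume.axial_axis)


def extract_surface(volume: LabelVolume, iso: float = 0.5) -> Surface:
    """Marching-cubes isosurface at ``iso`` in physical mm coordinates.

    The mask is padded with one background layer so foreground touching the
    array border still yields a closed surface.
    """
    if volume.n_foreground == 0:
        raise ValueError("extract_surface: empty foreground")
    if not 0.0 < iso < 1.0:
        raise ValueError("iso level must lie in (0, 1)")
    padded = np.pad(volume.voxels.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=iso, spacing=tuple(volume.spacing)
    )
    verts = verts - volume.spacing + volume.origin  # undo the pad shift
    return _orient_consistently(Surface(verts, faces))


def smooth_taubin(
    surface: Surface,
    passes: int = 20,
    lambda_factor: float = 0.5,
    mu_factor: float = -0.53,
) -> Surface:
    """Taubin lambda/mu smoothing: low-pass fairing without shrinkage.

    Each pass applies an inflating uniform-Laplacian step with
    ``lambda_factor`` followed by a deflating one with ``mu_factor``;
    |mu| > lambda is the classical non-shrinking condition.  Boundary
    vertices are kept fixed, so boundary loops are preserved exactly.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    if not 0.0 < lambda_factor < 1.0:
        raise ValueError("lambda_factor must lie in (0, 1)")
    if not (mu_factor < 0.0 and abs(mu_factor) > lambda_factor):
        raise ValueError("need mu_factor < 0 and |mu_factor| > lambda_factor")
    if passes == 0:
        return surface.copy()
    n = surface.n_vertices
    edges, counts = surface.edges_unique()
    boundary = np.zeros(n, dtype=bool)
    boundary[np.unique(edges[counts == 1])] = True
    movable = ~boundary

    from scipy import sparse

    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(i)), (i, j)), shape=(n, n), dtype=np.float64
    )
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0

    v = surface.vertices.copy()
    for _ in range(passes):
        for factor in (lambda_factor, mu_factor):
            lap = adj @ v / degree[:, None] - v
            v[movable] += factor * lap[movable]
    return Surface(v, surface.faces.copy())


def _geodesic_distances(surface: Surface, source: int) -> np.ndarray:
    """Dijkstra distances along mesh edges from one vertex (mm)."""
    edges, _ = surface.edges_unique()
    lengths = np.linalg.norm(
        surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1
    )
    nbrs: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in zip(edges, lengths):
        nbrs.setdefault(int(a), []).append((int(b), float(w)))
        nbrs.setdefault(int(b), []).append((int(a), float(w)))
    dist = np.full(surface.n_vertices, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for w, length in nbrs.get(u, ()):
            nd = d + length
            if nd < dist[w]:
                dist[w] = nd
                heapq.heappush(heap, (nd, w))
    return dist


def cut_boundary_holes(surface: Surface, seeds, radius: float = 0.0) -> Surface:
    """Cut two small holes at the given seed points.

    Removes every triangle touching the geodesic disc of ``radius`` mm around
    the mesh vertex nearest each 3D seed.  The input must be watertight and
    genus-0; the output has exactly two boundary loops (chi = 0), the
    topology the cylindrical parametrization requires.
    """
    seeds = np.asarray(seeds, dtype=np.float64)
    if seeds.shape != (2, 3):
        raise ValueError("seeds must be two 3D points")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not surface.is_watertight():
        raise TopologyError("cut_boundary_holes requires a watertight surface")
    seed_verts = [
        int(np.argmin(np.linalg.norm(surface.vertices - s, axis=1))) for s in seeds
    ]
    if seed_verts[0] == seed_verts[1]:
        raise ValueError("seed points resolve to the same mesh vertex")
    remove = np.zeros(surface.n_faces, dtype=bool)
    dists = []
    for sv in seed_verts:
        d = _geodesic_distances(surface, sv)
        dists.append(d)
        in_disc = d <= radius
        remove |= in_disc[surface.faces].any(axis=1)
    if min(dists[0][seed_verts[1]], dists[1][seed_verts[0]]) <= 2 * radius:
        raise ValueError("seed discs overlap: seeds closer than 2 x radius")
    faces = surface.faces[~remove]
    used = np.unique(faces)
    remap = np.full(surface.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = Surface(surface.vertices[used], remap[faces])
    loops = out.boundary_loops()
    if len(loops) != 2:
        raise TopologyError(
            f"hole cutting produced {len(loops)} boundary loops, expected 2"
        )
    from scipy.sparse.csgraph import connected_components
    from scipy import sparse

    edges, _ = out.edges_unique()
    g = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(out.n_vertices, out.n_vertices),
    )
    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise TopologyError("hole cutting disconnected the surface")
    return out
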