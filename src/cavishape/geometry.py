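"""Triangle-mesh container and exact geometric/topological primitives.

Every stage of the pipeline moves :class:`Surface` objects around: the
preprocessing stage produces them from label volumes, the cylindrical
parametrization consumes open ones, and the morphometrics stage measures
closed ones.  Vertex coordinates are always millimetres; volumes, areas and
surface-to-volume ratios are reported in cm^3 / cm^2 / cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "Surface",
    "TopologyReport",
    "TopologyError",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "topology",
    "enclosed_volume",
    "surface_area",
    "mirror",
]

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0


class TopologyError(ValueError):
    """The mesh violates a topological precondition (non-manifold, open, ...)."""


class MeshFormatError(ValueError):
    """A mesh file could not be parsed in the requested format."""


@dataclass
class Surface:
    """Triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Vertex-index triples with consistent winding.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _boundary_loops: list[np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- derived structures -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and the count of incident faces per edge."""
        if self.faces.size == 0:
            return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        edges, counts = np.unique(e, axis=0, return_counts=True)
        return edges, counts

    def check_manifold(self) -> None:
        edges, counts = self.edges_unique()
        bad = counts > 2
        if bad.any():
            i = int(np.argmax(bad))
            raise TopologyError(
                f"non-manifold edge {tuple(edges[i])} with {counts[i]} incident faces"
            )

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex cycles of edges with exactly one incident face."""
        if self._boundary_loops is not None:
            return self._boundary_loops
        self.check_manifold()
        edges, counts = self.edges_unique()
        bedges = edges[counts == 1]
        loops: list[np.ndarray] = []
        if len(bedges):
            nxt: dict[int, list[int]] = {}
            for a, b in bedges:
                nxt.setdefault(int(a), []).append(int(b))
                nxt.setdefault(int(b), []).append(int(a))
            seen: set[tuple[int, int]] = set()
            for a0, b0 in bedges:
                key = (int(a0), int(b0))
                if key in seen:
                    continue
                loop = [int(a0)]
                prev, cur = int(a0), int(b0)
                seen.add((min(prev, cur), max(prev, cur)))
                while cur != int(a0):
                    loop.append(cur)
                    nbrs = [x for x in nxt[cur] if x != prev]
                    if not nbrs:
                        raise TopologyError("open (non-cyclic) boundary edge chain")
                    prev, cur = cur, nbrs[0]
                    seen.add((min(prev, cur), max(prev, cur)))
                loops.append(np.array(loop, dtype=np.int64))
        self._boundary_loops = loops
        return loops

    def is_watertight(self) -> bool:
        return len(self.boundary_loops()) == 0

    def copy(self) -> "Surface":
        return Surface(self.vertices.copy(), self.faces.copy())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass(frozen=True)
class TopologyReport:
    euler_characteristic: int
    n_boundary_loops: int
    genus: int
    watertight: bool


def _orient_consistently(surface: Surface) -> Surface:
    """Repair winding so adjacent faces agree; flip globally for positive volume.

    Runs a breadth-first sweep over face adjacency per connected component.
    Only meaningful for edge-manifold meshes.
    """
    faces = surface.faces.copy()
    if not len(faces):
        return surface
    # map undirected edge -> incident face ids
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)
    visited = np.zeros(len(faces), dtype=bool)
    for start in range(len(faces)):
        if visited[start]:
            continue
        visited[start] = True
        stack = [start]
        while stack:
            fi = stack.pop()
            a, b, c = faces[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                for fj in edge_faces[(min(u, v), max(u, v))]:
                    if visited[fj]:
                        continue
                    visited[fj] = True
                    fa, fb, fc = faces[fj]
                    # neighbour must traverse the shared edge as (v, u)
                    directed = ((fa, fb), (fb, fc), (fc, fa))
                    if (u, v) in directed:
                        faces[fj] = faces[fj][::-1]
                    stack.append(fj)
    out = Surface(surface.vertices, faces)
    if out.is_watertight():
        vol6 = np.einsum(
            "ij,ij->i",
            out.vertices[out.faces[:, 0]],
            np.cross(out.vertices[out.faces[:, 1]], out.vertices[out.faces[:, 2]]),
        ).sum()
        if vol6 < 0:
            out = Surface(out.vertices, out.faces[:, ::-1])
    return out


def read_mesh(path: str | Path, format: str | None = None) -> Surface:
    """Load an STL/PLY/OBJ file as a :class:`Surface`.

    STL repeats every vertex per triangle, so vertices are merged by exact
    bitwise coordinate equality; PLY/OBJ keep the file's own indexing.
    Watertight meshes are re-oriented to consistent outward winding so the
    sign of the enclosed volume is well defined.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    ftype = (format or path.suffix.lstrip(".")).lower()
    if ftype not in ("stl", "ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format: {ftype!r}")
    try:
        loaded = trimesh.load(str(path), file_type=ftype, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise MeshFormatError(f"cannot parse {path} as {ftype}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangles")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if ftype == "stl":
        vertices, inverse = np.unique(vertices, axis=0, return_inverse=True)
        faces = inverse[faces]
        area2 = np.linalg.norm(
            np.cross(
                vertices[faces[:, 1]] - vertices[faces[:, 0]],
                vertices[faces[:, 2]] - vertices[faces[:, 0]],
            ),
            axis=1,
        )
        faces = faces[area2 > 0]
    surface = Surface(vertices, faces)
    surface.check_manifold()
    return _orient_consistently(surface)


def write_mesh(surface: Surface, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    ftype = (format or path.suffix.lstrip(".")).lower()
    if ftype not in ("stl", "ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format: {ftype!r}")
    surface.as_trimesh().export(str(path), file_type=ftype)


def topology(surface: Surface) -> TopologyReport:
    """Euler characteristic, boundary-loop count, genus and watertightness.

    genus = (2 - chi - n_boundary_loops) / 2 for a connected orientable
    manifold with boundary.
    """
    loops = surface.boundary_loops()  # raises on non-manifold input
    edges, _ = surface.edges_unique()
    chi = surface.n_vertices - len(edges) + surface.n_faces
    genus2 = 2 - chi - len(loops)
    if genus2 < 0 or genus2 % 2:
        raise TopologyError(
            f"inconsistent topology: chi={chi}, boundary loops={len(loops)}"
        )
    return TopologyReport(
        euler_characteristic=int(chi),
        n_boundary_loops=len(loops),
        genus=genus2 // 2,
        watertight=len(loops) == 0,
    )


def enclosed_volume(surface: Surface) -> float:
    """Volume enclosed by a watertight, consistently oriented surface, in cm^3.

    Divergence-theorem sum of signed tetrahedron volumes against the origin;
    the absolute value is returned, so a globally inverted orientation is
    harmless.
    """
    if not surface.is_watertight():
        raise TopologyError("enclosed_volume requires a watertight surface")
    v = surface.vertices
    f = surface.faces
    vol6 = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
    return abs(vol6) / 6.0 / MM3_PER_CM3


def surface_area(surface: Surface, warn_degenerate: list | None = None) -> float:
    """Total triangle area in cm^2; zero-area faces contribute 0.

    If ``warn_degenerate`` is a list, indices of degenerate faces are
    appended to it.
    """
    if surface.n_faces == 0:
        return 0.0
    v = surface.vertices
    f = surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if warn_degenerate is not None:
        warn_degenerate.extend(np.flatnonzero(areas == 0.0).tolist())
    return float(areas.sum()) / MM2_PER_CM2


def triangle_areas(surface: Surface) -> np.ndarray:
    """Per-face areas in mm^2 (internal helper used by several stages)."""
    v = surface.vertices
    f = surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mirror(surface: Surface, point, normal) -> Surface:
    """Reflect across the plane through ``point`` with unit ``normal``.

    Triangle winding is reversed so orientation (the sign of the enclosed
    volume) is preserved under the reflection.
    """
    point = np.asarray(point, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    nrm = np.linalg.norm(normal)
    if not np.isclose(nrm, 1.0, atol=1e-8):
        raise ValueError(f"plane normal must be unit length, got |n|={nrm}")
    d = (surface.vertices - point) @ normal
    vertices = surface.vertices - 2.0 * d[:, None] * normal
    return Surface(vertices, surface.faces[:, ::-1])
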