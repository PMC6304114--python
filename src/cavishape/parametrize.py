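"""Cylindrical parametrization of open genus-0 surfaces with two boundary loops.

Each tube-like surface is equipped with per-vertex (u, v) coordinates mapping
it one-to-one onto the unit cylinder: v in [0, 1] runs along the tube between
the two boundary loops, u in [0, 1) runs around it (periodic).  The map is
initialized harmonically — v solves the Laplace equation with Dirichlet
values 0/1 on the boundary loops, u solves it on the mesh cut open along a
boundary-to-boundary path with a unit jump across the cut — and is then
refined by per-vertex relaxation of the area-weighted L2 stretch metric
(the RMS of the per-triangle singular values of the parameter-to-surface
affine map).

The parametrization is the carrier of correspondence: once every subject has
a chart to the same cylinder, resampling all subjects on one (u, v) grid
yields corresponding landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .geometry import Surface, TopologyError, triangle_areas

__all__ = [
    "CylindricalParam",
    "parametrize",
    "stretch_distortion",
    "sample_surface",
]


@dataclass
class CylindricalParam:
    """Per-vertex chart of an open tube onto the unit cylinder.

    u: angular coordinate in [0, 1) (periodic); v: axial coordinate in
    [0, 1], exactly 0 on one boundary loop and 1 on the other; circumference
    and height: physical scales (mm) used when evaluating stretch; stretch:
    the distortion value of this chart; n_flipped: parameter triangles whose
    orientation disagrees with the majority (0 for a bijective chart).
    """

    u: np.ndarray
    v: np.ndarray
    circumference: float
    height: float
    stretch: float = np.nan
    n_flipped: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64) % 1.0
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1D arrays of equal length")

    def copy(self) -> "CylindricalParam":
        return CylindricalParam(
            self.u.copy(),
            self.v.copy(),
            self.circumference,
            self.height,
            self.stretch,
            self.n_flipped,
        )


# ---------------------------------------------------------------------------
# helpers


def _unwrap_triangle_u(u_face: np.ndarray) -> np.ndarray:
    """Lift periodic u values of each face to a common branch.

    u_face: (m, 3) values in [0, 1).  Each row is shifted so all three values
    lie within half a period of the first one.
    """
    ref = u_face[:, :1]
    return ref + ((u_face - ref + 0.5) % 1.0) - 0.5


def _param_signed_areas(faces: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    uf = _unwrap_triangle_u(u[faces])
    vf = v[faces]
    return 0.5 * (
        (uf[:, 1] - uf[:, 0]) * (vf[:, 2] - vf[:, 0])
        - (uf[:, 2] - uf[:, 0]) * (vf[:, 1] - vf[:, 0])
    )


def _assemble_weights(surface: Surface, uniform: bool = False) -> sparse.csr_matrix:
    """Symmetric edge-weight matrix: cotangent by default, or uniform."""
    v = surface.vertices
    f = surface.faces
    n = surface.n_vertices
    I, J, W = [], [], []
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        if uniform:
            w = np.ones(len(f))
        else:
            a = v[i] - v[o]
            b = v[j] - v[o]
            cross = np.maximum(np.linalg.norm(np.cross(a, b), axis=1), 1e-300)
            w = 0.5 * np.einsum("ij,ij->i", a, b) / cross
        I.extend([i, j])
        J.extend([j, i])
        W.extend([w, w])
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    return sparse.csr_matrix((W, (I, J)), shape=(n, n))


def _solve_harmonic(
    weights: sparse.csr_matrix, fixed_idx: np.ndarray, fixed_val: np.ndarray
) -> np.ndarray:
    """Solve the weighted Laplace equation with Dirichlet constraints."""
    n = weights.shape[0]
    deg = np.asarray(weights.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - weights
    free = np.ones(n, dtype=bool)
    free[fixed_idx] = False
    x = np.zeros(n)
    x[fixed_idx] = fixed_val
    lap_ff = lap[free][:, free]
    rhs = -lap[free][:, ~free] @ x[~free]
    x[free] = spsolve(lap_ff.tocsc(), rhs)
    return x


def _boundary_path(surface: Surface, loop_a: np.ndarray, loop_b: np.ndarray):
    """Shortest edge path from loop_a to loop_b avoiding other boundary vertices."""
    import heapq

    edges, _ = surface.edges_unique()
    lengths = np.linalg.norm(
        surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1
    )
    start = int(loop_a.min())
    goal = set(int(x) for x in loop_b)
    blocked = set(int(x) for x in loop_a) - {start}
    nbrs: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in zip(edges, lengths):
        a, b = int(a), int(b)
        nbrs.setdefault(a, []).append((b, float(w)))
        nbrs.setdefault(b, []).append((a, float(w)))
    dist = {start: 0.0}
    prev: dict[int, int] = {}
    heap = [(0.0, start)]
    end = None
    while heap:
        d, x = heapq.heappop(heap)
        if d > dist.get(x, np.inf):
            continue
        if x in goal:
            end = x
            break
        for y, w in nbrs.get(x, ()):
            if y in blocked:
                continue
            nd = d + w
            if nd < dist.get(y, np.inf):
                dist[y] = nd
                prev[y] = x
                heapq.heappush(heap, (nd, y))
    if end is None:
        raise TopologyError("no path between the two boundary loops")
    path = [end]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return path[::-1]


def _cut_along_path(surface: Surface, path: list[int]):
    """Duplicate the path vertices and reattach the faces on the left side.

    Returns (faces_cut, dup_index) where dup_index maps each path vertex to
    its duplicate id in the cut mesh (vertices n .. n+len(path)-1).
    """
    f = surface.faces
    n = surface.n_vertices
    dup = {p: n + i for i, p in enumerate(path)}
    vert_faces: dict[int, list[int]] = {}
    for fi, tri in enumerate(f):
        for vid in tri:
            vert_faces.setdefault(int(vid), []).append(fi)

    # directed edge -> face (consistent winding makes this unique)
    dir_edge_face = {}
    for fi, (a, b, c) in enumerate(f):
        dir_edge_face[(int(a), int(b))] = fi
        dir_edge_face[(int(b), int(c))] = fi
        dir_edge_face[(int(c), int(a))] = fi

    faces_cut = f.copy()
    path_set = set(path)
    for idx, p in enumerate(path):
        neighbours_on_path = set()
        if idx > 0:
            neighbours_on_path.add(path[idx - 1])
        if idx < len(path) - 1:
            neighbours_on_path.add(path[idx + 1])
        incident = vert_faces[p]
        # adjacency between incident faces through non-path edges at p
        comp = {fi: fi for fi in incident}

        def find(x):
            while comp[x] != x:
                comp[x] = comp[comp[x]]
                x = comp[x]
            return x

        edge_to_faces: dict[int, list[int]] = {}
        for fi in incident:
            for vid in f[fi]:
                vid = int(vid)
                if vid != p and vid not in neighbours_on_path:
                    edge_to_faces.setdefault(vid, []).append(fi)
        for flist in edge_to_faces.values():
            for fi in flist[1:]:
                ra, rb = find(flist[0]), find(fi)
                if ra != rb:
                    comp[rb] = ra
        # the left component: face containing the directed path edge (p -> next)
        if idx < len(path) - 1:
            key = (p, path[idx + 1])
        else:
            key = (path[idx - 1], p)
        left_face = dir_edge_face.get(key)
        if left_face is None:
            raise TopologyError("cut path does not follow mesh edges consistently")
        left_root = find(left_face)
        for fi in incident:
            if find(fi) == left_root:
                tri = faces_cut[fi]
                faces_cut[fi] = [dup[p] if int(x) == p else int(x) for x in tri]
    return faces_cut, dup


def _iso_u_column(
    vertices: np.ndarray,
    edges: np.ndarray,
    eu: np.ndarray,
    ev: np.ndarray,
    u_c: float,
) -> tuple[np.ndarray, np.ndarray]:
    """3D points and v values where the iso-u line u=u_c crosses mesh edges."""
    u1 = eu[:, 0]
    du = ((eu[:, 1] - u1 + 0.5) % 1.0) - 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        d_pos = (u_c - u1) % 1.0
        d_neg = (u1 - u_c) % 1.0
        t = np.where(du > 0, d_pos / du, d_neg / np.abs(du))
    hit = (np.abs(du) > 1e-15) & (t >= 0.0) & (t < 1.0)
    t = t[hit][:, None]
    p = vertices[edges[hit, 0]] * (1 - t) + vertices[edges[hit, 1]] * t
    vv = ev[hit, 0] * (1 - t[:, 0]) + ev[hit, 1] * t[:, 0]
    order = np.argsort(vv, kind="stable")
    return p[order], vv[order]


def sample_surface(
    surface: Surface, param: CylindricalParam, n_u: int, n_v: int
) -> np.ndarray:
    """Resample the surface on the regular cylinder grid.

    For each of the n_u iso-u columns u_i = i / n_u the crossing polyline
    from v=0 to v=1 is traced through the triangulation; the n_v grid values
    v_j = j / (n_v - 1) are then located along it by linear interpolation in
    v.  Charts produced by :func:`parametrize` store v as the normalized arc
    length along each column, so for them the samples are uniformly spaced
    on the surface along every column; a subsequent reparametrization (warp)
    of v deliberately redistributes them.  Returns an (n_u * n_v, 3) array
    in u-major order (landmark i * n_v + j is column i, row j).
    """
    if len(param.u) != surface.n_vertices:
        raise ValueError("parametrization does not match surface")
    if n_u < 2 or n_v < 2:
        raise ValueError("need n_u >= 2 and n_v >= 2")
    edges, _ = surface.edges_unique()
    # orient every edge so its u-increment is positive, then find all grid
    # columns k/n_u inside [u1, u1 + du) in one vectorized pass
    eu = param.u[edges]
    ev = param.v[edges]
    u1 = eu[:, 0]
    du = ((eu[:, 1] - u1 + 0.5) % 1.0) - 0.5
    swap = du < 0
    u1 = np.where(swap, (u1 + du) % 1.0, u1)
    du = np.abs(du)
    a_idx = np.where(swap, edges[:, 1], edges[:, 0])
    b_idx = np.where(swap, edges[:, 0], edges[:, 1])
    va = np.where(swap, ev[:, 1], ev[:, 0])
    vb = np.where(swap, ev[:, 0], ev[:, 1])
    live = du > 1e-15
    k0 = np.ceil(u1 * n_u - 1e-12).astype(np.int64)
    k1 = np.ceil((u1 + du) * n_u - 1e-12).astype(np.int64) - 1
    counts = np.where(live, np.maximum(k1 - k0 + 1, 0), 0)
    e_rep = np.repeat(np.arange(len(edges)), counts)
    cum = np.cumsum(counts) - counts
    k_off = np.arange(counts.sum()) - np.repeat(cum, counts)
    cols_k = np.repeat(k0, counts) + k_off
    t = (cols_k / n_u - u1[e_rep]) / du[e_rep]
    cols = cols_k % n_u
    pa = surface.vertices[a_idx[e_rep]]
    pb = surface.vertices[b_idx[e_rep]]
    pts = pa + t[:, None] * (pb - pa)
    vv = va[e_rep] + t * (vb[e_rep] - va[e_rep])
    order = np.lexsort((vv, cols))
    cols, vv, pts = cols[order], vv[order], pts[order]
    starts = np.searchsorted(cols, np.arange(n_u))
    ends = np.searchsorted(cols, np.arange(n_u) + 1)
    out = np.empty((n_u * n_v, 3))
    targets = np.linspace(0.0, 1.0, n_v)
    for i in range(n_u):
        a, b = starts[i], ends[i]
        if b - a < 2:
            raise RuntimeError(
                f"iso-u column {i} crosses fewer than 2 edges; chart is not bijective"
            )
        for k in range(3):
            out[i * n_v : (i + 1) * n_v, k] = np.interp(
                targets, vv[a:b], pts[a:b, k]
            )
    return out


def _normalize_v_arclength(
    surface: Surface, u: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Replace v with the normalized 3D arc length along each iso-u column.

    This realizes the uniform-surface-sampling guarantee: after
    normalization, equal v steps travel equal distances on the surface along
    every column.  Columns are cached by u value, which collapses the cost
    on structured meshes.
    """
    edges, _ = surface.edges_unique()
    eu = u[edges]
    ev = v[edges]
    new_v = np.empty_like(v)
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(len(v)):
        key = round(float(u[i]), 12)
        if key not in cache:
            pts, vv = _iso_u_column(surface.vertices, edges, eu, ev, u[i])
            if len(pts) < 2:
                cache[key] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
            else:
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                s = np.concatenate([[0.0], np.cumsum(seg)])
                total = s[-1] if s[-1] > 0 else 1.0
                cache[key] = (vv, s / total)
        vv, s = cache[key]
        new_v[i] = np.interp(v[i], vv, s)
    new_v[v <= 0.0] = 0.0
    new_v[v >= 1.0] = 1.0
    return new_v


def stretch_distortion(
    surface: Surface,
    param: CylindricalParam,
    circumference: float | None = None,
    height: float | None = None,
) -> float:
    """Area-weighted L2 stretch of the chart.

    Per triangle, the affine map from the unrolled parameter triangle
    (circumference * u, height * v) to the 3D triangle has singular values
    Gamma >= gamma; the metric is sqrt(sum_T A_T (Gamma^2 + gamma^2) / 2 /
    sum_T A_T) with A_T the 3D triangle area.  1 means isometry at the
    chosen scales; infinity flags a degenerate parameter triangle.
    """
    if len(param.u) != surface.n_vertices:
        raise ValueError("parametrization does not match surface")
    C = param.circumference if circumference is None else circumference
    H = param.height if height is None else height
    f = surface.faces
    uf = _unwrap_triangle_u(param.u[f]) * C
    vf = param.v[f] * H
    # 2D edge matrix [q2-q1, q3-q1]
    a = uf[:, 1] - uf[:, 0]
    b = uf[:, 2] - uf[:, 0]
    c = vf[:, 1] - vf[:, 0]
    d = vf[:, 2] - vf[:, 0]
    det = a * d - b * c
    if np.any(np.abs(det) < 1e-300):
        return np.inf
    p = surface.vertices[f]
    e1 = p[:, 1] - p[:, 0]  # (m, 3)
    e2 = p[:, 2] - p[:, 0]
    # J = [e1, e2] @ inv([[a, b], [c, d]]); columns of J:
    j1 = (e1 * d[:, None] - e2 * c[:, None]) / det[:, None]
    j2 = (-e1 * b[:, None] + e2 * a[:, None]) / det[:, None]
    frob2 = np.einsum("ij,ij->i", j1, j1) + np.einsum("ij,ij->i", j2, j2)
    areas = triangle_areas(surface)
    w = areas.sum()
    if w <= 0:
        raise ValueError("surface has zero area")
    return float(np.sqrt((areas * frob2 / 2.0).sum() / w))


def _relax_stretch(
    surface: Surface,
    u: np.ndarray,
    v: np.ndarray,
    circumference: float,
    height: float,
    passes: int,
    rel_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex coordinate descent on the L2 stretch energy.

    Deterministic sweep over vertices; each vertex tries a shrinking set of
    (u, v) steps over its one-ring and keeps the best non-flipping move.
    Boundary vertices keep v fixed and move only in u.
    """
    f = surface.faces
    areas = triangle_areas(surface)
    p = surface.vertices[f]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    vert_faces: dict[int, list[int]] = {}
    for fi, tri in enumerate(f):
        for vid in tri:
            vert_faces.setdefault(int(vid), []).append(fi)
    on_boundary = np.zeros(surface.n_vertices, dtype=bool)
    edges, counts = surface.edges_unique()
    on_boundary[np.unique(edges[counts == 1])] = True

    sign_ref = np.sign(_param_signed_areas(f, u, v))

    def local_energy(vid: int, uu: float, vv: float, faces_i: list[int]) -> float:
        total = 0.0
        for fi in faces_i:
            tri = f[fi]
            uvals = []
            vvals = []
            for t in tri:
                t = int(t)
                if t == vid:
                    uvals.append(uu)
                    vvals.append(vv)
                else:
                    uvals.append(u[t])
                    vvals.append(v[t])
            # unwrap relative to this vertex's u
            uw = [uu + (((x - uu) + 0.5) % 1.0) - 0.5 for x in uvals]
            aa = (uw[1] - uw[0]) * circumference
            bb = (uw[2] - uw[0]) * circumference
            cc = (vvals[1] - vvals[0]) * height
            dd = (vvals[2] - vvals[0]) * height
            det = aa * dd - bb * cc
            if det * sign_ref[fi] <= 0 or abs(det) < 1e-300:
                return np.inf
            j1 = (e1[fi] * dd - e2[fi] * cc) / det
            j2 = (-e1[fi] * bb + e2[fi] * aa) / det
            total += areas[fi] * (j1 @ j1 + j2 @ j2) / 2.0
        return total

    du0 = 0.25 / max(1.0, np.sqrt(surface.n_vertices))
    dirs = [
        (1, 0), (-1, 0), (0, 1), (0, -1),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ]
    for _ in range(max(0, passes)):
        moved = 0.0
        for vid in range(surface.n_vertices):
            faces_i = vert_faces.get(vid)
            if not faces_i:
                continue
            best = local_energy(vid, u[vid], v[vid], faces_i)
            if not np.isfinite(best):
                continue
            best_uv = (u[vid], v[vid])
            step = du0
            for _level in range(3):
                for dx, dy in dirs:
                    if on_boundary[vid] and dy != 0:
                        continue
                    uu = (u[vid] + dx * step) % 1.0
                    vv = v[vid] + dy * step
                    if not 0.0 < vv < 1.0 and dy != 0:
                        continue
                    e = local_energy(vid, uu, vv, faces_i)
                    if e < best * (1 - rel_tol):
                        best, best_uv = e, (uu, vv)
                step *= 0.5
            if best_uv != (u[vid], v[vid]):
                u[vid], v[vid] = best_uv
                moved += 1
        if moved == 0:
            break
    return u, v


def parametrize(
    surface: Surface, relax_passes: int = 2, seed_vertex: int | None = None
) -> CylindricalParam:
    """Compute the cylindrical chart of an open genus-0 tube.

    The surface must be edge-manifold with chi = 0 and exactly two boundary
    loops.  The boundary loop containing the smallest vertex index gets v=0
    (deterministic); the u origin is fixed by the cut path starting at
    ``seed_vertex`` (default: the smallest vertex index on the v=0 loop), so
    the result is reproducible and equivariant under rigid motions.
    """
    from .geometry import topology

    report = topology(surface)
    if report.euler_characteristic != 0 or report.n_boundary_loops != 2:
        raise TopologyError(
            "cylindrical parametrization needs chi=0 and 2 boundary loops, got "
            f"chi={report.euler_characteristic}, loops={report.n_boundary_loops}"
        )
    loops = surface.boundary_loops()
    if loops[0].min() > loops[1].min():
        loops = [loops[1], loops[0]]
    loop_a, loop_b = loops
    if seed_vertex is not None:
        if seed_vertex in set(int(x) for x in loop_b):
            loop_a, loop_b = loop_b, loop_a
        loop_a = np.roll(loop_a, -int(np.argmin(np.abs(loop_a - seed_vertex))))

    weights = _assemble_weights(surface)
    fixed = np.concatenate([loop_a, loop_b])
    vals = np.concatenate([np.zeros(len(loop_a)), np.ones(len(loop_b))])
    v = _solve_harmonic(weights, fixed, vals)
    v = np.clip(v, 0.0, 1.0)

    path = _boundary_path(surface, loop_a, loop_b)
    faces_cut, dup = _cut_along_path(surface, path)
    n = surface.n_vertices
    n_cut = n + len(path)
    # weights on the cut mesh: same cotangents, reindexed faces
    vx = np.vstack([surface.vertices, surface.vertices[path]])
    cut_surface = Surface(vx, faces_cut)
    w_cut = _assemble_weights(cut_surface)
    fixed_u = np.concatenate([np.array(path), np.array([dup[p] for p in path])])
    vals_u = np.concatenate([np.zeros(len(path)), np.ones(len(path))])
    u_cut = _solve_harmonic(w_cut, fixed_u, vals_u)
    u = u_cut[:n] % 1.0

    def flipped(uu, vv, ref=None):
        sa = _param_signed_areas(surface.faces, uu, vv)
        s = np.sign(sa)
        majority = 1.0 if (s > 0).sum() >= (s < 0).sum() else -1.0
        return int((s * majority <= 0).sum())

    nf = flipped(u, v)
    if nf > 0:
        # retry with uniform weights, keep the better initialization
        w_uni = _assemble_weights(surface, uniform=True)
        v2 = np.clip(_solve_harmonic(w_uni, fixed, vals), 0.0, 1.0)
        w_cut_uni = _assemble_weights(cut_surface, uniform=True)
        u2 = _solve_harmonic(w_cut_uni, fixed_u, vals_u)[:n] % 1.0
        if flipped(u2, v2) < nf:
            u, v = u2, v2
            nf = flipped(u, v)

    circumference = float(
        np.mean(
            [
                np.linalg.norm(
                    np.diff(
                        surface.vertices[np.append(lp, lp[0])], axis=0
                    ),
                    axis=1,
                ).sum()
                for lp in (loop_a, loop_b)
            ]
        )
    )
    if nf == 0:
        v = _normalize_v_arclength(surface, u, v)
    param = CylindricalParam(u, v, circumference, height=1.0)
    # height scale: mean arc length of a handful of iso-u columns
    edges, _ = surface.edges_unique()
    eu = param.u[edges]
    ev = param.v[edges]
    lengths = []
    for i in range(8):
        pts, _ = _iso_u_column(surface.vertices, edges, eu, ev, (i + 0.5) / 8)
        if len(pts) >= 2:
            lengths.append(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    param.height = float(np.mean(lengths)) if lengths else circumference

    if relax_passes > 0 and nf == 0:
        u, v = _relax_stretch(
            surface, param.u.copy(), param.v.copy(),
            param.circumference, param.height, relax_passes,
        )
        if flipped(u, v) == 0:
            v = _normalize_v_arclength(surface, u, v)
        param = CylindricalParam(u, v, param.circumference, param.height)
        nf = flipped(u, v)
    param.n_flipped = nf
    param.stretch = stretch_distortion(surface, param)
    return param
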