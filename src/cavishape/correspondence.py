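"""Groupwise correspondence by minimum-description-length optimization.

Given a population of cylindrically parametrized tubes, the correspondence
is refined in the order: per-subject rigid pose and u-rotation of the chart,
then non-rigid (u, v) reparametrizations on control grids of increasing
resolution.  Every candidate move is accepted only if it lowers the MDL
objective

    mu(lambda_1..lambda_{n_s-1}) = sum_{lambda_i >= lambda_c} (1 + log(lambda_i / lambda_c))
                                 + sum_{lambda_i < lambda_c} lambda_i / lambda_c,

the simplified description-length of the PCA model built from the current
landmarks, with lambda_c the expected noise variance (mm^2).  mu favours
compact models: it is zero when every eigenvalue is zero, and any sliding of
landmarks along the surfaces that inflates PCA variance increases it.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .geometry import Surface
from .model import CorrespondedPopulation, quaternion_rotation, shapes_to_matrix
from .parametrize import (
    CylindricalParam,
    _param_signed_areas,
    sample_surface,
)

__all__ = [
    "MdlConfig",
    "UVWarp",
    "SubjectChart",
    "PopulationParam",
    "mdl_objective",
    "model_eigenvalues",
    "align_rigid_and_rotate",
    "refine_nonrigid",
    "extract_landmarks",
]


def mdl_objective(eigenvalues, lambda_c: float) -> float:
    """Simplified MDL of a PCA spectrum (natural log, noise cutoff lambda_c)."""
    if lambda_c <= 0:
        raise ValueError("lambda_c must be positive")
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if np.any(lam < -1e-9):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    big = lam >= lambda_c
    mu = float(np.sum(1.0 + np.log(lam[big] / lambda_c)))
    mu += float(np.sum(lam[~big] / lambda_c))
    return mu


def model_eigenvalues(shape_matrix: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the sample covariance of shape vectors.

    shape_matrix: (n_s, 3n); at most n_s - 1 eigenvalues are nonzero.  Uses
    the Gram matrix, so the cost is O(n_s^2 * 3n).
    """
    x = np.asarray(shape_matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n_s >= 2, 3n) matrix")
    xc = x - x.mean(axis=0)
    gram = xc @ xc.T / (x.shape[0] - 1)
    vals = np.linalg.eigvalsh(gram)[::-1]
    return np.clip(vals[: x.shape[0] - 1], 0.0, None)


@dataclass
class MdlConfig:
    """Tuning of the MDL optimization.

    lambda_c: noise-variance cutoff in mm^2 (default the variance of a
    0.25 mm displacement per coordinate); levels: control-grid resolutions
    (n_u x n_v) for the non-rigid stage, coarse to fine; grid: landmark
    sampling grid.
    """

    lambda_c: float = 0.0625
    levels: tuple = ((2, 4), (4, 8), (8, 16))
    grid: tuple = (20, 50)
    max_iter: int = 10
    tol: float = 1e-4
    warp_sweeps: int = 1
    shift_refine_iters: int = 30

    def __post_init__(self) -> None:
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be positive")
        sizes = [a * b for a, b in self.levels]
        if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
            raise ValueError("levels must be strictly increasing in resolution")


class UVWarp:
    """Periodic bilinear reparametrization of the cylinder domain.

    Control displacements (du, dv) live on an (n_cu x n_cv) lattice with u
    nodes at i / n_cu (periodic) and v nodes at linspace(0, 1, n_cv); the
    first and last v rows have dv = 0 so the boundary circles stay fixed.
    Amplitudes are capped at ``max_fraction`` of the control spacing, which
    keeps the warp bijective for the populations handled here; candidate
    warps are additionally rejected if they flip any parameter triangle.
    """

    def __init__(self, n_cu: int, n_cv: int, max_fraction: float = 0.3):
        if n_cu < 1 or n_cv < 2:
            raise ValueError("control grid must be at least 1 x 2")
        self.n_cu = n_cu
        self.n_cv = n_cv
        self.max_fraction = max_fraction
        self.du = np.zeros((n_cu, n_cv))
        self.dv = np.zeros((n_cu, n_cv))

    @property
    def u_limit(self) -> float:
        return self.max_fraction / self.n_cu

    @property
    def v_limit(self) -> float:
        return self.max_fraction / (self.n_cv - 1)

    def copy(self) -> "UVWarp":
        w = UVWarp(self.n_cu, self.n_cv, self.max_fraction)
        w.du = self.du.copy()
        w.dv = self.dv.copy()
        return w

    def set_control(self, iu: int, iv: int, comp: str, value: float) -> bool:
        """Set one control displacement; returns False if out of bounds."""
        limit = self.u_limit if comp == "u" else self.v_limit
        if abs(value) > limit:
            return False
        if comp == "v" and iv in (0, self.n_cv - 1):
            return False
        (self.du if comp == "u" else self.dv)[iu, iv] = value
        return True

    def apply(self, u: np.ndarray, v: np.ndarray):
        """Warp (u, v) points; u is periodic, v is clipped to [0, 1]."""
        u = np.asarray(u, dtype=np.float64) % 1.0
        v = np.clip(np.asarray(v, dtype=np.float64), 0.0, 1.0)
        fu = u * self.n_cu
        i0 = np.floor(fu).astype(int) % self.n_cu
        tu = fu - np.floor(fu)
        i1 = (i0 + 1) % self.n_cu
        fv = v * (self.n_cv - 1)
        j0 = np.minimum(np.floor(fv).astype(int), self.n_cv - 2)
        tv = fv - j0
        w00 = (1 - tu) * (1 - tv)
        w10 = tu * (1 - tv)
        w01 = (1 - tu) * tv
        w11 = tu * tv
        du = (
            w00 * self.du[i0, j0]
            + w10 * self.du[i1, j0]
            + w01 * self.du[i0, j0 + 1]
            + w11 * self.du[i1, j0 + 1]
        )
        dv = (
            w00 * self.dv[i0, j0]
            + w10 * self.dv[i1, j0]
            + w01 * self.dv[i0, j0 + 1]
            + w11 * self.dv[i1, j0 + 1]
        )
        return (u + du) % 1.0, np.clip(v + dv, 0.0, 1.0)

    def is_monotone(self) -> bool:
        """Strict v-monotonicity of v + dv along every u line.

        dv is piecewise bilinear, so the v-slope between adjacent control
        rows is linear in u; checking dv-row differences > -dv_spacing at
        the control columns is necessary and sufficient.
        """
        dv_spacing = 1.0 / (self.n_cv - 1)
        return bool(np.all(np.diff(self.dv, axis=1) > -dv_spacing))


@dataclass
class SubjectChart:
    """One subject in the groupwise optimization: surface + chart + transforms."""

    surface: Surface
    param: CylindricalParam
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    u_shift: float = 0.0
    warps: list = field(default_factory=list)

    def effective_param(self, extra_warp: UVWarp | None = None) -> CylindricalParam:
        u = (self.param.u + self.u_shift) % 1.0
        v = self.param.v.copy()
        for w in self.warps:
            u, v = w.apply(u, v)
        if extra_warp is not None:
            u, v = extra_warp.apply(u, v)
        return CylindricalParam(
            u, v, self.param.circumference, self.param.height
        )

    def landmarks(
        self, grid, extra_warp: UVWarp | None = None, raw: bool = False
    ) -> np.ndarray:
        """Sampled landmarks at the current transforms; ``raw`` skips the pose."""
        p = self.effective_param(extra_warp)
        if extra_warp is not None:
            sa = _param_signed_areas(self.surface.faces, p.u, p.v)
            s = np.sign(sa)
            if (s > 0).any() and (s < 0).any():
                raise _WarpFoldError()
        pts = sample_surface(self.surface, p, *grid)
        if raw:
            return pts
        return pts @ self.rotation.T + self.translation


class _WarpFoldError(RuntimeError):
    pass


@dataclass
class PopulationParam:
    subjects: list
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("need at least two subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def copy(self) -> "PopulationParam":
        return PopulationParam([_copy.deepcopy(s) for s in self.subjects])

    def landmark_stack(self, grid) -> np.ndarray:
        """(n_s, n, 3) landmarks at the current transforms."""
        return np.array([s.landmarks(grid) for s in self.subjects])


def _mu_of_stack(stack: np.ndarray, lambda_c: float) -> float:
    return mdl_objective(model_eigenvalues(shapes_to_matrix(stack)), lambda_c)


def align_rigid_and_rotate(
    pop: PopulationParam, cfg: MdlConfig, trace: list | None = None
) -> PopulationParam:
    """Optimize per-subject rigid pose and chart u-rotation under the MDL.

    Coordinate descent: for each subject in turn, (a) the Procrustes pose to
    the current mean, (b) a coarse u-shift search over whole column rolls
    (free: a roll permutes landmark columns), (c) a golden-section refinement
    of the shift — each accepted only if mu decreases.  The mu trace is
    therefore monotone non-increasing; pass ``trace`` to record it.
    """
    pop = pop.copy()
    n_u, n_v = cfg.grid
    stack = pop.landmark_stack(cfg.grid)
    mu = _mu_of_stack(stack, cfg.lambda_c)
    if trace is not None:
        trace.append(mu)
    gold = (np.sqrt(5) - 1) / 2

    def posed(raw: np.ndarray, mean_pts: np.ndarray):
        """Best Procrustes pose of raw landmarks onto the mean."""
        r = quaternion_rotation(raw, mean_pts)
        t = mean_pts.mean(axis=0) - raw.mean(axis=0) @ r.T
        return raw @ r.T + t, r, t

    for _it in range(cfg.max_iter):
        mu_start = mu
        for i, subj in enumerate(pop.subjects):
            mean_pts = stack.mean(axis=0)
            raw = (stack[i] - subj.translation) @ subj.rotation  # undo pose
            raw_grid = raw.reshape(n_u, n_v, 3)
            # --- joint coarse search: every whole-column roll of the chart
            # (a free permutation of the landmark columns), each with its
            # own optimal rigid pose
            best = None
            for roll in range(n_u):
                cand_raw = np.roll(raw_grid, roll, axis=0).reshape(-1, 3)
                cand, r_new, t_new = posed(cand_raw, mean_pts)
                trial = stack.copy()
                trial[i] = cand
                mu_c = _mu_of_stack(trial, cfg.lambda_c)
                if best is None or mu_c < best[0]:
                    best = (mu_c, roll, r_new, t_new, cand)
            mu_c, roll, r_new, t_new, cand = best
            if mu_c < mu:
                # rolled column j holds old column j - r, which samples chart
                # coordinate j/n_u - (shift + r/n_u): shift grows by r/n_u
                subj.u_shift = (subj.u_shift + roll / n_u) % 1.0
                subj.rotation, subj.translation = r_new, t_new
                stack[i] = cand
                mu = mu_c
                if trace is not None:
                    trace.append(mu)

            # --- golden-section refinement of the u-shift, re-posing at
            # every probe
            cache: dict[float, tuple] = {}
            r_keep, t_keep = subj.rotation, subj.translation

            def mu_at(shift: float) -> tuple:
                if shift in cache:
                    return cache[shift]
                old_shift = subj.u_shift
                old_r, old_t = subj.rotation, subj.translation
                subj.u_shift = shift % 1.0
                subj.rotation = np.eye(3)
                subj.translation = np.zeros(3)
                raw_s = subj.landmarks(cfg.grid)
                subj.u_shift = old_shift
                subj.rotation, subj.translation = old_r, old_t
                cand_s, r_s, t_s = posed(raw_s, mean_pts)
                trial = stack.copy()
                trial[i] = cand_s
                res = (_mu_of_stack(trial, cfg.lambda_c), cand_s, r_s, t_s)
                cache[shift] = res
                return res

            a = subj.u_shift - 1.0 / n_u
            b = subj.u_shift + 1.0 / n_u
            c = b - gold * (b - a)
            d = a + gold * (b - a)
            fc, fd = mu_at(c)[0], mu_at(d)[0]
            for _ in range(cfg.shift_refine_iters):
                if fc < fd:
                    b, d, fd = d, c, fc
                    c = b - gold * (b - a)
                    fc = mu_at(c)[0]
                else:
                    a, c, fc = c, d, fd
                    d = a + gold * (b - a)
                    fd = mu_at(d)[0]
            best_shift = c if fc < fd else d
            best_mu, cand_s, r_s, t_s = mu_at(best_shift)
            if best_mu < mu:
                subj.u_shift = best_shift % 1.0
                subj.rotation, subj.translation = r_s, t_s
                stack[i] = cand_s
                mu = best_mu
                if trace is not None:
                    trace.append(mu)
            else:
                subj.rotation, subj.translation = r_keep, t_keep
        if mu_start - mu <= cfg.tol * max(mu_start, 1e-30):
            break
    return pop


def refine_nonrigid(
    pop: PopulationParam, cfg: MdlConfig, trace: list | None = None
) -> PopulationParam:
    """Optimize per-subject (u, v) warps at each level of detail.

    For every control node and component an accept-if-improving +-step probe
    is run (shrinking step sizes); proposals breaking v-monotonicity or
    folding the chart are rejected outright, so mu never increases.  After
    each level the rigid poses and u-shifts are refreshed (one
    coordinate-descent pass), since undoing a reparametrization typically
    frees pose corrections that were compensating for it.
    """
    pop = pop.copy()
    stack = pop.landmark_stack(cfg.grid)
    mu = _mu_of_stack(stack, cfg.lambda_c)
    if trace is not None:
        trace.append(mu)
    import dataclasses

    rigid_cfg = dataclasses.replace(cfg, max_iter=1)
    for n_cu, n_cv in cfg.levels:
        warps = [UVWarp(n_cu, n_cv) for _ in pop.subjects]
        for _sweep in range(cfg.warp_sweeps):
            for i, subj in enumerate(pop.subjects):
                w = warps[i]
                for comp, limit in (("u", w.u_limit), ("v", w.v_limit)):
                    arr = w.du if comp == "u" else w.dv
                    for iu in range(n_cu):
                        iv_range = (
                            range(n_cv) if comp == "u" else range(1, n_cv - 1)
                        )
                        for iv in iv_range:
                            mean_pts = stack.mean(axis=0)
                            base_val = arr[iu, iv]
                            best_val, best_mu = base_val, mu
                            best_row = best_pose = None
                            for step in (limit, 0.5 * limit, 0.25 * limit):
                                for sgn in (1.0, -1.0):
                                    val = base_val + sgn * step
                                    if abs(val) > limit:
                                        continue
                                    cand = w.copy()
                                    (cand.du if comp == "u" else cand.dv)[
                                        iu, iv
                                    ] = val
                                    if comp == "v" and not cand.is_monotone():
                                        continue
                                    try:
                                        raw = subj.landmarks(
                                            cfg.grid, cand, raw=True
                                        )
                                    except (_WarpFoldError, RuntimeError):
                                        continue
                                    # each candidate gets its own optimal
                                    # rigid pose to the current mean
                                    r_c = quaternion_rotation(raw, mean_pts)
                                    t_c = mean_pts.mean(
                                        axis=0
                                    ) - raw.mean(axis=0) @ r_c.T
                                    row = raw @ r_c.T + t_c
                                    trial = stack.copy()
                                    trial[i] = row
                                    mu_c = _mu_of_stack(trial, cfg.lambda_c)
                                    if mu_c < best_mu:
                                        best_val, best_mu = val, mu_c
                                        best_row, best_pose = row, (r_c, t_c)
                            if best_row is not None:
                                arr[iu, iv] = best_val
                                subj.rotation, subj.translation = best_pose
                                stack[i] = best_row
                                mu = best_mu
                                if trace is not None:
                                    trace.append(mu)
        for subj, w in zip(pop.subjects, warps):
            if np.any(w.du) or np.any(w.dv):
                subj.warps.append(w)
        pop = align_rigid_and_rotate(pop, rigid_cfg, trace=trace)
        stack = pop.landmark_stack(cfg.grid)
        mu = _mu_of_stack(stack, cfg.lambda_c)
    return pop


def extract_landmarks(
    pop: PopulationParam, cfg: MdlConfig, covariates=None
) -> CorrespondedPopulation:
    """Sample every subject on the common grid through its optimized chart."""
    stack = pop.landmark_stack(cfg.grid)
    return CorrespondedPopulation(stack, covariates, cfg.grid)
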