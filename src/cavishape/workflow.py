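"""End-to-end pipeline helpers: surfaces in, shape model out.

These are the library-level entry points the command-line interface wraps:
cut the two sampling holes, parametrize every subject, run the MDL
correspondence (rigid + u-rotation, then non-rigid warps), extract the
corresponded landmarks, Procrustes-align and fit the PCA shape model.
"""

from __future__ import annotations

import numpy as np

from .correspondence import (
    MdlConfig,
    PopulationParam,
    SubjectChart,
    align_rigid_and_rotate,
    extract_landmarks,
    refine_nonrigid,
)
from .geometry import Surface, mirror as mirror_surface
from .model import (
    CorrespondedPopulation,
    PointDistributionModel,
    ProcrustesAligner,
    matrix_to_points,
)
from .parametrize import parametrize
from .preprocess import cut_boundary_holes

__all__ = ["charts_from_surfaces", "run_correspondence", "fit_shape_model",
           "run_pipeline"]


def charts_from_surfaces(
    surfaces: list[Surface],
    seeds,
    hole_radius: float = 1.0,
    relax_passes: int = 0,
) -> PopulationParam:
    """Cut the two sampling holes and parametrize every (closed) surface.

    ``seeds`` is either one (2, 3) array shared by all subjects or a list of
    per-subject seed pairs.  Surfaces that already have two boundary loops
    are parametrized as they are.
    """
    seeds = np.asarray(seeds, dtype=np.float64)
    per_subject = seeds.ndim == 3
    subjects = []
    for i, surf in enumerate(surfaces):
        s = surf
        if s.is_watertight():
            s = cut_boundary_holes(s, seeds[i] if per_subject else seeds,
                                   hole_radius)
        param = parametrize(s, relax_passes=relax_passes)
        subjects.append(SubjectChart(s, param))
    return PopulationParam(subjects)


def run_correspondence(
    pop: PopulationParam,
    cfg: MdlConfig | None = None,
    nonrigid: bool = True,
    trace: list | None = None,
) -> PopulationParam:
    """Rigid + u-rotation MDL alignment, then optional non-rigid refinement."""
    cfg = cfg or MdlConfig()
    pop = align_rigid_and_rotate(pop, cfg, trace=trace)
    if nonrigid:
        pop = refine_nonrigid(pop, cfg, trace=trace)
    return pop


def fit_shape_model(
    pop_corr: CorrespondedPopulation,
    mirror_plane: tuple | None = None,
    **model_kwargs,
):
    """Procrustes-align the landmark population and fit the PCA model.

    If ``mirror_plane`` (point, unit normal) is given, a mirrored copy of
    every subject is appended before alignment — the augmentation that makes
    the mean shape symmetric — with the ``mirrored`` covariate flag set.
    Returns (model, aligned_population).
    """
    landmarks = pop_corr.landmarks
    covariates = pop_corr.covariates
    if mirror_plane is not None:
        point, normal = (np.asarray(a, dtype=np.float64) for a in mirror_plane)
        normal = normal / np.linalg.norm(normal)
        d = (landmarks - point) @ normal
        mirrored = landmarks - 2.0 * d[..., None] * normal
        landmarks = np.concatenate([landmarks, mirrored], axis=0)
        if covariates is not None:
            import pandas as pd

            cov_m = covariates.copy()
            cov = pd.concat([covariates, cov_m], ignore_index=True)
            cov["mirrored"] = [False] * len(covariates) + [True] * len(cov_m)
            covariates = cov
    pop_all = CorrespondedPopulation(landmarks, covariates, pop_corr.grid)
    aligner = ProcrustesAligner()
    aligned_matrix = aligner.fit_transform(pop_all.matrix())
    aligned = CorrespondedPopulation(
        matrix_to_points(aligned_matrix), covariates, pop_corr.grid
    )
    model = PointDistributionModel(**model_kwargs).fit(aligned_matrix)
    return model, aligned


def run_pipeline(
    surfaces: list[Surface],
    seeds,
    cfg: MdlConfig | None = None,
    covariates=None,
    hole_radius: float = 1.0,
    nonrigid: bool = True,
    mirror_plane: tuple | None = None,
    relax_passes: int = 0,
    trace: list | None = None,
):
    """Surfaces -> corresponded landmarks -> Procrustes -> PCA shape model.

    Returns a dict with the optimized population, the corresponded landmark
    population, the aligned population, the fitted model and the mu trace.
    """
    cfg = cfg or MdlConfig()
    pop = charts_from_surfaces(surfaces, seeds, hole_radius, relax_passes)
    trace = [] if trace is None else trace
    pop = run_correspondence(pop, cfg, nonrigid=nonrigid, trace=trace)
    corresponded = extract_landmarks(pop, cfg, covariates)
    model, aligned = fit_shape_model(corresponded, mirror_plane=mirror_plane)
    return {
        "population": pop,
        "corresponded": corresponded,
        "aligned": aligned,
        "model": model,
        "mu_trace": trace,
    }
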