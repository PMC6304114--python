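"""Procrustes alignment and the PCA point-distribution model.

Shapes with n landmarks are handled as vectors x = (x1..xn, y1..yn, z1..zn)
of length 3n.  :class:`ProcrustesAligner` removes translation and rotation
(deliberately not scale) by generalized Procrustes analysis with the rotation
computed from the quaternion solution of the orthogonal Procrustes problem,
which by construction excludes reflections.  :class:`PointDistributionModel`
is the PCA shape model: a mean shape, orthonormal modes P and mode variances
lambda_i, with synthesis x = mean + P b (optionally clamped to +-3 sqrt(lambda))
and projection b = P^T (x - mean).

Both are scikit-learn style estimators operating on an (n_shapes, 3n) data
matrix, so they compose with sklearn pipelines; the module-level functions
are thin wrappers kept for pipeline scripting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CorrespondedPopulation",
    "ProcrustesAligner",
    "PointDistributionModel",
    "procrustes_align",
    "build_model",
    "synthesize",
    "project",
    "compactness",
    "quaternion_rotation",
    "shapes_to_matrix",
    "matrix_to_points",
]


def shapes_to_matrix(points: np.ndarray) -> np.ndarray:
    """(n_s, n, 3) landmark arrays -> (n_s, 3n) shape vectors (x..., y..., z...)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 3 or points.shape[2] != 3:
        raise ValueError("expected an (n_shapes, n_landmarks, 3) array")
    return points.transpose(0, 2, 1).reshape(points.shape[0], -1)


def matrix_to_points(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`shapes_to_matrix`; accepts a single vector or a matrix."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] % 3:
        raise ValueError("shape vectors must have length 3n")
    n = x.shape[1] // 3
    pts = x.reshape(x.shape[0], 3, n).transpose(0, 2, 1)
    return pts[0] if single else pts


@dataclass
class CorrespondedPopulation:
    """Population of corresponded landmark sets with per-subject covariates.

    landmarks: (n_s, n, 3) array, identical landmark ordering across
    subjects; covariates: DataFrame with at least subject_id; mirrored flag
    (if present) marks the duplicated half of a mirror-augmented population;
    grid: the (n_u, n_v) sampling grid the landmarks came from, if any.
    """

    landmarks: np.ndarray
    covariates: pd.DataFrame | None = None
    grid: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=np.float64)
        if self.landmarks.ndim != 3 or self.landmarks.shape[2] != 3:
            raise ValueError("landmarks must be (n_s, n, 3)")
        if self.landmarks.shape[0] < 2:
            raise ValueError("need at least two subjects")

    @property
    def n_subjects(self) -> int:
        return self.landmarks.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[1]

    def matrix(self) -> np.ndarray:
        return shapes_to_matrix(self.landmarks)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("landmarks", data=self.landmarks)
            if self.grid is not None:
                h5.attrs["grid"] = self.grid
            if self.covariates is not None:
                g = h5.create_group("covariates")
                for col in self.covariates.columns:
                    vals = self.covariates[col].to_numpy()
                    if vals.dtype == object:
                        vals = vals.astype("S")
                    g.create_dataset(col, data=vals)

    def to_ply_dir(self, directory) -> None:
        """Write one PLY per subject with shared vertex ordering.

        Requires the sampling grid so the landmark lattice can be
        triangulated consistently across subjects.
        """
        from pathlib import Path

        if self.grid is None:
            raise ValueError("PLY export needs the (n_u, n_v) sampling grid")
        from .geometry import write_mesh
        from .morphometrics import grid_surface

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i in range(self.n_subjects):
            surf = grid_surface(self.landmarks[i], *self.grid)
            write_mesh(surf, directory / f"subject_{i:03d}.ply")

    @classmethod
    def from_hdf5(cls, path) -> "CorrespondedPopulation":
        import h5py

        with h5py.File(path, "r") as h5:
            landmarks = h5["landmarks"][...]
            grid = tuple(h5.attrs["grid"]) if "grid" in h5.attrs else None
            cov = None
            if "covariates" in h5:
                cols = {}
                for name, ds in h5["covariates"].items():
                    vals = ds[...]
                    if vals.dtype.kind == "S":
                        vals = vals.astype(str)
                    cols[name] = vals
                cov = pd.DataFrame(cols)
        return cls(landmarks, cov, grid)


def quaternion_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation taking centred ``source`` onto centred ``target``.

    Horn's closed-form quaternion solution: the rotation is the unit
    eigenvector of the 4x4 cross-covariance matrix N with largest eigenvalue.
    The result always has determinant +1 (no reflection).
    """
    a = np.asarray(source, dtype=np.float64)
    b = np.asarray(target, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(n)
    w, x, y, z = vecs[:, np.argmax(vals)]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class ProcrustesAligner(BaseEstimator, TransformerMixin):
    """Generalized Procrustes alignment without scaling.

    fit() iterates: every shape is centred at the origin and rotated onto
    the current reference by the quaternion solution; the reference for the
    first iteration is training shape ``reference_index`` and afterwards the
    evolving mean, until the mean moves less than ``tol`` (RMS, mm).
    transform() maps new shapes into the fitted mean's frame.
    """

    def __init__(
        self, max_iter: int = 20, tol: float = 1e-7, reference_index: int = 0
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.reference_index = reference_index

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] % 3:
            raise ValueError("X must be (n_shapes, 3n)")
        pts = matrix_to_points(X)
        spread = pts.std(axis=(1, 2))
        if np.any(spread <= 0):
            raise ValueError("degenerate shape: all landmarks coincide")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        pts = matrix_to_points(X)
        pts = pts - pts.mean(axis=1, keepdims=True)
        n_s = len(pts)
        if not 0 <= self.reference_index < n_s:
            raise ValueError("reference_index out of range")
        ref = pts[self.reference_index].copy()
        n_iter = 0
        for it in range(self.max_iter):
            for i in range(n_s):
                r = quaternion_rotation(pts[i], ref)
                pts[i] = pts[i] @ r.T
            new_ref = pts.mean(axis=0)
            n_iter = it + 1
            shift = np.sqrt(np.mean((new_ref - ref) ** 2)) if it else np.inf
            ref = new_ref
            if shift < self.tol:
                break
        self.mean_points_ = ref
        self.aligned_ = shapes_to_matrix(pts)
        self.n_iter_ = n_iter
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_points_")
        X = self._validate(X)
        pts = matrix_to_points(X)
        pts = pts - pts.mean(axis=1, keepdims=True)
        for i in range(len(pts)):
            r = quaternion_rotation(pts[i], self.mean_points_)
            pts[i] = pts[i] @ r.T
        return shapes_to_matrix(pts)

    def fit_transform(self, X, y=None):
        return self.fit(X).aligned_


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA shape model: x ~= mean + P b.

    Fitted attributes: ``mean_`` (3n,), ``components_`` (m, 3n) with
    orthonormal rows (the shape modes P^T), ``variances_`` (m,) the mode
    variances lambda_i in mm^2, descending.  Modes with variance below
    ``rank_tol`` times the leading one are dropped.  transform() projects
    shapes to mode coefficients b = P^T (x - mean) (never clamped);
    inverse_transform() synthesizes shapes, clamping each b_i to
    +-``clamp_sd`` sqrt(lambda_i) when ``clamp`` is enabled.
    """

    def __init__(
        self, clamp: bool = True, clamp_sd: float = 3.0, rank_tol: float = 1e-12
    ):
        self.clamp = clamp
        self.clamp_sd = clamp_sd
        self.rank_tol = rank_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_shapes, 3n)")
        n_s = X.shape[0]
        if n_s < 2:
            raise ValueError("need at least two shapes")
        self.mean_ = X.mean(axis=0)
        xc = X - self.mean_
        # thin SVD of the centred data matrix == eigen-decomposition of the
        # sample covariance (1/(n_s - 1) normalization)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        variances = s**2 / (n_s - 1)
        keep = variances > self.rank_tol * max(variances[0], 1e-300)
        keep &= np.arange(len(variances)) < n_s - 1
        self.components_ = vt[keep]
        self.variances_ = variances[keep]
        self.n_shapes_ = n_s
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def n_modes_(self) -> int:
        check_is_fitted(self, "variances_")
        return len(self.variances_)

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("shape vector length mismatch")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, B):
        check_is_fitted(self, "mean_")
        B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        if B.shape[1] > self.n_modes_:
            raise ValueError("more coefficients than modes")
        b_full = np.zeros((B.shape[0], self.n_modes_))
        b_full[:, : B.shape[1]] = B
        if self.clamp:
            lim = self.clamp_sd * np.sqrt(self.variances_)
            b_full = np.clip(b_full, -lim, lim)
        return self.mean_ + b_full @ self.components_

    def synthesize(self, b, clamp: bool | None = None):
        """Shape vector for coefficients ``b``; returns (x, clamped_indices)."""
        check_is_fitted(self, "mean_")
        b = np.asarray(b, dtype=np.float64).ravel()
        if len(b) > self.n_modes_:
            raise ValueError("more coefficients than modes")
        use_clamp = self.clamp if clamp is None else clamp
        b_full = np.zeros(self.n_modes_)
        b_full[: len(b)] = b
        clamped: list[int] = []
        if use_clamp:
            lim = self.clamp_sd * np.sqrt(self.variances_)
            clamped = np.flatnonzero(np.abs(b_full) > lim).tolist()
            b_full = np.clip(b_full, -lim, lim)
        return self.mean_ + b_full @ self.components_, clamped

    def compactness(self, threshold: float = 0.95):
        """Normalized cumulative variance curve and the mode count reaching
        ``threshold``."""
        check_is_fitted(self, "variances_")
        total = self.variances_.sum()
        if total <= 0:
            raise ValueError("all-zero eigenvalue spectrum")
        curve = np.cumsum(self.variances_) / total
        m_star = int(np.searchsorted(curve, threshold - 1e-12) + 1)
        return curve, min(m_star, len(curve))

    def to_hdf5(self, path, extra_attrs: dict | None = None) -> None:
        import h5py

        check_is_fitted(self, "mean_")
        with h5py.File(path, "w") as h5:
            h5.create_dataset("mean", data=self.mean_)
            h5.create_dataset("modes", data=self.components_)
            h5.create_dataset("variances", data=self.variances_)
            h5.attrs["n_shapes"] = self.n_shapes_
            h5.attrs["clamp"] = self.clamp
            h5.attrs["clamp_sd"] = self.clamp_sd
            for k, v in (extra_attrs or {}).items():
                h5.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "PointDistributionModel":
        import h5py

        with h5py.File(path, "r") as h5:
            model = cls(
                clamp=bool(h5.attrs.get("clamp", True)),
                clamp_sd=float(h5.attrs.get("clamp_sd", 3.0)),
            )
            model.mean_ = h5["mean"][...]
            model.components_ = h5["modes"][...]
            model.variances_ = h5["variances"][...]
            model.n_shapes_ = int(h5.attrs["n_shapes"])
            model.n_features_in_ = len(model.mean_)
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers


def procrustes_align(
    pop: CorrespondedPopulation, max_iter: int = 20, tol: float = 1e-7
) -> CorrespondedPopulation:
    aligner = ProcrustesAligner(max_iter=max_iter, tol=tol)
    aligned = aligner.fit_transform(pop.matrix())
    return CorrespondedPopulation(matrix_to_points(aligned), pop.covariates, pop.grid)


def build_model(pop: CorrespondedPopulation, **kwargs) -> PointDistributionModel:
    return PointDistributionModel(**kwargs).fit(pop.matrix())


def synthesize(model: PointDistributionModel, b, clamp: bool | None = None):
    x, _clamped = model.synthesize(b, clamp=clamp)
    return x


def project(model: PointDistributionModel, x) -> np.ndarray:
    return model.transform(np.atleast_2d(x))[0]


def compactness(model: PointDistributionModel, threshold: float = 0.95):
    return model.compactness(threshold)
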