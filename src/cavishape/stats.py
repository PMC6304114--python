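"""Statistics relating shape-mode coefficients to covariates.

Per mode i, the coefficient b_i is regressed on age with a guarded pipeline:
ordinary least squares first; if the residuals fail a normality test the
response is Box-Cox transformed (after a positivity shift) and refit;
influential points are flagged by Cook's distance and, when present, the
inference is taken from a robust (Huber M-estimation) refit.  Sex groups are
compared per mode with a two-sample t-test, or a Wilcoxon rank-sum test when
either group fails normality.  Significant per-mode effects are finally
turned into a per-landmark Euclidean difference map through the shape model,
x_diff = |P b_diff| evaluated landmark-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "boxcox",
    "inverse_boxcox",
    "ModeRegressionResult",
    "fit_mode_regression",
    "GroupComparisonResult",
    "compare_groups",
    "DifferenceMap",
    "difference_shape",
    "age_difference_map",
    "group_difference_map",
]


def boxcox(x, lambda_bc="fit", search: tuple[float, float] = (-3.0, 3.0)):
    """Box-Cox power transform toward normality.

    Xt = (Xo^lambda - 1) / lambda for lambda != 0, log(Xo) for lambda = 0.
    With ``lambda_bc="fit"`` the exponent maximizing the profile
    log-likelihood over ``search`` is used.  Returns (transformed, lambda).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data; shift first")
    if isinstance(lambda_bc, str):
        if lambda_bc != "fit":
            raise ValueError("lambda_bc must be a number or 'fit'")
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda lam: -sps.boxcox_llf(lam, x),
            bounds=search,
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x)
    else:
        lam = float(lambda_bc)
    if lam == 0.0:
        return np.log(x), lam
    return (x**lam - 1.0) / lam, lam


def inverse_boxcox(y, lam: float):
    """Invert the Box-Cox transform (the lambda != 0 branch is clipped to
    its domain)."""
    y = np.asarray(y, dtype=np.float64)
    if lam == 0.0:
        return np.exp(y)
    base = np.maximum(lam * y + 1.0, 1e-12)
    return base ** (1.0 / lam)


@dataclass
class ModeRegressionResult:
    """Linear fit of one mode coefficient on age, with transform/robust flags.

    slope and intercept are in (possibly transformed) response units per
    year; ``predict`` maps ages back to the original b_i scale, inverting
    the Box-Cox transform and the positivity shift when they were applied.
    """

    mode: int
    slope: float
    intercept: float
    p_value: float
    alpha: float
    boxcox_lambda: float | None = None
    shift: float = 0.0
    robust_used: bool = False
    outlier_indices: list = field(default_factory=list)
    normality_p: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=np.float64)
        yhat = self.intercept + self.slope * age
        if self.boxcox_lambda is not None:
            yhat = inverse_boxcox(yhat, self.boxcox_lambda)
        return yhat - self.shift


def fit_mode_regression(
    b_values,
    age,
    alpha: float = 0.05,
    mode: int = 0,
    normality_alpha: float = 0.05,
    cooks_threshold: float | None = None,
) -> ModeRegressionResult:
    """Regression pipeline for one shape mode against age.

    OLS -> Shapiro-Wilk on residuals -> (if rejected) Box-Cox of the shifted
    response and refit -> Cook's distance (threshold 4/n unless given) ->
    (if any influential point) Huber robust refit whose t-statistic supplies
    the p-value.
    """
    import statsmodels.api as sm

    b = np.asarray(b_values, dtype=np.float64)
    age = np.asarray(age, dtype=np.float64)
    if b.shape != age.shape or b.ndim != 1:
        raise ValueError("b_values and age must be matching 1D arrays")
    n = len(b)
    if n < 8:
        raise ValueError("need at least 8 subjects for the regression pipeline")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; regression undefined")
    if cooks_threshold is None:
        cooks_threshold = 4.0 / n

    exog = sm.add_constant(age)
    y = b.copy()
    shift = 0.0
    bc_lambda: float | None = None

    ols = sm.OLS(y, exog).fit()
    norm_p = float(sps.shapiro(ols.resid).pvalue)
    if norm_p < normality_alpha:
        # shift to positivity, then transform; margin keeps the minimum away
        # from the singular point of the power transform
        shift = -y.min() + 0.05 * max(np.ptp(y), 1e-12)
        y_t, bc_lambda = boxcox(y + shift, "fit")
        ols = sm.OLS(y_t, exog).fit()
        y = y_t

    cooks = ols.get_influence().cooks_distance[0]
    outliers = np.flatnonzero(cooks > cooks_threshold).tolist()
    robust_used = False
    if outliers:
        rlm = sm.RLM(y, exog, M=sm.robust.norms.HuberT()).fit()
        # inference from the robust fit's t-statistic, n - 2 df
        t_stat = float(rlm.tvalues[1])
        p_value = float(2.0 * sps.t.sf(abs(t_stat), df=n - 2))
        slope = float(rlm.params[1])
        intercept = float(rlm.params[0])
        robust_used = True
    else:
        p_value = float(ols.pvalues[1])
        slope = float(ols.params[1])
        intercept = float(ols.params[0])

    return ModeRegressionResult(
        mode=mode,
        slope=slope,
        intercept=intercept,
        p_value=p_value,
        alpha=alpha,
        boxcox_lambda=bc_lambda,
        shift=shift,
        robust_used=robust_used,
        outlier_indices=outliers,
        normality_p=norm_p,
    )


@dataclass
class GroupComparisonResult:
    mode: int
    p_value: float
    test_used: str  # "t" or "wilcoxon"
    alpha: float
    mean_a: float
    mean_b: float

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def compare_groups(
    b_values,
    group,
    alpha: float = 0.05,
    mode: int = 0,
    normality_alpha: float = 0.05,
) -> GroupComparisonResult:
    """Two-sample comparison of mode coefficients between binary groups.

    Both groups are Shapiro-Wilk tested; a two-sample t-test is used when
    both pass, otherwise the Wilcoxon rank-sum test.
    """
    b = np.asarray(b_values, dtype=np.float64)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("group must be binary")
    a = b[group == labels[0]]
    c = b[group == labels[1]]
    if len(a) < 3 or len(c) < 3:
        raise ValueError("each group needs at least 3 members")

    def normal(x):
        if np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue >= normality_alpha

    if normal(a) and normal(c):
        stat = sps.ttest_ind(a, c)
        test_used, p = "t", float(stat.pvalue)
        if np.isnan(p):  # zero variance in both groups, identical means
            p = 1.0
    else:
        stat = sps.ranksums(a, c)
        test_used, p = "wilcoxon", float(stat.pvalue)
    return GroupComparisonResult(
        mode=mode,
        p_value=p,
        test_used=test_used,
        alpha=alpha,
        mean_a=float(a.mean()),
        mean_b=float(c.mean()),
    )


@dataclass
class DifferenceMap:
    """Mode-space difference and its per-landmark Euclidean magnitude (mm)."""

    b_diff: np.ndarray
    x_diff: np.ndarray  # (n_landmarks,) displacement magnitudes


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """False-discovery-rate control across the per-mode tests.

    Off by default in the pipeline (each mode is tested at its own level);
    callers who prefer FDR control can re-threshold with the returned
    boolean mask.
    """
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(p_values, dtype=float),
                               alpha=alpha, method="fdr_bh")
    return reject


def difference_shape(model, b_diff, significant_mask=None) -> DifferenceMap:
    """Per-landmark Euclidean magnitude of the shape change P b_diff.

    Non-significant modes contribute exactly zero: their entries are zeroed
    before synthesis.
    """
    from .model import matrix_to_points

    b = np.zeros(model.n_modes_)
    b_diff = np.asarray(b_diff, dtype=np.float64).ravel()
    b[: len(b_diff)] = b_diff
    if significant_mask is not None:
        mask = np.zeros(model.n_modes_, dtype=bool)
        m = np.asarray(significant_mask, dtype=bool).ravel()
        mask[: len(m)] = m
        b = np.where(mask, b, 0.0)
    disp = b @ model.components_  # (3n,)
    pts = matrix_to_points(disp)
    return DifferenceMap(b_diff=b, x_diff=np.linalg.norm(pts, axis=1))


def age_difference_map(
    model, results: list[ModeRegressionResult], age_a: float, age_b: float,
    observed_range: tuple[float, float] | None = None,
) -> DifferenceMap:
    """Difference map between two ages from per-mode regressions.

    For significant modes b_diff_i = b_hat_i(age_b) - b_hat_i(age_a)
    (back-transformed when Box-Cox was applied); other modes are zero.
    Requesting ages outside the observed range only warns (extrapolation).
    """
    if observed_range is not None:
        lo, hi = observed_range
        if not (lo <= age_a <= hi and lo <= age_b <= hi):
            import warnings

            warnings.warn(
                "difference map evaluated outside the observed age range",
                stacklevel=2,
            )
    b_diff = np.zeros(model.n_modes_)
    mask = np.zeros(model.n_modes_, dtype=bool)
    for r in results:
        if r.mode >= model.n_modes_:
            raise ValueError(f"mode {r.mode} not present in the model")
        if r.significant:
            b_diff[r.mode] = float(r.predict(age_b) - r.predict(age_a))
            mask[r.mode] = True
    return difference_shape(model, b_diff, mask)


def group_difference_map(
    model, results: list[GroupComparisonResult]
) -> DifferenceMap:
    """Difference map between group means for significant modes."""
    b_diff = np.zeros(model.n_modes_)
    mask = np.zeros(model.n_modes_, dtype=bool)
    for r in results:
        if r.mode >= model.n_modes_:
            raise ValueError(f"mode {r.mode} not present in the model")
        if r.significant:
            b_diff[r.mode] = r.mean_b - r.mean_a
            mask[r.mode] = True
    return difference_shape(model, b_diff, mask)
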