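"""Grouped fused LASSO attribution of loss anomalies to monthly drivers.

The linear anomaly model expresses the loss anomaly of cohort k in year Y as

    delta_{k,Y} = a0 + sum_F sum_i a_i^F x_{Y,i}^F

where F ranges over candidate environmental factors (chlorophyll C,
temperature T, ice cover I, SAM S by default) and i over the 16 months from
September of year Y-1 through December of year Y; all predictors are
standardized. The objective adds an L1 penalty on the coefficients and a
quadratic "fusion" penalty on differences between adjacent months within the
same factor block:

    J = (1/2m) sum_Y [delta_Y - h(X_Y)]^2 + lambda sum |a_j|
        + tau_fuse sum_F sum_i (a_i^F - a_{i-1}^F)^2

yielding sparse, month-smooth coefficient runs. Hyperparameters come from
K-fold cross-validation; model choice over the 15 non-empty factor subsets
uses lowest CV error with a 2% near-tie rule favoring fewer factors.

Note the fusion hyperparameter is named tau_fuse throughout: tau also names
the transition-window duration of the population model, and the two are
unrelated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import envstats
from ._kernels import fista_fused_lasso
from .errors import ConfigurationError, InputError

__all__ = [
    "DEFAULT_FACTORS",
    "FactorDesign",
    "FusedLassoModel",
    "CVResult",
    "SubsetSelection",
    "build_design",
    "fused_lasso_objective",
    "fit",
    "cross_validate",
    "subset_model_selection",
    "factor_importance",
    "bootstrap_bands",
    "predict_and_score",
    "default_lambda_grid",
    "default_tau_grid",
]

DEFAULT_FACTORS = ("Chl", "T", "Ice", "SAM")


def default_lambda_grid(n: int = 12) -> np.ndarray:
    return np.logspace(-4, 1, n)


def default_tau_grid(n: int = 12) -> np.ndarray:
    return np.logspace(-4, 1, n)


@dataclass
class FactorDesign:
    """Standardized response/predictor blocks for the anomaly regression.

    X holds contiguous month-ordered blocks, one per factor; ``means`` and
    ``sds`` are the per-column standardization parameters estimated on the
    training years (applied to any future rows).
    """

    X: np.ndarray  # (m, p) standardized predictors
    y: np.ndarray  # (m,) anomalies
    years: np.ndarray  # calendar year per row
    factors: tuple  # factor per block, in column order
    offsets: tuple  # month offsets within each block
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        m, p = self.X.shape
        if p != len(self.factors) * len(self.offsets):
            raise ConfigurationError("design width does not match blocks x months")
        if len(self.y) != m:
            raise ConfigurationError("response length does not match design rows")

    @property
    def n_months(self) -> int:
        return len(self.offsets)

    @property
    def block_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.n_months
        starts = np.arange(len(self.factors), dtype=np.int64) * k
        return starts, starts + k

    def column_labels(self) -> list[tuple[str, int]]:
        return [(f, o) for f in self.factors for o in self.offsets]

    def subset(self, factors) -> "FactorDesign":
        """Restrict to a factor subset (columns for excluded factors dropped)."""
        factors = tuple(factors)
        missing = set(factors) - set(self.factors)
        if missing:
            raise InputError(f"unknown factors {sorted(missing)}")
        k = self.n_months
        cols = np.concatenate(
            [np.arange(self.factors.index(f) * k, (self.factors.index(f) + 1) * k)
             for f in factors]
        )
        return FactorDesign(
            X=self.X[:, cols], y=self.y, years=self.years, factors=factors,
            offsets=self.offsets, means=self.means[cols], sds=self.sds[cols],
        )


def build_design(
    anomaly_values: np.ndarray,
    years: np.ndarray,
    env: pd.DataFrame,
    factors=DEFAULT_FACTORS,
    offsets=envstats.MONTH_OFFSETS,
) -> FactorDesign:
    """Assemble the standardized 16-month-per-factor design for one anomaly set.

    Climate-index factors enter as 9-month trailing moving averages (shared
    alignment with the correlation screen); columns are standardized to zero
    mean, unit variance over the supplied years.
    """
    years = np.asarray(years, dtype=int)
    y = np.asarray(anomaly_values, dtype=float)
    if len(y) != len(years):
        raise ConfigurationError("anomaly values and years differ in length")
    blocks = []
    for f in factors:
        mat = envstats.factor_month_matrix(env, f, years, offsets)
        if np.isnan(mat).any():
            raise InputError(f"environment does not cover all design months for {f!r}")
        blocks.append(mat)
    X = np.hstack(blocks)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    X = (X - means) / sds
    return FactorDesign(
        X=X, y=y, years=years, factors=tuple(factors), offsets=tuple(offsets),
        means=means, sds=sds,
    )


@dataclass
class FusedLassoModel:
    """A fitted grouped fused LASSO model for one anomaly set."""

    intercept: float
    coef: np.ndarray  # concatenated blocks, order = design.column_labels()
    factors: tuple
    offsets: tuple
    lambda_l1: float
    tau_fuse: float
    means: np.ndarray
    sds: np.ndarray
    cv_error: float | None = None
    r2: float | None = None
    objective: float | None = None
    n_iter: int = 0

    def coef_frame(self) -> pd.DataFrame:
        labels = [(f, o) for f in self.factors for o in self.offsets]
        return pd.DataFrame(
            {
                "factor": [f for f, _ in labels],
                "month_offset": [o for _, o in labels],
                "month_label": envstats.month_offset_labels(
                    [o for _, o in labels]
                ),
                "coefficient": self.coef,
            }
        )

    def block_coef(self, factor: str) -> np.ndarray:
        i = self.factors.index(factor)
        k = len(self.offsets)
        return self.coef[i * k : (i + 1) * k]


def fused_lasso_objective(
    intercept: float,
    coef: np.ndarray,
    design: FactorDesign,
    lambda_l1: float,
    tau_fuse: float,
) -> float:
    """J = (1/2m)||y - a0 - X a||^2 + lambda sum|a| + tau_fuse * fusion term.

    The fusion term sums squared differences of adjacent coefficients within
    each factor block only; the intercept is unpenalized.
    """
    coef = np.asarray(coef, dtype=float)
    m = len(design.y)
    resid = design.y - intercept - design.X @ coef
    J = 0.5 * float(resid @ resid) / m + lambda_l1 * float(np.sum(np.abs(coef)))
    starts, ends = design.block_bounds
    for s, e in zip(starts, ends):
        d = np.diff(coef[s:e])
        J += tau_fuse * float(d @ d)
    return J


def fit(
    design: FactorDesign,
    lambda_l1: float,
    tau_fuse: float,
    max_iter: int = 100000,
    tol: float = 1e-12,
    warm_start: FusedLassoModel | None = None,
) -> FusedLassoModel:
    """Minimize the fused LASSO objective by accelerated proximal gradient.

    The quadratic fusion term folds into the smooth gradient; the L1 term is
    handled by soft-thresholding, so exact zeros are attainable.
    ``warm_start`` (a model of identical width, e.g. from a neighboring grid
    point) only changes the starting iterate, not the minimizer.
    """
    if len(design.y) < 3:
        raise InputError("need at least 3 training rows")
    starts, ends = design.block_bounds
    if warm_start is not None and len(warm_start.coef) == design.X.shape[1]:
        a0_init, a_init = float(warm_start.intercept), np.asarray(warm_start.coef, float)
    else:
        a0_init, a_init = 0.0, np.zeros(design.X.shape[1])
    a0, a, J, n_iter = fista_fused_lasso(
        np.ascontiguousarray(design.X, dtype=np.float64),
        np.ascontiguousarray(design.y, dtype=np.float64),
        float(lambda_l1), float(tau_fuse), starts, ends, int(max_iter), float(tol),
        a0_init, a_init,
    )
    yhat = a0 + design.X @ a
    sst = float(np.sum((design.y - design.y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((design.y - yhat) ** 2)) / sst if sst > 0 else np.nan
    return FusedLassoModel(
        intercept=float(a0), coef=np.asarray(a), factors=design.factors,
        offsets=design.offsets, lambda_l1=float(lambda_l1),
        tau_fuse=float(tau_fuse), means=design.means, sds=design.sds,
        r2=r2, objective=float(J), n_iter=int(n_iter),
    )


def _fold_indices(m: int, K: int, seed: int, shuffle: bool) -> list[np.ndarray]:
    idx = np.arange(m)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(m)
    # contiguous-in-time blocks by default: years are autocorrelated
    return [np.sort(part) for part in np.array_split(idx, K)]


@dataclass
class CVResult:
    lambda0: float
    tau0: float
    cv_error: float
    surface: pd.DataFrame  # columns lambda_l1, tau_fuse, cv_error
    no_signal: bool  # CV error decreases monotonically with lambda


def cross_validate(
    design: FactorDesign,
    lambda_grid=None,
    tau_grid=None,
    K: int = 9,
    seed: int = 0,
    shuffle: bool = False,
) -> CVResult:
    """K-fold CV over the (lambda, tau_fuse) grid; returns the argmin.

    Folds are contiguous year blocks by default (``shuffle=True`` draws a
    seeded permutation instead). The ``no_signal`` flag is a diagnostic for
    an unpredictable response: when no linear combination of the predictors
    beats the mean, the CV error keeps decreasing as lambda increases, so the
    most-shrunk end of the lambda profile (minimized over tau) is as good as
    any grid point.
    """
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    m = len(design.y)
    if K < 2 or K > m:
        raise ConfigurationError("need 2 <= K <= number of rows")
    folds = _fold_indices(m, K, seed, shuffle)
    for f in folds:
        if len(f) < 1:
            raise ConfigurationError("empty cross-validation fold")
    errs = np.zeros((len(lambda_grid), len(tau_grid)))
    # folds outer, grid inner: neighboring grid points share warm starts
    for hold in folds:
        train = np.setdiff1d(np.arange(m), hold)
        sub = FactorDesign(
            X=design.X[train], y=design.y[train], years=design.years[train],
            factors=design.factors, offsets=design.offsets,
            means=design.means, sds=design.sds,
        )
        warm = None
        for li, lam in enumerate(lambda_grid):
            for ti, tau in enumerate(tau_grid):
                warm = fit(sub, lam, tau, tol=1e-10, warm_start=warm)
                pred = warm.intercept + design.X[hold] @ warm.coef
                errs[li, ti] += float(np.mean((design.y[hold] - pred) ** 2)) / K
    rows = [
        {"lambda_l1": lam, "tau_fuse": tau, "cv_error": errs[li, ti]}
        for li, lam in enumerate(lambda_grid)
        for ti, tau in enumerate(tau_grid)
    ]
    li, ti = np.unravel_index(np.argmin(errs), errs.shape)
    profile = errs.min(axis=1)
    # no-signal diagnostic: the CV error keeps improving with shrinkage, so
    # the fully shrunk (largest-lambda, intercept-only) end of the profile is
    # essentially as good as the best grid point (5% plateau tolerance)
    no_signal = bool(profile[-1] <= profile.min() * 1.05)
    return CVResult(
        lambda0=float(lambda_grid[li]), tau0=float(tau_grid[ti]),
        cv_error=float(errs[li, ti]), surface=pd.DataFrame(rows),
        no_signal=no_signal,
    )


@dataclass
class SubsetSelection:
    selected: FusedLassoModel
    selected_factors: tuple
    report: pd.DataFrame  # (subset, n_factors, cv_error, lambda0, tau0)
    models: dict = field(default_factory=dict)  # subset tuple -> FusedLassoModel


def subset_model_selection(
    design: FactorDesign,
    K: int = 9,
    lambda_grid=None,
    tau_grid=None,
    seed: int = 0,
    tie_tolerance: float = 0.02,
) -> SubsetSelection:
    """Fit all 2^F - 1 factor subsets with per-subset CV and select one.

    The subset with the lowest CV error wins; subsets whose CV error is
    within ``tie_tolerance`` (relative) of the minimum are near-ties, broken
    toward the fewest factors (then lowest CV error). Each selected subset's
    model is refit on all rows at its CV-chosen hyperparameters.
    """
    subsets = [
        tuple(c)
        for r in range(1, len(design.factors) + 1)
        for c in itertools.combinations(design.factors, r)
    ]
    rows, models = [], {}
    for sub_factors in subsets:
        sub = design.subset(sub_factors)
        cv = cross_validate(sub, lambda_grid, tau_grid, K=K, seed=seed)
        mod = fit(sub, cv.lambda0, cv.tau0)
        mod.cv_error = cv.cv_error
        models[sub_factors] = mod
        rows.append(
            {
                "subset": "+".join(sub_factors),
                "n_factors": len(sub_factors),
                "cv_error": cv.cv_error,
                "lambda0": cv.lambda0,
                "tau0": cv.tau0,
            }
        )
    report = pd.DataFrame(rows)
    best_err = report["cv_error"].min()
    near = report[report["cv_error"] <= best_err * (1.0 + tie_tolerance)]
    pick = near.sort_values(["n_factors", "cv_error"]).iloc[0]
    selected_factors = subsets[int(pick.name)]
    return SubsetSelection(
        selected=models[selected_factors],
        selected_factors=selected_factors,
        report=report,
        models=models,
    )


def factor_importance(models: dict, factors=DEFAULT_FACTORS) -> pd.Series:
    """Mean |coefficient| of each factor across the whole subset ensemble.

    importance(F) = sum over all models of sum_i |a_i^F|, divided by
    (number of models x months per factor); models not containing F
    contribute zero, so rarely selected or always-shrunk factors score low.
    """
    n_models = len(models)
    out = {}
    for f in factors:
        total = 0.0
        k = None
        for sub_factors, mod in models.items():
            k = len(mod.offsets)
            if f in sub_factors:
                total += float(np.sum(np.abs(mod.block_coef(f))))
        out[f] = total / (n_models * k)
    return pd.Series(out, name="importance")


def bootstrap_bands(
    design: FactorDesign,
    lambda_l1: float,
    tau_fuse: float,
    B: int = 500,
    level: float = 0.90,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap confidence bands for the coefficient runs.

    Years (rows) are resampled with replacement B times and the model refit
    at fixed hyperparameters; bands are the (1-level)/2 and (1+level)/2
    percentiles per coefficient. Degenerate resamples (a single distinct
    year) are redrawn.
    """
    if B < 200:
        raise InputError("need at least 200 bootstrap resamples")
    rng = np.random.default_rng(seed)
    m = len(design.y)
    coefs = np.empty((B, design.X.shape[1]))
    intercepts = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, m, m)
            if len(np.unique(design.years[idx])) > 1:
                break
        sub = FactorDesign(
            X=design.X[idx], y=design.y[idx], years=design.years[idx],
            factors=design.factors, offsets=design.offsets,
            means=design.means, sds=design.sds,
        )
        mod = fit(sub, lambda_l1, tau_fuse)
        coefs[b] = mod.coef
        intercepts[b] = mod.intercept
    lo_q, hi_q = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    point = fit(design, lambda_l1, tau_fuse)
    out = point.coef_frame()
    out["ci_low"] = np.percentile(coefs, lo_q, axis=0)
    out["ci_high"] = np.percentile(coefs, hi_q, axis=0)
    return out


def predict_and_score(
    model: FusedLassoModel, X_raw: np.ndarray, y: np.ndarray | None = None
):
    """Predict anomalies for raw (unstandardized) design rows.

    Rows must follow the model's column order (its factors x month offsets);
    they are standardized with the training means/sds. Returns predictions,
    or (predictions, R^2) when true anomalies ``y`` are supplied.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if X_raw.shape[1] != len(model.coef):
        raise InputError(
            f"expected {len(model.coef)} columns "
            f"({len(model.factors)} factors x {len(model.offsets)} months), "
            f"got {X_raw.shape[1]}"
        )
    Xs = (X_raw - model.means) / model.sds
    pred = model.intercept + Xs @ model.coef
    if y is None:
        return pred
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return pred, r2


def design_raw_matrix(design: FactorDesign) -> np.ndarray:
    """Recover the raw (unstandardized) predictor matrix of a design."""
    return design.X * design.sds + design.means
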