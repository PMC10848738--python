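"""Annual loss anomalies: schedule, cost functions, fitting, significance.

A loss anomaly delta_{k,Y} is a log-scale deviation of the background
mortality of cohort k in year Y: m'_k = m_k exp(delta_{k,Y}). The larval
anomaly of year Y acts from 1 November of year Y-1 through 31 October of
year Y; the juvenile anomaly from 1 August of year Y-1 through 31 July of
year Y, aligning each anomaly with the lifespan of the cohort that spent
most of its life in year Y. Adult mortality is never modulated.

Fitting minimizes a log-scale weighted least-squares data term plus a ridge
penalty on the anomalies (an inverse problem regularized toward "no
anomaly"), using restart cycles of a bounded quasi-Newton search; the
scatter of near-optimal cycles doubles as a confidence region for the
sign-consistency significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import model as mc
from .errors import ConfigurationError, InputError

__all__ = [
    "AnomalySeries",
    "CostConfig",
    "FitResult",
    "LAMBDA_REG_GRID",
    "FITTED_PARAM_NAMES",
    "mortality_at",
    "timeconstant_cost",
    "anomaly_cost",
    "fit_timeconstant",
    "fit_anomalies",
    "classify_significance",
]

#: regularization grid for the anomaly ridge penalty
LAMBDA_REG_GRID = (0.001, 0.003, 0.01, 0.03, 0.1)

#: standard parameters (and initial conditions) adjusted by the
#: time-constant fit; gamma, r, tau_window, m_exp stay at their preset values
FITTED_PARAM_NAMES = ("L_max", "G_max", "m_L", "m_J", "m_A", "L0", "J0", "A0")

SIGNIFICANT = "significant"
NONSIGNIFICANT = "nonsignificant"
NOT_ASSESSED = "not-assessed"


@dataclass
class AnomalySeries:
    """Per-year larval and juvenile loss anomalies (model-year indices)."""

    years: np.ndarray
    delta_L: np.ndarray
    delta_J: np.ndarray
    sig_L: np.ndarray | None = None
    sig_J: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.delta_L = np.asarray(self.delta_L, dtype=float)
        self.delta_J = np.asarray(self.delta_J, dtype=float)
        if not (len(self.years) == len(self.delta_L) == len(self.delta_J)):
            raise ConfigurationError("anomaly arrays must have equal length")
        if len(np.unique(self.years)) != len(self.years):
            raise ConfigurationError(
                "duplicate anomaly years would make application windows overlap"
            )

    def __len__(self) -> int:
        return len(self.years)

    @classmethod
    def zeros(cls, n_years: int) -> "AnomalySeries":
        return cls(np.arange(n_years), np.zeros(n_years), np.zeros(n_years))

    def permuted(self, rng: np.random.Generator) -> "AnomalySeries":
        """Jointly shuffle the year order of (delta_L, delta_J)."""
        order = rng.permutation(len(self.years))
        return AnomalySeries(self.years.copy(), self.delta_L[order], self.delta_J[order])

    def to_frame(self, start_year: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "year": self.years + start_year,
                "delta_L": self.delta_L,
                "delta_L_significant": (
                    self.sig_L if self.sig_L is not None else [NOT_ASSESSED] * len(self)
                ),
                "delta_J": self.delta_J,
                "delta_J_significant": (
                    self.sig_J if self.sig_J is not None else [NOT_ASSESSED] * len(self)
                ),
            }
        )
        return df

    def to_csv(self, path, start_year: int = 0) -> None:
        self.to_frame(start_year).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, start_year: int = 0) -> "AnomalySeries":
        out = cls(
            df["year"].to_numpy() - start_year,
            df["delta_L"].to_numpy(),
            df["delta_J"].to_numpy(),
        )
        if "delta_L_significant" in df:
            out.sig_L = df["delta_L_significant"].to_numpy()
            out.sig_J = df["delta_J_significant"].to_numpy()
        return out


@dataclass
class CostConfig:
    """Weights, regularization constants and priors for the two cost functions.

    alpha_* weight the squared log-residuals of each cohort so that all three
    contribute comparably; lambda_prior penalizes relative deviations of the
    fitted standard parameters from their priors; lambda_reg is the ridge
    constant on the annual anomalies.
    """

    alpha_L: float = 2.0 / 3.0
    alpha_J: float = 1.0
    alpha_A: float = 2.0
    lambda_prior: float = 0.01
    lambda_reg: float = 0.01
    priors: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("alpha_L", "alpha_J", "alpha_A"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.lambda_prior < 0 or self.lambda_reg < 0:
            raise ConfigurationError("regularization constants must be >= 0")


@dataclass
class FitResult:
    params: mc.ModelParams | None
    anomalies: AnomalySeries | None
    cost: float
    cycle_solutions: np.ndarray  # (n_cycles, dim)
    cycle_costs: np.ndarray
    best_cycle: int
    retained: np.ndarray  # bool mask: cycles within 2% of the best cost
    n_evaluations: int = 0


def mortality_at(t, cohort: str, base_mortality: float, anomalies: AnomalySeries | None):
    """Mortality rate of cohort "L" or "J" at time t under an anomaly series.

    Windows of consecutive years tile the time axis without overlap, so each
    t falls in exactly one anomaly year; outside the listed years (or with
    ``anomalies=None``) the base rate applies.
    """
    if cohort == "L":
        lead = -mc.LARVAL_WINDOW_MONTHS[0] / 12.0
    elif cohort == "J":
        lead = -mc.JUVENILE_WINDOW_MONTHS[0] / 12.0
    else:
        raise InputError("cohort must be 'L' or 'J' (adult mortality is never modulated)")
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(base_mortality))
    if anomalies is not None:
        year = np.floor(t + lead).astype(int)
        deltas = anomalies.delta_L if cohort == "L" else anomalies.delta_J
        lookup = dict(zip(anomalies.years.tolist(), deltas))
        mult = np.array([np.exp(lookup.get(int(y), 0.0)) for y in np.atleast_1d(year)])
        out = out * mult.reshape(t.shape)
    return out if out.ndim else float(out)


def _validate_observations(observations: pd.DataFrame) -> pd.DataFrame:
    obs = observations.sort_values("year").reset_index(drop=True)
    for col in ("L", "J", "A"):
        bad = obs.index[obs[col] <= 0]
        if len(bad):
            raise InputError(
                f"observation {col} must be strictly positive (log is taken); "
                f"offending year index {int(bad[0])}"
            )
    return obs


def _data_term(jan1: np.ndarray, obs: np.ndarray, config: CostConfig) -> float:
    n = obs.shape[0]
    lm = np.log(np.maximum(jan1[:n], 1e-30))
    lo = np.log(obs)
    w = np.array([config.alpha_L, config.alpha_J, config.alpha_A])
    return float(np.sum(w * (lo - lm) ** 2) / n)


def _simulate_jan1(params, anomalies, years, steps_per_month):
    """1 January samples via the compiled kernel, skipping frame assembly."""
    from . import _kernels

    mul_L, mul_J = mc.monthly_multipliers(anomalies, years)
    ka = mc._kernel_args(params)
    *_, jan1 = _kernels.rk4_simulate(
        years, steps_per_month,
        ka["gamma"], ka["beta"], ka["ricker"], ka["lmax"], ka["gmax"],
        ka["r"], ka["inv_sin_half"], ka["two_m"],
        params.m_L, params.m_J, params.m_A,
        mul_L, mul_J, params.L0, params.J0, params.A0,
        years * 12 * steps_per_month,
    )
    return jan1


def timeconstant_cost(
    params: mc.ModelParams,
    observations: pd.DataFrame,
    config: CostConfig | None = None,
    steps_per_month: int = 16,
) -> float:
    """Weighted log-scale SSE against 1 January samples plus the parameter prior.

    cost = (1/n) sum_Y [aL (log L' - log L)^2 + (log J' - log J)^2
                        + aA (log A' - log A)^2]
           + lambda_prior sum_k ((theta_k - theta_k0) / theta_k0)^2
    """
    config = config or CostConfig()
    obs = _validate_observations(observations)
    n = len(obs)
    jan1 = _simulate_jan1(params, None, n, steps_per_month)
    cost = _data_term(jan1, obs[["L", "J", "A"]].to_numpy(), config)
    if config.lambda_prior > 0 and config.priors:
        for name, prior in config.priors.items():
            theta = getattr(params, name)
            cost += config.lambda_prior * ((theta - prior) / prior) ** 2
    return cost


def anomaly_cost(
    anomalies: AnomalySeries,
    initial_conditions,
    fixed_params: mc.ModelParams,
    observations: pd.DataFrame,
    config: CostConfig | None = None,
    steps_per_month: int = 16,
) -> float:
    """Data term plus the anomaly ridge penalty lambda_reg sum(dL^2 + dJ^2).

    The standard parameters stay fixed at their time-constant values; only
    the anomalies and the initial conditions are free.
    """
    config = config or CostConfig()
    obs = _validate_observations(observations)
    n = len(obs)
    if len(anomalies) != n:
        raise ConfigurationError(
            f"anomaly series has {len(anomalies)} years, observations have {n}"
        )
    L0, J0, A0 = initial_conditions
    params = fixed_params.replace(L0=float(L0), J0=float(J0), A0=float(A0))
    jan1 = _simulate_jan1(params, anomalies, n, steps_per_month)
    cost = _data_term(jan1, obs[["L", "J", "A"]].to_numpy(), config)
    cost += config.lambda_reg * float(
        np.sum(anomalies.delta_L**2) + np.sum(anomalies.delta_J**2)
    )
    return cost


def _default_priors(preset_params: mc.ModelParams) -> dict:
    return {k: getattr(preset_params, k) for k in FITTED_PARAM_NAMES}


def fit_timeconstant(
    observations: pd.DataFrame,
    preset: str = "RK",
    config: CostConfig | None = None,
    seed: int = 0,
    n_starts: int = 6,
    maxfun_per_start: int = 4000,
    steps_per_month: int = 8,
) -> FitResult:
    """Fit the eight standard parameters of the time-constant model.

    gamma, r, tau_window and m_exp are fixed by the preset ("BH" or "RK");
    (L_max, G_max, m_L, m_J, m_A, L0, J0, A0) are optimized in log space
    with multi-start bounded quasi-Newton search (box: prior / 30 ... prior
    * 30, keeping everything positive).
    """
    obs = _validate_observations(observations)
    if len(obs) < 3:
        raise InputError("need at least 3 observation years")
    base = mc.PRESETS[preset]
    config = config or CostConfig()
    if not config.priors:
        config.priors = _default_priors(base)
    prior_vec = np.array([config.priors[k] for k in FITTED_PARAM_NAMES])
    log_prior = np.log(prior_vec)
    bounds = [(lp - np.log(30.0), lp + np.log(30.0)) for lp in log_prior]
    rng = np.random.default_rng(seed)

    obs_arr = obs[["L", "J", "A"]].to_numpy()
    n = len(obs)
    n_evals = 0

    def cost_of(x):
        nonlocal n_evals
        n_evals += 1
        params = base.replace(**dict(zip(FITTED_PARAM_NAMES, np.exp(x))))
        cost = _data_term(_simulate_jan1(params, None, n, steps_per_month), obs_arr, config)
        if config.lambda_prior > 0:
            for name, prior in config.priors.items():
                theta = getattr(params, name)
                cost += config.lambda_prior * ((theta - prior) / prior) ** 2
        return cost

    sols, costs = [], []
    converged = False
    for s in range(n_starts):
        x0 = log_prior if s == 0 else log_prior + rng.normal(0.0, 0.4, len(log_prior))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            cost_of, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": maxfun_per_start},
        )
        sols.append(res.x)
        costs.append(res.fun)
        converged = converged or res.success
    if not converged:
        warnings.warn("time-constant fit did not report convergence; returning best found")
    costs = np.asarray(costs)
    best = int(np.argmin(costs))
    fitted = base.replace(**dict(zip(FITTED_PARAM_NAMES, np.exp(sols[best]))))
    retained = costs <= costs[best] * 1.02
    return FitResult(
        params=fitted, anomalies=None, cost=float(costs[best]),
        cycle_solutions=np.exp(np.asarray(sols)), cycle_costs=costs,
        best_cycle=best, retained=retained, n_evaluations=n_evals,
    )


def _unpack(x: np.ndarray, n: int) -> tuple[AnomalySeries, np.ndarray]:
    anom = AnomalySeries(np.arange(n), x[:n], x[n : 2 * n])
    ics = np.exp(x[2 * n : 2 * n + 3])
    return anom, ics


def fit_anomalies(
    observations: pd.DataFrame,
    fixed_params: mc.ModelParams,
    config: CostConfig | None = None,
    n_primary_cycles: int = 300,
    n_final_cycles: int = 300,
    evals_per_cycle: int = 30000,
    seed: int = 0,
    delta_bound: float = 3.0,
    steps_per_month: int = 8,
    significance_level: float = 0.95,
) -> FitResult:
    """Estimate the minimal annual loss anomalies for a fitted model.

    The 2n anomalies (larval and juvenile, one per observation year) plus the
    three log initial conditions are optimized against ``anomaly_cost``.
    Stage 1 runs ``n_primary_cycles`` recentered cycles: each cycle starts a
    bounded quasi-Newton search (budget ``evals_per_cycle`` model
    evaluations) from the previous optimum plus a shrinking jitter, sliding
    the search region toward the global minimum. Stage 2 runs
    ``n_final_cycles`` independent restarts scattered around the stabilized
    optimum; their solutions form the confidence ensemble. Cycles whose cost
    exceeds the best by more than 2% are dropped from the ensemble, and an
    anomaly is flagged significant when at least ``significance_level`` of
    the retained cycle values share the sign of the best-cycle value.

    Each stochastic cycle c draws from a generator seeded with seed + c.
    """
    obs = _validate_observations(observations)
    n = len(obs)
    config = config or CostConfig()
    dim = 2 * n + 3
    ic_prior = np.log([fixed_params.L0, fixed_params.J0, fixed_params.A0])
    bounds = [(-delta_bound, delta_bound)] * (2 * n) + [
        (lp - np.log(100.0), lp + np.log(100.0)) for lp in ic_prior
    ]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    obs_arr = obs[["L", "J", "A"]].to_numpy()
    n_months = n * 12
    lw_lo, lw_hi = mc.LARVAL_WINDOW_MONTHS
    jw_lo, jw_hi = mc.JUVENILE_WINDOW_MONTHS
    ka = mc._kernel_args(fixed_params)
    from . import _kernels

    n_evals = 0

    def cost_of(x):
        nonlocal n_evals
        n_evals += 1
        mul_L = np.ones(n_months)
        mul_J = np.ones(n_months)
        for y in range(n):
            mul_L[max(12 * y + lw_lo, 0): min(12 * y + lw_hi, n_months)] = np.exp(x[y])
            mul_J[max(12 * y + jw_lo, 0): min(12 * y + jw_hi, n_months)] = np.exp(x[n + y])
        params = fixed_params
        L0, J0, A0 = np.exp(x[2 * n: 2 * n + 3])
        *_, jan1 = _kernels.rk4_simulate(
            n, steps_per_month,
            ka["gamma"], ka["beta"], ka["ricker"], ka["lmax"], ka["gmax"],
            ka["r"], ka["inv_sin_half"], ka["two_m"],
            params.m_L, params.m_J, params.m_A,
            mul_L, mul_J, L0, J0, A0, n_months * steps_per_month,
        )
        return _data_term(jan1, obs_arr, config) + config.lambda_reg * float(
            np.sum(x[: 2 * n] ** 2)
        )

    def run_cycle(x0):
        res = minimize(
            cost_of, np.clip(x0, lo, hi), method="L-BFGS-B", bounds=bounds,
            options={"maxfun": evals_per_cycle},
        )
        return res.x, float(res.fun)

    sols, costs = [], []
    # stage 1: sliding recentered search
    center = np.concatenate([np.zeros(2 * n), ic_prior])
    best_x, best_c = None, np.inf
    for c in range(n_primary_cycles):
        rng = np.random.default_rng(seed + c)
        jitter_sd = 0.3 / (1.0 + 0.2 * c)
        x0 = center if c == 0 else center + rng.normal(0.0, jitter_sd, dim)
        x, fc = run_cycle(x0)
        if fc < best_c:
            best_x, best_c = x, fc
        center = best_x
    # stage 2: independent restarts around the stabilized region
    for c in range(n_final_cycles):
        rng = np.random.default_rng(seed + n_primary_cycles + c)
        x0 = best_x + rng.uniform(-0.5, 0.5, dim)
        x, fc = run_cycle(x0)
        sols.append(x)
        costs.append(fc)
        if fc < best_c:
            best_x, best_c = x, fc
    if not sols:  # no final cycles requested: report the stage-1 optimum
        sols, costs = [best_x], [best_c]
    sols = np.asarray(sols)
    costs = np.asarray(costs)
    best_cycle = int(np.argmin(costs))
    retained = costs <= best_c * 1.02
    anom, ics = _unpack(best_x, n)
    kept = sols[retained]
    if kept.shape[0] >= 20:
        flags = classify_significance(kept[:, : 2 * n], best=np.concatenate(
            [anom.delta_L, anom.delta_J]), level=significance_level)
        anom.sig_L = flags[:n]
        anom.sig_J = flags[n:]
    params = fixed_params.replace(L0=float(ics[0]), J0=float(ics[1]), A0=float(ics[2]))
    return FitResult(
        params=params, anomalies=anom, cost=float(best_c),
        cycle_solutions=sols, cycle_costs=costs, best_cycle=best_cycle,
        retained=retained, n_evaluations=n_evals,
    )


def classify_significance(
    per_cycle: np.ndarray, best: np.ndarray | None = None, level: float = 0.95
) -> np.ndarray:
    """Sign-consistency significance flags for each anomaly component.

    A component is significant when at least ``level`` of the cycle values
    share the sign of the best-cycle value; zero values count against
    significance. ``best`` defaults to the first row.
    """
    per_cycle = np.asarray(per_cycle, dtype=float)
    if per_cycle.size == 0:
        raise InputError("empty cycle matrix")
    if per_cycle.ndim != 2:
        raise InputError("cycle matrix must be 2-D (cycle x component)")
    if per_cycle.shape[0] < 20:
        raise InputError("need at least 20 cycles to assess significance")
    if best is None:
        best = per_cycle[0]
    best = np.asarray(best, dtype=float)
    signs = np.sign(best)
    frac = np.mean(np.sign(per_cycle) == signs[None, :], axis=0)
    flags = np.where(
        (signs != 0) & (frac >= level), SIGNIFICANT, NONSIGNIFICANT
    )
    return flags.astype(object)
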