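"""Life-history labyrinth model for Antarctic krill.

Three stages — larvae L, juveniles J, adults A (ind/m^2) — evolve in
continuous time. Stage transitions are only possible while periodic,
smooth "window" functions are open, which blocks larva-to-adult shortcuts
within a season and makes the dynamics insensitive to the exact transition
rate. Egg production follows the generalized Deriso-Schnute
stock-recruitment function, which interpolates between Beverton-Holt
(gamma = -1, saturating) and Ricker (gamma -> 0-, overcompensating) while
keeping the habitat capacity G_max an independent parameter.

Calendar convention: the model year is exactly 1.0; t = 0 is 1 January of
the first modelled year, "1 January" samples are taken at integer t, and
month k (1-based) of year Y occupies t in [Y + (k-1)/12, Y + k/12). Leap
days are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .errors import InputError, IntegrationError, ParameterError

__all__ = [
    "ModelParams",
    "Trajectory",
    "PRESETS",
    "activation",
    "beta_norm",
    "recruitment",
    "rhs",
    "simulate",
    "leakage_fraction",
    "PHASE_SUMMER",
    "PHASE_SPRING",
    "PHASE_WINTER",
    "LARVAL_WINDOW_MONTHS",
    "JUVENILE_WINDOW_MONTHS",
]

PHASE_SUMMER = _kernels.PHASE_SUMMER
PHASE_WINTER = _kernels.PHASE_WINTER
PHASE_SPRING = _kernels.PHASE_SPRING

#: Loss-anomaly application windows as month offsets relative to 1 January of
#: the anomaly year Y: the larval anomaly of year Y acts from 1 November of
#: year Y-1 (offset -2) through 31 October of year Y (offset +10 exclusive);
#: the juvenile anomaly from 1 August of Y-1 through 31 July of Y.
LARVAL_WINDOW_MONTHS = (-2, 10)
JUVENILE_WINDOW_MONTHS = (-5, 7)

# switch to analytic limit expressions near the degenerate gamma values
# (the log1p-based evaluation stays accurate to tiny |gamma|, so the Ricker
# switch only guards the exact-zero neighborhood)
_GAMMA_RICKER_EPS = 1e-8
_GAMMA_BH_EPS = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the time-constant model.

    gamma       recruitment shape, in [-1, 0): -1 is Beverton-Holt, -> 0 Ricker
    r           stage transition rate (1/year)
    tau_window  duration of each transition window (year)
    m_exp       window steepness exponent (integer >= 1)
    L_max       initial slope of the recruitment curve (eggs/year per adult)
    G_max       habitat capacity (eggs/year per m^2)
    m_L, m_J, m_A  background stage mortalities (1/year)
    L0, J0, A0  initial abundances on 1 January of year 0 (ind/m^2)
    """

    gamma: float
    r: float = 30.0
    tau_window: float = 0.2
    m_exp: int = 5
    L_max: float = 2481.0
    G_max: float = 353.0
    m_L: float = 1.76
    m_J: float = 1.13
    m_A: float = 0.51
    L0: float = 0.75
    J0: float = 2.6
    A0: float = 3.9

    def __post_init__(self):
        if not (-1.0 <= self.gamma < 0.0):
            raise ParameterError(f"gamma must lie in [-1, 0), got {self.gamma}")
        if self.r <= 0:
            raise ParameterError("transition rate r must be positive")
        if not (0.0 < self.tau_window < 1.0):
            raise ParameterError("tau_window must lie in (0, 1)")
        if self.m_exp < 1:
            raise ParameterError("m_exp must be >= 1")
        for name in ("L_max", "G_max", "m_L", "m_J", "m_A"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("L0", "J0", "A0"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (int(v) if k == "m_exp" else float(v)) for k, v in d.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


#: Time-constant parameter presets (preset shape/rate values plus the fitted
#: standard parameters and 1 January initial conditions for each variant).
PRESETS: dict[str, ModelParams] = {
    "BH": ModelParams(
        gamma=-1.0, r=30.0, tau_window=0.2, m_exp=5,
        L_max=3368.0, G_max=101.0, m_L=2.6, m_J=1.31, m_A=0.6,
        L0=1.9, J0=2.94, A0=5.07,
    ),
    "RK": ModelParams(
        gamma=-0.09, r=30.0, tau_window=0.2, m_exp=5,
        L_max=2481.0, G_max=353.0, m_L=1.76, m_J=1.13, m_A=0.51,
        L0=0.75, J0=2.6, A0=3.9,
    ),
}


@dataclass
class Trajectory:
    """Solver output: dense states plus the 1 January samples per year."""

    frame: pd.DataFrame  # columns t, L, J, A
    jan1: pd.DataFrame  # columns year (0-based index), L, J, A

    def to_csv(self, trajectory_path, jan1_path) -> None:
        self.frame.to_csv(trajectory_path, index=False)
        self.jan1.to_csv(jan1_path, index=False)


def activation(t, t0: float, tau_window: float = 0.2, m_exp: int = 5):
    """Smooth period-1 window function, equal to 1 at t0 + integer.

    f(t) = exp(-{sin[pi(t - t0)] / sin(pi tau/2)}^(2m) ln 2); the ln 2
    normalization makes the half-maximum fall at t0 +/- tau/2, and the
    integral over one period approaches tau as m grows.
    """
    if not (0.0 < tau_window < 1.0):
        raise ParameterError("tau_window must lie in (0, 1)")
    if m_exp < 1:
        raise ParameterError("m_exp must be >= 1")
    s = np.sin(np.pi * (np.asarray(t, dtype=float) - t0)) / np.sin(
        np.pi * tau_window / 2.0
    )
    with np.errstate(over="ignore"):  # s^(2m) overflow -> exp(-inf) = 0, correct
        return np.exp(-(s ** (2 * int(m_exp))) * _kernels.LN2)


def beta_norm(gamma: float) -> float:
    """Normalizing constant beta_gamma = gamma / (gamma+1)^(1 + 1/gamma).

    Chosen so that sup_A R(A) = G_max for every gamma in [-1, 0). The
    gamma = -1 value is the analytic limit -1; near gamma = 0 the constant
    approaches gamma/e.
    """
    if not (-1.0 <= gamma < 0.0):
        raise ParameterError(f"gamma must lie in [-1, 0), got {gamma}")
    if gamma + 1.0 < _GAMMA_BH_EPS:
        return -1.0
    if -gamma < _GAMMA_RICKER_EPS:
        return gamma / np.e
    return gamma / (gamma + 1.0) ** (1.0 + 1.0 / gamma)


def recruitment(A, params: ModelParams):
    """Egg production rate R(A) (eggs/year per m^2).

    R(A) = L_max A (1 - beta_gamma L_max A / G_max)^(1/gamma); R(0) = 0,
    dR/dA|_0 = L_max and sup_A R = G_max. In the gamma -> 0- neighborhood
    the analytic Ricker limit R = L_max A exp(-L_max A / (e G_max)) is used.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise InputError("adult abundance must be non-negative")
    gamma = params.gamma
    x = params.L_max * A / params.G_max
    if -gamma < _GAMMA_RICKER_EPS:
        out = params.G_max * x * np.exp(-x / np.e)
    else:
        beta = beta_norm(gamma)
        out = params.G_max * x * np.exp(np.log1p(-beta * x) / gamma)
    return out if out.ndim else float(out)


def leakage_fraction(r: float, tau_window: float) -> float:
    """Fraction of a cohort failing to transit an open window: exp(-r tau)."""
    return float(np.exp(-r * tau_window))


def rhs(t: float, state: Sequence[float], params: ModelParams, mortality_lookup=None):
    """Time derivatives (dL/dt, dJ/dt, dA/dt) of the labyrinth system.

    dL/dt = R(A) f_sum - r f_spr L - m_L L
    dJ/dt = r f_spr L - r f_wnt J - m_J J
    dA/dt = r f_wnt J - m_A A

    with egg production gated by the summer window (phase 0), the
    larva->juvenile transition by the spring window (phase 9/12) and the
    juvenile->adult transition by the winter window (phase 1/2).
    ``mortality_lookup``, if given, is called as ``mortality_lookup(t)`` and
    must return the (m_L, m_J, m_A) triple effective at time t.
    """
    L, J, A = state
    if mortality_lookup is None:
        m_L, m_J, m_A = params.m_L, params.m_J, params.m_A
    else:
        m_L, m_J, m_A = mortality_lookup(t)
    inv_sin_half = 1.0 / np.sin(np.pi * params.tau_window / 2.0)
    two_m = 2 * int(params.m_exp)
    beta = beta_norm(params.gamma)
    ricker = -params.gamma < _GAMMA_RICKER_EPS
    dL, dJ, dA = _kernels._rhs(
        t, L, J, A, params.gamma, beta, ricker, params.L_max, params.G_max,
        params.r, inv_sin_half, two_m, m_L, m_J, m_A,
    )
    return np.array([dL, dJ, dA])


def monthly_multipliers(anomalies, years: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-month mortality multipliers exp(delta) implied by an anomaly series.

    ``anomalies`` needs attributes ``years`` (0-based model-year indices),
    ``delta_L`` and ``delta_J``. The anomaly of year Y is applied over its
    cohort-specific calendar window (see LARVAL_WINDOW_MONTHS /
    JUVENILE_WINDOW_MONTHS); months before t = 0 are clipped. Adult
    mortality is never modulated.
    """
    n_months = years * 12
    mul_L = np.ones(n_months)
    mul_J = np.ones(n_months)
    if anomalies is None:
        return mul_L, mul_J
    for y, dL, dJ in zip(anomalies.years, anomalies.delta_L, anomalies.delta_J):
        y = int(y)
        lo, hi = LARVAL_WINDOW_MONTHS
        a, b = max(12 * y + lo, 0), min(12 * y + hi, n_months)
        if a < b:
            mul_L[a:b] = np.exp(dL)
        lo, hi = JUVENILE_WINDOW_MONTHS
        a, b = max(12 * y + lo, 0), min(12 * y + hi, n_months)
        if a < b:
            mul_J[a:b] = np.exp(dJ)
    return mul_L, mul_J


def _kernel_args(params: ModelParams):
    return dict(
        gamma=params.gamma,
        beta=beta_norm(params.gamma),
        ricker=-params.gamma < _GAMMA_RICKER_EPS,
        lmax=params.L_max,
        gmax=params.G_max,
        r=params.r,
        inv_sin_half=1.0 / np.sin(np.pi * params.tau_window / 2.0),
        two_m=2 * int(params.m_exp),
    )


def simulate(
    params: ModelParams,
    anomalies=None,
    years: int = 27,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    steps_per_month: int = 40,
    store_stride: int | None = None,
    initial_state: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model over [0, years] and record 1 January samples.

    ``method="adaptive"`` uses a stiffness-switching adaptive solver with
    dense output (the reference path); ``method="fast"`` uses the compiled
    fixed-step RK4 kernel (~one step per 18 h), accurate to well under 0.1%
    of the adaptive solution and used inside fitting loops.
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    y0 = (
        np.asarray(initial_state, dtype=float)
        if initial_state is not None
        else np.array([params.L0, params.J0, params.A0])
    )
    mul_L, mul_J = monthly_multipliers(anomalies, years)
    ka = _kernel_args(params)

    if method == "fast":
        stride = store_stride or steps_per_month  # default: monthly snapshots
        ts, Ls, Js, As, jan1 = _kernels.rk4_simulate(
            years, steps_per_month,
            ka["gamma"], ka["beta"], ka["ricker"], ka["lmax"], ka["gmax"],
            ka["r"], ka["inv_sin_half"], ka["two_m"],
            params.m_L, params.m_J, params.m_A,
            mul_L, mul_J, y0[0], y0[1], y0[2], stride,
        )
        frame = pd.DataFrame({"t": ts, "L": Ls, "J": Js, "A": As})
    elif method == "adaptive":
        from scipy.integrate import solve_ivp

        n_months = years * 12

        def fun(t, y):
            month = min(int(t * 12.0), n_months - 1)
            dL, dJ, dA = _kernels._rhs(
                t, y[0], y[1], y[2],
                ka["gamma"], ka["beta"], ka["ricker"], ka["lmax"], ka["gmax"],
                ka["r"], ka["inv_sin_half"], ka["two_m"],
                params.m_L * mul_L[month], params.m_J * mul_J[month], params.m_A,
            )
            return (dL, dJ, dA)

        sol = solve_ivp(
            fun, (0.0, float(years)), y0, method="LSODA",
            rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed: {sol.message}", last_valid_time=float(sol.t[-1])
            )
        t_grid = np.linspace(0.0, years, years * 48 + 1)
        states = np.clip(sol.sol(t_grid), 0.0, None)
        frame = pd.DataFrame(
            {"t": t_grid, "L": states[0], "J": states[1], "A": states[2]}
        )
        jan1 = np.clip(sol.sol(np.arange(years, dtype=float)), 0.0, None).T
    else:
        raise ParameterError(f"unknown method {method!r}")

    jan1_df = pd.DataFrame(jan1, columns=["L", "J", "A"])
    jan1_df.insert(0, "year", np.arange(years))
    return Trajectory(frame=frame, jan1=jan1_df)
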