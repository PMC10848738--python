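"""Compiled numerical kernels.

Two hot loops live here: a fixed-step RK4 integrator for the
stage-structured ODE system (used inside fitting loops, where the model is
evaluated tens of thousands of times) and a FISTA solver for the fused
LASSO objective. Both are plain-array numba functions; all user-facing
validation happens in the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN2 = 0.6931471805599453

# phases of the three transition windows (fraction of the calendar year)
PHASE_SUMMER = 0.0  # egg production
PHASE_WINTER = 0.5  # juvenile -> adult
PHASE_SPRING = 0.75  # larva -> juvenile


@njit(cache=True)
def activation_scalar(t: float, t0: float, inv_sin_half: float, two_m: int) -> float:
    s = np.sin(np.pi * (t - t0)) * inv_sin_half
    return np.exp(-(s**two_m) * LN2)


@njit(cache=True)
def recruitment_scalar(
    A: float, gamma: float, beta: float, ricker: bool, lmax: float, gmax: float
) -> float:
    if A <= 0.0:
        return 0.0
    x = lmax * A / gmax
    if ricker:
        return gmax * x * np.exp(-x / np.e)
    # beta < 0 for gamma in [-1, 0), so the base is always > 1;
    # log1p keeps the power accurate as gamma -> 0
    return gmax * x * np.exp(np.log1p(-beta * x) / gamma)


@njit(cache=True)
def _rhs(
    t, L, J, A, gamma, beta, ricker, lmax, gmax, r, inv_sin_half, two_m, mL, mJ, mA
):
    # clip inside the RHS: keeps the vector field smooth for the integrator
    Lc = L if L > 0.0 else 0.0
    Jc = J if J > 0.0 else 0.0
    Ac = A if A > 0.0 else 0.0
    f_sum = activation_scalar(t, PHASE_SUMMER, inv_sin_half, two_m)
    f_spr = activation_scalar(t, PHASE_SPRING, inv_sin_half, two_m)
    f_wnt = activation_scalar(t, PHASE_WINTER, inv_sin_half, two_m)
    R = recruitment_scalar(Ac, gamma, beta, ricker, lmax, gmax)
    dL = R * f_sum - r * f_spr * Lc - mL * Lc
    dJ = r * f_spr * Lc - r * f_wnt * Jc - mJ * Jc
    dA = r * f_wnt * Jc - mA * Ac
    return dL, dJ, dA


@njit(cache=True)
def rk4_simulate(
    years: int,
    steps_per_month: int,
    gamma: float,
    beta: float,
    ricker: bool,
    lmax: float,
    gmax: float,
    r: float,
    inv_sin_half: float,
    two_m: int,
    m_L: float,
    m_J: float,
    m_A: float,
    mul_L: np.ndarray,  # per-month mortality multipliers, length years*12
    mul_J: np.ndarray,
    L0: float,
    J0: float,
    A0: float,
    store_stride: int,
):
    """Fixed-step RK4 over [0, years]; returns (t, L, J, A, jan1) arrays.

    Mortality multipliers are piecewise constant per calendar month; the
    month index is looked up from the step counter, so substage times within
    one step share the month's multiplier.
    """
    n_months = years * 12
    spm = steps_per_month
    h = 1.0 / (12.0 * spm)
    n_steps = n_months * spm
    n_store = n_steps // store_stride + 1
    ts = np.empty(n_store)
    Ls = np.empty(n_store)
    Js = np.empty(n_store)
    As = np.empty(n_store)
    jan1 = np.empty((years, 3))
    L, J, A = L0, J0, A0
    si = 0
    for k in range(n_steps):
        t = k * h
        if k % (12 * spm) == 0:
            y = k // (12 * spm)
            jan1[y, 0] = L if L > 0.0 else 0.0
            jan1[y, 1] = J if J > 0.0 else 0.0
            jan1[y, 2] = A if A > 0.0 else 0.0
        if k % store_stride == 0:
            ts[si] = t
            Ls[si] = L if L > 0.0 else 0.0
            Js[si] = J if J > 0.0 else 0.0
            As[si] = A if A > 0.0 else 0.0
            si += 1
        month = k // spm
        mL = m_L * mul_L[month]
        mJ = m_J * mul_J[month]
        h2 = 0.5 * h
        k1L, k1J, k1A = _rhs(
            t, L, J, A, gamma, beta, ricker, lmax, gmax, r, inv_sin_half, two_m, mL, mJ, m_A
        )
        k2L, k2J, k2A = _rhs(
            t + h2, L + h2 * k1L, J + h2 * k1J, A + h2 * k1A,
            gamma, beta, ricker, lmax, gmax, r, inv_sin_half, two_m, mL, mJ, m_A,
        )
        k3L, k3J, k3A = _rhs(
            t + h2, L + h2 * k2L, J + h2 * k2J, A + h2 * k2A,
            gamma, beta, ricker, lmax, gmax, r, inv_sin_half, two_m, mL, mJ, m_A,
        )
        k4L, k4J, k4A = _rhs(
            t + h, L + h * k3L, J + h * k3J, A + h * k3A,
            gamma, beta, ricker, lmax, gmax, r, inv_sin_half, two_m, mL, mJ, m_A,
        )
        L += h / 6.0 * (k1L + 2.0 * k2L + 2.0 * k3L + k4L)
        J += h / 6.0 * (k1J + 2.0 * k2J + 2.0 * k3J + k4J)
        A += h / 6.0 * (k1A + 2.0 * k2A + 2.0 * k3A + k4A)
    ts[si] = n_steps * h
    Ls[si] = L if L > 0.0 else 0.0
    Js[si] = J if J > 0.0 else 0.0
    As[si] = A if A > 0.0 else 0.0
    return ts[: si + 1], Ls[: si + 1], Js[: si + 1], As[: si + 1], jan1


@njit(cache=True)
def fista_fused_lasso(
    X: np.ndarray,  # (m, p) standardized design, no intercept column
    y: np.ndarray,  # (m,)
    lam: float,  # L1 penalty on slopes
    tau: float,  # quadratic fusion penalty between adjacent within-block coefs
    block_starts: np.ndarray,  # int64, start index of each factor block
    block_ends: np.ndarray,  # int64, one past the last index of each block
    max_iter: int,
    tol: float,
    a0_init: float,
    a_init: np.ndarray,  # warm start for the slopes (zeros for a cold start)
):
    """Minimize the fused LASSO objective; returns (intercept, coef, J, n_iter).

    J = (1/2m)||y - a0 - X a||^2 + lam*sum|a| + tau*sum_F sum_i (a_i - a_{i-1})^2

    FISTA with soft-thresholding on the slopes; the intercept and the
    (smooth, quadratic) fusion term fold into the gradient step.
    """
    m, p = X.shape
    # Lipschitz bound: ||[1 X]||_2^2/m <= (m + ||X||_F^2)/m; fusion adds <= 8*tau
    fro2 = 0.0
    for i in range(m):
        for j in range(p):
            fro2 += X[i, j] * X[i, j]
    Lip = (m + fro2) / m + 8.0 * tau
    step = 1.0 / Lip

    a = a_init.copy()
    a0 = a0_init
    za = a.copy()
    za0 = a0
    t_mom = 1.0
    J_prev = 1e300
    n_blocks = block_starts.shape[0]
    it = 0
    for it in range(max_iter):
        # gradient of the smooth part at (za0, za)
        resid = X @ za + za0 - y
        g = X.T @ resid / m
        g0 = np.sum(resid) / m
        for b in range(n_blocks):
            for j in range(block_starts[b] + 1, block_ends[b]):
                d = 2.0 * tau * (za[j] - za[j - 1])
                g[j] += d
                g[j - 1] -= d
        a0_new = za0 - step * g0
        a_new = za - step * g
        # soft threshold slopes
        thr = step * lam
        for j in range(p):
            v = a_new[j]
            if v > thr:
                a_new[j] = v - thr
            elif v < -thr:
                a_new[j] = v + thr
            else:
                a_new[j] = 0.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        mom = (t_mom - 1.0) / t_new
        za = a_new + mom * (a_new - a)
        za0 = a0_new + mom * (a0_new - a0)
        a = a_new
        a0 = a0_new
        t_mom = t_new
        if it % 10 == 9:
            resid = X @ a + a0 - y
            J_cur = 0.5 * (resid @ resid) / m + lam * np.sum(np.abs(a))
            for b in range(n_blocks):
                for j in range(block_starts[b] + 1, block_ends[b]):
                    d = a[j] - a[j - 1]
                    J_cur += tau * d * d
            if abs(J_prev - J_cur) <= tol * max(1.0, abs(J_cur)):
                J_prev = J_cur
                break
            J_prev = J_cur
    return a0, a, J_prev, it + 1
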