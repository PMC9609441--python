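"""Fixed-step backward-differentiation-formula (BDF) integration.

The spray-drying balances form a semi-explicit DAE/ODE system advanced by
substituting the BDF approximation of the time derivative,

    xdot(t_n) ~= (1/h) * sum_{l=0..k} a_l x_{n-l},

into the residual ``F(t, x, xdot) = 0`` and Newton-solving each step for
``x_n``.  The coefficients ``a_l`` are the unique set that makes the
formula exact for polynomials up to degree ``k`` on a uniform grid
(order 1 is implicit Euler).  Startup ramps the order from 1 to ``k`` over
the first steps; the Newton Jacobian comes from forward differences and is
factored once per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BdfConfig", "bdf_coefficients", "bdf_integrate"]


@dataclass(frozen=True)
class BdfConfig:
    step: float  # h_s, s
    order: int = 2  # k in 1..5
    newton_tol: float = 1e-10
    newton_max_iter: int = 25

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 1 <= self.order <= 5:
            raise ValueError("order must be between 1 and 5")


def bdf_coefficients(k: int) -> np.ndarray:
    """Coefficients (a_0, ..., a_k) of the k-step BDF derivative formula.

    Determined by exactness on monomials: with x(t) = ((j... the formula
    (1/h) sum_l a_l x(t_n - l h) must equal xdot(t_n) for x = t^m,
    m = 0..k, which yields a Vandermonde system in the lags l.
    Order 1 gives (1, -1); order 2 gives (3/2, -2, 1/2).
    """
    if not 1 <= int(k) == k <= 5:
        raise ValueError("order must be an integer between 1 and 5")
    lags = np.arange(k + 1, dtype=float)
    # sum_l a_l (-l)^m = [m == 1] for m = 0..k  (h-scaled Taylor condition)
    vandermonde = np.vander(-lags, k + 1, increasing=True).T
    rhs = np.zeros(k + 1)
    rhs[1] = 1.0
    return np.linalg.solve(vandermonde, rhs)


def _fd_jacobian(residual, t, x, history_term, a0_over_h, f):
    """Forward-difference Jacobian of the step residual w.r.t. x."""
    n = x.size
    jac = np.empty((n, n))
    for col in range(n):
        delta = 1e-8 * max(abs(x[col]), 1.0)
        xp = x.copy()
        xp[col] += delta
        jac[:, col] = (residual(t, xp, a0_over_h * xp + history_term) - f) / delta
    return jac


def _newton_step(residual, t, x_pred, history_term, a0_over_h, tol, max_iter, lu=None):
    """Solve F(t, x, a0/h * x + history) = 0 for x by modified Newton.

    ``lu`` is an optionally reused LU factorization of the step Jacobian
    from an earlier step; it is refreshed whenever the iteration stalls.
    Returns (x, iterations, lu).
    """
    from scipy.linalg import lu_factor, lu_solve

    x = x_pred.copy()
    refreshed = lu is None
    previous_norm = np.inf
    iteration = 0
    while iteration < max_iter:
        xdot = a0_over_h * x + history_term
        f = residual(t, x, xdot)
        # component-wise relative norm: the residual has the units of xdot,
        # whose entries span many orders of magnitude across the state
        norm = np.max(np.abs(f) / (1.0 + np.abs(xdot)))
        if norm < tol:
            return x, iteration, lu
        stalled = norm > 0.5 * previous_norm and iteration > 0
        if lu is None or stalled:
            if stalled and refreshed:
                # fresh Jacobian and still stalling: take the step anyway
                # if the residual is already tiny, else keep iterating
                pass
            jac = _fd_jacobian(residual, t, x, history_term, a0_over_h, f)
            try:
                lu = lu_factor(jac)
            except Exception as exc:
                raise RuntimeError(f"singular Newton Jacobian at t={t:.6g}") from exc
            refreshed = True
        dx = lu_solve(lu, -f)
        x = x + dx
        previous_norm = norm
        iteration += 1
    xdot = a0_over_h * x + history_term
    f = residual(t, x, xdot)
    norm = np.max(np.abs(f) / (1.0 + np.abs(xdot)))
    if norm < tol * 1e3:
        logger.debug("Newton accepted loose tolerance %.2e at t=%.6g", norm, t)
        return x, max_iter, lu
    raise RuntimeError(
        f"Newton failed to converge at t={t:.6g} "
        f"(residual {norm:.3e} after {max_iter} iterations)"
    )


def bdf_integrate(
    residual: Callable[[float, np.ndarray, np.ndarray], np.ndarray],
    x0: np.ndarray,
    config: BdfConfig,
    t_end: float,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance ``F(t, x, xdot) = 0`` from ``x0`` with fixed-step BDF.

    Returns ``(times, states)`` with one row of ``states`` per time,
    including the initial condition.  The order ramps 1 -> k over the
    first steps (self-starting).  ``t_end < t0 + step`` returns just the
    initial state.
    """
    x0 = np.asarray(x0, dtype=float)
    h = config.step
    n_steps = int(round((t_end - t0) / h))
    if n_steps <= 0:
        return np.array([t0]), x0[np.newaxis, :].copy()
    times = t0 + h * np.arange(n_steps + 1)
    states = np.empty((n_steps + 1, x0.size))
    states[0] = x0
    coeff_cache = {k: bdf_coefficients(k) for k in range(1, config.order + 1)}

    # self-starting ramp: the first k-1 grid values come from implicit-Euler
    # substeps, refined enough (h^2/m <= h^k) not to spoil the k-th order
    n_startup = min(config.order - 1, n_steps)
    if n_startup > 0:
        m_sub = 1
        if config.order >= 3 and h < 1.0:
            m_sub = min(int(np.ceil(h ** (2 - config.order))), 4096)
        a1 = coeff_cache[1]
        h_sub = h / m_sub
        for step in range(1, n_startup + 1):
            x = states[step - 1].copy()
            t_base = times[step - 1]
            for sub in range(1, m_sub + 1):
                x, _, _ = _newton_step(
                    residual,
                    t_base + sub * h_sub,
                    x.copy(),
                    (a1[1] * x) / h_sub,
                    a1[0] / h_sub,
                    config.newton_tol,
                    config.newton_max_iter,
                    lu=None,
                )
            states[step] = x

    a = coeff_cache[config.order]
    lu = None
    for step in range(n_startup + 1, n_steps + 1):
        order = min(step, config.order)
        a_step = coeff_cache[order]
        history = states[step - order : step][::-1]  # x_{n-1}, x_{n-2}, ...
        history_term = (a_step[1:] @ history) / h
        x_pred = states[step - 1].copy()
        states[step], n_iter, lu = _newton_step(
            residual,
            times[step],
            x_pred,
            history_term,
            a_step[0] / h,
            config.newton_tol,
            config.newton_max_iter,
            lu=lu,
        )
        logger.debug("t=%.6g order=%d newton_iters=%d", times[step], order, n_iter)
    return times, states
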