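"""Generic self-consistency solvers shared by the LIF and binary modules.

Both solve ``x = f(x)`` for a population vector ``x`` with box bounds:
either by integrating the auxiliary ODE ``x' = -x + f(x)`` to its fixed
point, or by minimizing the quadratic deviation with a bounded
least-squares solver.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize

__all__ = ["ConvergenceError", "NotSelfConsistentError", "fixed_point_ode",
           "fixed_point_lstsq"]


class ConvergenceError(RuntimeError):
    """ODE integration reached t_max without settling; carries the endpoint."""

    def __init__(self, message, endpoint=None):
        super().__init__(message)
        self.endpoint = endpoint


class NotSelfConsistentError(RuntimeError):
    """Least-squares terminated at a non-vanishing residual; carries it."""

    def __init__(self, message, x=None, residual=None):
        super().__init__(message)
        self.x = x
        self.residual = residual


def fixed_point_ode(f, x0, *, tol=1e-9, t_max=50.0, lower=0.0, upper=np.inf):
    """Integrate ``x' = -x + f(x)`` until ``||x'||_inf < tol``.

    Uses a stiff-capable integrator; raises :class:`ConvergenceError` if the
    derivative has not settled by ``t_max`` (dimensionless auxiliary time).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))

    def rhs(t, x):
        return -x + f(np.clip(x, lower, upper))

    def settled(t, x):
        # terminate at half the tolerance so the endpoint residual is
        # strictly below tol after clipping
        return np.max(np.abs(rhs(t, x))) - 0.5 * tol

    settled.terminal = True
    settled.direction = -1

    sol = integrate.solve_ivp(
        rhs, (0.0, t_max), x0, method="LSODA", events=settled,
        rtol=1e-10, atol=1e-12, dense_output=False,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}",
                               endpoint=sol.y[:, -1])
    x = np.clip(sol.y[:, -1], lower, upper)
    if np.max(np.abs(-x + f(x))) > tol:
        raise ConvergenceError(
            f"no fixed point within t_max={t_max}; residual "
            f"{np.max(np.abs(-x + f(x))):.3e} > {tol:.1e}", endpoint=x)
    return x


def fixed_point_lstsq(f, x0, *, tol=1e-12, lower=0.0, upper=np.inf):
    """Minimize ``sum (x - f(x))^2`` with box bounds.

    Returns only genuinely self-consistent solutions: raises
    :class:`NotSelfConsistentError` if the final quadratic deviation exceeds
    ``tol`` (a local minimum is not a solution of the fixed-point problem).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    upper_arr = np.broadcast_to(np.asarray(upper, dtype=float), x0.shape)
    lower_arr = np.broadcast_to(np.asarray(lower, dtype=float), x0.shape)
    x0 = np.clip(x0, lower_arr, np.where(np.isfinite(upper_arr),
                                         upper_arr * (1 - 1e-12), upper_arr))

    res = optimize.least_squares(
        lambda x: x - f(x), x0, bounds=(lower_arr, upper_arr),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    dev = float(np.sum(res.fun ** 2))
    if dev > tol:
        raise NotSelfConsistentError(
            f"least-squares converged to a non-self-consistent point "
            f"(quadratic deviation {dev:.3e} > {tol:.1e})",
            x=res.x, residual=dev)
    return res.x
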