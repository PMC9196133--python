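"""Mean-field activity of binary-neuron networks.

Mean activities obey the self-consistency relation

    m_a = 1/2 erfc( (Theta_a - mu_a) / (sqrt(2) sigma_a) ),
    mu_a = sum_b K_ab J_ab m_b,
    sigma_a^2 = sum_b K_ab J_ab^2 m_b (1 - m_b),

which has the same structure as the LIF rate problem and reuses its
solvers.  The sum over b may include external columns with fixed
activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._solvers import fixed_point_lstsq, fixed_point_ode

__all__ = ["BinaryNetwork", "binary_input_stats", "binary_mean_activity",
           "solve_binary_activity"]


@dataclass
class BinaryNetwork:
    """K and J may carry extra external columns (fixed activities
    ``m_ext``); ``theta`` are the per-population thresholds."""

    K: np.ndarray
    J: np.ndarray
    theta: np.ndarray
    m_ext: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.J = np.atleast_2d(np.asarray(self.J, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.m_ext = np.atleast_1d(np.asarray(self.m_ext, dtype=float))
        P = self.theta.size
        if self.K.shape != self.J.shape:
            raise ValueError("K and J must have identical shapes")
        if self.K.shape[0] != P:
            raise ValueError("row count of K must match number of thresholds")
        if self.K.shape[1] != P + self.m_ext.size:
            raise ValueError(
                "column count of K must equal P plus the number of external "
                "activities")
        if np.any((self.m_ext < 0) | (self.m_ext > 1)):
            raise ValueError("external activities must lie in [0, 1]")

    @property
    def P(self) -> int:
        return self.theta.size


def _full_activity(net: BinaryNetwork, m):
    return np.concatenate([m, net.m_ext]) if net.m_ext.size else m


def binary_input_stats(net: BinaryNetwork, m):
    m = np.atleast_1d(np.asarray(m, dtype=float))
    m_all = _full_activity(net, m)
    mu = (net.K * net.J) @ m_all
    var = (net.K * net.J ** 2) @ (m_all * (1.0 - m_all))
    return mu, np.sqrt(var)


def binary_mean_activity(net: BinaryNetwork, m):
    """One application of the activity map; the sigma = 0 limit is the
    Heaviside step with value 1/2 at threshold."""
    m = np.atleast_1d(np.asarray(m, dtype=float))
    if np.any((m < 0) | (m > 1)):
        raise ValueError("activities must lie in [0, 1]")
    mu, sigma = binary_input_stats(net, m)
    out = np.empty(net.P)
    pos = sigma > 0
    out[pos] = 0.5 * special.erfc(
        (net.theta[pos] - mu[pos]) / (np.sqrt(2.0) * sigma[pos]))
    out[~pos] = 0.5 * (1.0 + np.sign(mu[~pos] - net.theta[~pos]))
    return out


def solve_binary_activity(net: BinaryNetwork, m_init=None, method="ode",
                          tol_ode=1e-9, t_max=200.0, tol_lstsq=1e-12):
    """Self-consistent mean activities in [0, 1]^P via the shared solvers."""
    if m_init is None:
        m_init = np.full(net.P, 0.5)
    f = lambda m: binary_mean_activity(net, np.clip(m, 0.0, 1.0))
    if method == "ode":
        return fixed_point_ode(f, m_init, tol=tol_ode, t_max=t_max,
                               lower=0.0, upper=1.0)
    if method == "lstsq":
        return fixed_point_lstsq(f, m_init, tol=tol_lstsq, lower=0.0, upper=1.0)
    raise ValueError(f"unknown method {method!r}")
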