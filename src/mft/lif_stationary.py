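"""Stationary mean-field theory for LIF networks.

Input statistics, the first-passage (Siegert) firing rate for instantaneous
and exponentially filtered synapses, and the self-consistency solvers for
the network rates.

The rate of a white-noise driven LIF neuron with threshold ``V_th``, reset
``V_0`` (relative to rest), membrane time constant ``tau_m`` and refractory
period ``tau_r`` is

    phi(mu, sigma) = 1 / (tau_r + tau_m * sqrt(pi) * I),
    I = integral of exp(s^2)*(1 + erf(s)) from (V_0-mu)/sigma
        to (V_th-mu)/sigma.

The integrand equals ``erfcx(-s)`` identically, which is what the
implementation integrates: for s < 0 it is bounded by 1, and the
exponentially growing part for s > 0 is captured in closed form through the
imaginary error function, so no factor exp(s^2) is ever formed.  For
rescaled thresholds beyond the overflow range of erfi the rate is evaluated
from the asymptotic expansion of the integral in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from ._solvers import ConvergenceError, NotSelfConsistentError  # noqa: F401
from ._solvers import fixed_point_lstsq, fixed_point_ode
from .models_io import AnalysisParams, PopulationNetwork

__all__ = [
    "COLORED_NOISE_ALPHA", "InputStats", "WorkingPoint", "RescaledBounds",
    "input_stats", "siegert_rate_delta", "siegert_rate_exp",
    "rescaled_bounds", "solve_rates_ode", "solve_rates_lstsq", "working_point",
]

#: Boundary-shift constant of the colored-noise (exponential synapse) rate,
#: sqrt(2)*|zeta(1/2)| ~= 2.07.
COLORED_NOISE_ALPHA = float(np.sqrt(2.0) * np.abs(special.zeta(0.5)))


@dataclass
class InputStats:
    mu: np.ndarray      # volts, per population
    sigma: np.ndarray   # volts, per population


@dataclass
class WorkingPoint:
    nu: np.ndarray      # Hz, per population
    stats: InputStats

    @property
    def mu(self):
        return self.stats.mu

    @property
    def sigma(self):
        return self.stats.sigma


@dataclass
class RescaledBounds:
    y0: np.ndarray
    yth: np.ndarray
    y0_cn: np.ndarray
    yth_cn: np.ndarray


def input_stats(net: PopulationNetwork, nu) -> InputStats:
    """Mean and noise intensity of the input to each population.

    mu_a     = tau_m * (sum_b J_ab K_ab nu_b + sum_x Jx_ax Kx_ax nux_x)
    sigma_a2 = tau_m * (sum_b J_ab^2 K_ab nu_b + sum_x Jx_ax^2 Kx_ax nux_x)

    with signed weights J (inhibitory entries negative).
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    if np.any(nu < 0):
        raise ValueError("rates must be nonnegative")
    JK = net.J * net.K
    JJK = net.J ** 2 * net.K
    mu = net.tau_m * (JK @ nu + (net.J_ext * net.K_ext) @ net.nu_ext)
    var = net.tau_m * (JJK @ nu + (net.J_ext ** 2 * net.K_ext) @ net.nu_ext)
    return InputStats(mu=mu, sigma=np.sqrt(var))


# ---------------------------------------------------------------------------
# Siegert rate

_ERFI_MAX = 26.0  # erfi overflows just above; switch to log-space asymptotics


def _siegert_integral(y0: float, yth: float) -> float:
    """integral of erfcx(-s) over [y0, yth] (both bounds finite, y0 < yth)."""
    opts = dict(epsabs=0.0, epsrel=1e-13, limit=200)
    if yth <= 0.0:
        return integrate.quad(lambda s: special.erfcx(-s), y0, yth, **opts)[0]
    lower = 0.0
    if y0 < 0.0:
        part = integrate.quad(lambda s: special.erfcx(-s), y0, 0.0, **opts)[0]
    else:
        part = 0.0
        lower = y0
    # on s > 0: erfcx(-s) = 2 exp(s^2) - erfcx(s); the first term integrates
    # to sqrt(pi) * erfi(s)
    grow = np.sqrt(np.pi) * (special.erfi(yth) - special.erfi(lower))
    decay = integrate.quad(special.erfcx, lower, yth, **opts)[0]
    return part + grow - decay


def _log_rate_subthreshold(yth: float, tau_m: float) -> float:
    """log of the rate from the asymptotic expansion
    I ~ exp(yth^2)/yth * sum_k (2k-1)!!/(2 yth^2)^k (lower bound negligible)."""
    y2 = yth * yth
    series, term = 1.0, 1.0
    for k in range(1, 60):
        term *= (2 * k - 1) / (2.0 * y2)
        series += term
        if term < 1e-18:
            break
    log_integral = y2 - np.log(yth) + np.log(series)
    return -(np.log(tau_m * np.sqrt(np.pi)) + log_integral)


def _rate_scalar(mu, sigma, tau_m, tau_r, V_th_rel, V_0_rel, shift=0.0):
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive "
                         "(the deterministic limit is not supported)")
    if V_th_rel <= V_0_rel:
        raise ValueError("V_th_rel must exceed V_0_rel")
    y0 = (V_0_rel - mu) / sigma + shift
    yth = (V_th_rel - mu) / sigma + shift
    if yth > _ERFI_MAX:
        log_rate = _log_rate_subthreshold(yth, tau_m)
        return np.exp(log_rate) if log_rate > -744.0 else 0.0
    integral = _siegert_integral(y0, yth)
    return 1.0 / (tau_r + tau_m * np.sqrt(np.pi) * integral)


def _vectorized_rate(mu, sigma, tau_m, tau_s, tau_r, V_th_rel, V_0_rel, shifted):
    mu, sigma, tau_m, tau_s, tau_r, V_th_rel, V_0_rel = np.broadcast_arrays(
        *np.atleast_1d(mu, sigma, tau_m, tau_s, tau_r, V_th_rel, V_0_rel))
    out = np.empty(mu.shape)
    it = np.nditer(mu, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        shift = 0.0
        if shifted:
            shift = COLORED_NOISE_ALPHA / 2.0 * np.sqrt(tau_s[i] / tau_m[i])
        out[i] = _rate_scalar(mu[i], sigma[i], tau_m[i], tau_r[i],
                              V_th_rel[i], V_0_rel[i], shift=shift)
    return out


def siegert_rate_delta(mu, sigma, tau_m, tau_r, V_th_rel, V_0_rel):
    """Stationary rate (Hz) for instantaneous synapses; vectorized."""
    scalar = np.isscalar(mu) or np.ndim(mu) == 0
    out = _vectorized_rate(mu, sigma, tau_m, 0.0, tau_r, V_th_rel, V_0_rel,
                           shifted=False)
    return float(out[0]) if scalar and out.size == 1 else out


def siegert_rate_exp(mu, sigma, tau_m, tau_s, tau_r, V_th_rel, V_0_rel):
    """Stationary rate (Hz) for exponential synapses: both integration
    boundaries are shifted by ``alpha/2 * sqrt(tau_s/tau_m)`` with
    ``alpha = sqrt(2)|zeta(1/2)|``.  Valid for tau_s << tau_m."""
    if np.any(np.asarray(tau_s) / np.asarray(tau_m) > 0.1):
        warnings.warn(
            "tau_s/tau_m > 0.1: the boundary-shift approximation assumes a "
            "synaptic time constant much smaller than the membrane time "
            "constant", stacklevel=2)
    scalar = np.isscalar(mu) or np.ndim(mu) == 0
    out = _vectorized_rate(mu, sigma, tau_m, tau_s, tau_r, V_th_rel, V_0_rel,
                           shifted=True)
    return float(out[0]) if scalar and out.size == 1 else out


def rescaled_bounds(mu, sigma, tau_m, tau_s, V_th_rel, V_0_rel) -> RescaledBounds:
    """Dimensionless reset/threshold bounds and their colored-noise shifts."""
    mu, sigma, tau_m, tau_s, V_th_rel, V_0_rel = np.broadcast_arrays(
        *np.atleast_1d(mu, sigma, tau_m, tau_s, V_th_rel, V_0_rel))
    y0 = (V_0_rel - mu) / sigma
    yth = (V_th_rel - mu) / sigma
    shift = COLORED_NOISE_ALPHA / 2.0 * np.sqrt(tau_s / tau_m)
    return RescaledBounds(y0=y0, yth=yth, y0_cn=y0 + shift, yth_cn=yth + shift)


# ---------------------------------------------------------------------------
# self-consistency solvers


def _rate_map(net: PopulationNetwork):
    shifted = bool(np.any(net.tau_s > 0))

    def f(nu):
        stats = input_stats(net, nu)
        return _vectorized_rate(stats.mu, stats.sigma, net.tau_m, net.tau_s,
                                net.tau_r, net.V_th_rel, net.V_0_rel, shifted)

    return f


def _as_working_point(net: PopulationNetwork, nu) -> WorkingPoint:
    return WorkingPoint(nu=nu, stats=input_stats(net, nu))


def solve_rates_ode(net: PopulationNetwork,
                    analysis: AnalysisParams | None = None) -> WorkingPoint:
    """Self-consistent rates via the auxiliary ODE ``nu' = -nu + phi(nu)``."""
    analysis = analysis or AnalysisParams()
    nu0 = analysis.nu_init
    if nu0 is None:
        nu0 = np.zeros(net.P)
    f = _rate_map(net)
    nu = fixed_point_ode(f, nu0, tol=analysis.tol_ode, t_max=analysis.t_max,
                         lower=0.0, upper=1.0 / net.tau_r)
    return _as_working_point(net, nu)


def solve_rates_lstsq(net: PopulationNetwork,
                      analysis: AnalysisParams | None = None) -> WorkingPoint:
    """Self-consistent rates via bounded least squares from ``nu_init``.

    Raises :class:`NotSelfConsistentError` when the optimizer settles in a
    local minimum with non-vanishing deviation; such a point is not a
    solution of the self-consistency problem.
    """
    analysis = analysis or AnalysisParams()
    nu0 = analysis.nu_init
    if nu0 is None:
        nu0 = np.zeros(net.P)
    f = _rate_map(net)
    nu = fixed_point_lstsq(f, nu0, tol=analysis.tol_lstsq,
                           lower=0.0, upper=1.0 / net.tau_r)
    return _as_working_point(net, nu)


def working_point(net: PopulationNetwork,
                  analysis: AnalysisParams | None = None) -> WorkingPoint:
    """Solve for the working point with the solver named in the analysis
    parameters (default: ODE)."""
    analysis = analysis or AnalysisParams()
    if analysis.solver == "lstsq":
        return solve_rates_lstsq(net, analysis)
    return solve_rates_ode(net, analysis)
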