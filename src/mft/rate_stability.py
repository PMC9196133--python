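"""Mapping the spiking model to a low-pass rate model and delay-induced
linear stability of the spatially structured network.

The pipeline: fix the working point by solving for the external drive,
fit the amplitude of the colored-noise transfer function with a one-pole
low-pass model ``w / (1 + i omega tau)``, attach symmetric spatial
connectivity profiles, and evaluate the temporal eigenvalues of the delayed
rate model on every Lambert-W branch:

    lambda_B(k) = -1/tau + (1/d) W_B( c(k) (d/tau) exp(d/tau) ),

which inverts the characteristic relation ``(1 + lambda tau) = c(k)
exp(-lambda d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .lif_stationary import input_stats, siegert_rate_delta, siegert_rate_exp
from .lif_dynamics import TransferFunction
from .models_io import PopulationNetwork

__all__ = [
    "InfeasibleTargetError", "FitError", "LowPassFit", "SpatialProfile",
    "BranchSpectrum", "external_rates_for_working_point",
    "fit_transfer_function", "profile_ft", "characteristic_eigenvalues",
    "stability_verdict",
]


class InfeasibleTargetError(ValueError):
    """Requested working point needs a negative external rate."""

    def __init__(self, message, rates=None):
        super().__init__(message)
        self.rates = rates


class FitError(RuntimeError):
    pass


@dataclass
class LowPassFit:
    tau: float              # s
    w_E: float              # dimensionless
    w_I: float              # = -g * w_E
    g: float
    eta: float              # combined rms relative amplitude error
    frequencies: np.ndarray
    fitted_amplitude: np.ndarray  # (2, F): model amplitudes for E and I columns


@dataclass
class SpatialProfile:
    """Symmetric, normalized boxcar connectivity density per presynaptic
    population; ``halfwidth`` in meters."""
    halfwidth: np.ndarray
    kind: str = "boxcar"

    def __post_init__(self):
        self.halfwidth = np.atleast_1d(np.asarray(self.halfwidth, dtype=float))
        if self.kind != "boxcar":
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if np.any(self.halfwidth <= 0):
            raise ValueError("profile halfwidth must be positive")


@dataclass
class BranchSpectrum:
    wavenumbers: np.ndarray     # 1/m
    branches: list
    eigenvalues: np.ndarray     # complex, (|B|, |k|), 1/s
    tau: float
    delay: float
    c_of_k: np.ndarray
    lambda_star: complex = field(init=False)
    k_star: float = field(init=False)

    def __post_init__(self):
        b0 = self.branches.index(0)
        lam0 = self.eigenvalues[b0]
        finite = np.isfinite(lam0.real)
        j = int(np.argmax(np.where(finite, lam0.real, -np.inf)))
        self.lambda_star = complex(lam0[j])
        self.k_star = float(self.wavenumbers[j])


# ---------------------------------------------------------------------------
# working point calibration


def external_rates_for_working_point(net: PopulationNetwork, target_mu,
                                     target_sigma):
    """External (excitatory, inhibitory) Poisson rates that realize the
    target working point ``(mu, sigma)`` for every population.

    The recurrent contribution is evaluated at the self-consistent internal
    rate implied by the target, ``nu = phi(target_mu, target_sigma)``; the
    two external rates then solve the remaining 2x2 linear system in the
    mean and variance.  Requires an external pair with opposite signs
    (same relative inhibition as the recurrent connections).
    """
    target_mu = float(target_mu)
    target_sigma = float(target_sigma)
    if net.nu_ext.size != 2:
        raise ValueError("needs exactly two external sources (E and I)")
    if np.any(net.tau_s > 0):
        nu_int = siegert_rate_exp(target_mu, target_sigma, net.tau_m,
                                  net.tau_s, net.tau_r, net.V_th_rel,
                                  net.V_0_rel)
    else:
        nu_int = siegert_rate_delta(target_mu, target_sigma, net.tau_m,
                                    net.tau_r, net.V_th_rel, net.V_0_rel)
    nu_int = np.atleast_1d(nu_int)
    rec_mu = (net.J * net.K) @ nu_int
    rec_var = (net.J ** 2 * net.K) @ nu_int
    rates = None
    for a in range(net.P):
        A = np.array([
            net.J_ext[a] * net.K_ext[a],
            net.J_ext[a] ** 2 * net.K_ext[a],
        ])
        rhs = np.array([
            target_mu / net.tau_m[a] - rec_mu[a],
            target_sigma ** 2 / net.tau_m[a] - rec_var[a],
        ])
        sol = np.linalg.solve(A, rhs)
        if rates is None:
            rates = sol
        elif not np.allclose(sol, rates, rtol=1e-8, atol=1e-6):
            raise ValueError(
                "populations are not homogeneous: external-rate solutions "
                "differ between rows")
    if np.any(rates < -1e-9):
        raise InfeasibleTargetError(
            f"target working point requires negative external rates "
            f"{rates}", rates=rates)
    return float(max(rates[0], 0.0)), float(max(rates[1], 0.0))


# ---------------------------------------------------------------------------
# transfer-function fit


def _reduce_to_columns(net: PopulationNetwork, tf: TransferFunction,
                       row_tol: float = 1e-6):
    """Reduce tau_m * N(omega) * (J o K) to per-presynaptic-population
    columns; the rows must agree (identical postsynaptic dynamics)."""
    JK = net.J * net.K
    target = (net.tau_m[:, np.newaxis, np.newaxis]
              * tf.values[:, np.newaxis, :]
              * JK[:, :, np.newaxis])            # (post, pre, F)
    ref = target[0]
    scale = np.max(np.abs(ref))
    if np.max(np.abs(target - ref[np.newaxis])) > row_tol * scale:
        raise ValueError(
            "postsynaptic rows of tau_m N J*K differ beyond tolerance; "
            "select a row explicitly before fitting")
    return ref                                    # (pre, F)


def fit_transfer_function(tf: TransferFunction, net: PopulationNetwork,
                          g: float | None = None) -> LowPassFit:
    """Fit ``|w_b / (1 + i omega tau)|`` to ``|tau_m N_cn,s J o K|`` by
    nonlinear least squares over (tau, w_E), with the inhibitory weight
    structurally tied to the excitatory one, ``w_I = -g w_E``.

    ``g`` defaults to the network's weight ratio ``|J_I| / J_E``.
    """
    target = _reduce_to_columns(net, tf)
    amp = np.abs(target)                          # (2, F)
    if amp.shape[0] != 2:
        raise ValueError("low-pass fit expects an E/I network (2 columns)")
    if g is None:
        g = float(np.abs(net.J[0, 1]) / net.J[0, 0])
    omega = 2.0 * np.pi * tf.frequencies
    data = np.concatenate([amp[0], amp[1]])

    def model(_, tau, w_E):
        lp = 1.0 / np.abs(1.0 + 1j * omega * tau)
        return np.concatenate([w_E * lp, g * w_E * lp])

    w0 = max(amp[0, 0], 1e-12)
    tau0 = float(np.mean(net.tau_m))
    try:
        popt, _ = optimize.curve_fit(
            model, None, data, p0=[tau0, w0],
            bounds=([1e-12, 1e-12], [1.0, 1e3]),
            x_scale=[tau0, w0], xtol=3e-16, ftol=3e-16, gtol=3e-16)
    except RuntimeError as exc:
        raise FitError(f"low-pass fit did not converge: {exc}") from exc
    tau, w_E = float(popt[0]), float(popt[1])
    if tau <= 0:
        raise FitError("fitted time constant is nonpositive")
    fitted = model(None, tau, w_E).reshape(2, -1)
    rel = (fitted - np.vstack([amp[0], amp[1]])) / np.where(amp == 0, 1.0, amp)
    eta = float(np.sqrt(np.mean(rel ** 2)))
    return LowPassFit(tau=tau, w_E=w_E, w_I=-g * w_E, g=g, eta=eta,
                      frequencies=tf.frequencies, fitted_amplitude=fitted)


# ---------------------------------------------------------------------------
# spatial profiles and the characteristic equation


def profile_ft(profile: SpatialProfile, k):
    """Fourier transform of the normalized boxcar density of halfwidth R:
    ``sin(kR)/(kR)`` with the k=0 limit 1.  Shape (n_pops, |k|)."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    kR = np.outer(profile.halfwidth, k)
    return np.sinc(kR / np.pi)


def characteristic_eigenvalues(fit: LowPassFit, profile: SpatialProfile,
                               delay: float, k, branches=None) -> BranchSpectrum:
    """Temporal eigenvalues ``lambda_B(k)`` of the delayed spatial rate model
    for every requested Lambert-W branch."""
    if delay <= 0:
        raise ValueError("delay must be positive")
    branches = list(branches) if branches is not None else list(range(-3, 4))
    if 0 not in branches:
        branches.append(0)
    k = np.atleast_1d(np.asarray(k, dtype=float))
    weights = np.array([fit.w_E, fit.w_I])
    p_hat = profile_ft(profile, k)                # (2, |k|)
    c = weights @ p_hat                           # effective profile c(k)
    tau = fit.tau
    arg = c * (delay / tau) * np.exp(delay / tau)
    lam = np.empty((len(branches), k.size), dtype=complex)
    n_failed = 0
    for i, B in enumerate(branches):
        with np.errstate(invalid="ignore"):
            W = special.lambertw(arg, k=B)
        lam[i] = -1.0 / tau + W / delay
        bad = ~np.isfinite(lam[i])
        if np.any(bad):
            n_failed += int(np.sum(bad))
            lam[i][bad] = complex(np.nan, np.nan)
    if n_failed:
        import warnings
        warnings.warn(f"{n_failed} branch evaluations failed and were masked",
                      stacklevel=2)
    return BranchSpectrum(wavenumbers=k, branches=branches, eigenvalues=lam,
                          tau=tau, delay=delay, c_of_k=c)


def characteristic_residual(spectrum: BranchSpectrum) -> np.ndarray:
    """|(1 + lambda tau) - c(k) exp(-lambda d)| for every stored eigenvalue;
    independent of the Lambert-W branch bookkeeping."""
    lam = spectrum.eigenvalues
    c = spectrum.c_of_k[np.newaxis, :]
    return np.abs((1.0 + lam * spectrum.tau)
                  - c * np.exp(-lam * spectrum.delay))


def stability_verdict(spectrum: BranchSpectrum) -> dict:
    """Classify the spectrum by the principal-branch eigenvalue with the
    largest real part."""
    lam = spectrum.lambda_star
    k_star = spectrum.k_star
    if lam.real <= 0:
        kind = "stable"
    elif abs(lam.imag) > 1e-12:
        kind = "oscillatory"
    else:
        kind = "static"
    freq = lam.imag / (2.0 * np.pi)
    velocity = lam.imag / k_star if k_star != 0 else np.nan
    return {
        "verdict": kind,
        "lambda_star": lam,
        "k_star": k_star,
        "oscillation_frequency": freq,
        "phase_velocity": velocity,
    }
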