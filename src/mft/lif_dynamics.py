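"""Linear-response machinery for LIF networks.

Transfer functions built from parabolic cylinder functions, Fourier-domain
delay kernels, the effective connectivity matrix, population power spectra,
and the eigenvalue sensitivity measure with its amplitude/frequency
projections.

Conventions
-----------
Public interfaces take ordinary frequencies ``f`` in Hz; ``omega = 2 pi f``
is used internally.  The rescaled variable entering the parabolic cylinder
functions is ``x = sqrt(2) (mu - V) / sigma`` (minus the colored-noise shift
for the ``cn`` variants).  The transfer function carries the stationary
refractory factor ``(1 - nu tau_r)`` so that its zero-frequency limit equals
the derivative of the stationary rate with respect to the mean input.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy import linalg, optimize, special

from .lif_stationary import COLORED_NOISE_ALPHA, WorkingPoint
from .models_io import PopulationNetwork

__all__ = [
    "PrecisionError", "SingularityError", "DegeneracyError", "TrackingError",
    "TransferFunction", "DelayKernel", "EffectiveConnectivity", "PowerSpectra",
    "SensitivityOutput", "phi_omega", "transfer_function", "delay_kernel",
    "effective_connectivity", "power_spectra", "sensitivity_measure",
    "sensitivity_all_eigenmodes",
]

VARIANTS = ("delta", "cn_shift", "cn_shift_filtered")


class PrecisionError(ArithmeticError):
    """Evaluation outside the supported accuracy box."""


class SingularityError(RuntimeError):
    """(1 - M(omega)) singular: the system sits at an instability."""


class DegeneracyError(RuntimeError):
    """Effective connectivity not safely diagonalizable."""


class TrackingError(RuntimeError):
    """Eigenmode identity could not be followed across the frequency grid."""


@dataclass
class TransferFunction:
    values: np.ndarray          # complex, (P, F), units 1/(V s)
    frequencies: np.ndarray     # Hz, (F,)
    variant: str


@dataclass
class DelayKernel:
    values: np.ndarray          # complex, (P, P, F)
    frequencies: np.ndarray
    kind: str
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class EffectiveConnectivity:
    values: np.ndarray          # complex, (F, P, P), dimensionless
    frequencies: np.ndarray


@dataclass
class PowerSpectra:
    values: np.ndarray          # real, (P, F), 1/s
    frequencies: np.ndarray


@dataclass
class SensitivityOutput:
    Z: np.ndarray               # complex (P, P)
    Z_amp: np.ndarray           # real (P, P)
    Z_freq: np.ndarray          # real (P, P)
    mode: int
    eigenvalue: complex
    frequency: float            # Hz
    left_eigenvector: np.ndarray
    right_eigenvector: np.ndarray


# ---------------------------------------------------------------------------
# parabolic cylinder building block

_MP_DPS = 30


def phi_omega(x: float, omega: float, tau_m: float):
    """Return ``(Phi, dPhi/dx)`` of ``Phi(x) = exp(x^2/4) U(i omega tau_m - 1/2, x)``.

    The exponential prefactor is fused with the decay of the parabolic
    cylinder function ``U`` by evaluating the product in arbitrary precision,
    so no overflowing intermediate is formed; the derivative uses the
    recurrence ``dPhi/dx = -i omega tau_m exp(x^2/4) U(i omega tau_m + 1/2, x)``.
    """
    if not (np.isfinite(x) and np.isfinite(omega) and np.isfinite(tau_m)):
        raise ValueError("arguments must be finite")
    with mp.workdps(_MP_DPS):
        a = mp.mpc(-0.5, omega * tau_m)
        pref = mp.exp(mp.mpf(x) ** 2 / 4)
        val = pref * mp.pcfu(a, x)
        dval = -mp.mpc(0, omega * tau_m) * pref * mp.pcfu(a + 1, x)
        val_c, dval_c = complex(val), complex(dval)
    if not (np.isfinite(val_c.real) and np.isfinite(val_c.imag)
            and np.isfinite(dval_c.real) and np.isfinite(dval_c.imag)):
        raise PrecisionError(
            f"Phi evaluation overflows double precision at x={x}, "
            f"omega*tau_m={omega * tau_m} (growing direction of U)")
    return val_c, dval_c


def _dc_gain(nu, mu, sigma, tau_m, V_th_rel, V_0_rel, shift):
    """Exact zero-frequency gain: d(phi)/d(mu) of the (shifted) Siegert rate."""
    yth = (V_th_rel - mu) / sigma + shift
    y0 = (V_0_rel - mu) / sigma + shift
    return nu ** 2 * tau_m * np.sqrt(np.pi) / sigma * (
        special.erfcx(-yth) - special.erfcx(-y0))


def _transfer_scalar(f, nu, mu, sigma, tau_m, tau_r, V_th_rel, V_0_rel, shift):
    """Linear-response gain of one population at ordinary frequency f (Hz)."""
    if f == 0.0:
        return complex(_dc_gain(nu, mu, sigma, tau_m, V_th_rel, V_0_rel, shift))
    omega = 2.0 * np.pi * f
    sq2 = np.sqrt(2.0)
    x_th = sq2 * ((mu - V_th_rel) / sigma - shift)
    x_0 = sq2 * ((mu - V_0_rel) / sigma - shift)
    Phi_th, dPhi_th = phi_omega(x_th, omega, tau_m)
    Phi_0, dPhi_0 = phi_omega(x_0, omega, tau_m)
    frac = (dPhi_th - dPhi_0) / (Phi_th - Phi_0)
    refractory = 1.0 - nu * tau_r
    return -refractory * sq2 * nu / sigma / (1.0 + 1j * omega * tau_m) * frac


def transfer_function(net: PopulationNetwork, wp: WorkingPoint, freqs,
                      variant: str = "cn_shift_filtered") -> TransferFunction:
    """Per-population transfer function N(omega) on a frequency grid (Hz).

    variant 'delta' uses the unshifted bounds; 'cn_shift' shifts both bounds
    by ``alpha/2 sqrt(tau_s/tau_m)``; 'cn_shift_filtered' additionally
    applies the synaptic low-pass ``1/(1 + i omega tau_s)``.
    """
    if variant == "taylor":
        raise NotImplementedError(
            "the 'taylor' transfer-function variant is not implemented; "
            "use 'cn_shift' or 'cn_shift_filtered'")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    P = net.P
    values = np.empty((P, freqs.size), dtype=complex)
    for a in range(P):
        shift = 0.0
        if variant != "delta":
            shift = COLORED_NOISE_ALPHA / 2.0 * np.sqrt(net.tau_s[a] / net.tau_m[a])
        for j, f in enumerate(freqs):
            values[a, j] = _transfer_scalar(
                f, wp.nu[a], wp.mu[a], wp.sigma[a], net.tau_m[a], net.tau_r[a],
                net.V_th_rel[a], net.V_0_rel[a], shift)
        if variant == "cn_shift_filtered":
            values[a, :] /= 1.0 + 2j * np.pi * freqs * net.tau_s[a]
    return TransferFunction(values=values, frequencies=freqs, variant=variant)


# ---------------------------------------------------------------------------
# delay kernels


def _truncated_gaussian_ft(omega, mean, sd):
    """Characteristic function E[exp(-i omega d)] of a normal distribution
    truncated to d > 0 and renormalized."""
    z_lo = -mean / sd
    norm = special.erfc(z_lo / np.sqrt(2.0))  # 2 * P(d > 0)
    arg = (z_lo + 1j * omega * sd) / np.sqrt(2.0)
    return (np.exp(-1j * omega * mean - omega ** 2 * sd ** 2 / 2.0)
            * special.erfc(arg) / norm)


def delay_kernel(net: PopulationNetwork, freqs) -> DelayKernel:
    """Fourier-transformed delay distributions D_ab(omega), shape (P, P, F)."""
    if np.any(net.delay_sd < 0):
        raise ValueError("delay sd must be nonnegative")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    omega = 2.0 * np.pi * freqs
    P = net.P
    values = np.empty((P, P, freqs.size), dtype=complex)
    for a in range(P):
        for b in range(P):
            d, s = net.delay_mean[a, b], net.delay_sd[a, b]
            if net.delay_kind == "delta" or s == 0.0:
                values[a, b, :] = np.exp(-1j * omega * d)
            elif net.delay_kind == "truncated_gaussian":
                values[a, b, :] = _truncated_gaussian_ft(omega, d, s)
            else:
                raise ValueError(f"unknown delay kind {net.delay_kind!r}")
    return DelayKernel(values=values, frequencies=freqs, kind=net.delay_kind,
                       mean=net.delay_mean, sd=net.delay_sd)


# ---------------------------------------------------------------------------
# effective connectivity and power spectra


def effective_connectivity(net: PopulationNetwork, tf: TransferFunction,
                           dk: DelayKernel) -> EffectiveConnectivity:
    """M(omega)_ab = tau_m_a N_a(omega) J_ab K_ab D_ab(omega), shape (F, P, P)."""
    if not np.array_equal(tf.frequencies, dk.frequencies):
        raise ValueError("transfer function and delay kernel grids differ")
    JK = net.J * net.K
    # (F, P, P): frequency axis first so each slice is one matrix
    M = (net.tau_m[np.newaxis, :, np.newaxis]
         * tf.values.T[:, :, np.newaxis]
         * JK[np.newaxis, :, :]
         * np.moveaxis(dk.values, 2, 0))
    return EffectiveConnectivity(values=M, frequencies=tf.frequencies)


def power_spectra(net: PopulationNetwork, wp: WorkingPoint,
                  tf: TransferFunction, dk: DelayKernel) -> PowerSpectra:
    """Population-rate power spectra, Eqs. of linear-response theory:

    P_a(omega) = [ (1-M)^-1 diag(nu/n) (1-M(-omega))^-T ]_aa
               = sum_b | [(1-M)^-1]_ab |^2 nu_b / n_b

    computed per frequency by solving linear systems (no explicit inverse).
    """
    M = effective_connectivity(net, tf, dk).values
    F, P = M.shape[0], net.P
    amp = np.sqrt(wp.nu / net.n)
    out = np.empty((P, F))
    eye = np.eye(P, dtype=complex)
    for j in range(F):
        A = eye - M[j]
        try:
            Y = linalg.solve(A, np.diag(amp.astype(complex)))
        except linalg.LinAlgError as exc:
            raise SingularityError(
                f"1 - M(omega) singular at f = {tf.frequencies[j]} Hz"
            ) from exc
        if not np.all(np.isfinite(Y)):
            raise SingularityError(
                f"1 - M(omega) singular at f = {tf.frequencies[j]} Hz")
        out[:, j] = np.sum(np.abs(Y) ** 2, axis=1)
    return PowerSpectra(values=out, frequencies=tf.frequencies)


# ---------------------------------------------------------------------------
# sensitivity measure

_EIG_COND_MAX = 1e10


def _eig_with_left(M):
    lam, vl, vr = linalg.eig(M, left=True, right=True)
    cond = np.linalg.cond(vr)
    if not np.isfinite(cond) or cond > _EIG_COND_MAX:
        raise DegeneracyError(
            f"effective connectivity close to defective "
            f"(eigenvector condition number {cond:.2e})")
    # scipy returns vl with vl^H M = lam vl^H; the left eigenvector v with
    # v^T M = lam v^T is the conjugate of the returned column
    return lam, vl.conj(), vr


def _freq_index(tf: TransferFunction, frequency: float) -> int:
    j = int(np.argmin(np.abs(tf.frequencies - frequency)))
    if not np.isclose(tf.frequencies[j], frequency, rtol=0, atol=1e-9):
        raise ValueError(
            f"frequency {frequency} Hz is not on the transfer-function grid")
    return j


def _sensitivity_at(M, mode, frequency):
    lam, vls, vrs = _eig_with_left(M)
    if mode == "closest":
        mode = int(np.argmin(np.abs(1.0 - lam)))
    v = vls[:, mode]
    u = vrs[:, mode]
    Z = np.outer(v, u) * M / (v @ u)
    lam_b = lam[mode]
    direction = 1.0 - lam_b
    if direction == 0:
        raise SingularityError("eigenvalue exactly at the instability 1+0i")
    e = direction / abs(direction)
    Z_amp = np.real(Z * np.conj(e))
    Z_freq = np.imag(Z * np.conj(e))
    return SensitivityOutput(
        Z=Z, Z_amp=Z_amp, Z_freq=Z_freq, mode=mode, eigenvalue=lam_b,
        frequency=float(frequency), left_eigenvector=v, right_eigenvector=u)


def sensitivity_measure(net: PopulationNetwork, wp: WorkingPoint,
                        tf: TransferFunction, dk: DelayKernel,
                        frequency: float, mode="closest") -> SensitivityOutput:
    """Sensitivity of one eigenvalue of M(omega) to relative in-degree
    perturbations, ``Z_cd = v_c M_cd u_d / (v . u)``, evaluated at one grid
    frequency; ``mode='closest'`` selects the eigenvalue nearest 1+0i."""
    j = _freq_index(tf, frequency)
    M = effective_connectivity(net, tf, dk).values[j]
    return _sensitivity_at(M, mode, tf.frequencies[j])


def _track_modes(lams, vecs, min_overlap):
    """Reorder eigenvalue trajectories across the frequency grid by maximal
    eigenvector overlap between adjacent grid points."""
    F, P = lams.shape
    order = np.arange(P)
    tracked_lam = np.empty_like(lams)
    tracked_idx = np.empty((F, P), dtype=int)
    prev = vecs[0]
    tracked_lam[0] = lams[0]
    tracked_idx[0] = order
    for j in range(1, F):
        overlap = np.abs(prev.conj().T @ vecs[j])  # (tracked, new)
        row, col = optimize.linear_sum_assignment(-overlap)
        if np.any(overlap[row, col] < min_overlap):
            raise TrackingError(
                f"eigenmode overlap dropped below {min_overlap} between "
                f"adjacent frequencies (grid too coarse near index {j})")
        perm = np.empty(P, dtype=int)
        perm[row] = col
        tracked_lam[j] = lams[j][perm]
        tracked_idx[j] = perm
        prev = vecs[j][:, perm]
    return tracked_lam, tracked_idx


def sensitivity_all_eigenmodes(net: PopulationNetwork, wp: WorkingPoint,
                               tf: TransferFunction, dk: DelayKernel,
                               min_overlap: float = 0.3):
    """For each eigenmode trajectory, evaluate the sensitivity measure at the
    frequency where that mode is closest to the instability 1+0i.

    Modes are matched between adjacent grid frequencies by maximal
    eigenvector overlap; ties in the distance to instability resolve to the
    lower frequency."""
    M_all = effective_connectivity(net, tf, dk).values
    F, P = M_all.shape[0], net.P
    lams = np.empty((F, P), dtype=complex)
    vecs = np.empty((F, P, P), dtype=complex)
    for j in range(F):
        lam, _, vr = _eig_with_left(M_all[j])
        lams[j] = lam
        vecs[j] = vr / np.linalg.norm(vr, axis=0, keepdims=True)
    tracked_lam, tracked_idx = _track_modes(lams, vecs, min_overlap)
    outputs = []
    for b in range(P):
        dist = np.abs(1.0 - tracked_lam[:, b])
        j_star = int(np.argmin(dist))  # argmin returns the first (lowest f) tie
        outputs.append(_sensitivity_at(
            M_all[j_star], int(tracked_idx[j_star, b]), tf.frequencies[j_star]))
    return outputs
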