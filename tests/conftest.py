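"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the Siegert
oracle integrates the raw first-passage integrand with arbitrary-precision
adaptive quadrature, and calibration helpers use plain bracketed root
finding on top of it.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np
import pytest
from scipy import optimize

from mft import fixtures as fx
from mft import lif_stationary as stat

# Parameters of the single-neuron examples: V_th = 20 mV, V_0 = 15 mV,
# tau_m = 20 ms, tau_s = 0.5 ms, tau_r = 2 ms.
FIG_PARAMS = dict(tau_m=20e-3, tau_s=0.5e-3, tau_r=2e-3,
                  V_th_rel=20e-3, V_0_rel=15e-3)


def siegert_oracle(mu, sigma, tau_m, tau_r, V_th_rel, V_0_rel, shift=0.0,
                   dps=50):
    """Arbitrary-precision adaptive quadrature of the raw first-passage
    integrand exp(s^2)(1+erf(s)) = exp(s^2) erfc(-s)."""
    with mp.workdps(dps):
        y0 = (mp.mpf(V_0_rel) - mp.mpf(mu)) / mp.mpf(sigma) + mp.mpf(shift)
        yth = (mp.mpf(V_th_rel) - mp.mpf(mu)) / mp.mpf(sigma) + mp.mpf(shift)
        points = [y0, 0, yth] if y0 < 0 < yth else [y0, yth]
        integral = mp.quad(lambda s: mp.exp(s * s) * mp.erfc(-s), points)
        return float(1 / (tau_r + tau_m * mp.sqrt(mp.pi) * integral))


def calibrate_mu(target_rate, sigma, shifted=True, **params):
    """Mean input giving the requested stationary rate (bracketed search)."""
    p = {**FIG_PARAMS, **params}
    if shifted:
        rate = lambda m: stat.siegert_rate_exp(
            m, sigma, p["tau_m"], p["tau_s"], p["tau_r"],
            p["V_th_rel"], p["V_0_rel"])
    else:
        rate = lambda m: stat.siegert_rate_delta(
            m, sigma, p["tau_m"], p["tau_r"], p["V_th_rel"], p["V_0_rel"])
    return optimize.brentq(lambda m: rate(m) - target_rate, -0.2, 0.2,
                           xtol=1e-14)


@pytest.fixture(scope="session")
def ei_delta():
    return fx.make_network(fx.FixtureSpec("ei_delta"))


@pytest.fixture(scope="session")
def ei_exp():
    return fx.make_network(fx.FixtureSpec("ei_exp"))


@pytest.fixture(scope="session")
def ei_exp_wp(ei_exp):
    return stat.solve_rates_ode(ei_exp)


@pytest.fixture(scope="session")
def ring_net():
    return fx.make_network(fx.FixtureSpec("ring_spatial"))
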