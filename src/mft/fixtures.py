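"""Deterministic parameter-set generators for tests and examples.

The flavors mirror the classic example networks of the mean-field
literature in structure only: a two-population EI network with delta or
exponential synapses, an eight-population laminar circuit with plausible
(not publication-exact) numbers, and a spatially structured ring network
with boxcar profiles and wider excitation than inhibition.

All generators are pure functions of their :class:`FixtureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models_io import PopulationNetwork
from .rate_stability import SpatialProfile

__all__ = ["FixtureSpec", "make_network", "sweep", "random_network",
           "FLAVORS"]

FLAVORS = ("ei_delta", "ei_exp", "microcircuit_like", "ring_spatial")


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    flavor: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flavor not in FLAVORS:
            raise FixtureSpecError(
                f"unknown flavor {self.flavor!r}; choose from {FLAVORS}")


def _ei_network(tau_s: float) -> PopulationNetwork:
    J_E = 0.2e-3
    g = 5.0
    return PopulationNetwork(
        labels=["E", "I"],
        n=[8000, 2000],
        J=[[J_E, -g * J_E], [J_E, -g * J_E]],
        K=[[400.0, 100.0], [400.0, 100.0]],
        J_ext=[[J_E], [J_E]],
        K_ext=[[400.0], [400.0]],
        nu_ext=[20.0],
        tau_m=20e-3, tau_s=tau_s, tau_r=2e-3,
        V_th_rel=20e-3, V_0_rel=0.0,
        delay_mean=1.5e-3, delay_sd=0.0, delay_kind="delta",
    )


def _microcircuit_like() -> PopulationNetwork:
    labels = ["2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I"]
    n = np.array([20000, 5000, 22000, 5500, 5000, 1000, 14000, 3000], float)
    # plausible laminar in-degrees: strong intra-layer loops, weak
    # inter-layer feed-forward coupling
    base = np.array([
        [200, 400, 100, 120, 60, 0, 20, 0],
        [250, 300, 80, 90, 100, 0, 10, 0],
        [30, 20, 180, 350, 20, 5, 80, 0],
        [120, 10, 200, 320, 10, 0, 150, 0],
        [180, 120, 120, 10, 160, 250, 40, 0],
        [100, 60, 60, 5, 120, 200, 20, 0],
        [40, 20, 50, 40, 110, 40, 90, 300],
        [70, 5, 10, 2, 60, 20, 130, 220],
    ], dtype=float)
    J_E = 0.15e-3
    g = 4.0
    exc = np.array([not lab.endswith("I") for lab in labels])
    col_sign = np.where(exc, 1.0, -g)
    J = np.tile(col_sign * J_E, (8, 1))
    d_e, d_i = 1.5e-3, 0.75e-3
    dm = np.where(exc[np.newaxis, :], d_e, d_i) * np.ones((8, 1))
    ds = dm / 2.0
    return PopulationNetwork(
        labels=labels, n=n, J=J, K=base,
        J_ext=np.full((8, 1), J_E),
        K_ext=np.array([1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100],
                       float).reshape(8, 1),
        nu_ext=[8.0],
        tau_m=10e-3, tau_s=0.5e-3, tau_r=2e-3,
        V_th_rel=15e-3, V_0_rel=0.0,
        delay_mean=dm, delay_sd=ds, delay_kind="truncated_gaussian",
    )


def _ring_spatial() -> PopulationNetwork:
    J_E = 0.01e-3
    g = 5.0
    net = PopulationNetwork(
        labels=["E", "I"],
        n=[4000, 1000],
        J=[[J_E, -g * J_E], [J_E, -g * J_E]],
        K=[[1000.0, 250.0], [1000.0, 250.0]],
        J_ext=[[J_E, -g * J_E], [J_E, -g * J_E]],
        K_ext=[[1000.0, 250.0], [1000.0, 250.0]],
        nu_ext=[80.0, 20.0],
        tau_m=20e-3, tau_s=0.5e-3, tau_r=2e-3,
        V_th_rel=20e-3, V_0_rel=0.0,
        delay_mean=1.5e-3, delay_sd=0.0, delay_kind="delta",
    )
    # boxcar halfwidths per presynaptic population: wider excitation
    net.spatial_profile = SpatialProfile(halfwidth=[1.0e-3, 0.5e-3])
    return net


def _apply_override(net: PopulationNetwork, path: str, value):
    if "." in path:
        attr, idx = path.split(".", 1)
        if not hasattr(net, attr):
            raise FixtureSpecError(f"override path {path!r} not found")
        arr = np.array(getattr(net, attr), dtype=float)
        try:
            arr.flat[int(idx)] = value
        except (ValueError, IndexError) as exc:
            raise FixtureSpecError(f"bad override index in {path!r}") from exc
        return net.with_overrides(**{attr: arr})
    if not hasattr(net, path):
        raise FixtureSpecError(f"override path {path!r} not found")
    return net.with_overrides(**{path: value})


def make_network(spec: FixtureSpec) -> PopulationNetwork:
    """Build the fully validated network for a fixture spec."""
    if spec.flavor == "ei_delta":
        net = _ei_network(tau_s=0.0)
    elif spec.flavor == "ei_exp":
        net = _ei_network(tau_s=0.5e-3)
    elif spec.flavor == "microcircuit_like":
        net = _microcircuit_like()
    elif spec.flavor == "ring_spatial":
        net = _ring_spatial()
    else:  # pragma: no cover - guarded by FixtureSpec
        raise FixtureSpecError(spec.flavor)
    profile = getattr(net, "spatial_profile", None)
    for path, value in spec.overrides.items():
        net = _apply_override(net, path, value)
    if profile is not None:
        net.spatial_profile = profile
    net.validate()
    return net


def sweep(spec: FixtureSpec, path: str, values):
    """One network per value of the swept parameter, all else fixed."""
    attr = path.split(".", 1)[0]
    if not hasattr(make_network(spec), attr):
        raise FixtureSpecError(f"sweep path {path!r} not found")
    return [
        make_network(FixtureSpec(spec.flavor, spec.seed,
                                 {**spec.overrides, path: v}))
        for v in values
    ]


def random_network(P: int, seed: int, zero_fraction: float = 0.2,
                   tau_s: float = 0.5e-3) -> PopulationNetwork:
    """Random small network with signed columns and some absent connections;
    used for property tests of the linear-response machinery."""
    rng = np.random.default_rng(seed)
    exc = rng.random(P) < 0.6
    exc[0] = True
    J_mag = rng.uniform(0.05e-3, 0.2e-3, size=(P, P))
    J = np.where(exc[np.newaxis, :], J_mag, -5.0 * J_mag)
    K = rng.integers(30, 150, size=(P, P)).astype(float)
    K[rng.random((P, P)) < zero_fraction] = 0.0
    labels = [f"P{i}{'E' if exc[i] else 'I'}" for i in range(P)]
    return PopulationNetwork(
        labels=labels,
        n=rng.integers(1000, 20000, size=P).astype(float),
        J=J, K=K,
        J_ext=np.full((P, 1), 0.15e-3),
        K_ext=np.full((P, 1), float(rng.integers(800, 2500))),
        nu_ext=[8.0],
        tau_m=rng.uniform(10e-3, 25e-3), tau_s=tau_s, tau_r=2e-3,
        V_th_rel=rng.uniform(12e-3, 22e-3), V_0_rel=0.0,
        delay_mean=rng.uniform(0.5e-3, 2e-3, size=(P, P)),
        delay_sd=rng.uniform(0.1e-3, 0.5e-3, size=(P, P)),
        delay_kind="truncated_gaussian",
    ).validate()
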