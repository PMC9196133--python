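"""Network/analysis parameter ingestion, validation, caching, and HDF5 I/O.

Parameter files use a small yaml dialect: mapping values are either bare
scalars/lists (unitless) or ``{val: ..., unit: ...}`` mappings; matrices are
nested lists.  Two model flavors are shipped, ``basic_ei`` (two populations,
weight matrix built from a scalar excitatory weight and an inhibition ratio
``g``) and ``microcircuit8`` (eight populations, weights derived from a
post-synaptic current amplitude, in-degrees optionally derived from
connection probabilities).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import yaml

from .units import UnitError, convert_quantity  # noqa: F401  (re-exported)

__all__ = [
    "ValidationError",
    "PopulationNetwork",
    "AnalysisParams",
    "ResultsStore",
    "load_network",
    "load_network_params",
    "load_analysis_params",
    "cache_or_compute",
    "export_results",
    "import_results",
    "params_digest",
]


class ValidationError(ValueError):
    """Raised when a parameter set violates a structural invariant."""


def _as_vector(x, P, name):
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(P, arr.item())
    if arr.shape != (P,):
        raise ValidationError(f"{name}: expected shape ({P},), got {arr.shape}")
    return arr


@dataclass
class PopulationNetwork:
    """Full parameter set of a population-level network model.

    Weights ``J`` are stored *signed* (inhibitory entries negative) in volts,
    so that the input statistics read as plain sums over populations without
    case splits.  External drive is described by ``J_ext`` (P x E, volts),
    ``K_ext`` (P x E, counts) and ``nu_ext`` (E, Hz).
    """

    labels: list
    n: np.ndarray
    J: np.ndarray
    K: np.ndarray
    J_ext: np.ndarray
    K_ext: np.ndarray
    nu_ext: np.ndarray
    tau_m: np.ndarray
    tau_s: np.ndarray
    tau_r: np.ndarray
    V_th_rel: np.ndarray
    V_0_rel: np.ndarray
    delay_mean: np.ndarray = None
    delay_sd: np.ndarray = None
    delay_kind: str = "delta"

    def __post_init__(self):
        P = len(self.labels)
        self.n = _as_vector(self.n, P, "n")
        self.J = np.asarray(self.J, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.J_ext = np.atleast_2d(np.asarray(self.J_ext, dtype=float))
        self.K_ext = np.atleast_2d(np.asarray(self.K_ext, dtype=float))
        if self.J_ext.shape[0] == 1 and P > 1:
            self.J_ext = np.repeat(self.J_ext, P, axis=0)
        if self.K_ext.shape[0] == 1 and P > 1:
            self.K_ext = np.repeat(self.K_ext, P, axis=0)
        self.nu_ext = np.atleast_1d(np.asarray(self.nu_ext, dtype=float))
        for name in ("tau_m", "tau_s", "tau_r", "V_th_rel", "V_0_rel"):
            setattr(self, name, _as_vector(getattr(self, name), P, name))
        if self.delay_mean is None:
            self.delay_mean = np.zeros((P, P))
        if self.delay_sd is None:
            self.delay_sd = np.zeros((P, P))
        self.delay_mean = np.broadcast_to(
            np.asarray(self.delay_mean, dtype=float), (P, P)
        ).copy()
        self.delay_sd = np.broadcast_to(
            np.asarray(self.delay_sd, dtype=float), (P, P)
        ).copy()

    @property
    def P(self) -> int:
        return len(self.labels)

    def validate(self):
        """Check every structural invariant; raise :class:`ValidationError`."""
        P = self.P
        if self.J.shape != (P, P):
            raise ValidationError(f"J: expected shape ({P},{P}), got {self.J.shape}")
        if self.K.shape != (P, P):
            raise ValidationError(f"K: expected shape ({P},{P}), got {self.K.shape}")
        E = self.nu_ext.shape[0]
        if self.J_ext.shape != (P, E):
            raise ValidationError(
                f"J_ext: expected shape ({P},{E}), got {self.J_ext.shape}"
            )
        if self.K_ext.shape != (P, E):
            raise ValidationError(
                f"K_ext: expected shape ({P},{E}), got {self.K_ext.shape}"
            )
        for name in ("tau_m", "tau_r"):
            if np.any(getattr(self, name) <= 0):
                raise ValidationError(f"{name}: must be strictly positive")
        if np.any(self.tau_s < 0):
            raise ValidationError("tau_s: must be nonnegative")
        if np.any(self.V_th_rel <= self.V_0_rel):
            raise ValidationError("V_th_rel must exceed V_0_rel")
        if np.any(self.n <= 0):
            raise ValidationError("n: population sizes must be positive")
        for name in ("K", "K_ext"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name}: in-degrees must be nonnegative")
        if np.any(self.nu_ext < 0):
            raise ValidationError("nu_ext: external rates must be nonnegative")
        if np.any(self.delay_mean < 0) or np.any(self.delay_sd < 0):
            raise ValidationError("delays: mean and sd must be nonnegative")
        if self.delay_kind not in ("delta", "truncated_gaussian"):
            raise ValidationError(f"delay_kind: unknown kind {self.delay_kind!r}")
        return self

    def with_overrides(self, **kwargs) -> "PopulationNetwork":
        return replace(self, **kwargs)


@dataclass
class AnalysisParams:
    """Grids and solver options for the analysis pipeline."""

    frequencies: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 400.0, 401))
    wavenumbers: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 3e4, 200))
    branches: list = field(default_factory=lambda: list(range(-3, 4)))
    solver: str = "ode"
    nu_init: np.ndarray = None
    tol_ode: float = 1e-9
    t_max: float = 200.0
    tol_lstsq: float = 1e-12
    maxiter: int = 100000

    def __post_init__(self):
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        self.wavenumbers = np.atleast_1d(np.asarray(self.wavenumbers, dtype=float))
        if np.any(self.frequencies < 0):
            raise ValidationError("frequencies must be nonnegative")
        if np.any(np.diff(self.frequencies) <= 0) and self.frequencies.size > 1:
            raise ValidationError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("wavenumber grid must be finite")
        if self.solver not in ("ode", "lstsq"):
            raise ValidationError(f"unknown solver {self.solver!r}")


# ---------------------------------------------------------------------------
# yaml flavors


def _req(raw: dict, key: str):
    if key not in raw:
        raise KeyError(f"missing required parameter key {key!r}")
    return raw[key]


def _delay_matrices(raw, P, labels):
    """Build delay mean/sd matrices from either full matrices or per-source
    excitatory/inhibitory scalars (keys d_e, d_i, d_e_sd, d_i_sd)."""
    kind = raw.get("delay_dist", "delta")
    if "delay_mean" in raw:
        dm = np.broadcast_to(convert_quantity(raw["delay_mean"]), (P, P)).copy()
        ds = np.broadcast_to(
            convert_quantity(raw.get("delay_sd", 0.0)), (P, P)
        ).copy()
        return dm, ds, kind
    if "d_e" in raw:
        d_e = convert_quantity(raw["d_e"])
        d_i = convert_quantity(raw.get("d_i", raw["d_e"]))
        d_e_sd = convert_quantity(raw.get("d_e_sd", 0.0))
        d_i_sd = convert_quantity(raw.get("d_i_sd", 0.0))
        exc = np.array([not lab.endswith("I") for lab in labels])
        dm = np.where(exc[np.newaxis, :], d_e, d_i) * np.ones((P, 1))
        ds = np.where(exc[np.newaxis, :], d_e_sd, d_i_sd) * np.ones((P, 1))
        return dm, ds, kind
    return np.zeros((P, P)), np.zeros((P, P)), kind


def _build_basic_ei(raw: dict) -> PopulationNetwork:
    """Two populations E, I.  J from scalar weight J_E and ratio g:
    ``J = [[J_E, -g*J_E], [J_E, -g*J_E]]``.  External columns follow the
    sign pattern ``ext_signs`` (default all excitatory) with the same g.
    """
    labels = ["E", "I"]
    n = convert_quantity(_req(raw, "N"))
    J_E = convert_quantity(_req(raw, "J_E"))
    g = float(convert_quantity(_req(raw, "g")))
    K = np.asarray(convert_quantity(_req(raw, "K")), dtype=float)
    K_ext = np.atleast_1d(np.asarray(convert_quantity(_req(raw, "K_ext")), dtype=float))
    nu_ext = np.atleast_1d(np.asarray(convert_quantity(_req(raw, "nu_ext")), dtype=float))
    if K_ext.ndim == 1:
        K_ext = np.tile(K_ext, (2, 1)) if K_ext.size == nu_ext.size else K_ext.reshape(2, -1)
    ext_signs = np.atleast_1d(np.asarray(raw.get("ext_signs", np.ones(nu_ext.size))))
    J = np.array([[J_E, -g * J_E], [J_E, -g * J_E]])
    J_ext_row = np.where(ext_signs > 0, J_E, -g * J_E)
    J_ext = np.tile(J_ext_row, (2, 1))
    dm, ds, kind = _delay_matrices(raw, 2, labels)
    return PopulationNetwork(
        labels=labels, n=n, J=J, K=K, J_ext=J_ext, K_ext=K_ext, nu_ext=nu_ext,
        tau_m=convert_quantity(_req(raw, "tau_m")),
        tau_s=convert_quantity(raw.get("tau_s", 0.0)),
        tau_r=convert_quantity(_req(raw, "tau_r")),
        V_th_rel=convert_quantity(_req(raw, "V_th_rel")),
        V_0_rel=convert_quantity(_req(raw, "V_0_rel")),
        delay_mean=dm, delay_sd=ds, delay_kind=kind,
    )


MICROCIRCUIT_LABELS = ["2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I"]


def _indegrees_from_probabilities(p, n):
    """In-degrees per target neuron for 'fixed total number' connectivity:
    the expected synapse count solves ``p = 1 - (1 - 1/(n_a n_b))^C``."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    n_prod = np.outer(n, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.log1p(-p) / np.log1p(-1.0 / n_prod)
    C = np.where(p > 0, C, 0.0)
    return C / n[:, np.newaxis]


def _build_microcircuit8(raw: dict) -> PopulationNetwork:
    """Eight populations 2/3E ... 6I.  Weights are derived from the
    post-synaptic current amplitude ``w`` (amperes) via ``J = w*tau_s/C``
    with inhibitory columns scaled by ``-g``; optional multiplicative
    ``weight_scale`` entries adjust individual connections."""
    labels = list(raw.get("populations", MICROCIRCUIT_LABELS))
    P = len(labels)
    if P != 8:
        raise ValidationError("microcircuit8 flavor requires exactly 8 populations")
    n = np.asarray(convert_quantity(_req(raw, "N")), dtype=float)
    tau_s = convert_quantity(_req(raw, "tau_s"))
    C_m = convert_quantity(_req(raw, "C"))
    w = convert_quantity(_req(raw, "w"))
    g = float(convert_quantity(_req(raw, "g")))
    J_unit = w * tau_s / C_m  # voltage jump of one exponential PSC
    exc = np.array([not lab.endswith("I") for lab in labels])
    col_sign = np.where(exc, 1.0, -g)
    J = np.tile(col_sign * J_unit, (P, 1))
    for a, b, factor in raw.get("weight_scale", []):
        J[int(a), int(b)] *= float(factor)
    if "K" in raw:
        K = np.asarray(convert_quantity(raw["K"]), dtype=float)
    else:
        K = _indegrees_from_probabilities(convert_quantity(_req(raw, "conn_probs")), n)
    K_ext = np.asarray(convert_quantity(_req(raw, "K_ext")), dtype=float).reshape(P, 1)
    nu_ext = np.atleast_1d(convert_quantity(_req(raw, "nu_ext")))
    w_ext = convert_quantity(raw.get("w_ext", raw["w"]))
    J_ext = np.full((P, 1), w_ext * tau_s / C_m)
    if "V_th_rel" in raw:
        V_th_rel = convert_quantity(raw["V_th_rel"])
        V_0_rel = convert_quantity(raw["V_0_rel"])
    else:
        E_L = convert_quantity(_req(raw, "E_L"))
        V_th_rel = convert_quantity(_req(raw, "V_th_abs")) - E_L
        V_0_rel = convert_quantity(_req(raw, "V_0_abs")) - E_L
    dm, ds, kind = _delay_matrices(raw, P, labels)
    return PopulationNetwork(
        labels=labels, n=n, J=J, K=K, J_ext=J_ext, K_ext=K_ext, nu_ext=nu_ext,
        tau_m=convert_quantity(_req(raw, "tau_m")),
        tau_s=tau_s,
        tau_r=convert_quantity(_req(raw, "tau_r")),
        V_th_rel=V_th_rel, V_0_rel=V_0_rel,
        delay_mean=dm, delay_sd=ds, delay_kind=kind,
    )


_FLAVORS = {"basic_ei": _build_basic_ei, "microcircuit8": _build_microcircuit8}


def load_network_params(params_file) -> PopulationNetwork:
    with open(params_file) as f:
        raw = yaml.safe_load(f)
    if raw is None:
        raise ValidationError(f"empty parameter file: {params_file}")
    flavor = raw.get("flavor")
    if flavor not in _FLAVORS:
        raise ValidationError(
            f"unknown or missing model flavor {flavor!r}; "
            f"supported: {sorted(_FLAVORS)}"
        )
    net = _FLAVORS[flavor](raw)
    net.validate()
    return net


def load_analysis_params(analysis_file) -> AnalysisParams:
    with open(analysis_file) as f:
        raw = yaml.safe_load(f) or {}
    kwargs = {}
    if "frequencies" in raw:
        kwargs["frequencies"] = convert_quantity(raw["frequencies"])
    elif {"f_min", "f_max", "n_freqs"} <= set(raw):
        kwargs["frequencies"] = np.linspace(
            convert_quantity(raw["f_min"]),
            convert_quantity(raw["f_max"]),
            int(raw["n_freqs"]),
        )
    if "wavenumbers" in raw:
        kwargs["wavenumbers"] = convert_quantity(raw["wavenumbers"])
    for key in ("branches", "solver", "tol_ode", "t_max", "tol_lstsq", "maxiter"):
        if key in raw:
            kwargs[key] = raw[key]
    if "nu_init" in raw:
        kwargs["nu_init"] = np.asarray(convert_quantity(raw["nu_init"]), dtype=float)
    return AnalysisParams(**kwargs)


def load_network(params_file, analysis_file=None):
    """Load a network parameter file (and optionally analysis parameters)."""
    net = load_network_params(params_file)
    analysis = load_analysis_params(analysis_file) if analysis_file else AnalysisParams()
    return net, analysis


# ---------------------------------------------------------------------------
# result store


def _canonical(obj):
    """Canonical, order-independent representation for digesting."""
    if isinstance(obj, dict):
        return {str(k): _canonical(obj[k]) for k in sorted(obj, key=str)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__array__": obj.shape, "data": [float(v).hex() for v in obj.ravel()]}
    if isinstance(obj, (np.floating, float)):
        return float(obj).hex()
    if isinstance(obj, (np.integer, int, bool)) or obj is None:
        return obj
    return str(obj)


def params_digest(params: dict) -> str:
    blob = json.dumps(_canonical(params), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class CacheCollisionError(RuntimeError):
    pass


class ResultsStore:
    """Keyed result cache: (quantity name, parameter digest) -> payload.

    Payloads are dicts mapping dataset names to numpy arrays (scalars are
    stored as 0-d arrays); each entry keeps the creating parameters and an
    optional unit string per dataset.
    """

    def __init__(self):
        self._entries = {}

    def __len__(self):
        return len(self._entries)

    def keys(self):
        return list(self._entries)

    def put(self, name: str, params: dict, payload: dict, units: dict | None = None):
        digest = params_digest(params)
        key = (name, digest)
        if key in self._entries:
            stored = self._entries[key]
            if _canonical(stored["params"]) != _canonical(params):
                raise CacheCollisionError(
                    f"digest collision for {name!r}: differing parameters"
                )
        payload = {
            k: np.array(v) for k, v in payload.items()
        }
        self._entries[key] = {
            "params": params,
            "payload": payload,
            "units": dict(units or {}),
        }
        return digest

    def get(self, name: str, params: dict):
        key = (name, params_digest(params))
        entry = self._entries.get(key)
        if entry is None:
            return None
        if _canonical(entry["params"]) != _canonical(params):
            raise CacheCollisionError(
                f"digest collision for {name!r}: differing parameters"
            )
        return entry["payload"]

    def items(self):
        return self._entries.items()


def cache_or_compute(store: ResultsStore, name: str, params: dict, compute,
                     units: dict | None = None):
    """Return the cached payload for (name, params) or evaluate ``compute``.

    ``compute`` is called with no arguments and must return a payload dict.
    """
    hit = store.get(name, params)
    if hit is not None:
        return hit
    payload = compute()
    if not isinstance(payload, dict):
        payload = {"value": payload}
    store.put(name, params, payload, units=units)
    return store.get(name, params)


def export_results(store: ResultsStore, file):
    """Write the store to HDF5: /<quantity>/<digest>/<dataset> with a string
    attribute ``unit`` per dataset and the creating parameters as JSON."""
    with h5py.File(file, "w") as h5:
        for (name, digest), entry in store.items():
            grp = h5.require_group(name.replace("/", "|")).create_group(digest)
            grp.attrs["params_json"] = json.dumps(_canonical(entry["params"]))
            for dset_name, arr in entry["payload"].items():
                arr = np.asarray(arr)
                if arr.dtype.kind == "U":
                    dset = grp.create_dataset(dset_name, data=arr.astype("S"))
                else:
                    dset = grp.create_dataset(dset_name, data=arr)
                dset.attrs["unit"] = entry["units"].get(dset_name, "")


class ImportError_(RuntimeError):
    pass


def import_results(file) -> ResultsStore:
    store = ResultsStore()
    with h5py.File(file, "r") as h5:
        for name in h5:
            for digest in h5[name]:
                grp = h5[name][digest]
                try:
                    params = json.loads(grp.attrs["params_json"])
                    payload, units = {}, {}
                    for dset_name in grp:
                        arr = grp[dset_name][()]
                        if isinstance(arr, np.ndarray) and arr.dtype.kind == "S":
                            arr = arr.astype("U")
                        payload[dset_name] = np.array(arr)
                        units[dset_name] = grp[dset_name].attrs.get("unit", "")
                except Exception as exc:
                    raise ImportError_(
                        f"unreadable group /{name}/{digest}: {exc}"
                    ) from exc
                store._entries[(name.replace("|", "/"), digest)] = {
                    "params": params, "payload": payload, "units": units,
                }
    return store
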