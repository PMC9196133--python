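"""Unit handling for parameter files.

A deliberately closed set of units is supported; every quantity is converted
to SI on ingestion and all internal computation is unit-free SI.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UnitError", "SI_FACTORS", "to_si", "from_si", "convert_quantity"]


class UnitError(ValueError):
    """Raised for units outside the supported closed set."""


#: Multiplicative factor taking a value in `unit` to SI.
SI_FACTORS: dict[str, float] = {
    "": 1.0,
    "s": 1.0,
    "ms": 1e-3,
    "V": 1.0,
    "mV": 1e-3,
    "A": 1.0,
    "nA": 1e-9,
    "pA": 1e-12,
    "Hz": 1.0,
    "F": 1.0,
    "pF": 1e-12,
    "m": 1.0,
    "mm": 1e-3,
    "1/mm": 1e3,
    "1/m": 1.0,
}


def _factor(unit: str) -> float:
    try:
        return SI_FACTORS[unit]
    except KeyError:
        raise UnitError(
            f"unsupported unit {unit!r}; supported units: "
            f"{sorted(u for u in SI_FACTORS if u)}"
        ) from None


def to_si(value, unit: str = ""):
    """Convert ``value`` (scalar or nested list/array) in ``unit`` to SI."""
    f = _factor(unit)
    arr = np.asarray(value, dtype=float)
    out = arr * f
    return float(out) if out.ndim == 0 else out


def from_si(value, unit: str = ""):
    """Inverse of :func:`to_si`."""
    f = _factor(unit)
    arr = np.asarray(value, dtype=float)
    out = arr / f
    return float(out) if out.ndim == 0 else out


def convert_quantity(entry):
    """Convert a parameter-file entry to an SI value.

    Entries are either bare scalars/lists (unitless) or mappings with the
    keys ``val`` and ``unit``.
    """
    if isinstance(entry, dict):
        unknown = set(entry) - {"val", "unit"}
        if "val" not in entry:
            raise KeyError("quantity mapping requires the key 'val'")
        if unknown:
            raise KeyError(f"unexpected keys in quantity mapping: {sorted(unknown)}")
        return to_si(entry["val"], entry.get("unit", ""))
    return to_si(entry, "")
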