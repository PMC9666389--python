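"""Glucose unit handling.

The package works internally in mmol/L. Conversion to mg/dL uses the molar
mass convention 1 mmol/L = 18.016 mg/dL, under which the UK hypoglycaemia
cutoff of 3.5 mmol/L displays as 63 mg/dL.
"""

from __future__ import annotations

import math

MGDL_PER_MMOLL = 18.016

MMOLL = "mmol/L"
MGDL = "mg/dL"

_ALIASES = {
    "mmol/l": MMOLL,
    "mmol": MMOLL,
    "mmoll": MMOLL,
    "mg/dl": MGDL,
    "mgdl": MGDL,
    "mg": MGDL,
}


class UnitError(ValueError):
    """Raised for unrecognised glucose units."""


def normalize_unit(unit: str) -> str:
    """Return the canonical spelling of a glucose unit string."""
    key = str(unit).strip().lower()
    if key not in _ALIASES:
        raise UnitError(f"unknown glucose unit: {unit!r} (expected mmol/L or mg/dL)")
    return _ALIASES[key]


def convert_units(value, from_unit: str, to_unit: str):
    """Convert a glucose value (scalar or array) between mmol/L and mg/dL.

    No rounding is applied; integer display rounding (e.g. 3.5 mmol/L -> 63
    mg/dL) belongs to the reporting layer, see :func:`display_round`.
    """
    src = normalize_unit(from_unit)
    dst = normalize_unit(to_unit)
    if src == dst:
        return value
    if src == MMOLL and dst == MGDL:
        return value * MGDL_PER_MMOLL
    return value / MGDL_PER_MMOLL


def display_round(value: float, decimals: int = 0) -> float:
    """Round half away from zero, as clinical tables do (2.5 -> 3, not 2)."""
    scale = 10.0 ** decimals
    rounded = math.floor(abs(value) * scale + 0.5) / scale
    rounded = math.copysign(rounded, value)
    return rounded if decimals > 0 else int(rounded)
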