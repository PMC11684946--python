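"""Unit conversions used throughout the package.

Internal computation is carried out in SI (m, Pa, m/s); the reporting layer
uses the conventions of the pulmonary-hemodynamics literature (µm, mm/s,
mmHg).  Only the pairs needed by the workbench are supported; anything else
raises :class:`UnsupportedUnitError`.
"""

from __future__ import annotations

MMHG_PER_PA = 1.0 / 133.322
CMH2O_PER_PA = 1.0 / 98.0665

#: factor that converts *from* the key unit *to* the base unit of its group
_PRESSURE_TO_PA = {"Pa": 1.0, "mmHg": 133.322, "cmH2O": 98.0665}
_VELOCITY_TO_M_S = {"m/s": 1.0, "mm/s": 1e-3}
_LENGTH_TO_M = {"m": 1.0, "um": 1e-6, "µm": 1e-6}

_GROUPS = (_PRESSURE_TO_PA, _VELOCITY_TO_M_S, _LENGTH_TO_M)


class UnsupportedUnitError(ValueError):
    """Raised when a conversion pair is not supported."""


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same physical quantity.

    Supported groups: pressure (Pa, mmHg, cmH2O), velocity (m/s, mm/s) and
    length (m, um).

    >>> round(convert_units(11.5, "cmH2O", "Pa"), 1)
    1127.8
    """
    for group in _GROUPS:
        if from_unit in group and to_unit in group:
            return value * group[from_unit] / group[to_unit]
    raise UnsupportedUnitError(f"unsupported conversion {from_unit!r} -> {to_unit!r}")


def pa_to_mmhg(value_pa: float) -> float:
    return value_pa * MMHG_PER_PA


def mmhg_to_pa(value_mmhg: float) -> float:
    return value_mmhg * 133.322
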