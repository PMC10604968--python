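"""Unit conversions.

All model internals are SI: pressures in Pa, lengths in m (geometry objects
carry mm for readability and are converted once at solver entry),
concentrations in mol/m^3 (1 M = 1e3 mol/m^3), rates in 1/s.
"""

from __future__ import annotations

MMHG_TO_PA = 133.3224
MM_TO_M = 1e-3


def mmhg_to_pa(p: float) -> float:
    """Convert a pressure from mmHg to Pa (1 mmHg = 133.3224 Pa)."""
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


# Multiplicative factors to SI for the unit strings accepted in config files.
_TO_SI = {
    # pressure -> Pa
    "pa": 1.0,
    "kpa": 1e3,
    "mmhg": MMHG_TO_PA,
    # length -> m
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "cm": 1e-2,
    # diffusivity -> m^2/s
    "m^2/s": 1.0,
    "m2/s": 1.0,
    "cm^2/s": 1e-4,
    "cm2/s": 1e-4,
    # speed / permeability -> m/s
    "m/s": 1.0,
    "cm/s": 1e-2,
    "um/s": 1e-6,
    # concentration -> mol/m^3
    "mol/m^3": 1.0,
    "mol/m3": 1.0,
    "molar": 1e3,
    "mm_molar": 1.0,  # 1 mM = 1 mol/m^3
    "um_molar": 1e-3,
    # binding rate -> m^3/(mol s)
    "m^3/(mol*s)": 1.0,
    "1/(m*s)": 1e-3,  # per-molar per-second
    "1/(M*s)": 1e-3,
    # rate -> 1/s
    "1/s": 1.0,
    "1/min": 1.0 / 60.0,
    "1/h": 1.0 / 3600.0,
    # time -> s
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
}

# Case-sensitive molar shorthands resolved before lowercasing.
_CASE_SENSITIVE = {
    "M": 1e3,            # molar -> mol/m^3
    "mM": 1.0,
    "uM": 1e-3,
    "µM": 1e-3,
    "nM": 1e-6,
    "1/(M*s)": 1e-3,
    "M^-1*s^-1": 1e-3,
}


def to_si(value: float, unit: str | None) -> float:
    """Convert ``value`` expressed in ``unit`` to SI.

    ``unit`` of ``None`` or ``"si"`` is a pass-through. Unknown units raise
    ``KeyError`` so config validation can report the offending field.
    """
    if unit is None:
        return value
    u = unit.strip()
    if u in _CASE_SENSITIVE:
        return value * _CASE_SENSITIVE[u]
    u = u.lower().replace(" ", "")
    if u in ("", "si", "-"):
        return value
    return value * _TO_SI[u]
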