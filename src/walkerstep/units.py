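"""Concentration unit handling.

Configuration files and tables accept human-readable concentration tokens
("1 nM", "10 uM", "2.3e-7 M"); everything internal is SI molar.
"""

from __future__ import annotations

import math
import re

__all__ = ["parse_concentration", "format_concentration"]

# Unit keys are lowercased before lookup; both the micro sign and 'u' spellings
# are accepted.
_UNIT_SCALE = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,  # µM
    "μm": 1e-6,  # μM (Greek mu)
    "nm": 1e-9,
    "pm": 1e-12,
    "fm": 1e-15,
}

_TOKEN = re.compile(r"^\s*([+-]?[0-9][0-9_.]*(?:[eE][+-]?[0-9]+)?)\s*([a-zA-Zµμ]+)\s*$")


def parse_concentration(value: str | float | int) -> float:
    """Return a concentration in molar.

    Strings must carry a unit ("10 nM", "0.5uM", "1e-7 M"); bare numbers are
    taken to already be molar. Negative concentrations are rejected.
    """
    if isinstance(value, (int, float)):
        conc = float(value)
        if not math.isfinite(conc) or conc < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {value!r}")
        return conc
    match = _TOKEN.match(value)
    if match is None:
        raise ValueError(
            f"cannot parse concentration {value!r}; expected forms like '10 nM' or '1e-6 M'"
        )
    quantity = float(match.group(1).replace("_", ""))
    unit = match.group(2).lower()
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown concentration unit {match.group(2)!r} in {value!r}")
    conc = quantity * _UNIT_SCALE[unit]
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {value!r}")
    return conc


def format_concentration(conc_molar: float) -> str:
    """Render a molar concentration with the largest unit giving mantissa >= 1."""
    if conc_molar < 0:
        raise ValueError("concentration must be >= 0")
    if conc_molar == 0:
        return "0 M"
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12)):
        if conc_molar >= scale:
            return f"{conc_molar / scale:g} {unit}"
    return f"{conc_molar / 1e-15:g} fM"
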