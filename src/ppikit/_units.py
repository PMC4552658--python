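"""Parsing of SI-prefixed molar concentrations at the CLI surface.

Flags take explicit units, e.g. ``--enzyme 4.34nM`` or ``--ki 11.16uM``;
everything is converted to mol/L internally.
"""

from __future__ import annotations

import re

__all__ = ["parse_molar"]

_PREFIX = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([A-Za-zµμ]*M)\s*$")


def parse_molar(text: str) -> float:
    """Parse '4.34nM' / '80uM' / '1.2e-6M' into mol/L."""
    m = _RE.match(text)
    if not m:
        raise ValueError(
            f"cannot parse concentration {text!r}; expected e.g. '4.34nM', '80uM'"
        )
    value_s, unit = m.groups()
    try:
        value = float(value_s)
    except ValueError:
        raise ValueError(f"bad numeric part in concentration {text!r}") from None
    if unit not in _PREFIX:
        raise ValueError(
            f"unknown unit {unit!r} in {text!r}; use one of " + ", ".join(_PREFIX)
        )
    return value * _PREFIX[unit]
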