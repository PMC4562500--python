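"""Environments of the doxycycline x zeocin design.

Conditions are written in ``DxZy`` notation: x ug/ml doxycycline and
y mg/ml zeocin, with the special inducer level ``Di`` = 0.2 ug/ml.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

DI_DOX = 0.2  # ug/ml, the "intermediate" inducer level

_LABEL_RE = re.compile(r"^D(i|\d+(?:\.\d+)?)Z(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class Environment:
    """A (doxycycline, zeocin) condition.

    Parameters
    ----------
    dox : float
        Doxycycline concentration in ug/ml (>= 0).
    zeo : float
        Zeocin concentration in mg/ml (>= 0).
    label : str, optional
        Condition tag in DxZy notation; generated from the
        concentrations when omitted.
    """

    dox: float
    zeo: float
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dox) and math.isfinite(self.zeo)):
            raise ValueError("concentrations must be finite")
        if self.dox < 0 or self.zeo < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.label:
            object.__setattr__(self, "label", format_label(self.dox, self.zeo))

    @classmethod
    def from_label(cls, label: str) -> "Environment":
        dox, zeo = parse_label(label)
        return cls(dox=dox, zeo=zeo, label=label)

    def without_zeocin(self) -> "Environment":
        return Environment(dox=self.dox, zeo=0.0)


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return ("%g" % x)


def format_label(dox: float, zeo: float) -> str:
    d = "i" if math.isclose(dox, DI_DOX) else _fmt(dox)
    return f"D{d}Z{_fmt(zeo)}"


def parse_label(label: str) -> tuple[float, float]:
    """Parse a DxZy label into (dox ug/ml, zeo mg/ml)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a DxZy condition label: {label!r}")
    d = DI_DOX if m.group(1) == "i" else float(m.group(1))
    return d, float(m.group(2))


#: The conditions of the evolution experiments.
EVOLUTION_CONDITIONS = ("D0Z0", "DiZ0", "D2Z0", "D0Z2", "DiZ2", "D2Z2")
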