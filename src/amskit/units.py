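"""Dose quantities and unit conversion.

Two unit families exist in the scoring policy: mass (canonicalized to
micrograms) and counted administration units (tablets, puffs, sprays,
applications — all treated as the same "application" family, since each
means one unit-dose of the product). Conversion across families is an
error: 10 mg of loratadine is not "10 tablets".
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitError

_MASS_TO_UG = {
    "ug": 1.0,
    "μg": 1.0,  # μg
    "µg": 1.0,  # µg (micro sign)
    "mcg": 1.0,
    "mg": 1_000.0,
    "g": 1_000_000.0,
}
_COUNT_UNITS = {
    "application", "applications", "puff", "puffs", "tablet", "tablets",
    "actuation", "inhalation", "spray", "dose", "unit",
}


def unit_family(unit: str) -> str:
    """Return ``"mass"`` or ``"count"``; raise :class:`UnitError` otherwise."""
    u = unit.strip().lower()
    if u in _MASS_TO_UG:
        return "mass"
    if u in _COUNT_UNITS:
        return "count"
    raise UnitError(f"unknown dose unit {unit!r}")


def to_canonical(value: float, unit: str) -> float:
    """Convert to the family's canonical scale (μg for mass, count as-is)."""
    u = unit.strip().lower()
    if unit_family(u) == "mass":
        return value * _MASS_TO_UG[u]
    return float(value)


@dataclass(frozen=True)
class Dose:
    """A dose magnitude with its unit, e.g. ``Dose(100, "ug")``."""

    value: float
    unit: str = "application"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise UnitError(f"dose must be non-negative, got {self.value}")
        unit_family(self.unit)  # validate eagerly

    @property
    def family(self) -> str:
        return unit_family(self.unit)

    def ratio_to(self, other: "Dose") -> float:
        """Dimensionless ratio self/other; the families must match."""
        if self.family != other.family:
            raise UnitError(
                f"cannot convert {self.unit!r} to {other.unit!r}: "
                f"{self.family} vs {other.family} units"
            )
        return to_canonical(self.value, self.unit) / to_canonical(
            other.value, other.unit
        )
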