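"""Molecular diffusion in seawater and tortuosity-corrected sediment diffusivity.

Free-solution diffusion coefficients D(T, S) come from a small embedded table
(0/10/20 degC anchors per solute, infinite-dilution freshwater values compiled
from the standard tabulations of Li & Gregory 1974, Boudreau 1997 and
Schulz & Zabel 2006), linearly interpolated (and linearly extrapolated at the
ends) in temperature, with a linear viscosity-type salinity reduction between
freshwater and S = 35. This is accurate to a few percent, which is the accuracy
the flux calculations need.

Sediment diffusivity uses the tortuosity relation

    Ds = D / theta^2,      theta^2 = 1 - ln(phi^2)

with phi the porosity of the layer across which the gradient is evaluated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import log
from pathlib import Path

from .errors import DomainError, UnknownSoluteError

#: anchor temperatures (degC) for the embedded table
_T_ANCHORS = (0.0, 10.0, 20.0)

#: freshwater, infinite-dilution D in 1e-6 cm^2 s^-1 at the anchor temperatures.
#: DIC is represented by the bicarbonate ion, its dominant species at seawater pH.
_D_TABLE: dict[str, tuple[float, float, float]] = {
    "O2": (11.70, 15.70, 20.30),
    "DIC": (5.06, 7.76, 10.46),
    "PO4": (3.36, 4.95, 6.54),
    "NH4": (9.80, 13.80, 17.80),
    "NO2": (10.70, 14.30, 17.90),
    "NO3": (9.80, 13.50, 17.20),
    "SO4": (4.96, 7.26, 9.55),
}

#: fractional reduction of D per PSU; ~4.8% between freshwater and S = 35,
#: the ratio of freshwater to seawater dynamic viscosity.
_SALINITY_SLOPE = 0.048 / 35.0

SUPPORTED_SOLUTES = tuple(_D_TABLE)

TEMPERATURE_RANGE = (-2.0, 30.0)
SALINITY_RANGE = (0.0, 40.0)


@dataclass(frozen=True)
class SoluteSpec:
    """A solute at in situ temperature (degC) and salinity (PSU)."""

    name: str
    temperature: float
    salinity: float

    def __post_init__(self):
        if self.name not in _D_TABLE:
            raise UnknownSoluteError(
                f"unknown solute {self.name!r}; supported: {', '.join(SUPPORTED_SOLUTES)}"
            )
        lo, hi = TEMPERATURE_RANGE
        if not lo <= self.temperature <= hi:
            raise DomainError(f"temperature {self.temperature} degC outside [{lo}, {hi}]")
        lo, hi = SALINITY_RANGE
        if not lo <= self.salinity <= hi:
            raise DomainError(f"salinity {self.salinity} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class SedimentDiffusivity:
    """Free-solution and tortuosity-corrected diffusivity, cm^2 s^-1."""

    d_free: float
    theta_sq: float
    d_sed: float


def _interp_linear(t: float, values: tuple[float, float, float]) -> float:
    # piecewise linear over the anchors, end segments extended for extrapolation
    t0, t1, t2 = _T_ANCHORS
    if t <= t1:
        return values[0] + (values[1] - values[0]) * (t - t0) / (t1 - t0)
    return values[1] + (values[2] - values[1]) * (t - t1) / (t2 - t1)


def free_diffusion_coefficient(spec: SoluteSpec) -> float:
    """Molecular diffusion coefficient in seawater, cm^2 s^-1.

    Monotonically increasing in temperature for every supported solute.
    """
    d_fresh = _interp_linear(spec.temperature, _D_TABLE[spec.name]) * 1e-6
    return d_fresh * (1.0 - _SALINITY_SLOPE * spec.salinity)


def tortuosity_correction(d_free: float, porosity: float) -> SedimentDiffusivity:
    """Apply theta^2 = 1 - ln(phi^2) to a free-solution coefficient."""
    if not 0.0 < porosity <= 1.0:
        raise DomainError(f"porosity {porosity} outside (0, 1]")
    if d_free <= 0.0:
        raise DomainError(f"d_free must be positive, got {d_free}")
    theta_sq = 1.0 - log(porosity**2)
    return SedimentDiffusivity(d_free=d_free, theta_sq=theta_sq, d_sed=d_free / theta_sq)


def sediment_diffusivity(
    solute: str, temperature: float, salinity: float, porosity: float
) -> SedimentDiffusivity:
    """Convenience: D(T, S) for ``solute`` corrected for tortuosity at ``porosity``."""
    d = free_diffusion_coefficient(SoluteSpec(solute, temperature, salinity))
    return tortuosity_correction(d, porosity)


def export_coefficient_table(path: str | Path) -> Path:
    """Write the embedded freshwater coefficient table to CSV for audit."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["solute"] + [f"d_{int(t)}C_1e6_cm2_s" for t in _T_ANCHORS])
        for name, values in _D_TABLE.items():
            writer.writerow([name, *values])
    return path
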