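"""Benthic carbon demand vs. pelagic supply.

The benthic carbon demand is the community's oxygen uptake expressed in carbon
equivalents (C-TOU, Redfield C:O = 106:138); supply is the pelagic primary
production reaching the seafloor, accepted either as a single rate or as a
(min, max) band in mmol C m^-2 d^-1. The budget classifies each end of the
band as meeting the demand or not, and reports the diffusive share of the
total oxygen uptake (DOU/TOU) as a measure of how much mineralization the
microbial community alone accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .units import DEFAULT_CARBON_MOLAR_MASS

STATE_MET = "supply_meets_demand"
STATE_DEFICIT = "deficit"


def mgC_to_mmolC(rate: float, molar_mass: float = DEFAULT_CARBON_MOLAR_MASS) -> float:
    """Convert mg C m^-2 d^-1 to mmol C m^-2 d^-1."""
    if molar_mass <= 0:
        raise DomainError(f"molar mass must be positive, got {molar_mass}")
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    return rate / molar_mass


def mmolC_to_mgC(rate: float, molar_mass: float = DEFAULT_CARBON_MOLAR_MASS) -> float:
    """Inverse of :func:`mgC_to_mmolC`."""
    if molar_mass <= 0:
        raise DomainError(f"molar mass must be positive, got {molar_mass}")
    return rate * molar_mass


@dataclass(frozen=True)
class BudgetSummary:
    """Demand/supply comparison, per end of the supply band.

    All rates in mmol C m^-2 d^-1 except the oxygen fluxes (mmol O2 m^-2 d^-1).
    """

    demand: float
    supply_min: float
    supply_max: float
    balance_min: float  # supply_min - demand
    balance_max: float
    state_min: str
    state_max: str
    dou_share_of_tou: float | None

    @property
    def state(self) -> str:
        """Overall state: met only when the whole band covers the demand."""
        return STATE_MET if self.state_min == STATE_MET else self.state_max

    def summary(self) -> str:
        share = (
            "n/a" if self.dou_share_of_tou is None else f"{self.dou_share_of_tou:.3f}"
        )
        return (
            f"demand {self.demand:.1f} vs supply {self.supply_min:.1f}-"
            f"{self.supply_max:.1f} mmol C m-2 d-1: {self.state_min}/{self.state_max} "
            f"(DOU/TOU = {share})"
        )


def budget(
    demand: float,
    supply: float | tuple[float, float],
    dou: float | None = None,
    tou: float | None = None,
) -> BudgetSummary:
    """Assemble the carbon budget.

    ``demand`` is the C-TOU; ``supply`` a rate or (min, max) band; ``dou`` and
    ``tou`` are uptake magnitudes used for the DOU/TOU share (the share is
    reported missing when the TOU is absent or zero).
    """
    if demand < 0:
        raise DomainError(f"demand must be >= 0, got {demand}")
    if isinstance(supply, tuple):
        supply_min, supply_max = supply
    else:
        supply_min = supply_max = float(supply)
    if supply_min < 0 or supply_max < supply_min:
        raise DomainError(f"invalid supply band ({supply_min}, {supply_max})")
    share = None
    if dou is not None and tou is not None and tou > 0:
        if dou < 0:
            raise DomainError("DOU magnitude must be >= 0")
        share = dou / tou
    bal_min = supply_min - demand
    bal_max = supply_max - demand
    return BudgetSummary(
        demand=demand,
        supply_min=supply_min,
        supply_max=supply_max,
        balance_min=bal_min,
        balance_max=bal_max,
        state_min=STATE_MET if bal_min >= 0 else STATE_DEFICIT,
        state_max=STATE_MET if bal_max >= 0 else STATE_DEFICIT,
        dou_share_of_tou=share,
    )
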