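"""Benthic community metrics: carbon biomass, diversity, bioturbation potential.

Census data from three gears (syringe subcores for prokaryotes, small cores for
meiofauna, Van Veen grab plus diver photo survey for macrofauna) are converted
to carbon per unit seafloor area:

* prokaryotes: cells cm^-3 x mean cell volume x 3.0e-13 g C um^-3;
* macrofauna: ash-free dry weight (AFDW, dry minus ash) at 50% carbon;
* the deep-burrowing bivalve Laternula elliptica, undersampled by grabs, via a
  linear siphon-width-to-AFDW conversion applied to photo-survey widths.

The community bioturbation potential combines abundance Ai, biomass Bi and the
ordinal mobility (Mi, 1-4) and sediment-reworking (Ri, 1-5) trait scores:

    BPc = sum_i (Bi/Ai) * Ai * Mi * Ri        ("as_printed" variant)

The literature formulation carries a square root on Bi/Ai; both variants are
available and labelled in outputs (default follows the printed form, which
collapses to sum Bi*Mi*Ri).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InconsistentRecordError

CELL_CARBON_FACTOR = 3.0e-13  # g C per um^3 of prokaryote cell volume
AFDW_CARBON_FRACTION = 0.5
DEFAULT_PROKARYOTE_DEPTH_CM = 5.0  # sampled depth used for areal integration

BPC_VARIANTS = ("as_printed", "sqrt")


@dataclass(frozen=True)
class TaxonRecord:
    """Per-taxon density (ind m^-2), biomass (g C m^-2) and trait scores."""

    taxon: str
    density: float
    biomass: float
    mobility: int
    reworking: int

    def __post_init__(self):
        if self.density < 0 or self.biomass < 0:
            raise DomainError(f"{self.taxon}: density and biomass must be >= 0")
        if self.mobility not in (1, 2, 3, 4):
            raise DomainError(f"{self.taxon}: mobility score {self.mobility} not in 1-4")
        if self.reworking not in (1, 2, 3, 4, 5):
            raise DomainError(f"{self.taxon}: reworking score {self.reworking} not in 1-5")


@dataclass(frozen=True)
class ProkaryoteCensus:
    density: float  # cells cm^-3 sediment
    mean_cell_volume: float  # um^3
    integration_depth: float = DEFAULT_PROKARYOTE_DEPTH_CM  # cm

    def __post_init__(self):
        if self.density < 0 or self.mean_cell_volume <= 0 or self.integration_depth <= 0:
            raise DomainError("census fields must be positive (density may be 0)")


@dataclass(frozen=True)
class SizeClassStocks:
    """Carbon stocks (g C m^-2) of the size classes shown in community budgets."""

    prokaryote: float
    meiofauna: float
    macrofauna_excl_le: float
    laternula: float

    def __post_init__(self):
        for name in ("prokaryote", "meiofauna", "macrofauna_excl_le", "laternula"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} stock must be >= 0")

    @property
    def total(self) -> float:
        return self.prokaryote + self.meiofauna + self.macrofauna_excl_le + self.laternula


def afdw_to_carbon(afdw: float) -> float:
    """Carbon from ash-free dry weight, assuming 50% of AFDW is carbon."""
    if afdw < 0:
        raise DomainError(f"AFDW must be >= 0, got {afdw}")
    return AFDW_CARBON_FRACTION * afdw


def prokaryote_biomass(census: ProkaryoteCensus) -> dict:
    """Volumetric (mg C cm^-3) and areal (g C m^-2) prokaryote carbon."""
    volumetric_g = census.density * census.mean_cell_volume * CELL_CARBON_FACTOR
    areal = volumetric_g * census.integration_depth * 1e4  # cm^2 per m^2
    return {"volumetric": volumetric_g * 1e3, "areal": areal}


def laternula_biomass(
    siphon_widths: Sequence[float],
    density: float,
    slope: float,
    intercept: float = 0.0,
) -> dict:
    """Population and per-individual carbon of L. elliptica from siphon widths.

    AFDW per individual is linear in siphon width (``slope`` g AFDW per cm,
    plus ``intercept``); carbon is 50% of AFDW; the areal biomass multiplies
    the mean individual carbon by the photo-survey density (ind m^-2).
    """
    if density < 0:
        raise DomainError("density must be >= 0")
    if slope <= 0:
        raise DomainError("conversion slope must be positive")
    if density == 0:
        return {"biomass": 0.0, "individual": math.nan}
    widths = np.asarray(siphon_widths, float)
    if widths.size == 0:
        raise DomainError("missing siphon-width measurements for a nonzero density")
    if np.any(widths <= 0):
        raise DomainError("siphon widths must be positive")
    individual = float(np.mean([afdw_to_carbon(slope * w + intercept) for w in widths]))
    return {"biomass": individual * density, "individual": individual}


def bpc(community: Iterable[TaxonRecord], variant: str = "as_printed") -> float:
    """Community bioturbation potential.

    as_printed: sum (Bi/Ai)*Ai*Mi*Ri == sum Bi*Mi*Ri.
    sqrt: sum sqrt(Bi/Ai)*Ai*Mi*Ri (the formulation of the trait-score source).
    """
    if variant not in BPC_VARIANTS:
        raise DomainError(f"variant must be one of {BPC_VARIANTS}, got {variant!r}")
    total = 0.0
    for rec in community:
        if rec.density == 0:
            if rec.biomass > 0:
                raise InconsistentRecordError(
                    f"{rec.taxon}: biomass {rec.biomass} with zero abundance"
                )
            continue
        if variant == "as_printed":
            total += rec.biomass * rec.mobility * rec.reworking
        else:
            total += math.sqrt(rec.biomass / rec.density) * rec.density * rec.mobility * rec.reworking
    return total


def shannon(community: Iterable[TaxonRecord]) -> float:
    """Shannon-Wiener H' = -sum p_i ln p_i over density shares (zeros excluded)."""
    densities = np.array([rec.density for rec in community], float)
    densities = densities[densities > 0]
    total = densities.sum()
    if total <= 0:
        raise DomainError("H' undefined: all densities are zero")
    p = densities / total
    return float(-(p * np.log(p)).sum())


def stock_fractions(stocks: SizeClassStocks) -> dict:
    """Macrofauna share of the community stock and L. elliptica's share of it (%)."""
    total = stocks.total
    if total <= 0:
        raise DomainError("stock fractions undefined: zero total stock")
    macro = stocks.macrofauna_excl_le + stocks.laternula
    return {
        "macrofauna_fraction": macro / total * 100.0,
        "laternula_share_of_macrofauna": (
            stocks.laternula / macro * 100.0 if macro > 0 else math.nan
        ),
    }
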