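"""Sediment physical properties and biogenic compound descriptors.

Porosity is derived gravimetrically from the water mass a wet sample loses on
drying, with a salt correction for the sea salt left behind in the dried
sediment:

    phi = (m_w / rho_w) / (m_w / rho_w + (m_d - S * m_w) / rho_s)

where m_w is the evaporated-water mass, m_d the dried mass (sediment + salt),
S the overlying-water salinity as a mass fraction, rho_w the water density and
rho_s the grain density (2.66 g cm^-3 for terrigenous sediment).

Pigment descriptors: chloroplastic pigment equivalents CPE = Chl a + Phaeo as a
bulk food-availability proxy, and the Chl a / Phaeo ratio as an indicator of
the relative freshness of the organic material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidSampleError

DEFAULT_SEDIMENT_DENSITY = 2.66  # g cm^-3, terrigenous grains
DEFAULT_WATER_DENSITY = 1.0  # g cm^-3, evaporated (fresh) water


def psu_to_mass_fraction(salinity_psu: float) -> float:
    """Convert practical salinity (g salt per kg seawater) to a mass fraction."""
    if salinity_psu < 0:
        raise DomainError(f"salinity {salinity_psu} PSU is negative")
    return salinity_psu / 1000.0


@dataclass(frozen=True)
class GravimetricSample:
    """Wet/dry masses of one sediment subsample plus ambient densities.

    ``salinity`` is a mass fraction (e.g. 0.034 for 34 PSU); use
    :func:`psu_to_mass_fraction` or :meth:`from_psu` for field metadata in PSU.
    """

    wet_mass: float  # g
    dry_mass_with_salt: float  # g, sediment + precipitated salt
    salinity: float = 0.034  # mass fraction of the overlying water
    water_density: float = DEFAULT_WATER_DENSITY  # g cm^-3
    sediment_density: float = DEFAULT_SEDIMENT_DENSITY  # g cm^-3

    def __post_init__(self):
        if self.dry_mass_with_salt < 0 or self.wet_mass < self.dry_mass_with_salt:
            raise InvalidSampleError(
                f"need wet_mass >= dry_mass_with_salt >= 0, got "
                f"{self.wet_mass} / {self.dry_mass_with_salt}"
            )
        if not 0.0 <= self.salinity < 1.0:
            raise InvalidSampleError(f"salinity mass fraction {self.salinity} outside [0, 1)")
        if self.water_density <= 0 or self.sediment_density <= 0:
            raise InvalidSampleError("densities must be positive")

    @classmethod
    def from_psu(cls, wet_mass: float, dry_mass_with_salt: float, salinity_psu: float, **kw):
        return cls(wet_mass, dry_mass_with_salt, psu_to_mass_fraction(salinity_psu), **kw)

    @property
    def evaporated_water_mass(self) -> float:
        return self.wet_mass - self.dry_mass_with_salt


def porosity(sample: GravimetricSample) -> float:
    """Volumetric porosity of a gravimetric sample (fraction)."""
    m_w = sample.evaporated_water_mass
    salt_corrected_dry = sample.dry_mass_with_salt - sample.salinity * m_w
    if salt_corrected_dry < 0:
        raise InvalidSampleError(
            "salt correction exceeds dry mass "
            f"(m_d={sample.dry_mass_with_salt} g < S*m_w={sample.salinity * m_w:.4g} g)"
        )
    water_volume = m_w / sample.water_density
    grain_volume = salt_corrected_dry / sample.sediment_density
    denom = water_volume + grain_volume
    if denom <= 0:
        raise InvalidSampleError("sample has zero total volume")
    return water_volume / denom


@dataclass(frozen=True)
class SedimentLayer:
    """One depth interval [top, bottom) below the SWI with its properties.

    Depths in cm, positive downward. Pigments in ug g^-1 dry sediment,
    carbon/nitrogen contents in ug (C or N) per mg dry sediment.
    """

    top: float
    bottom: float
    porosity: float
    chl_a: float = 0.0
    phaeo: float = 0.0
    fuco: float = 0.0
    tc: float = 0.0
    toc: float = 0.0
    tn: float = 0.0
    median_grain: float = float("nan")  # um
    silt_fraction: float = float("nan")

    def __post_init__(self):
        if not (self.bottom > self.top >= 0.0):
            raise InvalidSampleError(f"need bottom > top >= 0, got [{self.top}, {self.bottom})")
        if not 0.0 < self.porosity < 1.0:
            raise InvalidSampleError(f"porosity {self.porosity} outside (0, 1)")
        for name in ("chl_a", "phaeo", "fuco", "tc", "toc", "tn"):
            if getattr(self, name) < 0:
                raise InvalidSampleError(f"{name} must be >= 0")
        if self.toc > self.tc:
            raise InvalidSampleError(f"TOC {self.toc} exceeds TC {self.tc}")


def tic(layer: SedimentLayer) -> float:
    """Total inorganic carbon = TC - TOC (ug C mg^-1 sediment)."""
    # SedimentLayer already guarantees tc >= toc; recheck to keep the
    # subtraction safe for duck-typed inputs.
    if layer.toc > layer.tc:
        raise InvalidSampleError(f"negative TIC: TOC {layer.toc} > TC {layer.tc}")
    return layer.tc - layer.toc


def pigment_summary(layer: SedimentLayer) -> dict:
    """CPE, Chl a/Phaeo ratio and organic-carbon fraction for one layer.

    A zero phaeophytin concentration leaves the ratio undefined; it is reported
    as NaN while CPE is still returned.
    """
    cpe = layer.chl_a + layer.phaeo
    chl_to_phaeo = layer.chl_a / layer.phaeo if layer.phaeo > 0 else math.nan
    toc_to_tc = layer.toc / layer.tc if layer.tc > 0 else math.nan
    return {"cpe": cpe, "chl_to_phaeo": chl_to_phaeo, "toc_to_tc": toc_to_tc}


def summarize_layers(df: pd.DataFrame) -> pd.DataFrame:
    """Per-location summary of a layer table.

    Expects the CSV layer schema (see :mod:`benthoflux.io`): one row per
    location/replicate/layer with gravimetric masses and compound contents.
    Porosity is computed per sample; ratios (Chl a/Phaeo, TOC/TC) are computed
    per sample and then averaged, so the summary ratios are means of ratios,
    not ratios of means.
    """
    df = df.copy()
    df["porosity"] = [
        porosity(
            GravimetricSample.from_psu(
                row.wet_mass_g, row.dry_mass_g, row.salinity_psu
            )
        )
        for row in df.itertuples()
    ]
    df["cpe"] = df["chl_a_ug_g"] + df["phaeo_ug_g"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["chl_to_phaeo"] = np.where(
            df["phaeo_ug_g"] > 0, df["chl_a_ug_g"] / df["phaeo_ug_g"], np.nan
        )
        df["toc_to_tc"] = np.where(
            df["tc_ugC_mg"] > 0, df["toc_ugC_mg"] / df["tc_ugC_mg"], np.nan
        )
    df["tic_ugC_mg"] = df["tc_ugC_mg"] - df["toc_ugC_mg"]
    cols = [
        "porosity",
        "chl_a_ug_g",
        "phaeo_ug_g",
        "fuco_ug_g",
        "cpe",
        "chl_to_phaeo",
        "tc_ugC_mg",
        "toc_ugC_mg",
        "tic_ugC_mg",
        "tn_ugN_mg",
        "toc_to_tc",
    ]
    return df.groupby("location")[cols].mean()


def porosity_first_cm(df: pd.DataFrame, location: str) -> float:
    """Mean porosity of all [top, bottom) layers contained in the first cm."""
    sub = df[(df["location"] == location) & (df["top_cm"] < 1.0)]
    if sub.empty:
        raise InvalidSampleError(f"no surface layers for location {location!r}")
    phis = [
        porosity(GravimetricSample.from_psu(r.wet_mass_g, r.dry_mass_g, r.salinity_psu))
        for r in sub.itertuples()
    ]
    return float(np.mean(phis))
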