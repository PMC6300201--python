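"""Diffusive solute fluxes from Rhizon pore-water profiles.

Pore water is extracted at 1 cm intervals; the point at -0.5 cm is the bottom
water reference. The diffusive flux across a chosen depth interval is Fick's
first law with tortuosity and porosity corrections:

    J_down = -phi * Ds * dC/dz

where dC/dz is the OLS gradient of concentration against depth over the points
inside the interval (finite difference for two-point intervals), phi the mean
porosity over the interval and Ds = D/(1 - ln phi^2) the sediment diffusion
coefficient of the solute at in situ temperature and salinity.

J_down is positive along the depth axis (into the sediment). The returned
:class:`~benthoflux.chamber.FluxResult` keeps the package-wide positive-efflux
convention, so ``value = -J_down``: a solute accumulating with depth (e.g.
ammonium from remineralization) yields a positive diffusive efflux. The
literal Fickian value is available as the ``fickian_downward`` helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .chamber import FluxResult, QC_NONSIGNIFICANT, QC_OK
from .errors import AlignmentError, DegenerateSeriesError, DomainError
from .transport import sediment_diffusivity
from .units import PORE_GRADIENT_TO_FLUX

DEFAULT_INTERVAL = (-0.5, 2.5)  # cm; near-surface gradients dominate exchange


@dataclass(frozen=True)
class PoreWaterProfile:
    """Interval-resolved solute concentrations with a bottom-water point.

    depths_cm are strictly increasing, positive downward, with at most one
    point above the SWI (the bottom-water reference at -0.5 cm).
    """

    analyte: str
    depths_cm: Sequence[float]
    concentrations: Sequence[float]  # umol L^-1
    porosity_mean: float
    temperature: float = 0.0
    salinity: float = 34.0
    flux_interval: tuple[float, float] = DEFAULT_INTERVAL
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        z = np.asarray(self.depths_cm, float)
        c = np.asarray(self.concentrations, float)
        if z.size != c.size or z.size < 2:
            raise DegenerateSeriesError("profile needs >=2 paired depth/concentration points")
        if np.any(np.diff(z) <= 0):
            raise DegenerateSeriesError("depths must be strictly increasing")
        if int(np.sum(z < 0)) > 1:
            raise DegenerateSeriesError("at most one bottom-water point above the SWI")
        if not 0.0 < self.porosity_mean < 1.0:
            raise DomainError(f"porosity {self.porosity_mean} outside (0, 1)")
        lo, hi = self.flux_interval
        if not lo < hi:
            raise DomainError(f"flux interval {self.flux_interval} is empty")
        if lo < z[0] - 1e-9 or hi > z[-1] + 1e-9:
            raise DomainError(
                f"flux interval {self.flux_interval} outside profile span [{z[0]}, {z[-1]}]"
            )


class PoreWaterFluxModel:
    """Fit the diffusive flux of one pore-water profile over its interval."""

    def __init__(self, profile: PoreWaterProfile, alpha: float = 0.05):
        if not 0.0 < alpha < 1.0:
            raise DomainError(f"alpha {alpha} outside (0, 1)")
        self.profile = profile
        self.alpha = alpha

    def fit(self) -> FluxResult:
        p = self.profile
        z = np.asarray(p.depths_cm, float)
        c = np.asarray(p.concentrations, float)
        lo, hi = p.flux_interval
        eps = 1e-9
        mask = (z >= lo - eps) & (z <= hi + eps)
        n = int(mask.sum())
        if n < 2:
            raise DegenerateSeriesError(
                f"interval [{lo}, {hi}] cm contains {n} point(s); need >=2"
            )
        if n == 2:
            gradient = (c[mask][1] - c[mask][0]) / (z[mask][1] - z[mask][0])
            pvalue, se = None, None
            qc = QC_OK
        else:
            res = stats.linregress(z[mask], c[mask])
            gradient = float(res.slope)
            pvalue = float(res.pvalue)
            se = float(res.stderr)
            qc = QC_OK if (not math.isnan(pvalue) and pvalue <= self.alpha) else QC_NONSIGNIFICANT
        diff = sediment_diffusivity(p.analyte, p.temperature, p.salinity, p.porosity_mean)
        scale = p.porosity_mean * diff.d_sed * PORE_GRADIENT_TO_FLUX
        return FluxResult(
            value=scale * gradient,  # positive-efflux convention (= -J_down)
            analyte=p.analyte,
            method="diffusive",
            qc=qc,
            slope_p=pvalue,
            slope_se=None if se is None else scale * se,
            n=n,
        )


def diffusive_flux(profile: PoreWaterProfile, alpha: float = 0.05) -> FluxResult:
    """Diffusive flux over the profile's interval (see :class:`PoreWaterFluxModel`)."""
    return PoreWaterFluxModel(profile, alpha=alpha).fit()


def fickian_downward(result: FluxResult) -> float:
    """The flux in the downward-positive Fickian form -phi*Ds*dC/dz."""
    return -result.value


def nitrate_from_nox(nox: PoreWaterProfile, no2: PoreWaterProfile) -> PoreWaterProfile:
    """Pointwise [NO3] = [NO3+NO2] - [NO2]; negative values kept and flagged."""
    z1 = np.asarray(nox.depths_cm, float)
    z2 = np.asarray(no2.depths_cm, float)
    if z1.size != z2.size or not np.allclose(z1, z2):
        raise AlignmentError("NOx and NO2 profiles must share their depth grid")
    conc = np.asarray(nox.concentrations, float) - np.asarray(no2.concentrations, float)
    flags = ("negative_concentration",) if np.any(conc < 0) else ()
    return PoreWaterProfile(
        analyte="NO3",
        depths_cm=tuple(z1),
        concentrations=tuple(conc),
        porosity_mean=nox.porosity_mean,
        temperature=nox.temperature,
        salinity=nox.salinity,
        flux_interval=nox.flux_interval,
        flags=flags,
    )


def diffusive_share(diffusive: FluxResult, total: FluxResult) -> float:
    """|diffusive| / |total|: the fraction of exchange explained by diffusion."""
    if total.value == 0:
        raise DomainError("diffusive share undefined: zero total flux")
    return abs(diffusive.value) / abs(total.value)
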