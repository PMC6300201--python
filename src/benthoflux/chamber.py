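"""Total fluxes across the sediment-water interface from closed-chamber incubations.

A benthic chamber encloses a known sediment area A and overlying water volume V;
the total flux of a solute is the rate of change of its concentration in the
enclosed water scaled by V/A:

    flux = dC/dt * V / A        [mmol m^-2 d^-1]

With more than two samplings the rate is the OLS slope of concentration against
time and a two-sided t-test on the slope provides the QC criterion
(nonsignificant slopes are reported but flagged). With exactly two samplings
the finite difference is used and the analyte's analytical detection limit
decides whether the change is real.

Sign convention: positive = efflux (sediment to water). A community consuming
oxygen therefore has a negative O2 flux; the conventional "total oxygen uptake"
(TOU) is its magnitude, available as :attr:`FluxResult.uptake`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeriesError,
    DomainError,
    InsufficientReplicationError,
)
from .units import CHAMBER_SLOPE_TO_FLUX, REDFIELD_C_TO_O2

QC_OK = "ok"
QC_NONSIGNIFICANT = "nonsignificant_slope"
QC_BELOW_DETECTION = "below_detection"
QC_OMITTED = "omitted"

#: analytical detection limits, umol L^-1, applied to two-point differences.
#: DIC from the incubation methodology; nutrient limits converted from the
#: analyzers' ppb element limits (2 ppb N ~ 0.14 uM, 2 ppb P ~ 0.065 uM).
DEFAULT_DETECTION_LIMITS = {
    "DIC": 0.05,
    "O2": 1.0,
    "NH4": 0.14,
    "NO2": 0.14,
    "NO3": 0.14,
    "NOx": 0.14,
    "PO4": 0.065,
}


@dataclass(frozen=True)
class ChamberGeometry:
    """Cylindrical chamber: inner diameter (cm) and >=1 water-height readings (cm).

    The enclosed water volume uses the mean of the height readings, which are
    measured in situ at several positions around each chamber.
    """

    inner_diameter: float
    height_readings: Sequence[float]

    def __post_init__(self):
        if self.inner_diameter <= 0:
            raise DomainError("inner_diameter must be positive")
        if len(self.height_readings) < 1 or any(h <= 0 for h in self.height_readings):
            raise DomainError("need >=1 positive height readings")

    @property
    def area_m2(self) -> float:
        return math.pi * (self.inner_diameter / 2.0 / 100.0) ** 2

    @property
    def mean_height_cm(self) -> float:
        return float(np.mean(self.height_readings))

    @property
    def volume_l(self) -> float:
        # area [m^2] * height [m] = m^3; 1 m^3 = 1000 L
        return self.area_m2 * (self.mean_height_cm / 100.0) * 1000.0


@dataclass(frozen=True)
class IncubationSeries:
    """Timed concentrations of one analyte in one chamber."""

    analyte: str
    times_h: Sequence[float]
    concentrations: Sequence[float]  # umol L^-1
    geometry: ChamberGeometry
    light: str = "transparent"  # or "black"
    tech_sd: Sequence[float] | None = None  # technical-replicate SD per sample
    detection_limit: float | None = None  # umol L^-1

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size < 2 or t.size != c.size:
            raise DegenerateSeriesError(
                f"need >=2 paired samples, got {t.size} times / {c.size} concentrations"
            )
        if np.any(np.diff(t) <= 0):
            raise DegenerateSeriesError("times must be strictly increasing")
        if self.light not in ("transparent", "black"):
            raise DomainError(f"light must be 'transparent' or 'black', got {self.light!r}")

    def resolved_detection_limit(self) -> float:
        if self.detection_limit is not None:
            return self.detection_limit
        return DEFAULT_DETECTION_LIMITS.get(self.analyte, 0.0)


@dataclass(frozen=True)
class FluxResult:
    """A flux estimate with its QC state.

    ``value`` is signed, positive = efflux, in mmol m^-2 d^-1. ``slope_p`` is
    the two-sided p-value of the slope t-test (None for two-point series).
    """

    value: float
    analyte: str
    method: str  # "total" or "diffusive"
    qc: str = QC_OK
    slope_p: float | None = None
    slope_se: float | None = None
    n: int = 0
    units: str = "mmol m-2 d-1"

    @property
    def ok(self) -> bool:
        return self.qc == QC_OK

    @property
    def uptake(self) -> float:
        """Flux into the sediment as a positive magnitude (paper-style TOU)."""
        return -self.value

    def summary(self) -> str:
        p = "n/a" if self.slope_p is None else f"{self.slope_p:.4g}"
        return (
            f"{self.method} {self.analyte} flux: {self.value:+.4g} {self.units} "
            f"(n={self.n}, slope p={p}, qc={self.qc})"
        )


class ChamberFluxModel:
    """OLS model for the total flux of one incubation series.

    Parameters
    ----------
    series:
        The incubation time series with chamber geometry attached.
    alpha:
        Significance level for the slope t-test when >2 samplings are present.
    """

    def __init__(self, series: IncubationSeries, alpha: float = 0.05):
        if not 0.0 < alpha < 1.0:
            raise DomainError(f"alpha {alpha} outside (0, 1)")
        self.series = series
        self.alpha = alpha

    def fit(self) -> FluxResult:
        s = self.series
        t = np.asarray(s.times_h, dtype=float)
        c = np.asarray(s.concentrations, dtype=float)
        v_over_a = s.geometry.volume_l / s.geometry.area_m2
        if t.size == 2:
            dt = t[1] - t[0]
            dc = c[1] - c[0]
            slope = dc / dt
            qc = QC_OK
            if abs(dc) < s.resolved_detection_limit():
                qc = QC_BELOW_DETECTION
            return FluxResult(
                value=slope * v_over_a * CHAMBER_SLOPE_TO_FLUX,
                analyte=s.analyte,
                method="total",
                qc=qc,
                slope_p=None,
                n=2,
            )
        res = stats.linregress(t, c)
        pvalue = float(res.pvalue)
        qc = QC_OK if (not math.isnan(pvalue) and pvalue <= self.alpha) else QC_NONSIGNIFICANT
        # a perfectly constant series yields slope 0 with p = 1: flagged, value 0
        return FluxResult(
            value=float(res.slope) * v_over_a * CHAMBER_SLOPE_TO_FLUX,
            analyte=s.analyte,
            method="total",
            qc=qc,
            slope_p=pvalue,
            slope_se=float(res.stderr) * v_over_a * CHAMBER_SLOPE_TO_FLUX,
            n=int(t.size),
        )


def total_flux(series: IncubationSeries, alpha: float = 0.05) -> FluxResult:
    """Total solute flux of one chamber incubation (see :class:`ChamberFluxModel`)."""
    return ChamberFluxModel(series, alpha=alpha).fit()


def nitrate_series(nox: IncubationSeries, no2: IncubationSeries) -> IncubationSeries:
    """Derive a nitrate series as [NO3+NO2] - [NO2] per time point.

    Negative derived concentrations within analytical noise are kept, not
    clipped; the flux fit only uses differences.
    """
    t1 = np.asarray(nox.times_h, float)
    t2 = np.asarray(no2.times_h, float)
    if t1.size != t2.size or not np.allclose(t1, t2):
        raise DegenerateSeriesError("NOx and NO2 series must share their time grid")
    conc = np.asarray(nox.concentrations, float) - np.asarray(no2.concentrations, float)
    return IncubationSeries(
        analyte="NO3",
        times_h=tuple(t1),
        concentrations=tuple(conc),
        geometry=nox.geometry,
        light=nox.light,
        detection_limit=nox.detection_limit,
    )


def carbon_equivalent(tou_magnitude: float) -> float:
    """Convert an oxygen-uptake magnitude to carbon equivalents (Redfield 106:138)."""
    if tou_magnitude < 0:
        raise DomainError(f"TOU magnitude must be >= 0, got {tou_magnitude}")
    return tou_magnitude * REDFIELD_C_TO_O2


def respiration_quotient(dic_flux: FluxResult, tou: FluxResult) -> float:
    """RQ = |total DIC flux| / TOU.

    Raises if the oxygen flux is zero. If either input carries a QC flag the
    quotient is still returned but a warning is emitted, mirroring how flagged
    fluxes propagate through the budget.
    """
    if tou.value == 0:
        raise DomainError("RQ undefined: zero oxygen flux")
    if not (dic_flux.ok and tou.ok):
        import warnings

        warnings.warn(
            f"RQ computed from flagged fluxes (DIC qc={dic_flux.qc}, O2 qc={tou.qc})",
            stacklevel=2,
        )
    return abs(dic_flux.value) / abs(tou.value)


@dataclass(frozen=True)
class PoolingResult:
    poolable: bool
    p: float
    test: str  # "student" or "welch"
    levene_p: float


def light_dark_pooling_check(
    fluxes_transparent: Sequence[float],
    fluxes_black: Sequence[float],
    alpha: float = 0.05,
) -> PoolingResult:
    """Decide whether transparent- and black-chamber fluxes can be pooled.

    A Levene test chooses between Student's and Welch's two-sample t-test; the
    groups are poolable when the t-test does not reject equal means at
    ``alpha``. Identical groups are poolable with p = 1 by convention (the
    t statistic is 0/0 there).
    """
    a = np.asarray(fluxes_transparent, float)
    b = np.asarray(fluxes_black, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("need >=2 fluxes per light treatment")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        return PoolingResult(poolable=p > alpha, p=p, test="student", levene_p=1.0)
    levene_p = float(stats.levene(a, b).pvalue)
    equal_var = levene_p > alpha
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(t.pvalue)
    return PoolingResult(
        poolable=p > alpha,
        p=p,
        test="student" if equal_var else "welch",
        levene_p=levene_p,
    )
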