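"""Diffusive oxygen uptake and penetration depth from O2 microprofiles.

A microsensor profile samples O2 at 100 um steps across the sediment-water
interface (SWI; depth 0, negative above). Above the sediment sits a thin
diffusive boundary layer (DBL) in which transport is purely molecular; below,
microbial consumption bends the profile down to anoxia at the oxygen
penetration depth (OPD).

The diffusive oxygen uptake is Fick's first law applied at the interface,

    DOU = phi * Ds * |dO2/dz|_{z=0},      Ds = D / (1 - ln(phi^2)),

with phi the porosity of the first centimetre. The porosity factor makes this
the flux per unit bed area, the same convention used for the pore-water
nutrient fluxes; applied to a gradient partly inside the DBL (where the free
coefficient D > phi*Ds governs) it errs on the low side, so DOU is a mild
underestimate of the interface flux whenever the window touches the DBL.

Estimation steps:

1. running-mean smoothing (centred, shrunken symmetric windows at the ends);
2. locate the first alteration: the overlying-water plateau is the longest
   initial run whose OLS slope is not significant, and the alteration is the
   first point deviating from the plateau mean by more than k plateau-SDs,
   sustained over a few consecutive points;
3. fit the interface gradient by OLS on the *raw* samples in a short window
   starting at max(first alteration, SWI) — raw because the running mean's
   support straddles the interface kink; short (default 0.5 mm, capped at
   1 mm) because consumption curvature biases long windows low;
4. OPD: first sustained drop of the smoothed profile below the anoxia
   threshold (default 1 umol L^-1, a typical electrochemical sensor floor),
   refined by inverting a local linear fit around the crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError, DomainError, FlatProfileError
from .transport import sediment_diffusivity
from .units import MICRO_GRADIENT_TO_FLUX

QC_OK = "ok"
QC_WINDOW_TOO_SHORT = "window_too_short"
QC_NO_ANOXIA = "no_anoxia"

MAX_WINDOW_MM = 1.0


@dataclass(frozen=True)
class MicroProfile:
    """Depth-resolved O2 concentrations across the SWI.

    depths_mm: strictly increasing, ~uniform spacing, negative above the SWI.
    """

    depths_mm: Sequence[float]
    o2_umol_l: Sequence[float]
    temperature: float = 0.0  # degC
    salinity: float = 34.0  # PSU
    sensor_noise_sd: float | None = None  # umol L^-1

    def __post_init__(self):
        z = np.asarray(self.depths_mm, float)
        c = np.asarray(self.o2_umol_l, float)
        if z.size != c.size or z.size < 3:
            raise DegenerateSeriesError("profile needs >=3 paired depth/O2 samples")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise DegenerateSeriesError("depths must be strictly increasing")
        if np.max(dz) > 2.0 * np.min(dz):
            raise DegenerateSeriesError("profile spacing is not approximately uniform")
        if self.sensor_noise_sd is not None and np.any(c < -3.0 * self.sensor_noise_sd):
            raise DegenerateSeriesError("O2 readings below -3 sensor SDs")

    @property
    def spacing_mm(self) -> float:
        return float(np.mean(np.diff(np.asarray(self.depths_mm, float))))


def smooth_profile(profile: MicroProfile, window: int = 3) -> MicroProfile:
    """Centred running mean; endpoints use shrunken symmetric windows."""
    n = len(profile.o2_umol_l)
    if window % 2 == 0 or window < 3 or window > n:
        raise DomainError(f"window must be odd, >=3 and <= profile length, got {window}")
    c = np.asarray(profile.o2_umol_l, float)
    half = window // 2
    out = np.empty_like(c)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = c[i - h : i + h + 1].mean()
    return MicroProfile(
        depths_mm=tuple(profile.depths_mm),
        o2_umol_l=tuple(out),
        temperature=profile.temperature,
        salinity=profile.salinity,
        sensor_noise_sd=profile.sensor_noise_sd,
    )


def _plateau_extent(z: np.ndarray, c: np.ndarray, alpha: float, min_points: int) -> int:
    """Index one past the longest initial run with a nonsignificant OLS slope."""
    best = min_points
    misses = 0
    for j in range(min_points, z.size + 1):
        zz, cc = z[:j], c[:j]
        if np.ptp(cc) == 0.0:  # perfectly flat: trivially nonsignificant
            best = j
            continue
        res = stats.linregress(zz, cc)
        p = res.pvalue
        if math.isnan(p) or p > alpha:
            best = j
            misses = 0
        else:
            misses += 1
            if misses >= 5:
                break
    return best


def detect_gradient_start(
    profile: MicroProfile,
    k: float = 3.0,
    smoothing_window: int = 3,
    alpha: float = 0.05,
    persistence: int = 5,
    min_plateau_points: int = 5,
) -> float:
    """Depth (mm) of the first alteration from the overlying-water plateau.

    The alteration must deviate from the plateau mean by more than
    ``k`` plateau standard deviations with a consistent sign over
    ``persistence`` consecutive smoothed points; the persistence requirement
    keeps the false-start rate on pure-noise plateaus below the percent level.
    """
    smoothed = smooth_profile(profile, smoothing_window)
    z = np.asarray(smoothed.depths_mm, float)
    c = np.asarray(smoothed.o2_umol_l, float)
    raw = np.asarray(profile.o2_umol_l, float)
    if z.size < min_plateau_points + persistence:
        raise DegenerateSeriesError("profile too short for plateau detection")
    j = _plateau_extent(z, c, alpha, min_plateau_points)
    # plateau statistics from the raw samples: the smoothed series has slow
    # correlated wiggles (and a transitional point at the plateau edge) that
    # would bias the mean and understate the scatter
    mean = raw[:j].mean()
    sd = raw[:j].std(ddof=1) if j > 1 else 0.0
    # floor keeps noiseless profiles detectable at the first deviating point
    sd = max(sd, 1e-9 * max(1.0, abs(mean)))
    dev = c - mean
    for i in range(z.size - persistence + 1):
        run = dev[i : i + persistence]
        if np.all(run > k * sd) or np.all(run < -k * sd):
            return float(z[i])
    raise FlatProfileError("no departure from the overlying-water plateau found")


@dataclass(frozen=True)
class DOUResult:
    """Diffusive oxygen uptake, its regression window, and the OPD."""

    dou: float  # mmol O2 m^-2 d^-1, uptake magnitude (>= 0)
    gradient: float  # fitted dO2/dz, umol L^-1 mm^-1 (signed)
    gradient_window: tuple[float, float]  # (top, bottom) mm
    opd_mm: float | None
    qc: str = QC_OK
    d_sed: float = float("nan")  # cm^2 s^-1
    porosity: float = float("nan")
    n: int = 0

    def summary(self) -> str:
        opd = "n/a" if self.opd_mm is None else f"{self.opd_mm:.2f} mm"
        lo, hi = self.gradient_window
        return (
            f"DOU = {self.dou:.3g} mmol O2 m-2 d-1 "
            f"(gradient {self.gradient:+.3g} uM/mm over [{lo:.2f}, {hi:.2f}] mm, "
            f"n={self.n}, OPD {opd}, qc={self.qc})"
        )


class MicroprofileModel:
    """Fit DOU and OPD for one microprofile.

    Parameters
    ----------
    profile:
        The measured profile.
    porosity_first_cm:
        Porosity of the upper centimetre, used for the tortuosity correction
        and the per-bed-area porosity factor.
    smoothing_window, k:
        Running-mean width and plateau-deviation multiplier for detection.
    span_mm:
        Length of the gradient regression window (capped at 1 mm).
    anoxia_threshold:
        O2 level (umol L^-1) defining operational anoxia for the OPD.
    """

    def __init__(
        self,
        profile: MicroProfile,
        porosity_first_cm: float,
        smoothing_window: int = 3,
        k: float = 3.0,
        span_mm: float = 0.5,
        anoxia_threshold: float = 1.0,
    ):
        if not 0.0 < porosity_first_cm < 1.0:
            raise DomainError(f"porosity {porosity_first_cm} outside (0, 1)")
        if not 0.0 < span_mm <= MAX_WINDOW_MM:
            raise DomainError(f"span_mm must be in (0, {MAX_WINDOW_MM}], got {span_mm}")
        if anoxia_threshold <= 0:
            raise DomainError("anoxia_threshold must be positive")
        self.profile = profile
        self.porosity = porosity_first_cm
        self.smoothing_window = smoothing_window
        self.k = k
        self.span_mm = span_mm
        self.anoxia_threshold = anoxia_threshold

    def fit(self) -> DOUResult:
        prof = self.profile
        z = np.asarray(prof.depths_mm, float)
        raw = np.asarray(prof.o2_umol_l, float)
        start = detect_gradient_start(
            prof, k=self.k, smoothing_window=self.smoothing_window
        )
        reg_start = max(start, 0.0)
        eps = 1e-9
        mask = (z >= reg_start - eps) & (z <= reg_start + self.span_mm + eps)
        diff = sediment_diffusivity("O2", prof.temperature, prof.salinity, self.porosity)
        opd, opd_qc = self._opd(z)
        if mask.sum() < 3:
            return DOUResult(
                dou=0.0,
                gradient=float("nan"),
                gradient_window=(reg_start, reg_start + self.span_mm),
                opd_mm=opd,
                qc=QC_WINDOW_TOO_SHORT,
                d_sed=diff.d_sed,
                porosity=self.porosity,
                n=int(mask.sum()),
            )
        res = stats.linregress(z[mask], raw[mask])
        gradient = float(res.slope)
        dou = self.porosity * diff.d_sed * max(-gradient, 0.0) * MICRO_GRADIENT_TO_FLUX
        return DOUResult(
            dou=dou,
            gradient=gradient,
            gradient_window=(float(z[mask][0]), float(z[mask][-1])),
            opd_mm=opd,
            qc=opd_qc,
            d_sed=diff.d_sed,
            porosity=self.porosity,
            n=int(mask.sum()),
        )

    def _opd(self, z: np.ndarray) -> tuple[float | None, str]:
        """First sustained drop of the smoothed profile below the anoxia threshold."""
        smoothed = smooth_profile(self.profile, self.smoothing_window)
        c = np.asarray(smoothed.o2_umol_l, float)
        thr = self.anoxia_threshold
        below = np.where(z > 0)[0]
        run = max(3, int(round(0.5 / self.profile.spacing_mm)))
        cross = None
        for i in below:
            if c[i] < thr and np.median(c[i : i + run]) < thr:
                cross = i
                break
        if cross is None:
            return None, QC_NO_ANOXIA
        # refine by inverting a local linear fit of the smoothed profile
        half = max(3, int(round(0.5 / self.profile.spacing_mm)))
        lo, hi = max(0, cross - half), min(z.size, cross + half + 1)
        res = stats.linregress(z[lo:hi], c[lo:hi])
        if res.slope < 0:
            refined = (thr - res.intercept) / res.slope
            if z[lo] - 0.5 <= refined <= z[hi - 1] + 0.5:
                return float(refined), QC_OK
        return float(z[cross]), QC_OK


def dou(profile: MicroProfile, porosity_first_cm: float, **kwargs) -> DOUResult:
    """Diffusive oxygen uptake of one profile (see :class:`MicroprofileModel`)."""
    return MicroprofileModel(profile, porosity_first_cm, **kwargs).fit()
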