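"""Detector and column calibration from a single protein standard.

The system is calibrated exactly as in routine multi-detector SEC
practice: a bovine serum albumin solution of known concentration,
molecular weight, dn/dc, dA/dc and intrinsic viscosity is injected before
each determination, and the per-channel response constants are fixed by
matching the integrated detector areas to the known injected quantities:

* k_RI   from the RI area vs injected mass x dn/dc,
* k_UV   from the UV area vs mass x dA/dc,
* k_RALS, k_LALS from the light-scattering areas vs mass x Mw x (dn/dc)^2,
* k_DP   from the viscometer area vs mass x [eta].

The column's mass-vs-volume calibration is log-linear,
log10(Mw/kDa) = a - b * Ve, fitted through retention anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chromatogram import CHANNELS, Chromatogram

__all__ = [
    "ColumnCalibration",
    "DetectorCalibration",
    "StandardReference",
    "DEFAULT_COLUMN_ANCHORS",
    "default_column_calibration",
    "fit_column_calibration",
    "calibrate_detectors",
    "align_interdetector",
    "estimate_delay",
]


@dataclass(frozen=True)
class ColumnCalibration:
    """log10(Mw_kda) = intercept_a - slope_b * Ve_mL over ``volume_range``."""

    intercept_a: float
    slope_b: float
    volume_range: tuple[float, float] = (8.0, 20.0)
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive (larger mass elutes earlier)")

    def elution_volume(self, mw_kda: float) -> float:
        """Retention volume of a species of mass ``mw_kda`` (mL)."""
        if mw_kda <= 0:
            raise ValueError("mw_kda must be positive")
        ve = (self.intercept_a - np.log10(mw_kda)) / self.slope_b
        lo, hi = self.volume_range
        if not lo <= ve <= hi:
            warnings.warn(f"mass {mw_kda:.1f} kDa elutes at {ve:.2f} mL, outside "
                          f"the calibrated range {self.volume_range}; clipped",
                          stacklevel=2)
            ve = float(np.clip(ve, lo, hi))
        return float(ve)

    def mass_at_volume(self, ve_ml: float) -> float:
        return float(10.0 ** (self.intercept_a - self.slope_b * ve_ml))


#: Retention anchors of the analytical column: the ~485 kDa ternary complex
#: elutes at 13.5 mL and the ~930 kDa high-order complex at 12.0 mL.
DEFAULT_COLUMN_ANCHORS = ((13.5, 485.0), (12.0, 930.0))


def fit_column_calibration(anchors: Sequence[tuple[float, float]],
                           volume_range: tuple[float, float] = (8.0, 20.0)
                           ) -> ColumnCalibration:
    """Least-squares log-linear fit of (Ve, Mw) anchors."""
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two (Ve, Mw) anchors")
    ve = np.array([a[0] for a in anchors], dtype=float)
    if len(np.unique(ve)) < 2:
        raise ValueError("anchors must have distinct volumes")
    logm = np.log10([a[1] for a in anchors])
    slope, intercept = np.polyfit(ve, logm, 1)
    if -slope <= 0:
        raise ValueError("anchors imply non-decreasing mass with volume")
    resid = logm - (intercept + slope * ve)
    return ColumnCalibration(float(intercept), float(-slope), volume_range,
                             tuple(float(r) for r in resid))


def default_column_calibration() -> ColumnCalibration:
    return fit_column_calibration(DEFAULT_COLUMN_ANCHORS)


@dataclass(frozen=True)
class StandardReference:
    """Known properties of the calibrant injection (defaults: monomeric BSA)."""

    name: str = "bsa"
    mw_kda: float = 66.4
    conc_mg_ml: float = 2.0
    dn_dc: float = 0.185
    da_dc: float = 0.67
    intrinsic_viscosity: float = 4.1
    injection_volume_ul: float = 100.0

    @property
    def injected_mass_mg(self) -> float:
        return self.conc_mg_ml * self.injection_volume_ul / 1000.0


@dataclass
class DetectorCalibration:
    """Per-channel response constants, delays and the column calibration."""

    constants: dict[str, float]
    delays: dict[str, float] = field(default_factory=dict)
    column: Optional[ColumnCalibration] = None
    standard_id: str = ""
    dn_dc_standard: float = 0.185

    def __post_init__(self) -> None:
        missing = [ch for ch in CHANNELS if ch not in self.constants]
        if missing:
            raise ValueError(f"missing response constant(s): {', '.join(missing)}")
        bad = [ch for ch, k in self.constants.items() if not k > 0]
        if bad:
            raise ValueError(f"non-positive response constant(s): {', '.join(bad)}")


class CalibrationError(RuntimeError):
    pass


def _peak_region(volume: np.ndarray, trace: np.ndarray,
                 n_sigma: float = 4.0) -> slice:
    """Slice covering apex +/- n_sigma of the dominant peak (moment width)."""
    if np.max(trace) <= 0:
        raise CalibrationError("no detectable peak (non-positive trace)")
    apex = int(np.argmax(trace))
    # second-moment width over the half-maximum region around the apex
    above = trace >= 0.5 * trace[apex]
    lo = apex
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = apex
    while hi < len(trace) - 1 and above[hi + 1]:
        hi += 1
    fwhm = volume[hi] - volume[lo]
    sigma = max(fwhm / 2.3548, volume[1] - volume[0])
    left = np.searchsorted(volume, volume[apex] - n_sigma * sigma)
    right = np.searchsorted(volume, volume[apex] + n_sigma * sigma, side="right")
    return slice(max(left, 0), min(right, len(volume)))


def calibrate_detectors(standard: Chromatogram,
                        reference: StandardReference = StandardReference(),
                        column: Optional[ColumnCalibration] = None,
                        delays: Optional[dict[str, float]] = None,
                        ) -> DetectorCalibration:
    """Fix the five response constants from a standard run.

    The integration region is apex +/- 4 sd of the RI peak (captures
    >99.99% of a Gaussian band).  Raises :class:`CalibrationError` naming
    the offending channel if any area is non-positive.
    """
    chrom = standard
    if delays:
        chrom = align_interdetector(chrom, delays)
    region = _peak_region(chrom.volume, chrom["RI"])
    v = chrom.volume[region]
    areas = {ch: float(np.trapezoid(chrom[ch][region], v)) for ch in CHANNELS}
    bad = [ch for ch, a in areas.items() if a <= 0]
    if bad:
        raise CalibrationError(f"non-positive peak area on channel(s): {', '.join(bad)}")

    m = reference.injected_mass_mg  # mg
    constants = {
        "RI": areas["RI"] / (m * reference.dn_dc),
        "UV280": areas["UV280"] / (m * reference.da_dc),
        "RALS": areas["RALS"] / (m * reference.mw_kda * reference.dn_dc ** 2),
        "LALS": areas["LALS"] / (m * reference.mw_kda * reference.dn_dc ** 2),
        "DP": areas["DP"] / (m * reference.intrinsic_viscosity),
    }
    return DetectorCalibration(constants, dict(delays or {}), column,
                               standard_id=reference.name,
                               dn_dc_standard=reference.dn_dc)


def align_interdetector(chrom: Chromatogram,
                        delays: dict[str, float]) -> Chromatogram:
    """Shift channels onto a common volume frame by linear interpolation.

    ``delays[ch]`` is the transfer volume (mL) by which channel ``ch``
    lags the reference frame; zero delays return an identical copy.
    """
    span = chrom.volume[-1] - chrom.volume[0]
    out = chrom.copy()
    for ch, delay in delays.items():
        if abs(delay) > span:
            raise ValueError(f"delay {delay} mL on {ch} exceeds the grid span")
        if delay == 0.0:
            continue
        out.channels[ch] = np.interp(chrom.volume, chrom.volume - delay,
                                     chrom[ch], left=0.0, right=0.0)
    out.metadata["aligned_delays_mL"] = dict(delays)
    return out


def estimate_delay(chrom: Chromatogram, channel: str,
                   reference: str = "RI") -> float:
    """Apex-to-apex delay of ``channel`` relative to ``reference`` (mL)."""
    apex_ref = chrom.volume[int(np.argmax(chrom[reference]))]
    apex_ch = chrom.volume[int(np.argmax(chrom[channel]))]
    return float(apex_ch - apex_ref)
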