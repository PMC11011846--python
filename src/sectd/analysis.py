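"""Chromatogram inversion: baseline, peaks, deconvolution and per-species
physical parameters.

Concentration is defined by the RI channel (c = RI / (k_RI dn/dc)); the
weight-average molecular weight of a species follows from the
light-scattering to RI ratio, the intrinsic viscosity from the viscometer
to RI area ratio, and the specific absorbance increment dA/dc from the UV
to RI area ratio.  Overlapping species are separated by nonlinear
least-squares deconvolution of the RI trace into Gaussian components;
centers and widths are then held fixed and per-channel amplitudes obtained
by non-negative linear least squares, mirroring the practice of defining
species on the concentration detector first.

Hydrodynamic radii come from the Einstein viscosity relation for an
equivalent sphere, [eta] M = 2.5 N_A V_h, i.e.
r_h = (3 [eta] M / (10 pi N_A))^(1/3); a Stokes-Einstein helper converts
diffusion coefficients from dynamic light scattering to the same radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .constants import AVOGADRO, BOLTZMANN, PROTEIN_DN_DC
from .calibration import DetectorCalibration, align_interdetector
from .chromatogram import CHANNELS, Chromatogram

__all__ = [
    "PeakRegion",
    "PeakComponent",
    "DeconvolutionError",
    "baseline_correct",
    "detect_peaks",
    "deconvolve",
    "slice_mw",
    "peak_intrinsic_viscosity",
    "peak_dadc",
    "einstein_rh",
    "stokes_einstein_rh",
]


# ---------------------------------------------------------------------------
# Baseline and peak detection


def baseline_correct(volume: np.ndarray, trace: np.ndarray,
                     signal_threshold: float = 0.02,
                     min_free_fraction: float = 0.10,
                     n_iter: int = 8) -> np.ndarray:
    """Subtract a linear baseline fitted to the signal-free part of a trace.

    The baseline is found by asymmetric sigma-clipping: a line is fitted
    to all points, points lying more than two residual standard deviations
    *above* the line (the chromatographic bands) are discarded, and the
    fit is repeated until stable.  Chromatographic signal is one-sided, so
    this converges onto the drifting baseline while ignoring peaks.  If
    fewer than ``min_free_fraction`` of the grid ends up within
    ``signal_threshold`` of the baseline, a warning is issued and the
    trace is returned unchanged (zero baseline).
    """
    volume = np.asarray(volume, dtype=float)
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if np.ptp(trace) == 0.0:
        return trace - trace[0] if trace[0] != 0.0 else trace.copy()

    # rough drift-tolerant line by asymmetric sigma-clipping
    mask = np.ones(n, dtype=bool)
    coeffs = np.polyfit(volume, trace, 1)
    for _ in range(n_iter):
        resid = trace - np.polyval(coeffs, volume)
        sigma = float(np.std(resid[mask]))
        if sigma <= 1e-12 * max(np.ptp(trace), 1.0):
            break
        new_mask = resid < 2.0 * sigma
        if new_mask.sum() < 2 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
        coeffs = np.polyfit(volume[mask], trace[mask], 1)
    detrended = trace - np.polyval(coeffs, volume)

    # locate the band envelope on a lightly smoothed detrended trace and
    # keep only the contiguous leading/trailing flanks (with a margin so
    # band tails do not bias the final fit)
    win = max(min(n // 40, 25), 1)
    smooth = np.convolve(detrended, np.ones(win) / win, mode="same")
    top = float(np.max(smooth))
    if top <= 0:
        return detrended
    above = np.flatnonzero(smooth > signal_threshold * top)
    step = volume[1] - volume[0]
    trim = int(round(0.5 / step))
    left_stop = max(above[0] - trim, 0) if len(above) else n
    right_start = min(above[-1] + 1 + trim, n) if len(above) else n
    free = np.zeros(n, dtype=bool)
    free[:left_stop] = True
    free[right_start:] = True
    if np.count_nonzero(free) < min_free_fraction * n:
        warnings.warn("no signal-free region found; zero baseline applied",
                      stacklevel=2)
        return trace.copy()
    slope, intercept = np.polyfit(volume[free], trace[free], 1)
    corrected = trace - (intercept + slope * volume)
    # a genuine baseline is flat in the flanks; a band too broad for the
    # window leaves curved wings there instead
    flank_spread = float(np.std(corrected[free]))
    if flank_spread > 0.05 * float(np.max(corrected)):
        warnings.warn("no signal-free region found; zero baseline applied",
                      stacklevel=2)
        return trace.copy()
    return corrected


@dataclass(frozen=True)
class PeakRegion:
    start: int
    stop: int        # exclusive
    apex: int
    apex_volume: float


def detect_peaks(volume: np.ndarray, trace: np.ndarray,
                 prominence_frac: float = 0.01) -> list[PeakRegion]:
    """Local maxima above a prominence threshold; regions split at minima."""
    trace = np.asarray(trace, dtype=float)
    top = float(np.max(trace))
    if top <= 0:
        return []
    peaks, _ = find_peaks(trace, prominence=prominence_frac * top)
    if len(peaks) == 0:
        return []
    boundaries = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        boundaries.append(left + int(np.argmin(trace[left:right + 1])))
    boundaries.append(len(trace))
    return [PeakRegion(b0, b1, p, float(volume[p]))
            for b0, b1, p in zip(boundaries[:-1], boundaries[1:], peaks)]


# ---------------------------------------------------------------------------
# Deconvolution


@dataclass
class PeakComponent:
    """One Gaussian component shared across channels.

    ``areas`` maps each channel to the component's integrated signal in
    that channel's detector units.
    """

    center_ml: float
    width_ml: float
    areas: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    def profile(self, grid: np.ndarray, channel: str = "RI") -> np.ndarray:
        z = (grid - self.center_ml) / self.width_ml
        return self.areas[channel] * np.exp(-0.5 * z * z) / (
            self.width_ml * math.sqrt(2 * math.pi))


class DeconvolutionError(RuntimeError):
    def __init__(self, message: str, components: Optional[list] = None,
                 diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.components = components or []
        self.diagnostics = diagnostics or {}


def _gaussian_basis(grid: np.ndarray, centers: Sequence[float],
                    widths: Sequence[float]) -> np.ndarray:
    cols = []
    for c, w in zip(centers, widths):
        z = (grid - c) / w
        cols.append(np.exp(-0.5 * z * z) / (w * math.sqrt(2 * math.pi)))
    return np.column_stack(cols)


def _merge_centers(centers: Sequence[float], merge_tol: float) -> list[float]:
    merged: list[list[float]] = []
    for c in sorted(centers):
        if merged and c - merged[-1][-1] < merge_tol:
            merged[-1].append(c)
        else:
            merged.append([c])
    return [float(np.mean(group)) for group in merged]


def deconvolve(chrom: Chromatogram,
               init_centers: Optional[Sequence[float]] = None,
               n_components: Optional[int] = None,
               width_init: float = 0.35,
               center_window: float = 0.25,
               width_bounds: tuple[float, float] = (0.12, 0.8),
               merge_tol: float = 0.05,
               share_width: bool = False,
               max_nfev: int = 20000) -> list[PeakComponent]:
    """Fit the RI trace as a sum of Gaussians, then resolve every channel.

    Initial centers come either from ``init_centers`` (e.g. expected
    elution volumes of candidate compositions; near-coincident entries are
    merged) or from peak detection (optionally truncated to
    ``n_components`` most prominent peaks).  Centers may move within
    ``center_window`` mL of their start; widths are bounded.  After the RI
    fit, centers and widths are frozen and the remaining channels receive
    non-negative least-squares amplitudes.

    ``share_width=True`` constrains all components to one common width —
    appropriate when band dispersion is uniform across the elution window
    — which stabilises area partitioning between overlapping neighbours.
    """
    grid = chrom.volume
    ri = chrom["RI"]
    if init_centers is None:
        regions = detect_peaks(grid, ri)
        if not regions:
            raise DeconvolutionError("no peaks detected on the RI channel")
        regions.sort(key=lambda r: ri[r.apex], reverse=True)
        if n_components is not None:
            regions = regions[:n_components]
        centers = sorted(r.apex_volume for r in regions)
    else:
        centers = _merge_centers(list(init_centers), merge_tol)
    n = len(centers)

    basis0 = _gaussian_basis(grid, centers, [width_init] * n)
    a0, _ = nnls(basis0, np.clip(ri, 0.0, None))

    params = lmfit.Parameters()
    for i, (c, a) in enumerate(zip(centers, a0)):
        params.add(f"a{i}", value=max(a, 1e-12), min=0.0)
        params.add(f"c{i}", value=c, min=c - center_window, max=c + center_window)
        if share_width and i > 0:
            params.add(f"s{i}", expr="s0")
        else:
            params.add(f"s{i}", value=width_init,
                       min=width_bounds[0], max=width_bounds[1])

    def residual(p):
        model = np.zeros_like(grid)
        for i in range(n):
            z = (grid - p[f"c{i}"]) / p[f"s{i}"]
            model += p[f"a{i}"] * np.exp(-0.5 * z * z) / (
                p[f"s{i}"] * math.sqrt(2 * math.pi))
        return model - ri

    result = lmfit.minimize(residual, params, method="least_squares",
                            max_nfev=max_nfev)
    signal_norm = float(np.linalg.norm(ri))
    resid_norm = float(np.linalg.norm(result.residual))
    diagnostics = {
        "success": bool(result.success),
        "nfev": int(result.nfev),
        "residual_norm": resid_norm,
        "relative_residual": resid_norm / signal_norm if signal_norm else math.nan,
        "n_components": n,
    }
    fit_centers = [float(result.params[f"c{i}"]) for i in range(n)]
    fit_widths = [float(result.params[f"s{i}"]) for i in range(n)]
    fit_areas = [float(result.params[f"a{i}"]) for i in range(n)]
    components = [
        PeakComponent(c, w, {"RI": a}, dict(diagnostics))
        for c, w, a in zip(fit_centers, fit_widths, fit_areas)
    ]
    if not result.success:
        raise DeconvolutionError(
            f"deconvolution did not converge: {result.message}",
            components, diagnostics)

    basis = _gaussian_basis(grid, fit_centers, fit_widths)
    for ch in CHANNELS:
        if ch == "RI":
            continue
        # amplitudes constrained non-negative; the trace itself keeps its
        # noise excursions (rectifying them would bias weak components)
        amps, _ = nnls(basis, chrom[ch])
        for comp, a in zip(components, amps):
            comp.areas[ch] = float(a)
    components.sort(key=lambda comp: comp.center_ml)
    return components


# ---------------------------------------------------------------------------
# Physical-parameter inversion


def slice_mw(chrom: Chromatogram, calibration: DetectorCalibration,
             dn_dc: float = PROTEIN_DN_DC,
             region: Optional[slice] = None,
             include_threshold: float = 0.05
             ) -> tuple[np.ndarray, float]:
    """Slice-wise Mw trace and the concentration-weighted peak average.

    Mw(v) = [LS(v)/k_LS] / [c(v) dn/dc^2] with c(v) = RI(v)/(k_RI dn/dc),
    evaluated for RALS and LALS and averaged.  Slices with RI below
    ``include_threshold`` of the regional maximum are excluded (NaN in the
    returned trace) to bound noise amplification in the channel ratio.
    """
    sl = region if region is not None else slice(None)
    ri = chrom["RI"][sl]
    k = calibration.constants
    conc = ri / (k["RI"] * dn_dc)
    with np.errstate(divide="ignore", invalid="ignore"):
        mw_rals = (chrom["RALS"][sl] / k["RALS"]) / (conc * dn_dc ** 2)
        mw_lals = (chrom["LALS"][sl] / k["LALS"]) / (conc * dn_dc ** 2)
        mw = 0.5 * (mw_rals + mw_lals)
    top = float(np.max(ri)) if len(ri) else 0.0
    if top <= 0:
        return np.full_like(ri, np.nan), math.nan
    included = ri >= include_threshold * top
    mw = np.where(included, mw, np.nan)
    weight = np.where(included, conc, 0.0)
    peak_mw = float(np.nansum(np.where(included, mw * weight, 0.0)) / np.sum(weight))
    return mw, peak_mw


def component_concentration_mass(ri_area: float,
                                 calibration: DetectorCalibration,
                                 dn_dc: float = PROTEIN_DN_DC) -> float:
    """Injected mass (mg) of a component from its RI area."""
    return ri_area / (calibration.constants["RI"] * dn_dc)


def component_mw(areas: dict[str, float], calibration: DetectorCalibration,
                 dn_dc: float = PROTEIN_DN_DC) -> float:
    """Weight-average Mw (kDa) of a component from LS/RI area ratios."""
    mass = component_concentration_mass(areas["RI"], calibration, dn_dc)
    if mass <= 0:
        return math.nan
    k = calibration.constants
    mw_rals = areas["RALS"] / k["RALS"] / (mass * dn_dc ** 2)
    mw_lals = areas["LALS"] / k["LALS"] / (mass * dn_dc ** 2)
    if mw_rals > 0 and mw_lals > 0:
        if abs(mw_rals - mw_lals) / (0.5 * (mw_rals + mw_lals)) > 0.02:
            warnings.warn("RALS/LALS disagree by > 2%; size regime may violate "
                          "the P(theta)=1 assumption", stacklevel=2)
    return 0.5 * (mw_rals + mw_lals)


def peak_intrinsic_viscosity(dp_area: float, ri_area: float,
                             calibration: DetectorCalibration,
                             dn_dc: float = PROTEIN_DN_DC) -> float:
    """[eta] (mL/g) from viscometer and RI areas of one component."""
    mass = component_concentration_mass(ri_area, calibration, dn_dc)
    if mass <= 0:
        raise ValueError("non-positive RI area; concentration undefined")
    return dp_area / calibration.constants["DP"] / mass


def peak_dadc(uv_area: float, ri_area: float,
              calibration: DetectorCalibration,
              dn_dc: float = PROTEIN_DN_DC) -> float:
    """dA/dc (mL g^-1 cm^-1) by matching RI- and UV-derived concentration."""
    mass = component_concentration_mass(ri_area, calibration, dn_dc)
    if mass <= 0:
        raise ValueError("non-positive RI area; concentration undefined")
    return uv_area / calibration.constants["UV280"] / mass


def einstein_rh(mw_kda: float, intrinsic_viscosity: float) -> float:
    """Equivalent-sphere hydrodynamic radius (nm) from [eta] and Mw.

    r_h = (3 [eta] M / (10 pi N_A))^(1/3) with [eta] in mL/g and
    M in g/mol; the hydrodynamic volume obeys [eta] M = 2.5 N_A V_h.
    """
    if mw_kda <= 0 or intrinsic_viscosity <= 0:
        raise ValueError("mw_kda and intrinsic_viscosity must be positive")
    m_g_mol = mw_kda * 1000.0
    vol_cm3 = 3.0 * intrinsic_viscosity * m_g_mol / (10.0 * math.pi * AVOGADRO)
    return vol_cm3 ** (1.0 / 3.0) * 1e7  # cm -> nm


def stokes_einstein_rh(diffusion_m2_s: float, temperature_k: float,
                       solvent_viscosity_pa_s: float) -> float:
    """Hydrodynamic radius (nm) from a translational diffusion coefficient."""
    if min(diffusion_m2_s, temperature_k, solvent_viscosity_pa_s) <= 0:
        raise ValueError("all inputs must be positive")
    r_m = BOLTZMANN * temperature_k / (
        6.0 * math.pi * solvent_viscosity_pa_s * diffusion_m2_s)
    return r_m * 1e9
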