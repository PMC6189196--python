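"""Solution-marker mediated particle sizing.

The sharp marker band (perchlorate, 938 cm^-1) reports how much solution a
trapped particle displaces from the confocal volume.  The marker ratio
(A_t - A_p) / A_p — total spectral area over marker band area — rises with
particle volume; calibrating mean ratios of reference sizes against log
volume gives a per-particle size estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ramantrap.spectra import Band, Spectrum, band_area

MARKER_BAND = Band("perchlorate", 938.0, 15.0)


@dataclass
class PerchlorateRatio:
    """Marker displacement ratio with its area components."""

    total_area: float  # A_t: full-axis trapezoidal area (baseline-subtracted)
    marker_area: float  # A_p: marker band area
    ratio: float
    warning: str | None = None


def perchlorate_ratio(spectrum: Spectrum, band: Band = MARKER_BAND) -> PerchlorateRatio:
    """Compute (A_t - A_p) / A_p on a baseline-subtracted, NOT normalised spectrum.

    The ratio goes to zero for a particle-free trap (A_t -> A_p) and grows
    without bound as the particle fills the trap (A_p -> 0).  A negative
    ratio (noise pushing A_t below A_p) is returned with a warning.
    """
    a_t = spectrum.total_area()
    a_p = band_area(spectrum, band)
    if a_p <= 0:
        raise ValueError("no marker signal: marker band area <= 0")
    ratio = (a_t - a_p) / a_p
    warning = "negative ratio (A_t < A_p): noise-dominated" if ratio < 0 else None
    return PerchlorateRatio(a_t, a_p, ratio, warning)


@dataclass
class CalibrationFit:
    """OLS fit of mean marker ratio against log10(particle volume, nm^3)."""

    slope: float
    intercept: float
    r_squared: float
    reference_diameters: np.ndarray
    reference_ratios: np.ndarray

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(np.min(self.reference_ratios)), float(np.max(self.reference_ratios))


def volume_nm3(diameter_nm: np.ndarray | float) -> np.ndarray | float:
    return np.pi / 6.0 * np.asarray(diameter_nm, dtype=float) ** 3


def fit_calibration(mean_ratios, diameters_nm) -> CalibrationFit:
    """Least-squares calibration line from >= 3 reference sizes."""
    ratios = np.asarray(mean_ratios, dtype=float)
    diameters = np.asarray(diameters_nm, dtype=float)
    if ratios.size != diameters.size:
        raise ValueError("ratio and diameter arrays differ in length")
    if np.unique(diameters).size < 3:
        raise ValueError("calibration needs >= 3 distinct reference sizes")
    log_volume = np.log10(volume_nm3(diameters))
    if np.ptp(log_volume) == 0:
        raise ValueError("zero volume spread")
    result = stats.linregress(log_volume, ratios)
    return CalibrationFit(
        float(result.slope),
        float(result.intercept),
        float(result.rvalue**2),
        diameters,
        ratios,
    )


@dataclass
class SizeEstimate:
    diameter_nm: float
    volume_nm3: float
    extrapolated: bool


def estimate_size(
    ratio: PerchlorateRatio | float,
    fit: CalibrationFit,
    guard: float = 0.5,
) -> SizeEstimate:
    """Invert the calibration line: V = 10^((ratio - intercept)/slope), d = (6V/pi)^(1/3).

    Ratios farther than ``guard`` times the calibration ratio span outside
    the calibrated range are flagged as extrapolated (still returned).
    """
    value = ratio.ratio if isinstance(ratio, PerchlorateRatio) else float(ratio)
    if fit.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert")
    volume = 10.0 ** ((value - fit.intercept) / fit.slope)
    diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    lo, hi = fit.ratio_range
    span = hi - lo
    extrapolated = value < lo - guard * span or value > hi + guard * span
    return SizeEstimate(float(diameter), float(volume), extrapolated)


@dataclass
class SizeDistribution:
    diameters_nm: np.ndarray
    mean: float
    sd: float
    pdi: float  # (sd / mean)^2
    hist_counts: np.ndarray
    bin_edges: np.ndarray


def distribution_stats(diameters_nm, bin_edges=None) -> SizeDistribution:
    """Mean, s.d. (n-1), PDI = (s.d./mean)^2 and a histogram on given edges."""
    diameters = np.asarray(diameters_nm, dtype=float)
    if diameters.size == 0:
        raise ValueError("empty size list")
    if np.any(diameters <= 0):
        raise ValueError("diameters must be > 0")
    mean = float(np.mean(diameters))
    sd = float(np.std(diameters, ddof=1)) if diameters.size > 1 else 0.0
    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(diameters, bins=10)
    counts, edges = np.histogram(diameters, bins=bin_edges)
    return SizeDistribution(diameters, mean, sd, (sd / mean) ** 2, counts, edges)


def size_population(
    ratios, fit: CalibrationFit, bin_edges=None
) -> tuple[np.ndarray, SizeDistribution]:
    """Invert every ratio and summarise the resulting size distribution."""
    estimates = np.array([estimate_size(r, fit).diameter_nm for r in np.asarray(ratios)])
    return estimates, distribution_stats(estimates, bin_edges)
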