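"""Time-resolved band traces for on-particle reaction monitoring.

Supports two sampling modes: repeatedly trapping fresh particles from the
population at successive time points, or holding one particle for the
whole reaction.  Traces of reactant and product band intensities are
min-max scaled per band; completion is read off the product trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ramantrap.spectra import Band, Spectrum, band_intensity


@dataclass
class TimeTrace:
    timestamps: np.ndarray  # s, strictly increasing
    raw: dict[str, np.ndarray]  # per-band raw intensities
    scaled: dict[str, np.ndarray]  # per-band min-max scaled to [0, 1]
    mode: str  # "population" | "hold"
    trap_identities: np.ndarray | None = None
    zero_range_bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.timestamps}
        for name, series in self.scaled.items():
            data[name] = series
        return pd.DataFrame(data)


def extract_trace(
    spectra: list[Spectrum],
    timestamps,
    bands: list[Band],
    mode: str = "population",
    trap_identities=None,
) -> TimeTrace:
    """Band-intensity time series from a chronological spectrum list.

    Each band series is min-max scaled over the trace; a zero-range band
    (constant signal) is flagged rather than divided by zero.
    """
    if mode not in ("population", "hold"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(spectra) < 3:
        raise ValueError("need >= 3 time points")
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size != len(spectra):
        raise ValueError("timestamps and spectra lengths differ")
    order = np.argsort(timestamps)
    timestamps = timestamps[order]
    spectra = [spectra[i] for i in order]

    raw: dict[str, np.ndarray] = {}
    scaled: dict[str, np.ndarray] = {}
    zero_range = []
    for band in bands:
        series = np.array([band_intensity(s, band) for s in spectra])
        raw[band.name] = series
        span = np.ptp(series)
        if span == 0:
            zero_range.append(band.name)
            scaled[band.name] = np.zeros_like(series)
        else:
            scaled[band.name] = (series - series.min()) / span
    identities = None
    if trap_identities is not None:
        identities = np.asarray(trap_identities)[order]
    return TimeTrace(
        timestamps, raw, scaled, mode, identities, tuple(zero_range)
    )


@dataclass
class CompletionResult:
    time_s: float | None
    reached: bool
    threshold: float


def completion_time(
    trace: TimeTrace, band: str, threshold: float = 0.95
) -> CompletionResult:
    """First time the scaled product intensity reaches ``threshold``.

    Linear interpolation between bracketing samples; never reaching the
    threshold yields an undefined (flagged) result.
    """
    series = trace.scaled[band]
    t = trace.timestamps
    above = series >= threshold
    if not above.any():
        return CompletionResult(None, False, threshold)
    i = int(np.argmax(above))
    if i == 0 or threshold <= 0:
        return CompletionResult(float(t[i]), True, threshold)
    t0, t1 = t[i - 1], t[i]
    y0, y1 = series[i - 1], series[i]
    frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 1.0
    return CompletionResult(float(t0 + frac * (t1 - t0)), True, threshold)


@dataclass
class BandStability:
    relative_sd: float
    slope: float  # per second, on the scaled series
    p_value: float
    stable: bool


@dataclass
class StabilityReport:
    per_band: dict[str, BandStability]
    stable: bool
    alpha: float


def stability_check(
    trace: TimeTrace,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> StabilityReport:
    """Photostability verdict: no band shows a significant linear drift.

    Per band: relative s.d. of the raw intensities plus a least-squares
    slope with a permutation p-value; "stable" when no slope is significant
    at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    t = trace.timestamps
    per_band: dict[str, BandStability] = {}
    all_stable = True
    for name, raw in trace.raw.items():
        mean = np.mean(raw)
        rel_sd = float(np.std(raw, ddof=1) / mean) if mean != 0 else float("inf")
        slope = float(np.polyfit(t, raw, 1)[0])
        count = 0
        for _ in range(n_permutations):
            perm_slope = float(np.polyfit(t, rng.permutation(raw), 1)[0])
            if abs(perm_slope) >= abs(slope) - 1e-18:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        stable = p >= alpha
        all_stable &= stable
        per_band[name] = BandStability(rel_sd, slope, float(p), stable)
    return StabilityReport(per_band, all_stable, alpha)
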