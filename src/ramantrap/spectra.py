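"""Spectrum container, file I/O and the standard preprocessing chain.

The chain applied to every acquired spectrum is: truncation to the analysis
range, cosmic-spike removal, asymmetric-least-squares baseline subtraction
(Whittaker smoother), Savitzky-Golay smoothing and area normalisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.signal import savgol_coeffs
from scipy.sparse.linalg import spsolve


class SpectrumParseError(ValueError):
    """A spectrum file contains a row that cannot be parsed."""


class SpectrumFormatError(ValueError):
    """A spectrum violates structural requirements (axis shape, monotonicity)."""


@dataclass
class SpectrumMeta:
    """Acquisition metadata carried alongside the signal."""

    integration_time: float = 1.0
    timestamp: float = 0.0
    iteration_number: int = 0
    label: str = ""


@dataclass
class Spectrum:
    """A single Raman spectrum: wavenumber axis (cm^-1) plus CCD counts.

    The axis is strictly increasing with approximately uniform spacing.
    Raw spectra have non-negative counts; baseline-subtracted spectra may
    dip below zero.
    """

    axis: np.ndarray
    counts: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.axis.ndim != 1 or self.counts.ndim != 1:
            raise SpectrumFormatError("axis and counts must be 1-D")
        if self.axis.size != self.counts.size:
            raise SpectrumFormatError(
                f"axis ({self.axis.size}) and counts ({self.counts.size}) lengths differ"
            )
        if self.axis.size < 2:
            raise SpectrumFormatError("spectrum needs at least 2 channels")
        if not np.all(np.diff(self.axis) > 0):
            raise SpectrumFormatError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size

    def with_counts(self, counts: np.ndarray) -> "Spectrum":
        return replace(self, counts=np.asarray(counts, dtype=float))

    def total_area(self) -> float:
        """Trapezoidal integral of counts over the full axis."""
        return float(np.trapezoid(self.counts, self.axis))


@dataclass(frozen=True)
class Band:
    """A named integration window [center - half_width, center + half_width]."""

    name: str
    center: float
    half_width: float = 15.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError(f"band {self.name!r}: half_width must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass
class PreprocessConfig:
    """Parameters of the standard preprocessing chain.

    Defaults follow the standard analysis recipe: 350-1825 cm^-1 truncation,
    Whittaker baseline with lambda = 1e5, 3-point first-order Savitzky-Golay
    smoothing and area normalisation.  Deuterium/alkyne scenarios use the
    extended 606-2254 cm^-1 range instead.
    """

    truncate_lo: float = 350.0
    truncate_hi: float = 1825.0
    whittaker_lambda: float = 1.0e5
    whittaker_asymmetry: float = 0.001
    whittaker_iterations: int = 10
    savgol_window: int = 3
    savgol_order: int = 1
    spike_z_threshold: float = 8.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.truncate_lo >= self.truncate_hi:
            raise ValueError("truncation range is empty")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if not 0.0 < self.whittaker_asymmetry < 1.0:
            raise ValueError("whittaker_asymmetry must be in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# File I/O


def _parse_two_column(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    axis, counts = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if lineno == 1 and any(not _is_number(p) for p in parts):
            continue  # optional header row
        if len(parts) < 2 or not all(_is_number(p) for p in parts[:2]):
            raise SpectrumParseError(f"{path}: cannot parse line {lineno}: {line!r}")
        axis.append(float(parts[0]))
        counts.append(float(parts[1]))
    return np.array(axis), np.array(counts)


def _is_number(token: str) -> bool:
    try:
        value = float(token)
    except ValueError:
        return False
    return np.isfinite(value)


def read_spectrum(path: str | Path, dialect: str = "two_column") -> Spectrum:
    """Read a spectrum from delimited text (wavenumber, counts).

    A descending axis is re-sorted ascending with counts permuted alongside.
    ``dialect`` must be ``"two_column"``; use :func:`read_spectra_matrix` for
    the matrix layout.
    """
    if dialect != "two_column":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    axis, counts = _parse_two_column(path.read_text().splitlines(), str(path))
    if axis.size < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    order = np.argsort(axis)
    axis, counts = axis[order], counts[order]
    if np.any(np.diff(axis) <= 0):
        raise SpectrumFormatError(f"{path}: axis not strictly monotone after sorting")
    return Spectrum(axis, counts)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write two-column text; values round-trip to >= 9 significant digits."""
    rows = "\n".join(
        f"{w:.12g},{c:.12g}" for w, c in zip(spectrum.axis, spectrum.counts)
    )
    Path(path).write_text("wavenumber_cm1,counts\n" + rows + "\n")


def read_spectra_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a matrix CSV (column 1 = wavenumber, one column per spectrum).

    Returns ``(axis, counts)`` with counts shaped (n_spectra, n_channels).
    """
    import pandas as pd

    frame = pd.read_csv(path)
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    counts = frame.iloc[:, 1:].to_numpy(dtype=float).T
    order = np.argsort(axis)
    return axis[order], counts[:, order]


def write_spectra_matrix(axis: np.ndarray, counts: np.ndarray, path: str | Path) -> None:
    import pandas as pd

    counts = np.atleast_2d(counts)
    data = {"wavenumber_cm1": axis}
    for i, row in enumerate(counts):
        data[f"spectrum_{i}"] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Preprocessing operations


def truncate(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep exactly the channels with lo <= wavenumber <= hi."""
    if lo >= hi:
        raise ValueError("truncate: lo must be < hi")
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if not mask.any():
        raise ValueError("truncation removes all channels")
    return Spectrum(spectrum.axis[mask], spectrum.counts[mask], spectrum.meta)


@dataclass
class SpikeRemovalResult:
    spectrum: Spectrum
    repaired: list[int]
    warning: str | None = None


def remove_cosmic_spikes(spectrum: Spectrum, z_threshold: float = 8.0) -> SpikeRemovalResult:
    """Detect and repair cosmic-ray spikes.

    A channel is flagged when the modified z-score (median/MAD) of the
    second difference of the counts exceeds ``z_threshold`` and its counts
    exceed the local 7-channel median (amplitude guard).  Flagged channels
    are replaced by linear interpolation between the nearest unflagged
    neighbours.  If more than 10% of channels are flagged a warning is
    attached (the features are probably not spikes) but nothing is dropped.
    """
    y = spectrum.counts
    n = y.size
    if n < 5:
        raise ValueError("spike removal needs >= 5 channels")

    d2 = np.zeros(n)
    d2[1:-1] = y[:-2] - 2.0 * y[1:-1] + y[2:]
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    if mad == 0.0:
        mad = np.mean(np.abs(d2 - med)) or 1.0
    mz = 0.6745 * (d2 - med) / mad

    local_med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 3), min(n, i + 4)
        local_med[i] = np.median(y[lo:hi])

    flagged = (np.abs(mz) > z_threshold) & (y > local_med)
    idx = np.flatnonzero(flagged)
    warning = None
    if idx.size > 0.1 * n:
        warning = f"{idx.size}/{n} channels flagged; features may not be spikes"
    if idx.size == 0:
        return SpikeRemovalResult(spectrum.with_counts(y.copy()), [], warning)

    good = np.flatnonzero(~flagged)
    repaired = y.copy()
    repaired[idx] = np.interp(spectrum.axis[idx], spectrum.axis[good], y[good])
    return SpikeRemovalResult(spectrum.with_counts(repaired), idx.tolist(), warning)


@dataclass
class BaselineResult:
    spectrum: Spectrum
    baseline: np.ndarray
    converged: bool


def whittaker_asls(
    y: np.ndarray, lam: float, p: float, n_iter: int = 10
) -> tuple[np.ndarray, bool]:
    """Asymmetric-least-squares Whittaker baseline.

    Minimises sum w_i (y_i - z_i)^2 + lam * sum (D2 z)^2 with asymmetric
    weights w_i = p for y_i > z_i else 1 - p, re-estimated for ``n_iter``
    passes.  Returns the baseline and a convergence flag (weights stable).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    diff2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (diff2.T @ diff2)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(n_iter):
        weight_mat = sparse.diags(w, format="csc")
        z = spsolve(weight_mat + penalty, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    return z, converged


def subtract_baseline(
    spectrum: Spectrum,
    lam: float = 1.0e5,
    p: float = 0.001,
    n_iter: int = 10,
) -> BaselineResult:
    """Subtract the fluorescence background via asymmetric Whittaker smoothing."""
    baseline, converged = whittaker_asls(spectrum.counts, lam, p, n_iter)
    return BaselineResult(spectrum.with_counts(spectrum.counts - baseline), baseline, converged)


def savgol_smooth(spectrum: Spectrum, window: int = 3, order: int = 1) -> Spectrum:
    """Savitzky-Golay smoothing; edge windows shrink symmetrically.

    Interior channels use the standard least-squares polynomial convolution
    (for window 3 / order 1 this is a 3-point moving average).  Near the
    edges the window shrinks to the largest symmetric window that fits, with
    the polynomial order capped accordingly, leaving the end channels
    unchanged for the default 3-point filter.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    y = spectrum.counts
    n = y.size
    half = window // 2
    out = y.astype(float).copy()
    if n >= window:
        coeffs = savgol_coeffs(window, order)
        out[half : n - half] = np.convolve(y, coeffs[::-1], mode="valid")
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        k = min(i, n - 1 - i, half)
        if k == 0:
            continue
        win = 2 * k + 1
        eff_order = min(order, win - 1)
        c = savgol_coeffs(win, eff_order)
        out[i] = float(np.dot(c[::-1], y[i - k : i + k + 1]))
    return spectrum.with_counts(out)


def auc_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale counts so the trapezoidal integral over the axis equals 1."""
    area = spectrum.total_area()
    if area <= 0:
        raise ValueError("cannot normalise: non-positive total area")
    return spectrum.with_counts(spectrum.counts / area)


def _check_window(spectrum: Spectrum, band: Band) -> np.ndarray:
    if band.lo < spectrum.axis[0] or band.hi > spectrum.axis[-1]:
        raise ValueError(
            f"band {band.name!r} window [{band.lo}, {band.hi}] outside spectrum axis "
            f"[{spectrum.axis[0]}, {spectrum.axis[-1]}]"
        )
    return (spectrum.axis >= band.lo) & (spectrum.axis <= band.hi)


def band_intensity(spectrum: Spectrum, band: Band) -> float:
    """Maximum counts within the band window."""
    mask = _check_window(spectrum, band)
    return float(np.max(spectrum.counts[mask]))


def band_area(spectrum: Spectrum, band: Band) -> float:
    """Trapezoidal integral of counts over the band window."""
    mask = _check_window(spectrum, band)
    return float(np.trapezoid(spectrum.counts[mask], spectrum.axis[mask]))


@dataclass
class PreprocessResult:
    spectrum: Spectrum
    baseline: np.ndarray
    repaired_channels: list[int]
    spike_warning: str | None
    baseline_converged: bool


def preprocess(spectrum: Spectrum, config: PreprocessConfig | None = None) -> PreprocessResult:
    """Run the full standard chain: truncate, despike, baseline, smooth, normalise."""
    cfg = config or PreprocessConfig()
    s = truncate(spectrum, cfg.truncate_lo, cfg.truncate_hi)
    despiked = remove_cosmic_spikes(s, cfg.spike_z_threshold)
    base = subtract_baseline(
        despiked.spectrum,
        cfg.whittaker_lambda,
        cfg.whittaker_asymmetry,
        cfg.whittaker_iterations,
    )
    s = savgol_smooth(base.spectrum, cfg.savgol_window, cfg.savgol_order)
    if cfg.normalize:
        s = auc_normalize(s)
    return PreprocessResult(
        s, base.baseline, despiked.repaired, despiked.warning, base.converged
    )
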