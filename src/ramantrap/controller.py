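"""Trap-recognition acquisition state machine.

Alternates short "iteration" acquisitions (occupancy probes) with long
high-SNR acquisitions once a characteristic band crosses a calibrated
threshold, disabling the laser between attempts so the analysed particle
can diffuse away.  Every success is logged with its iteration number for
post-hoc verification of the disabling time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ramantrap.spectra import Band, Spectrum, band_intensity


class CalibrationError(RuntimeError):
    """Threshold calibration could not observe an occupied trap."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """User-set acquisition parameters."""

    n_a: int  # target number of successful acquisitions
    t_iter: float = 1.0  # s, occupancy-probe acquisition
    t_acq: float = 10.0  # s, high-SNR acquisition
    t_off: float = 0.5  # s, laser disabling between attempts
    max_iterations: int = 10
    max_cycles: int | None = None  # instrument-exhaustion bound

    def __post_init__(self) -> None:
        if self.n_a < 1:
            raise ValueError("n_a must be >= 1")
        if min(self.t_iter, self.t_acq) <= 0 or self.t_off < 0:
            raise ValueError("acquisition times must be positive (t_off >= 0)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class TrapThreshold:
    """Characteristic band and the intensity that defines a successful trap."""

    band: Band
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("threshold intensity must be > 0")


@dataclass
class TrapRecord:
    trap_index: int
    iteration_number: int
    timestamp: float
    t_iter: float
    t_acq: float
    t_off: float
    threshold: float
    band_center: float
    spectrum: Spectrum | None = None
    spectrum_file: str = ""
    identity: int | None = None  # generator ground truth, None on real logs
    post_threshold_pass: bool = True

    def to_json_dict(self) -> dict:
        return {
            "trap_index": self.trap_index,
            "iteration_number": self.iteration_number,
            "timestamp_s": self.timestamp,
            "t_iter_s": self.t_iter,
            "t_acq_s": self.t_acq,
            "t_off_s": self.t_off,
            "threshold_counts": self.threshold,
            "band_center_cm1": self.band_center,
            "spectrum_file": self.spectrum_file,
            "post_threshold_pass": self.post_threshold_pass,
        }


@dataclass
class TrappingLog:
    records: list[TrapRecord] = field(default_factory=list)
    unsuccessful_cycles: int = 0
    total_cycles: int = 0
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def iteration_numbers(self) -> list[int]:
        return [r.iteration_number for r in self.records]

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for record in self.records:
                fh.write(json.dumps(record.to_json_dict()) + "\n")

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "TrappingLog":
        records = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                TrapRecord(
                    trap_index=obj["trap_index"],
                    iteration_number=obj["iteration_number"],
                    timestamp=obj["timestamp_s"],
                    t_iter=obj["t_iter_s"],
                    t_acq=obj["t_acq_s"],
                    t_off=obj["t_off_s"],
                    threshold=obj["threshold_counts"],
                    band_center=obj["band_center_cm1"],
                    spectrum_file=obj.get("spectrum_file", ""),
                    post_threshold_pass=obj.get("post_threshold_pass", True),
                )
            )
        return cls(records=records)


def calibrate_threshold(
    instrument,
    band: Band,
    n_samples: int = 11,
    t_iter: float = 1.0,
    max_attempts: int | None = None,
) -> TrapThreshold:
    """Trap an initial particle and take the median band height as threshold.

    Collects ``n_samples`` occupied-trap iteration spectra (the virtual
    instrument exposes ground-truth occupancy); fails if none appears within
    ``max_attempts`` iteration acquisitions.
    """
    max_attempts = max_attempts or 50 * n_samples
    heights = []
    for _ in range(max_attempts):
        spectrum = instrument.iteration_spectrum(t_iter)
        if getattr(instrument, "occupied", True):
            heights.append(band_intensity(spectrum, band))
            if len(heights) >= n_samples:
                break
    if not heights:
        raise CalibrationError(
            f"no occupied trap within {max_attempts} calibration attempts"
        )
    return TrapThreshold(band, float(np.median(heights)))


def run_acquisition(
    instrument,
    config: AcquisitionConfig,
    threshold: TrapThreshold,
) -> tuple[TrappingLog, list[Spectrum]]:
    """Run attempt cycles until ``n_a`` successes (or exhaustion).

    Within a cycle up to ``max_iterations`` probes are taken; the first one
    whose band intensity is strictly above the threshold triggers exactly one
    high-SNR acquisition and a log record.  Whether or not the cycle
    succeeds, the laser is disabled for ``t_off`` before the next attempt.
    A bounded number of total cycles guards against exhaustion: hitting it
    returns a partial log flagged as truncated.
    """
    log = TrappingLog()
    spectra: list[Spectrum] = []
    max_cycles = config.max_cycles or 200 * config.n_a
    while len(log.records) < config.n_a:
        if log.total_cycles >= max_cycles:
            log.truncated = True
            break
        log.total_cycles += 1
        success = False
        for iteration in range(1, config.max_iterations + 1):
            probe = instrument.iteration_spectrum(config.t_iter, iteration)
            if band_intensity(probe, threshold.band) > threshold.intensity:
                high_snr = instrument.acquire(config.t_acq, iteration)
                record = TrapRecord(
                    trap_index=len(log.records),
                    iteration_number=iteration,
                    timestamp=high_snr.meta.timestamp,
                    t_iter=config.t_iter,
                    t_acq=config.t_acq,
                    t_off=config.t_off,
                    threshold=threshold.intensity,
                    band_center=threshold.band.center,
                    spectrum=high_snr,
                    identity=getattr(instrument, "current_identity", None),
                )
                log.records.append(record)
                spectra.append(high_snr)
                success = True
                break
        if not success:
            log.unsuccessful_cycles += 1
        instrument.disable(config.t_off)
    return log, spectra


@dataclass
class IterationSummary:
    histogram: dict[int, int]
    fraction_at_first: float | None
    duplicate_risk: float | None  # alias of the iteration-1 fraction proxy
    n_records: int

    @property
    def undefined(self) -> bool:
        return self.fraction_at_first is None


def iteration_check(log: TrappingLog) -> IterationSummary:
    """Histogram of success iteration numbers and the iteration-1 fraction.

    A high iteration-1 fraction indicates an insufficient disabling time
    (the same particle is likely re-trapped immediately).
    """
    iterations = log.iteration_numbers()
    if not iterations:
        return IterationSummary({}, None, None, 0)
    histogram: dict[int, int] = {}
    for it in iterations:
        histogram[it] = histogram.get(it, 0) + 1
    frac = histogram.get(1, 0) / len(iterations)
    return IterationSummary(histogram, frac, frac, len(iterations))


def post_threshold_filter(
    spectra: list[Spectrum], band: Band, new_threshold: float
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Re-partition saved high-SNR spectra against a stricter threshold.

    Picks out false-positive traps when the live threshold was set too low.
    Order is preserved; kept + rejected is the full input.
    """
    kept, rejected = [], []
    for spectrum in spectra:
        if band_intensity(spectrum, band) > new_threshold:
            kept.append(spectrum)
        else:
            rejected.append(spectrum)
    return kept, rejected


def duplicate_fraction(log: TrappingLog) -> float | None:
    """Fraction of successive records sharing a generator identity tag.

    Only available on simulated logs; returns None when identities are
    absent (real logs fall back to the iteration-1 fraction proxy).
    """
    identities = [r.identity for r in log.records]
    if len(identities) < 2 or any(i is None for i in identities):
        return None
    dup = sum(1 for a, b in zip(identities, identities[1:]) if a == b)
    return dup / (len(identities) - 1)
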