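"""Physics-based virtual instrument and synthetic-data generator.

Renders per-iteration spectra from ground-truth particle state, with
Brownian escape/arrival kinetics, a solution-marker (perchlorate)
volume-displacement law and configurable noise, so the acquisition
controller, sizing and chemometrics stacks are testable without hardware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ramantrap.spectra import Spectrum, SpectrumMeta

BOLTZMANN = 1.380649e-23  # J/K

# Characteristic band positions (cm^-1) used across the synthetic scenarios.
CD_STRETCH = 2105.0
CH2_BEND = 1450.0
PERCHLORATE = 938.0
ALKYNE = 2129.0
AZIDE = 2116.0
TRIAZOLE = 1331.0
SH_BEND = 936.0
SS_STRETCH = (452.0, 512.0)
TYROSINE_RING = (840.0, 860.0)
PDMS_PEAKS = (490.0, 709.0)
HEPARIN_PEAKS = (930.0, 1070.0)


@dataclass(frozen=True)
class ComponentSpectrum:
    """Ground-truth Raman signature of one chemical component.

    Bands are (center cm^-1, FWHM cm^-1, relative amplitude) pseudo-Voigt
    lines; ``scattering_strength`` scales the whole signature per unit
    particle volume (um^3).
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    scattering_strength: float = 2.5e4

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r}: band list empty")
        for center, width, amp in self.bands:
            if width <= 0 or amp <= 0:
                raise ValueError(f"component {self.name!r}: widths and amplitudes must be > 0")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        """Unit-strength signature on ``axis`` (sum of pseudo-Voigt lines)."""
        out = np.zeros_like(axis, dtype=float)
        for center, width, amp in self.bands:
            out += amp * pseudo_voigt(axis, center, width)
        return out


def pseudo_voigt(axis: np.ndarray, center: float, fwhm: float, eta: float = 0.5) -> np.ndarray:
    """Unit-height pseudo-Voigt line: eta*Lorentzian + (1-eta)*Gaussian."""
    x = (axis - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    gauss = np.exp(-4.0 * np.log(2.0) * x * x)
    return eta * lorentz + (1.0 - eta) * gauss


def default_library() -> dict[str, ComponentSpectrum]:
    """Built-in component signatures for all simulation presets."""

    def comp(name, bands, strength=2.5e4):
        return ComponentSpectrum(name, tuple(bands), strength)

    return {
        "water": comp("water", [(1640.0, 90.0, 0.3), (800.0, 250.0, 0.15)], 1.0),
        "perchlorate": comp("perchlorate", [(PERCHLORATE, 8.0, 1.0)], 1.0),
        "dppc": comp(
            "dppc",
            [
                (718.0, 10.0, 0.3),
                (1090.0, 12.0, 0.5),
                (1296.0, 14.0, 0.8),
                (CH2_BEND, 16.0, 1.0),
            ],
        ),
        "d_dppc": comp(
            "d_dppc",
            [
                (718.0, 10.0, 0.3),
                (1090.0, 12.0, 0.5),
                (1296.0, 14.0, 0.4),
                (CH2_BEND, 16.0, 0.5),
                (CD_STRETCH, 14.0, 1.2),
            ],
        ),
        "polystyrene": comp(
            "polystyrene",
            [
                (620.0, 8.0, 0.4),
                (1001.0, 6.0, 1.0),
                (1031.0, 8.0, 0.5),
                (CH2_BEND, 12.0, 0.4),
                (1602.0, 10.0, 0.6),
            ],
        ),
        "pdms": comp(
            "pdms",
            [(PDMS_PEAKS[0], 14.0, 1.0), (PDMS_PEAKS[1], 12.0, 0.8), (1410.0, 14.0, 0.3)],
        ),
        # integrated strengths per unit weight kept close to pdms so that
        # normalised band-area ratios track weight-fraction quotients
        "pmoxa": comp("pmoxa", [(1240.0, 14.0, 0.9), (1475.0, 16.0, 1.0)]),
        "heparin": comp(
            "heparin", [(HEPARIN_PEAKS[0], 12.0, 1.15), (HEPARIN_PEAKS[1], 12.0, 1.15)]
        ),
        "sulfhydryl": comp("sulfhydryl", [(SH_BEND, 10.0, 0.5)]),
        "disulfide_tnb": comp(
            "disulfide_tnb",
            [(SS_STRETCH[0], 10.0, 0.6), (SS_STRETCH[1], 10.0, 0.7), (1345.0, 12.0, 0.5)],
        ),
        "tyrosine": comp(
            "tyrosine", [(TYROSINE_RING[0], 10.0, 0.6), (TYROSINE_RING[1], 10.0, 0.6)]
        ),
        "alkyne": comp("alkyne", [(ALKYNE, 10.0, 1.0)]),
        "azide": comp("azide", [(AZIDE, 10.0, 1.0)]),
        "triazole": comp("triazole", [(TRIAZOLE, 12.0, 1.0)]),
    }


@dataclass(frozen=True)
class ParticleSpec:
    """Ground truth for one particle: size, composition and identity."""

    diameter: float  # nm
    composition: Mapping[str, float]
    identity: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weight fractions sum to {total}, not 1")

    @property
    def volume_nm3(self) -> float:
        return np.pi / 6.0 * self.diameter**3

    @property
    def volume_um3(self) -> float:
        return self.volume_nm3 * 1e-9


@dataclass(frozen=True)
class TrapPhysics:
    """Phenomenological trap parameters (none are vendor-specified)."""

    temperature: float = 298.0  # K
    viscosity: float = 0.89e-3  # Pa s
    capture_radius_um: float = 0.5
    confocal_volume_um3: float = 1.0
    arrival_rate: float | None = None  # s^-1; None -> Smoluchowski
    concentration_per_ml: float = 1e11
    perchlorate: bool = True

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "capture_radius_um", "confocal_volume_um3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def diffusivity(self, diameter_nm: float) -> float:
        """Stokes-Einstein diffusion coefficient, m^2/s."""
        return BOLTZMANN * self.temperature / (
            3.0 * np.pi * self.viscosity * diameter_nm * 1e-9
        )

    def smoluchowski_rate(self, diameter_nm: float) -> float:
        """Diffusive arrival rate 4*pi*D*a*c at the working concentration (s^-1)."""
        conc_m3 = self.concentration_per_ml * 1e6
        return 4.0 * np.pi * self.diffusivity(diameter_nm) * self.capture_radius_um * 1e-6 * conc_m3


@dataclass
class StreamConfig:
    """Axis, noise and background model for rendered spectra."""

    axis_lo: float = 300.0
    axis_hi: float = 2000.0
    axis_step: float = 3.0
    shot_noise: bool = True
    read_noise_sigma: float = 1.0
    baseline_amplitude: float = 60.0
    background_amplitude: float = 5.0
    perchlorate_amplitude: float = 50.0
    spike_probability: float = 0.0
    spike_amplitude: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must be in [0, 1]")

    def axis(self) -> np.ndarray:
        return np.arange(self.axis_lo, self.axis_hi + 0.5 * self.axis_step, self.axis_step)


def extended_range_config(**kwargs) -> StreamConfig:
    """Stream config on the 606-2254 cm^-1 extended axis (C-D/alkyne work)."""
    kwargs.setdefault("axis_lo", 606.0)
    kwargs.setdefault("axis_hi", 2254.0)
    return StreamConfig(**kwargs)


# ---------------------------------------------------------------------------
# Spectral rendering


def render_spectrum(
    particle: ParticleSpec | None,
    fill: float,
    t_int: float,
    config: StreamConfig,
    physics: TrapPhysics | None = None,
    library: Mapping[str, ComponentSpectrum] | None = None,
    rng: np.random.Generator | None = None,
    meta: SpectrumMeta | None = None,
) -> Spectrum:
    """Render one acquisition.

    ``fill`` is the fraction of the integration time the particle was
    present (mid-acquisition arrivals give fill < 1).  The solution-marker
    band amplitude is scaled by ``1 - fill * V_p / V_c`` (volume
    displacement); particle bands scale with particle volume.  With the
    same rng seed the output is bitwise identical.
    """
    if not 0.0 <= fill <= 1.0:
        raise ValueError("fill fraction must be in [0, 1]")
    physics = physics or TrapPhysics()
    library = library or default_library()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    axis = config.axis()

    # slowly varying fluorescence background: broad Lorentzian shoulder
    baseline = config.baseline_amplitude * pseudo_voigt(
        axis, config.axis_lo - 200.0, 2400.0, eta=1.0
    )
    signal = baseline + config.background_amplitude * library["water"].evaluate(axis)

    displaced = 0.0
    if particle is not None:
        v_p = particle.volume_um3
        if v_p > physics.confocal_volume_um3:
            raise ValueError("particle exceeds confocal volume")
        for name, w in particle.composition.items():
            component = library[name]
            signal = signal + (
                fill * w * component.scattering_strength * v_p * component.evaluate(axis)
            )
        displaced = fill * v_p / physics.confocal_volume_um3

    if physics.perchlorate and config.perchlorate_amplitude > 0:
        signal = signal + (
            config.perchlorate_amplitude
            * (1.0 - displaced)
            * library["perchlorate"].evaluate(axis)
        )

    expected = signal * t_int
    if config.shot_noise:
        counts = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    else:
        counts = expected.copy()
    if config.read_noise_sigma > 0 and config.shot_noise:
        counts = counts + rng.normal(0.0, config.read_noise_sigma, axis.size)
    if config.spike_probability > 0 and rng.random() < config.spike_probability:
        counts[rng.integers(0, axis.size)] += config.spike_amplitude
    counts = np.maximum(counts, 0.0)
    return Spectrum(axis, counts, meta or SpectrumMeta(integration_time=t_int))


# ---------------------------------------------------------------------------
# Brownian escape / arrival kinetics


def escape_probability(
    t_off: float, diameter_nm: float, physics: TrapPhysics | None = None
) -> float:
    """Probability the particle is still inside the capture radius after t_off.

    Free 3-D Brownian displacement from the trap centre: |r|^2 / (2 D t) is
    chi-square with 3 d.o.f., so the retained probability is
    P(chi2_3 <= a^2 / (2 D t_off)).  Returns 1 for t_off = 0; the escape
    probability is 1 minus this value.
    """
    if t_off < 0:
        raise ValueError("t_off must be >= 0")
    physics = physics or TrapPhysics()
    if t_off == 0.0:
        return 1.0
    diffusivity = physics.diffusivity(diameter_nm)
    a_m = physics.capture_radius_um * 1e-6
    return float(chi2.cdf(a_m**2 / (2.0 * diffusivity * t_off), df=3))


def monte_carlo_retention(
    t_off: float,
    diameter_nm: float,
    physics: TrapPhysics | None = None,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of the retained fraction after a disable event.

    Draws isotropic 3-D Gaussian displacements with variance 2 D t_off per
    axis and counts the fraction within the capture radius.  Independent of
    the closed form in :func:`escape_probability`.
    """
    physics = physics or TrapPhysics()
    rng = rng if rng is not None else np.random.default_rng(0)
    if t_off == 0.0:
        return 1.0
    sigma = np.sqrt(2.0 * physics.diffusivity(diameter_nm) * t_off)
    disp = rng.normal(0.0, sigma, size=(n_draws, 3))
    a_m = physics.capture_radius_um * 1e-6
    return float(np.mean(np.sum(disp * disp, axis=1) <= a_m * a_m))


@dataclass
class TrapState:
    """Occupancy state advanced by :func:`step_stream`."""

    occupied: bool = False
    particle: ParticleSpec | None = None
    fill: float = 0.0  # presence fraction of the last laser-on interval
    next_identity: int = 1


def step_stream(
    state: TrapState,
    laser_on: bool,
    dt: float,
    rng: np.random.Generator,
    physics: TrapPhysics,
    particle_sampler: Callable[[np.random.Generator], ParticleSpec] | None = None,
    arrival_rate: float | None = None,
) -> TrapState:
    """Advance trap occupancy over one interval.

    Laser off while occupied: the particle is retained with the Brownian
    return probability for ``dt``, otherwise it vacates.  Laser on while
    empty: a Poisson arrival occurs with probability 1 - exp(-k_a dt),
    uniformly within the interval, giving a fill fraction < 1 for that
    acquisition.  Laser on while occupied holds the particle (fill 1).
    Every arrival receives a fresh identity tag.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = replace(state)
    if laser_on:
        if state.occupied:
            state.fill = 1.0
            return state
        if particle_sampler is None:
            state.fill = 0.0
            return state
        k_a = arrival_rate
        if k_a is None:
            k_a = physics.arrival_rate
        if k_a is None:
            k_a = physics.smoluchowski_rate(200.0)
        if k_a > 0 and rng.random() < 1.0 - np.exp(-k_a * dt):
            arrival_frac = rng.random()  # uniform arrival time within dt
            particle = particle_sampler(rng)
            state.particle = replace(particle, identity=state.next_identity)
            state.next_identity += 1
            state.occupied = True
            state.fill = 1.0 - arrival_frac
        else:
            state.fill = 0.0
        return state
    # laser off
    if state.occupied:
        retained = escape_probability(dt, state.particle.diameter, physics)
        if rng.random() >= retained:
            state.occupied = False
            state.particle = None
    state.fill = 0.0
    return state


# ---------------------------------------------------------------------------
# Composition arithmetic


def component_weight_fractions(masses: Mapping[str, object]) -> dict[str, float]:
    """Weight fractions from block molar masses or mixing masses.

    Values are either plain masses (leaf components) or ``(mass, submix)``
    pairs where ``submix`` is itself a mapping of the same shape, enabling
    nested mixtures such as a blend of block copolymers.  Leaf names are
    accumulated across the tree.
    """
    totals: dict[str, float] = {}

    def visit(mapping: Mapping[str, object], scale: float) -> None:
        local_total = 0.0
        entries = []
        for name, value in mapping.items():
            if isinstance(value, (tuple, list)):
                mass, submix = float(value[0]), value[1]
            else:
                mass, submix = float(value), None
            if mass < 0:
                raise ValueError(f"negative mass for {name!r}")
            entries.append((name, mass, submix))
            local_total += mass
        if local_total <= 0:
            raise ValueError("zero total mass")
        for name, mass, submix in entries:
            share = scale * mass / local_total
            if submix is None:
                totals[name] = totals.get(name, 0.0) + share
            else:
                visit(submix, share)

    visit(masses, 1.0)
    return totals


ABA_BLOCK_MASSES_KDA = {"pmoxa_a": 0.5, "pdms": 4.8, "pmoxa_b": 0.5}
PDMS_HEPARIN_BLOCK_MASSES_KDA = {"pdms": 5.0, "heparin": 11.0}


def aba_pdms_fraction() -> float:
    """PDMS weight fraction of the triblock (0.5-4.8-0.5 kDa blocks)."""
    return component_weight_fractions(ABA_BLOCK_MASSES_KDA)["pdms"]


def aba_heparin_pdms_fraction(aba_wt: float = 75.0, heparin_copolymer_wt: float = 25.0) -> float:
    """PDMS weight fraction of the 75:25 triblock / PDMS-b-heparin blend."""
    blend = {
        "aba": (aba_wt, ABA_BLOCK_MASSES_KDA),
        "pdms_heparin": (heparin_copolymer_wt, PDMS_HEPARIN_BLOCK_MASSES_KDA),
    }
    return component_weight_fractions(blend)["pdms"]


# ---------------------------------------------------------------------------
# Sizing law


@dataclass(frozen=True)
class SizingLaw:
    """Empirical log-linear marker-ratio law: ratio = alpha + beta*log10(V_nm3).

    The spectral render keeps the physical displacement law; population-level
    sizing scenarios use this calibration-style law, which matches the
    observed linear correlation of mean ratio against log volume.
    """

    alpha: float = -6.0
    beta: float = 1.5
    noise_rel: float = 0.03  # relative (multiplicative) noise on the ratio

    def ratio(self, diameter_nm: np.ndarray | float) -> np.ndarray | float:
        volume = np.pi / 6.0 * np.asarray(diameter_nm, dtype=float) ** 3
        return self.alpha + self.beta * np.log10(volume)

    def noisy_ratio(self, diameter_nm, rng: np.random.Generator):
        base = np.asarray(self.ratio(diameter_nm), dtype=float)
        if self.noise_rel <= 0:
            return base
        return base * (1.0 + rng.normal(0.0, self.noise_rel, size=base.shape))


# ---------------------------------------------------------------------------
# Population presets


PRESETS = (
    "sizing",
    "dppc_mixture",
    "aba_mixture",
    "functionalisation",
    "cuaac_kinetics",
)


def _aba_composition() -> dict[str, float]:
    f = aba_pdms_fraction()
    return {"pdms": f, "pmoxa": 1.0 - f}


def _aba_heparin_composition() -> dict[str, float]:
    fracs = component_weight_fractions(
        {
            "aba": (75.0, ABA_BLOCK_MASSES_KDA),
            "pdms_heparin": (25.0, PDMS_HEPARIN_BLOCK_MASSES_KDA),
        }
    )
    pmoxa = fracs["pmoxa_a"] + fracs["pmoxa_b"]
    return {"pdms": fracs["pdms"], "pmoxa": pmoxa, "heparin": fracs["heparin"]}


def simulate_population(
    preset: str,
    n_traps: int,
    config: StreamConfig | None = None,
    physics: TrapPhysics | None = None,
    seed: int | None = None,
    **kwargs,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a high-SNR population with per-trap ground truth.

    Returns (spectra, table); the table carries identity, composition label,
    true size and — for the sizing preset — the true and noisy marker ratios.
    Presets: 'sizing', 'dppc_mixture', 'aba_mixture', 'functionalisation',
    'cuaac_kinetics'.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    physics = physics or TrapPhysics()
    rng = np.random.default_rng(seed)
    t_int = kwargs.pop("t_int", 10.0)

    if preset == "sizing":
        return _sizing_population(n_traps, config, physics, rng, t_int, **kwargs)
    if preset == "cuaac_kinetics":
        return _cuaac_population(n_traps, config, physics, rng, t_int, **kwargs)

    if preset == "dppc_mixture":
        proportions = kwargs.pop("proportions", (0.44, 0.56))
        choices = [
            ("dppc", {"dppc": 1.0}),
            ("d_dppc", {"dppc": 0.5, "d_dppc": 0.5}),
        ]
        config = config or extended_range_config(seed=int(rng.integers(2**31)))
    elif preset == "aba_mixture":
        proportions = kwargs.pop("proportions", (0.5, 0.5))
        choices = [("aba", _aba_composition()), ("aba_heparin", _aba_heparin_composition())]
        config = config or StreamConfig(seed=int(rng.integers(2**31)))
    else:  # functionalisation
        series = kwargs.pop(
            "series",
            [
                ("sulfhydryl", {"polystyrene": 0.9, "sulfhydryl": 0.1}),
                ("tnb", {"polystyrene": 0.9, "disulfide_tnb": 0.1}),
                ("cyy", {"polystyrene": 0.85, "disulfide_tnb": 0.05, "tyrosine": 0.1}),
            ],
        )
        proportions = kwargs.pop("proportions", tuple(1.0 / len(series) for _ in series))
        choices = list(series)
        config = config or StreamConfig(seed=int(rng.integers(2**31)))
    if kwargs:
        raise TypeError(f"unexpected preset arguments: {sorted(kwargs)}")

    diameter = 200.0
    labels = rng.choice(len(choices), size=n_traps, p=np.asarray(proportions))
    spectra: list[Spectrum] = []
    rows = []
    for i in range(n_traps):
        label, composition = choices[labels[i]]
        particle = ParticleSpec(diameter, composition, identity=i + 1)
        spectra.append(
            render_spectrum(
                particle, 1.0, t_int, config, physics, rng=rng,
                meta=SpectrumMeta(integration_time=t_int, timestamp=float(i), label=label),
            )
        )
        rows.append(
            {"trap": i, "identity": i + 1, "label": label, "diameter_nm": diameter}
        )
    return spectra, pd.DataFrame(rows, columns=["trap", "identity", "label", "diameter_nm"])


def _sizing_population(n_traps, config, physics, rng, t_int, **kwargs):
    diameters = kwargs.pop("diameters", None)
    law: SizingLaw = kwargs.pop("law", SizingLaw())
    render = kwargs.pop("render", False)
    if kwargs:
        raise TypeError(f"unexpected preset arguments: {sorted(kwargs)}")
    if diameters is None:
        reference = np.array([50.0, 100.0, 200.0])
        diameters = np.repeat(reference, max(n_traps // 3, 1))[:n_traps]
    else:
        diameters = np.asarray(diameters, dtype=float)[:n_traps]
    true_ratio = np.asarray(law.ratio(diameters), dtype=float)
    ratio = np.asarray(law.noisy_ratio(diameters, rng), dtype=float)
    rows = pd.DataFrame(
        {
            "trap": np.arange(diameters.size),
            "identity": np.arange(1, diameters.size + 1),
            "diameter_nm": diameters,
            "volume_nm3": np.pi / 6.0 * diameters**3,
            "ratio_true": true_ratio,
            "ratio": ratio,
        }
    )
    spectra: list[Spectrum] = []
    if render:
        config = config or StreamConfig(seed=int(rng.integers(2**31)))
        spectra = [
            _spectrum_with_ratio(r, config, t_int, i)
            for i, r in enumerate(ratio)
        ]
    return spectra, rows


def _spectrum_with_ratio(ratio: float, config: StreamConfig, t_int: float, index: int) -> Spectrum:
    """Noiseless spectrum whose total/marker areas reproduce a target ratio."""
    axis = config.axis()
    library = default_library()
    marker = library["perchlorate"].evaluate(axis) * config.perchlorate_amplitude
    marker_area = np.trapezoid(marker, axis)
    particle = library["polystyrene"].evaluate(axis)
    particle_area = np.trapezoid(particle, axis)
    counts = (marker + particle * (ratio * marker_area / particle_area)) * t_int
    return Spectrum(
        axis, counts, SpectrumMeta(integration_time=t_int, timestamp=float(index))
    )


def _cuaac_population(n_traps, config, physics, rng, t_int, **kwargs):
    tau = kwargs.pop("tau_s", 160.0)
    duration = kwargs.pop("duration_s", 600.0)
    mode = kwargs.pop("mode", "population")
    if kwargs:
        raise TypeError(f"unexpected preset arguments: {sorted(kwargs)}")
    config = config or extended_range_config(seed=int(rng.integers(2**31)))
    times = np.linspace(0.0, duration, n_traps)
    spectra: list[Spectrum] = []
    rows = []
    for i, t in enumerate(times):
        conversion = 1.0 - np.exp(-t / tau)
        remaining = max(1.0 - conversion, 1e-6)
        produced = max(conversion, 1e-6)
        total = 2.0 * remaining + produced
        composition = {
            "polystyrene": 0.0,
            "alkyne": remaining / total,
            "azide": remaining / total,
            "triazole": produced / total,
        }
        # keep polystyrene core dominant, reaction markers on the surface
        composition = {k: v * 0.2 for k, v in composition.items() if v > 0}
        composition["polystyrene"] = 1.0 - sum(composition.values())
        identity = 1 if mode == "hold" else i + 1
        particle = ParticleSpec(200.0, composition, identity=identity)
        spectra.append(
            render_spectrum(
                particle, 1.0, t_int, config, physics, rng=rng,
                meta=SpectrumMeta(integration_time=t_int, timestamp=float(t), label="cuaac"),
            )
        )
        rows.append(
            {
                "trap": i,
                "identity": identity,
                "time_s": float(t),
                "conversion": conversion,
                "diameter_nm": 200.0,
            }
        )
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Virtual instrument facade used by the acquisition controller


class VirtualInstrument:
    """Stand-in for the trapping microscope: spectra on demand plus a clock.

    The controller drives it through ``iteration_spectrum``, ``acquire`` and
    ``disable``; occupancy evolves via :func:`step_stream`.  Ground-truth
    attributes (``occupied``, ``current_identity``) exist only here, for
    verification against simulations.
    """

    def __init__(
        self,
        config: StreamConfig | None = None,
        physics: TrapPhysics | None = None,
        particle_sampler: Callable[[np.random.Generator], ParticleSpec] | None = None,
        arrival_rate: float | None = None,
        seed: int | None = None,
        library: Mapping[str, ComponentSpectrum] | None = None,
        initially_occupied: bool = False,
    ) -> None:
        self.config = config or StreamConfig()
        self.physics = physics or TrapPhysics()
        self.library = library or default_library()
        default_sampler = particle_sampler or (
            lambda rng: ParticleSpec(200.0, {"polystyrene": 1.0})
        )
        self.particle_sampler = default_sampler
        self.arrival_rate = arrival_rate
        self.rng = np.random.default_rng(self.config.seed if seed is None else seed)
        self.state = TrapState()
        if initially_occupied:
            particle = default_sampler(self.rng)
            self.state = TrapState(
                occupied=True,
                particle=replace(particle, identity=1),
                fill=1.0,
                next_identity=2,
            )
        self.time = 0.0

    # -- ground truth --------------------------------------------------
    @property
    def occupied(self) -> bool:
        return self.state.occupied

    @property
    def current_identity(self) -> int | None:
        return self.state.particle.identity if self.state.occupied else None

    # -- controller-facing API -----------------------------------------
    def _render(self, t_int: float, iteration: int) -> Spectrum:
        meta = SpectrumMeta(
            integration_time=t_int, timestamp=self.time, iteration_number=iteration
        )
        particle = self.state.particle if self.state.occupied else None
        fill = self.state.fill if self.state.occupied else 0.0
        return render_spectrum(
            particle, fill, t_int, self.config, self.physics,
            library=self.library, rng=self.rng, meta=meta,
        )

    def iteration_spectrum(self, t_iter: float, iteration: int = 0) -> Spectrum:
        self.state = step_stream(
            self.state, True, t_iter, self.rng, self.physics,
            self.particle_sampler, self.arrival_rate,
        )
        self.time += t_iter
        return self._render(t_iter, iteration)

    def acquire(self, t_acq: float, iteration: int = 0) -> Spectrum:
        self.state = step_stream(
            self.state, True, t_acq, self.rng, self.physics,
            self.particle_sampler, self.arrival_rate,
        )
        self.time += t_acq
        return self._render(t_acq, iteration)

    def disable(self, t_off: float) -> None:
        if t_off <= 0:
            return
        self.state = step_stream(
            self.state, False, t_off, self.rng, self.physics,
            self.particle_sampler, self.arrival_rate,
        )
        self.time += t_off


def save_stream_config(config: StreamConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.__dict__, indent=2))


def load_stream_config(path: str | Path) -> StreamConfig:
    return StreamConfig(**json.loads(Path(path).read_text()))
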