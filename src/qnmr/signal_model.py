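"""Quantitative signal model and synthetic spectrum generation.

The quantitative backbone of proton qNMR is that an integrated signal area I
is proportional to the molar concentration c of the species and the number n
of equivalent protons behind the signal, attenuated by incomplete
longitudinal relaxation between pulses:

    I = Ks * c * n * (1 - exp(-TR / T1))

with Ks the spectrometer constant, TR the repetition time and T1 the
longitudinal relaxation time. When TR exceeds roughly five T1 the
exponential term is negligible (99.3 % recovery at TR = 5*T1) and the
measurement is quantitative.

This module renders that model as synthetic data: each spectral line becomes
a damped complex exponential in the time domain (a Lorentzian after
transformation), amplitudes follow the equation above, additive complex
Gaussian noise shrinks as 1/sqrt(n_scans) after scan averaging, and baseline
drift can be injected as a low-order polynomial in the frequency domain.

For flip angles other than 90 degrees the amplitude is multiplied by the
steady-state (Ernst) factor sin(theta) * (1 - E) / (1 - E*cos(theta)) with
E = exp(-TR/T1), which reduces to 1 - E at 90 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .containers import FID, AcquisitionParams, Spectrum

__all__ = [
    "Line",
    "AnalyteSpec",
    "SampleComponent",
    "SampleSpec",
    "ConfigurationError",
    "longitudinal_recovery",
    "ernst_factor",
    "signal_amplitude",
    "molar_concentration",
    "synthesize_fid",
    "add_polynomial_baseline",
]


class ConfigurationError(ValueError):
    """A sample or acquisition configuration is physically inconsistent."""


@dataclass(frozen=True)
class Line:
    """One resonance line: position (ppm), relative intensity, width (Hz FWHM)."""

    position_ppm: float
    relative_intensity: float
    width_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.relative_intensity <= 0:
            raise ValueError("relative_intensity must be positive")
        if self.width_hz <= 0:
            raise ValueError("width_hz must be positive")


@dataclass(frozen=True)
class AnalyteSpec:
    """One compound's quantitative signal definition.

    ``n_protons`` is the number of nuclei generating the quantitative
    multiplet; ``purity_percent`` the declared assay purity of the material;
    ``lines`` the explicit multiplet line list (relative intensities summing
    to one).
    """

    name: str
    molar_mass: float
    purity_percent: float
    n_protons: int
    t1_s: float
    lines: tuple[Line, ...]

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")
        if not 0 < self.purity_percent <= 100:
            raise ValueError(f"{self.name}: purity_percent must lie in (0, 100]")
        if self.n_protons < 1:
            raise ValueError(f"{self.name}: n_protons must be at least 1")
        if self.t1_s <= 0:
            raise ValueError(f"{self.name}: t1_s must be positive")
        if not self.lines:
            raise ValueError(f"{self.name}: at least one line is required")
        total = sum(ln.relative_intensity for ln in self.lines)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(
                f"{self.name}: relative line intensities must sum to 1 (got {total:g})"
            )

    @property
    def ppm_span(self) -> tuple[float, float]:
        positions = [ln.position_ppm for ln in self.lines]
        return min(positions), max(positions)


@dataclass(frozen=True)
class SampleComponent:
    """An analyte at a concentration, optionally with its gravimetric weight."""

    analyte: AnalyteSpec
    concentration_mg_ml: float
    weight_g: float | None = None
    volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration_mg_ml < 0:
            raise ValueError("concentration_mg_ml must be non-negative")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")


@dataclass
class SampleSpec:
    """Composition and noise description of one simulated NMR sample.

    ``noise_sigma_per_scan`` is the per-scan additive noise standard
    deviation in the time domain; after averaging ``n_scans`` scans the
    effective sigma is ``noise_sigma_per_scan / sqrt(n_scans)``.
    ``amplitude_noise_frac`` applies an independent multiplicative
    perturbation ``1 + frac * N(0,1)`` to each component's total amplitude,
    emulating run-to-run integration/instrument variability.
    ``baseline_coefficients`` are ascending-power polynomial coefficients in
    ppm added to the real spectrum after transformation.

    In internal-standard work all components share one solution volume; mixed
    volumes are rejected.
    """

    components: list[SampleComponent] = field(default_factory=list)
    solvent_line: Line | None = Line(2.5, 1.0, 1.2)
    solvent_amplitude: float = 0.0
    noise_sigma_per_scan: float = 0.0
    amplitude_noise_frac: float = 0.0
    baseline_coefficients: tuple[float, ...] = ()
    ks: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma_per_scan < 0:
            raise ValueError("noise_sigma_per_scan must be non-negative")
        if self.amplitude_noise_frac < 0:
            raise ValueError("amplitude_noise_frac must be non-negative")
        if self.ks <= 0:
            raise ValueError("ks must be positive")
        volumes = {c.volume_ml for c in self.components}
        if len(volumes) > 1:
            raise ConfigurationError(
                "internal-standard samples must share a single volume; "
                f"got volumes {sorted(volumes)}"
            )


def longitudinal_recovery(tr_s: float, t1_s: float) -> float:
    """Fraction of equilibrium z-magnetisation recovered after TR (90° pulse).

    Returns ``1 - exp(-TR/T1)``: 0 at TR = 0, ~63 % at TR = T1, 99.3 % at
    TR = 5*T1, approaching 1 as TR grows.
    """
    if t1_s <= 0:
        raise ValueError("t1_s must be positive")
    if tr_s < 0:
        raise ValueError("tr_s must be non-negative")
    return 1.0 - math.exp(-tr_s / t1_s)


def ernst_factor(flip_angle_deg: float, tr_s: float, t1_s: float) -> float:
    """Steady-state amplitude factor sin(t)*(1-E)/(1-E*cos(t)), E=exp(-TR/T1).

    Extends the 90-degree recovery model to arbitrary pulse angles; equal to
    ``longitudinal_recovery`` at 90 degrees.
    """
    if not 0 < flip_angle_deg <= 180:
        raise ValueError("flip_angle_deg must lie in (0, 180]")
    if t1_s <= 0:
        raise ValueError("t1_s must be positive")
    theta = math.radians(flip_angle_deg)
    e1 = math.exp(-tr_s / t1_s)
    return math.sin(theta) * (1.0 - e1) / (1.0 - e1 * math.cos(theta))


def signal_amplitude(
    c: float, n: int, tr_s: float, t1_s: float, ks: float = 1.0
) -> float:
    """Quantitative signal amplitude I = Ks * c * n * (1 - exp(-TR/T1)).

    ``c`` is a molar concentration (any consistent unit: Ks absorbs scale).
    Linear in both c and n; within 0.7 % of Ks*c*n once TR > 5*T1.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    if ks <= 0:
        raise ValueError("ks must be positive")
    return ks * c * n * longitudinal_recovery(tr_s, t1_s)


def molar_concentration(mg_per_ml: float, molar_mass: float) -> float:
    """Convert a mass concentration in mg/ml to mol/l."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return mg_per_ml / molar_mass  # (g/l) / (g/mol) = mol/l


def _check_line_in_window(
    label: str, line: Line, acq: AcquisitionParams
) -> None:
    low, high = acq.window_ppm
    if not low <= line.position_ppm <= high:
        raise ConfigurationError(
            f"line of {label} at {line.position_ppm} ppm falls outside the "
            f"spectral window [{low}, {high}] ppm"
        )


def synthesize_fid(
    sample: SampleSpec,
    acq: AcquisitionParams,
    seed: int | None = None,
) -> FID:
    """Render a sample as a noisy complex FID under the quantitative model.

    Each line contributes ``a * exp(2i*pi*f*t) * exp(-pi*w*t)`` with offset
    frequency f relative to the carrier and natural width w (Hz); the line
    amplitude is the component amplitude ``Ks * c_molar * (P/100) * n *
    ernst_factor`` split by relative intensity — concentrations refer to the
    material as weighed, so the declared purity P scales the actual analyte
    content. Deterministic for a given seed.
    """
    if seed is None:
        seed = sample.seed
    rng = np.random.default_rng(seed)
    n_pts = acq.data_points
    dwell = acq.dwell_time_s
    t = np.arange(n_pts) * dwell
    tr = acq.repetition_time_s
    sf = acq.spectrometer_frequency_mhz
    fid = np.zeros(n_pts, dtype=np.complex128)

    for comp in sample.components:
        spec = comp.analyte
        for line in spec.lines:
            _check_line_in_window(spec.name, line, acq)
        c_molar = molar_concentration(comp.concentration_mg_ml, spec.molar_mass)
        amp = (
            sample.ks
            * c_molar
            * (spec.purity_percent / 100.0)
            * spec.n_protons
            * ernst_factor(acq.flip_angle_deg, tr, spec.t1_s)
        )
        if sample.amplitude_noise_frac > 0:
            amp *= 1.0 + sample.amplitude_noise_frac * rng.standard_normal()
        for line in spec.lines:
            f_off = (line.position_ppm - acq.frequency_offset_ppm) * sf  # Hz
            fid += (
                amp
                * line.relative_intensity
                * np.exp((2j * np.pi * f_off - np.pi * line.width_hz) * t)
            )

    if sample.solvent_line is not None and sample.solvent_amplitude > 0:
        _check_line_in_window("solvent", sample.solvent_line, acq)
        f_off = (sample.solvent_line.position_ppm - acq.frequency_offset_ppm) * sf
        fid += (
            sample.solvent_amplitude
            * np.exp((2j * np.pi * f_off - np.pi * sample.solvent_line.width_hz) * t)
        )

    if sample.noise_sigma_per_scan > 0:
        sigma = sample.noise_sigma_per_scan / math.sqrt(acq.n_scans)
        fid += sigma * (rng.standard_normal(n_pts) + 1j * rng.standard_normal(n_pts))

    provenance: dict[str, Any] = {
        "seed": seed,
        "ks": sample.ks,
        "components": {
            c.analyte.name: c.concentration_mg_ml for c in sample.components
        },
        "noise_sigma_per_scan": sample.noise_sigma_per_scan,
        "amplitude_noise_frac": sample.amplitude_noise_frac,
    }
    if sample.baseline_coefficients:
        provenance["baseline_coefficients"] = tuple(sample.baseline_coefficients)
    return FID(samples=fid, dwell_time_s=dwell, acquisition=acq, provenance=provenance)


def add_polynomial_baseline(
    spectrum: Spectrum, coefficients: Sequence[float]
) -> Spectrum:
    """Inject baseline drift: add a polynomial in ppm to the real part.

    ``coefficients`` are ascending powers (c0 + c1*ppm + c2*ppm^2 + ...).
    This is a simulation artefact generator, the counterpart of the
    processing layer's baseline correction.
    """
    out = spectrum.copy()
    if coefficients:
        drift = np.polynomial.polynomial.polyval(out.ppm, np.asarray(coefficients))
        out.real = out.real + drift
    out.log("synthetic_baseline", coefficients=tuple(coefficients))
    return out
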