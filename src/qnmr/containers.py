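"""Core data containers shared across the simulation and processing layers.

The containers mirror what an NMR spectrometer hands to the analyst: the
acquisition parameter block, the complex time-domain free induction decay
(FID), and the frequency-domain spectrum on a descending ppm axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["AcquisitionParams", "FID", "Spectrum"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectrometer and experiment settings driving simulation and processing.

    Defaults correspond to a routine small-molecule quantitative experiment on
    a 400 MHz instrument: 15 ppm sweep centred at 6.175 ppm, 65 536 complex
    points, 90-degree pulses, a 10 s relaxation delay and 64 scans.

    The repetition time TR — the time between two excitation pulses — is the
    sum of the pulse width, receiver dead time, acquisition time and
    relaxation delay.
    """

    spectral_width_ppm: float = 15.0
    frequency_offset_ppm: float = 6.175
    spectrometer_frequency_mhz: float = 400.0
    data_points: int = 65536
    acquisition_time_s: float = 4.08
    pulse_width_us: float = 13.5
    flip_angle_deg: float = 90.0
    relaxation_delay_s: float = 10.0
    dead_time_s: float = 0.0
    n_scans: int = 64
    receiver_gain_db: float = 32.0
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        if self.data_points <= 0:
            raise ValueError("data_points must be positive")
        if self.spectral_width_ppm <= 0:
            raise ValueError("spectral_width_ppm must be positive")
        if self.n_scans < 1:
            raise ValueError("n_scans must be at least 1")
        if not 0.0 < self.flip_angle_deg <= 180.0:
            raise ValueError("flip_angle_deg must lie in (0, 180]")
        if self.relaxation_delay_s < 0:
            raise ValueError("relaxation_delay_s must be non-negative")
        if self.spectrometer_frequency_mhz <= 0:
            raise ValueError("spectrometer_frequency_mhz must be positive")

    @property
    def spectral_width_hz(self) -> float:
        return self.spectral_width_ppm * self.spectrometer_frequency_mhz

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def repetition_time_s(self) -> float:
        """TR = pulse width + dead time + acquisition time + relaxation delay."""
        return (
            self.pulse_width_us * 1e-6
            + self.dead_time_s
            + self.acquisition_time_s
            + self.relaxation_delay_s
        )

    @property
    def window_ppm(self) -> tuple[float, float]:
        """(low, high) ppm bounds of the observable spectral window."""
        half = self.spectral_width_ppm / 2.0
        return (
            self.frequency_offset_ppm - half,
            self.frequency_offset_ppm + half,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "spectral_width_ppm": self.spectral_width_ppm,
            "frequency_offset_ppm": self.frequency_offset_ppm,
            "spectrometer_frequency_mhz": self.spectrometer_frequency_mhz,
            "data_points": self.data_points,
            "acquisition_time_s": self.acquisition_time_s,
            "pulse_width_us": self.pulse_width_us,
            "flip_angle_deg": self.flip_angle_deg,
            "relaxation_delay_s": self.relaxation_delay_s,
            "dead_time_s": self.dead_time_s,
            "n_scans": self.n_scans,
            "receiver_gain_db": self.receiver_gain_db,
            "temperature_c": self.temperature_c,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AcquisitionParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def replace(self, **changes: Any) -> "AcquisitionParams":
        return replace(self, **changes)


@dataclass
class FID:
    """A free induction decay: complex time-domain samples plus metadata.

    ``dwell_time_s`` is the sampling interval, the reciprocal of the spectral
    width in Hz. ``provenance`` records how the FID came to be (seed,
    spectrometer constant, injected artefacts) so downstream steps can act on
    or audit it.
    """

    samples: np.ndarray
    dwell_time_s: float
    acquisition: AcquisitionParams
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("FID samples must be one-dimensional")
        if len(self.samples) != self.acquisition.data_points:
            raise ValueError(
                f"FID has {len(self.samples)} samples but acquisition declares "
                f"{self.acquisition.data_points} data points"
            )
        expected_dwell = self.acquisition.dwell_time_s
        if not np.isclose(self.dwell_time_s, expected_dwell, rtol=1e-9):
            raise ValueError(
                "dwell_time_s must equal 1/spectral_width_hz "
                f"({expected_dwell!r}), got {self.dwell_time_s!r}"
            )

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dwell_time_s

    def copy(self) -> "FID":
        return FID(
            samples=self.samples.copy(),
            dwell_time_s=self.dwell_time_s,
            acquisition=self.acquisition,
            provenance=dict(self.provenance),
        )


@dataclass
class Spectrum:
    """A frequency-domain spectrum: real and imaginary parts on a ppm axis.

    The ppm axis is strictly descending (conventional left-to-right NMR
    display). ``processing_log`` is an append-only record of every applied
    processing step with its parameters.
    """

    real: np.ndarray
    imag: np.ndarray
    ppm: np.ndarray
    acquisition: AcquisitionParams | None = None
    processing_log: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real, dtype=np.float64)
        self.imag = np.asarray(self.imag, dtype=np.float64)
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        if not (len(self.real) == len(self.imag) == len(self.ppm)):
            raise ValueError("real, imag and ppm must have equal lengths")
        diffs = np.diff(self.ppm)
        if len(diffs) and not (np.all(diffs < 0) or np.all(diffs > 0)):
            raise ValueError("ppm axis must be strictly monotonic")
        if len(diffs) and diffs[0] > 0:
            # normalise to the descending display convention
            self.real = self.real[::-1].copy()
            self.imag = self.imag[::-1].copy()
            self.ppm = self.ppm[::-1].copy()

    @property
    def complex_data(self) -> np.ndarray:
        return self.real + 1j * self.imag

    def log(self, step: str, **params: Any) -> None:
        self.processing_log.append((step, params))

    def copy(self) -> "Spectrum":
        return Spectrum(
            real=self.real.copy(),
            imag=self.imag.copy(),
            ppm=self.ppm.copy(),
            acquisition=self.acquisition,
            processing_log=list(self.processing_log),
            metadata=dict(self.metadata),
        )

    def slice_indices(self, low_ppm: float, high_ppm: float) -> np.ndarray:
        """Indices of points whose ppm lies in the closed interval [low, high]."""
        if low_ppm > high_ppm:
            raise ValueError("low_ppm must not exceed high_ppm")
        return np.nonzero((self.ppm >= low_ppm) & (self.ppm <= high_ppm))[0]
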