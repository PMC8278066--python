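"""Region integration, integral ratios, purity and concentration estimates.

Quantification rests on the proportionality between integrated signal area
and (molar concentration x proton count). Two modes are supported:

* calibration mode — the analyte/standard integral ratio is converted to a
  mass concentration through a fitted straight line (ratio = a + b*C);
* absolute purity mode — the internal-standard purity equation

      P1 = (I1/I2) * (n2/n1) * (M1/M2) * (W2/W1) * P2

  turns an integral ratio directly into an assay purity from the weighed
  masses W, molar masses M, proton counts n and the standard's declared
  purity P2.

Integration is a plain trapezoidal sum of the real part over a declared ppm
window, mirroring instrument-style region integrals; no peak fitting is done
by default. Default windows for a multiplet are its extreme line positions
padded by +/-0.02 ppm (configurable), wide enough to hold the Lorentzian
tails at the simulated linewidths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .containers import Spectrum
from .signal_model import AnalyteSpec, Line

if TYPE_CHECKING:  # pragma: no cover
    from .validation import CalibrationModel

__all__ = [
    "IntegrationRegion",
    "IntegralResult",
    "ConcentrationEstimate",
    "SolventOverlapWarning",
    "default_region",
    "default_regions",
    "integrate_region",
    "integral_ratio",
    "purity_from_ratio",
    "concentration_from_calibration",
]

logger = logging.getLogger(__name__)

DEFAULT_REGION_PAD_PPM = 0.02


class SolventOverlapWarning(UserWarning):
    """An integration region overlaps a declared solvent line."""


@dataclass(frozen=True)
class IntegrationRegion:
    """A labelled ppm interval owned by one analyte."""

    label: str
    low_ppm: float
    high_ppm: float
    owner: str

    def __post_init__(self) -> None:
        if self.low_ppm >= self.high_ppm:
            raise ValueError(
                f"region {self.label!r}: low_ppm must be below high_ppm"
            )

    def overlaps(self, other: "IntegrationRegion") -> bool:
        return self.low_ppm < other.high_ppm and other.low_ppm < self.high_ppm


@dataclass(frozen=True)
class IntegralResult:
    """Absolute trapezoidal area of a region, optionally as a ratio to the standard."""

    region: IntegrationRegion
    absolute_area: float
    ratio_to_standard: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.absolute_area):
            raise ValueError("absolute_area must be finite")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A back-calculated concentration with range bookkeeping."""

    concentration_mg_ml: float
    within_range: bool
    flag: str | None = None


def default_region(
    analyte: AnalyteSpec, pad_ppm: float = DEFAULT_REGION_PAD_PPM
) -> IntegrationRegion:
    low, high = analyte.ppm_span
    return IntegrationRegion(
        label=analyte.name,
        low_ppm=low - pad_ppm,
        high_ppm=high + pad_ppm,
        owner=analyte.name,
    )


def default_regions(
    analytes: Iterable[AnalyteSpec], pad_ppm: float = DEFAULT_REGION_PAD_PPM
) -> list[IntegrationRegion]:
    """Default windows for a set of analytes, checked for mutual overlap."""
    regions = [default_region(a, pad_ppm) for a in analytes]
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1 :]:
            if r1.overlaps(r2):
                raise ValueError(
                    f"default regions for {r1.owner} and {r2.owner} overlap; "
                    "reduce pad_ppm or declare regions explicitly"
                )
    return regions


def integrate_region(
    spectrum: Spectrum,
    region: IntegrationRegion,
    solvent_line: Line | None = None,
) -> IntegralResult:
    """Trapezoidal area of the real part over [low, high] ppm.

    The area is reported in ppm * intensity units and is positive for an
    upright absorption signal. Integrating across a declared solvent line
    emits a warning; a region outside the axis raises.
    """
    lo_axis = float(spectrum.ppm.min())
    hi_axis = float(spectrum.ppm.max())
    if region.low_ppm < lo_axis or region.high_ppm > hi_axis:
        raise ValueError(
            f"region {region.label!r} [{region.low_ppm}, {region.high_ppm}] ppm "
            f"exceeds the axis [{lo_axis:.4f}, {hi_axis:.4f}] ppm"
        )
    if solvent_line is not None and (
        region.low_ppm <= solvent_line.position_ppm <= region.high_ppm
    ):
        warnings.warn(
            f"region {region.label!r} overlaps the solvent line at "
            f"{solvent_line.position_ppm} ppm",
            SolventOverlapWarning,
            stacklevel=2,
        )
    idx = spectrum.slice_indices(region.low_ppm, region.high_ppm)
    if len(idx) < 2:
        raise ValueError(
            f"region {region.label!r} covers fewer than two axis points"
        )
    # ppm axis is descending; integrate on the ascending view for a positive area
    x = spectrum.ppm[idx][::-1]
    y = spectrum.real[idx][::-1]
    area = float(np.trapezoid(y, x))
    return IntegralResult(region=region, absolute_area=area)


def integral_ratio(analyte: IntegralResult, standard: IntegralResult) -> float:
    """I_analyte / I_standard; invariant to any global rescaling of the spectrum."""
    if standard.absolute_area <= 0:
        raise ValueError(
            f"degenerate standard region {standard.region.label!r}: "
            f"area {standard.absolute_area!r} is not positive"
        )
    return analyte.absolute_area / standard.absolute_area


def purity_from_ratio(
    ratio: float,
    n1: int,
    n2: int,
    m1: float,
    m2: float,
    w1: float,
    w2: float,
    p2: float,
) -> float:
    """Internal-standard purity: P1 = ratio * (n2/n1) * (M1/M2) * (W2/W1) * P2.

    Subscript 1 is the analyte, 2 the internal standard; both dissolved in
    the same volume. Returns a percent purity.
    """
    for label, value in (("n1", n1), ("n2", n2), ("M1", m1), ("M2", m2)):
        if value <= 0:
            raise ValueError(f"{label} must be positive")
    if w1 <= 0 or w2 <= 0:
        raise ValueError("gravimetric weights must be positive")
    if not 0 < p2 <= 100:
        raise ValueError("standard purity P2 must lie in (0, 100]")
    return ratio * (n2 / n1) * (m1 / m2) * (w2 / w1) * p2


def concentration_from_calibration(
    ratio: float,
    model: "CalibrationModel",
    extrapolation_guard_percent: float = 10.0,
) -> ConcentrationEstimate:
    """Invert the calibration line: C = (ratio - a) / b.

    Values outside the validated range are flagged (warning, not failure);
    beyond the range by more than ``extrapolation_guard_percent`` of the
    range span the flag escalates to an extrapolation notice.
    """
    if model.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    conc = (ratio - model.intercept) / model.slope
    low, high = model.conc_range
    within = low <= conc <= high
    flag = None
    if not within:
        span = high - low
        guard = span * extrapolation_guard_percent / 100.0
        if conc < low - guard or conc > high + guard:
            flag = "extrapolated far outside validated range"
        else:
            flag = "outside validated range"
        logger.warning(
            "back-calculated concentration %.4g mg/ml is %s (%.3g-%.3g)",
            conc,
            flag,
            low,
            high,
        )
    return ConcentrationEstimate(
        concentration_mg_ml=float(conc), within_range=within, flag=flag
    )


def integrate_all(
    spectrum: Spectrum,
    regions: Sequence[IntegrationRegion],
    standard_owner: str,
    solvent_line: Line | None = None,
) -> dict[str, IntegralResult]:
    """Integrate every region and attach ratios to the standard's region.

    Returns a mapping from region owner to its result; the standard's own
    entry carries ratio 1.
    """
    results = {
        r.owner: integrate_region(spectrum, r, solvent_line=solvent_line)
        for r in regions
    }
    if standard_owner not in results:
        raise ValueError(
            f"standard owner {standard_owner!r} has no integration region"
        )
    std = results[standard_owner]
    return {
        owner: IntegralResult(
            region=res.region,
            absolute_area=res.absolute_area,
            ratio_to_standard=integral_ratio(res, std),
        )
        for owner, res in results.items()
    }
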