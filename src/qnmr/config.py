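"""Run configuration: YAML schema, defaults, and parsing.

A run configuration describes one end-to-end study: the acquisition
parameters, the analytes and the internal standard, simulation noise
settings, processing parameters, integration regions, the calibration
levels, and the samples to assay. The defaults mirror the nasal-spray assay
this package ships with: FLP and AZH against a 10 mg/ml inositol internal
standard in DMSO-d6 on a 400 MHz instrument.

Schema (all keys optional; shown with defaults)::

    seed: 42
    mode: calibration            # calibration | absolute
    acquisition: {}              # AcquisitionParams field overrides
    internal_standard:
      name: inositol
      concentration_mg_ml: 10.0
    analytes: [FLP, AZH]         # preset names, or full inline specs
    simulation:
      ks: 1000.0
      noise_sigma_per_scan: 0.0
      amplitude_noise_frac: 0.005
      baseline_coefficients: []
      solvent_amplitude: 20.0
    processing:
      lb_hz: 0.3
      baseline_order: 2
      zero_fill_to: null
      reference: {observed_ppm: 2.5, assigned_ppm: 2.5}
    regions:
      pad_ppm: 0.02              # or an explicit list of regions
    calibration_levels:
      FLP: [0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0]
      AZH: [0.2, 0.5, 1.0, 2.5, 5.0, 10.0, 12.5, 15.0]
    samples:
      - name: lab_mixture
        concentrations: {FLP: 7.3, AZH: 20.0}
        replicates: 3
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .containers import AcquisitionParams
from .presets import DEFAULT_ANALYTES, DMSO_LINE, INOSITOL, analyte_by_name
from .quantification import IntegrationRegion, default_regions
from .signal_model import AnalyteSpec, Line

__all__ = ["SimulationSettings", "ProcessingSettings", "SampleScenario", "RunConfig",
           "load_config", "default_config"]


@dataclass(frozen=True)
class SimulationSettings:
    ks: float = 1000.0
    noise_sigma_per_scan: float = 0.0
    amplitude_noise_frac: float = 0.005
    baseline_coefficients: tuple[float, ...] = ()
    solvent_amplitude: float = 20.0
    solvent_line: Line = DMSO_LINE


@dataclass(frozen=True)
class ProcessingSettings:
    lb_hz: float = 0.3
    baseline_order: int = 2
    zero_fill_to: int | None = None
    reference_observed_ppm: float | None = 2.5
    reference_assigned_ppm: float = 2.5


@dataclass(frozen=True)
class SampleScenario:
    name: str
    concentrations: dict[str, float]
    replicates: int = 3


@dataclass
class RunConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    analytes: list[AnalyteSpec] = field(default_factory=list)
    internal_standard: AnalyteSpec = INOSITOL
    internal_standard_mg_ml: float = 10.0
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    processing: ProcessingSettings = field(default_factory=ProcessingSettings)
    regions: list[IntegrationRegion] = field(default_factory=list)
    calibration_levels: dict[str, list[float]] = field(default_factory=dict)
    calibration_replicates: int = 3
    samples: list[SampleScenario] = field(default_factory=list)
    mode: str = "calibration"
    seed: int | None = 42

    def __post_init__(self) -> None:
        if self.mode not in ("calibration", "absolute"):
            raise ValueError("mode must be 'calibration' or 'absolute'")
        if not self.regions:
            self.regions = default_regions(
                list(self.analytes) + [self.internal_standard]
            )
        owners = {r.owner for r in self.regions}
        declared = {a.name for a in self.analytes} | {self.internal_standard.name}
        unresolved = owners - declared
        if unresolved:
            raise ValueError(
                f"regions owned by undeclared analytes: {sorted(unresolved)}"
            )
        if self.internal_standard.name not in owners:
            raise ValueError("the internal standard needs an integration region")

    def analyte(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        if name == self.internal_standard.name:
            return self.internal_standard
        raise KeyError(f"analyte {name!r} is not declared in this configuration")


def _parse_analyte(entry: Any) -> AnalyteSpec:
    if isinstance(entry, str):
        return analyte_by_name(entry)
    lines = tuple(
        Line(position_ppm=ln[0], relative_intensity=ln[1],
             width_hz=ln[2] if len(ln) > 2 else 0.5)
        for ln in entry["lines"]
    )
    return AnalyteSpec(
        name=entry["name"],
        molar_mass=entry["molar_mass"],
        purity_percent=entry.get("purity_percent", 100.0),
        n_protons=entry.get("n_protons", 1),
        t1_s=entry.get("t1_s", 1.5),
        lines=lines,
    )


def _parse_regions(raw: Any, analytes, standard) -> list[IntegrationRegion]:
    if raw is None:
        return default_regions(list(analytes) + [standard])
    if isinstance(raw, dict) and "pad_ppm" in raw:
        return default_regions(
            list(analytes) + [standard], pad_ppm=float(raw["pad_ppm"])
        )
    return [
        IntegrationRegion(
            label=r.get("label", r["owner"]),
            low_ppm=float(r["low_ppm"]),
            high_ppm=float(r["high_ppm"]),
            owner=r["owner"],
        )
        for r in raw
    ]


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    acq = AcquisitionParams.from_dict(raw.get("acquisition") or {})
    analytes = [_parse_analyte(a) for a in raw.get("analytes", ["FLP", "AZH"])]
    std_raw = raw.get("internal_standard") or {}
    if isinstance(std_raw, str):
        standard = analyte_by_name(std_raw)
        std_conc = 10.0
    else:
        name = std_raw.get("name", "inositol")
        standard = (
            analyte_by_name(name) if name in DEFAULT_ANALYTES else _parse_analyte(std_raw)
        )
        std_conc = float(std_raw.get("concentration_mg_ml", 10.0))
    sim_raw = raw.get("simulation") or {}
    sim = SimulationSettings(
        ks=float(sim_raw.get("ks", 1000.0)),
        noise_sigma_per_scan=float(sim_raw.get("noise_sigma_per_scan", 0.0)),
        amplitude_noise_frac=float(sim_raw.get("amplitude_noise_frac", 0.005)),
        baseline_coefficients=tuple(sim_raw.get("baseline_coefficients", ()) or ()),
        solvent_amplitude=float(sim_raw.get("solvent_amplitude", 20.0)),
    )
    proc_raw = raw.get("processing") or {}
    ref = proc_raw.get("reference", {"observed_ppm": 2.5, "assigned_ppm": 2.5})
    proc = ProcessingSettings(
        lb_hz=float(proc_raw.get("lb_hz", 0.3)),
        baseline_order=int(proc_raw.get("baseline_order", 2)),
        zero_fill_to=proc_raw.get("zero_fill_to"),
        reference_observed_ppm=(
            None if ref is None else float(ref.get("observed_ppm", 2.5))
        ),
        reference_assigned_ppm=(
            2.5 if ref is None else float(ref.get("assigned_ppm", 2.5))
        ),
    )
    regions = _parse_regions(raw.get("regions"), analytes, standard)
    levels = {
        str(k): [float(v) for v in vs]
        for k, vs in (raw.get("calibration_levels") or _default_levels(analytes)).items()
    }
    samples = [
        SampleScenario(
            name=s["name"],
            concentrations={str(k): float(v) for k, v in s["concentrations"].items()},
            replicates=int(s.get("replicates", 3)),
        )
        for s in raw.get("samples", [])
    ]
    return RunConfig(
        acquisition=acq,
        analytes=analytes,
        internal_standard=standard,
        internal_standard_mg_ml=std_conc,
        simulation=sim,
        processing=proc,
        regions=regions,
        calibration_levels=levels,
        calibration_replicates=int(raw.get("calibration_replicates", 3)),
        samples=samples,
        mode=raw.get("mode", "calibration"),
        seed=raw.get("seed", 42),
    )


def _default_levels(analytes) -> dict[str, list[float]]:
    ranges = {
        "FLP": [0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0],
        "AZH": [0.2, 0.5, 1.0, 2.5, 5.0, 10.0, 12.5, 15.0],
    }
    return {a.name: ranges.get(a.name, [0.5, 1.0, 2.0, 5.0, 10.0]) for a in analytes}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def default_config(**overrides: Any) -> RunConfig:
    """The packaged nasal-spray assay configuration.

    Ships three scenarios: the two-analyte calibration series, the 1:2.74
    laboratory mixture (7.3 mg/ml FLP, 20.0 mg/ml AZH), and the nasal-spray
    sample reconstituted from twenty 50 ug FLP / 137 ug AZH actuations in
    1.0 ml (1.0 and 2.74 mg/ml nominal).
    """
    raw: dict[str, Any] = {
        "samples": [
            {
                "name": "lab_mixture",
                "concentrations": {"FLP": 7.3, "AZH": 20.0},
                "replicates": 3,
            },
            {
                "name": "nasal_spray",
                "concentrations": {"FLP": 1.0, "AZH": 2.74},
                "replicates": 3,
            },
        ]
    }
    raw.update(overrides)
    return config_from_dict(raw)
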