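"""Built-in analyte definitions for the fluticasone/azelastine nasal-spray assay.

The quantitative signals, in DMSO-d6 at 400 MHz, are:

* fluticasone propionate (FLP): doublet of doublets at 6.290, 6.294, 6.316
  and 6.319 ppm (four equal lines);
* azelastine hydrochloride (AZH): doublet at 8.292 and 8.310 ppm;
* myo-inositol (internal standard): doublet at 3.70 and 3.71 ppm;
* residual DMSO-d6 solvent line at 2.5 ppm.

Multiplets are written as explicit equal-intensity line lists at the
reported chemical shifts rather than being derived from J-couplings.
T1 values are working defaults in the 1-2 s range typical for small
molecules in DMSO-d6; with a 10 s relaxation delay plus ~4 s acquisition the
repetition time comfortably exceeds 5*T1, so the defaults keep the model in
the quantitative regime. The number of protons behind each quantitative
signal defaults to one and is configurable on the spec. Azelastine is
handled as the hydrochloride salt, the form actually weighed.
"""

from __future__ import annotations

from .signal_model import AnalyteSpec, Line

__all__ = [
    "FLUTICASONE",
    "AZELASTINE",
    "INOSITOL",
    "DMSO_LINE",
    "DEFAULT_ANALYTES",
    "analyte_by_name",
]

_DEFAULT_WIDTH_HZ = 0.5

FLUTICASONE = AnalyteSpec(
    name="FLP",
    molar_mass=500.57,  # C25H31F3O5S
    purity_percent=99.50,
    n_protons=1,
    t1_s=1.8,
    lines=(
        Line(6.290, 0.25, _DEFAULT_WIDTH_HZ),
        Line(6.294, 0.25, _DEFAULT_WIDTH_HZ),
        Line(6.316, 0.25, _DEFAULT_WIDTH_HZ),
        Line(6.319, 0.25, _DEFAULT_WIDTH_HZ),
    ),
)

AZELASTINE = AnalyteSpec(
    name="AZH",
    molar_mass=418.36,  # C22H24ClN3O * HCl, salt as weighed
    purity_percent=99.80,
    n_protons=1,
    t1_s=1.6,
    lines=(
        Line(8.292, 0.5, _DEFAULT_WIDTH_HZ),
        Line(8.310, 0.5, _DEFAULT_WIDTH_HZ),
    ),
)

INOSITOL = AnalyteSpec(
    name="inositol",
    molar_mass=180.16,  # C6H12O6
    purity_percent=99.50,
    n_protons=1,
    t1_s=1.2,
    lines=(
        Line(3.70, 0.5, _DEFAULT_WIDTH_HZ),
        Line(3.71, 0.5, _DEFAULT_WIDTH_HZ),
    ),
)

DMSO_LINE = Line(2.50, 1.0, 1.2)

DEFAULT_ANALYTES = {a.name: a for a in (FLUTICASONE, AZELASTINE, INOSITOL)}


def analyte_by_name(name: str) -> AnalyteSpec:
    try:
        return DEFAULT_ANALYTES[name]
    except KeyError:
        raise KeyError(
            f"unknown analyte {name!r}; known: {sorted(DEFAULT_ANALYTES)}"
        ) from None
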