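# Methods

This note documents the models, numerical choices and limitations behind
the package: what the simulator emulates, how the processing and
quantification layers are defined, which statistical conventions the
validation layer uses, and what the synthetic studies can and cannot show
about real spectra.

## Signal model

Each spectral line is rendered in the time domain as a damped complex
exponential `a·exp(2πi·f·t − π·w·t)`, whose Fourier transform is a
Lorentzian of full width at half maximum `w` (Hz) centred at offset
frequency `f`. A compound's quantitative multiplet is an explicit line list
(four equal lines for the FLP doublet of doublets, two for the AZH and
inositol doublets) at the reported chemical shifts; scalar couplings are
never resolved into J-values because only line positions are known, and no
quantum-mechanical spin evolution is modelled (no strong coupling, no 2D).

The component amplitude follows the quantitative equation
`a = Ks · c_molar · (P/100) · n · E(θ, TR, T1)`, where `c_molar` is the
weighed mass concentration divided by the molar mass, `P` the declared
purity of the material (weighed mass times P/100 is actual analyte), `n`
the proton count behind the multiplet and `E` the steady-state flip-angle
factor `sinθ·(1−e^(−TR/T1))/(1−e^(−TR/T1)·cosθ)`, which reduces to the
`1 − e^(−TR/T1)` recovery at 90°. The flip-angle factor is an extension
beyond the 90°-only recovery equation, needed so that pulse-angle trends
can be explored. TR is the pulse width + receiver dead time + acquisition
time + relaxation delay.

Default acquisition parameters mirror a routine 400 MHz experiment:
15 ppm sweep centred at 6.175 ppm, 65 536 points, 90° pulses of 13.5 µs,
4.08 s acquisition time, 10 s relaxation delay, 64 scans, 32 dB receiver
gain, 20 °C. Receiver gain and temperature are metadata only: ratios are
invariant to absolute scaling and the model carries no
temperature-dependent physics. One internal inconsistency of these values
is resolved in favour of the point grid: with a 6 000 Hz sweep, 65 536
complex points span 10.9 s, so the 4.08 s acquisition-time entry is treated
as the metadata value used inside TR while the FID length follows
`data_points / spectral_width`.

### Parameters without reported values

* **T1** — not reported for any compound. Defaults of 1.8 s (FLP), 1.6 s
  (AZH) and 1.2 s (inositol) sit in the 1–2 s range typical of small
  molecules in DMSO-d6 and keep TR ≈ 14.1 s > 5·T1, consistent with the
  finding that a 10 s relaxation delay suffices for quantitation.
* **n** — the proton count behind each quantitative signal is not stated;
  all default to 1 and are configurable on the analyte spec, never
  hard-coded downstream.
* **Linewidths** — 0.5 Hz natural width per line (1.2 Hz for the solvent),
  a well-shimmed small-molecule value; configurable per line.
* **Noise** — additive complex Gaussian noise of per-scan standard
  deviation σ in the time domain, with effective σ/√N after averaging N
  scans (the √N law is verified by a Monte-Carlo test). A multiplicative
  per-component amplitude perturbation `1 + frac·N(0,1)` emulates
  run-to-run integral variability; the headline robustness studies use
  frac = 0.5 %. Baseline drift is injected as a polynomial (order ≤ 3) in
  ppm added to the real spectrum after transformation.
* **AZH mass basis** — the hydrochloride salt mass (418.36 g/mol), the form
  actually weighed.

All randomness in a sample derives from one integer seed recorded in the
FID provenance; identical spec + seed gives a bit-identical FID.

## Processing

The elaboration chain mirrors instrument practice and logs every step with
its parameters:

1. **Exponential apodization** (default 0.3 Hz) multiplies the FID by
   `exp(−π·lb·t)`, adding exactly `lb` Hz to every Lorentzian width.
2. **Transform** halves the first point (one-sided transform convention,
   flat baseline) and scales by the dwell time, so a time-domain amplitude
   A integrates to A/2 in intensity·Hz units; the ppm axis is descending.
   Zero-filling is off by default (the acquired grid is kept) and
   preserves region integrals provided the FID has decayed within the
   acquisition window — for truncated FIDs, zero-filling redistributes
   sinc ripple and the conservation property intentionally does not hold.
3. **Automatic phasing** minimises the integrated negative part of the
   real spectrum over zero- and first-order phase (first-order expressed
   as total sweep across the window, pivot at the axis centre): a coarse
   grid seeds a Nelder–Mead polish. The criterion is documented and
   swappable; it is robust for sparse, upright small-molecule spectra but
   would need a different penalty for spectra with genuine negative
   features. A spectrum already within tolerance of non-negative is
   returned unchanged, which also makes the step idempotent; a
   non-convergent optimisation returns the input flagged in the log.
4. **Baseline correction** fits a polynomial (default order 2, capped at
   3) to points outside user-declared signal windows and subtracts it.
5. **Referencing** rigidly shifts the axis so the observed solvent line
   (sought within ±0.05 ppm, required to stand 5× above the median
   absolute intensity) sits at its assigned 2.5 ppm.

## Quantification

Integration is a plain trapezoidal sum of the real part over a declared
ppm window — the instrument-style region integral; no peak fitting is
applied by default. Default windows pad each multiplet's extreme line
positions by ±0.02 ppm. At the simulated 0.8 Hz effective linewidth this
leaves ~2–3 % of each Lorentzian's area in the tails outside the window;
because analyte and standard windows lose nearly the same fraction, the
effect largely cancels in ratios, contributes < 1 % bias to absolute
purities, and is absorbed entirely by the slope in calibration mode. The
ratio of any region to the internal-standard region feeds either the
calibration line (C = (ratio − a)/b, with values outside the validated
range flagged but not rejected) or the purity equation. Whether the
standard's area should be per-proton-normalised is ambiguous in the source
protocol; the ratio is taken over the configured regions as-is and
n-normalisation enters only through the purity equation.

## Validation statistics

Sample standard deviations use the n−1 denominator throughout — the only
convention that reproduces the bench tables (e.g. 0.91/1.04 for the
pure-form recoveries). The percent error of a mean is %RSD/√n, the only
reading consistent with the printed 0.32 (= 0.91/100.14·100/√8) and 0.39
(= 0.68/100.85·100/√3). The method comparison uses the two-sided
pooled-variance t-test with n1+n2−2 degrees of freedom (Welch available as
an option) and the variance-ratio F-test with the larger variance in the
numerator, so F ≥ 1. Critical values at α = 0.05 come from the t and F
distribution quantiles, never from hard-coded tables. One consequence: for
the FLP pure-form comparison the larger variance lies in the 4-replicate
HPLC group, so the critical value is F(0.95; 3, 7) = 4.35 rather than the
F(0.95; 7, 3) = 8.89 bracketed in the bench table for both drugs; the
quantile convention is kept and the discrepancy noted here.

The published LOD/LOQ values (0.04/0.12 mg/ml FLP, 0.02/0.05 AZH) are not
reproducible from the published Sa and slope through LOD = 3.3·Sa/b and
LOQ = 10·Sa/b (which give 0.035/0.105 and 0.014/0.043); the formulas are
implemented as stated and both sets of numbers are reported side by side
rather than reconciled. Similarly, a few tabulated amount-found values
disagree with their printed recoveries at the shown precision; the
recoveries are treated as authoritative. The linearity ranges are taken in
mg/ml, consistent with the stock preparations.

## Study designs and problem sizes

The pipeline default acquires each calibration level in triplicate and
fits the line to per-level mean ratios, mirroring bench calibration
practice; samples are assayed in triplicate. The Monte-Carlo robustness
studies use a deliberately harsher single-spectrum-per-level design with
0.5 % multiplicative amplitude noise, 16 384-point spectra and 200 seeded
runs — a problem size at which the full 200-run study completes in about a
minute while keeping every spectral feature resolved. Run k derives its
seed deterministically from (base_seed, k).

## What the synthetic data does not show

The simulator emulates lineshape, relaxation attenuation, scan-averaged
noise, amplitude variability and baseline drift, but not field
inhomogeneity or shimming artefacts, solvent suppression, radiation
damping, 13C satellites, temperature drift of chemical shifts, or real
excipient backgrounds. Passing tests therefore demonstrate that the
processing and statistics layers are correct and that the workflow is
robust to the modelled noise sources — not that the assay would meet the
same figures of merit on any particular instrument. Degenerate inputs are
rejected loudly rather than patched: lines outside the spectral window,
regions outside the axis, all-signal baseline fits, zero-variance groups
and zero-slope calibrations all raise with a named cause.
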