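# qnmr

Quantitative proton-NMR (qNMR) toolkit for the simultaneous assay of
**fluticasone propionate (FLP)** and **azelastine hydrochloride (AZH)** —
the two actives of combination nasal sprays for allergic rhinitis — against
a **myo-inositol internal standard** in DMSO-d6, with full ICH Q2(R1)
validation statistics.

The package is aimed at analytical scientists who want a tested, scriptable
version of the internal-standard qNMR workflow: a physically grounded
spectrum simulator standing in for the spectrometer, the routine 1D
elaboration chain, region-integral quantification, and the statistics used
to validate a pharmaceutical assay.

## The model

The integrated area *I* of a signal is proportional to the molar
concentration *c* of the species and the number *n* of protons behind the
signal, attenuated by incomplete longitudinal relaxation between pulses:

    I = Ks · c · n · (1 − e^(−TR/T1))

where *Ks* is the spectrometer constant, *TR* the repetition time and *T1*
the longitudinal relaxation time. At TR = 5·T1 the recovery is 99.3 % and
the measurement is quantitative. Because *Ks* is common to all signals of
one spectrum, the ratio of two areas obeys

    I1/I2 = (c1·n1)/(c2·n2)

and with the internal-standard purity equation

    P1 = (I1/I2)·(n2/n1)·(M1/M2)·(W2/W1)·P2

a weighed sample plus a standard of known purity *P2* yields the analyte
purity *P1* directly (M: molar masses, W: weighed masses, same solution
volume). Alternatively, analyte/standard area ratios are mapped to
concentrations through an ordinary-least-squares calibration line, from
which LOD = 3.3·Sa/b and LOQ = 10·Sa/b follow (Sa: standard deviation of
the intercept, b: slope).

Quantitative signals, in DMSO-d6 at 400 MHz: FLP doublet of doublets at
6.290/6.294/6.316/6.319 ppm, AZH doublet at 8.292/8.310 ppm, inositol
doublet at 3.70/3.71 ppm; residual solvent line at 2.5 ppm is used for axis
referencing.

## Worked example

```python
from qnmr import default_config, run_pipeline

cfg = default_config(acquisition={"data_points": 16384}, seed=42)
result = run_pipeline(cfg, outdir="out")
print(result.report.precision[["sample", "analyte", "mean_recovery", "sd"]])
```

This simulates triplicate calibrations over 0.25–20.0 (FLP) and 0.2–15.0
mg/ml (AZH) with 10 mg/ml inositol, processes every FID (0.3 Hz line
broadening, Fourier transform, automatic phasing, polynomial baseline,
solvent referencing), integrates the three quantitative regions, fits both
calibration lines and assays two samples. Output:

```
     sample analyte  mean_recovery       sd
lab_mixture     AZH      99.89       0.18
lab_mixture     FLP      98.96       0.52
nasal_spray     AZH     100.58       0.52
nasal_spray     FLP      99.47       0.55
```

The `lab_mixture` rows are the 1:2.74 FLP:AZH mixture (7.3 and 20.0 mg/ml)
assayed at 98.96 % and 99.89 % mean recovery; `nasal_spray` is the
spray-pump sample (20 actuations of 50 µg FLP / 137 µg AZH reconstituted in
1.0 ml, i.e. 1.0 and 2.74 mg/ml nominal). Recoveries near 100 % with sub-1 %
standard deviations indicate an accurate, precise assay.

The same workflow is available from the shell:

```sh
qnmr pipeline --seed 42 -o out/
qnmr simulate -c cfg.yaml --seed 42 -o spectra/
qnmr process spectra/lab_mixture_r1.jdx --lb 0.3 -o processed.jdx
qnmr quantify processed.jdx --regions regions.csv --calib calib.csv
```

## Analysis scripts

The `analysis/` directory holds the numbered study drivers, each writing
its tables under `results/`:

1. `01_simulate_spectra.py` — archive the packaged scenarios as JCAMP-DX;
2. `02_assay_pipeline.py` — end-to-end calibration + assay + specificity;
3. `03_validation_statistics.py` — accuracy/precision/stability/LOD–LOQ and
   qNMR-vs-HPLC t/F comparisons recomputed from the bundled bench datasets;
4. `04_headline_robustness.py` — 200-run Monte-Carlo check of the r² >
   0.999 and %RSD < 1.5 performance bounds.

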