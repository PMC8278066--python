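#!/usr/bin/env python
"""Simulate the assay's spectra and archive them as JCAMP-DX.

Generates the three packaged scenarios — one calibration level per drug,
the 1:2.74 laboratory mixture (7.3 / 20.0 mg/ml FLP/AZH) and the
nasal-spray sample (1.0 / 2.74 mg/ml from twenty 50 ug / 137 ug
actuations in 1.0 ml) — each with the 10 mg/ml inositol internal standard,
and writes raw FIDs, processed spectra and a manifest under
results/spectra/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qnmr.config import default_config
from qnmr.jcampdx import export_xy, write_fid, write_spectrum
from qnmr.pipeline import derive_seed, process_fid, simulate_sample

OUT = Path(__file__).resolve().parents[1] / "results" / "spectra"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    cfg = default_config(acquisition={"data_points": 16384}, seed=args.seed)
    OUT.mkdir(parents=True, exist_ok=True)

    scenarios = {
        "calibration_FLP_5mg": {"FLP": 5.0},
        "calibration_AZH_5mg": {"AZH": 5.0},
        "lab_mixture": {"FLP": 7.3, "AZH": 20.0},
        "nasal_spray": {"FLP": 1.0, "AZH": 2.74},
    }
    rows = []
    for idx, (name, concs) in enumerate(scenarios.items()):
        seed = derive_seed(args.seed, 50, idx)
        fid = simulate_sample(cfg, concs, seed=seed)
        spectrum = process_fid(cfg, fid)
        write_fid(fid, OUT / f"{name}_fid.jdx", title=name)
        write_spectrum(spectrum, OUT / f"{name}.jdx", title=name)
        export_xy(spectrum, OUT / f"{name}.xy")
        rows.append({"scenario": name, "seed": seed, **concs})
        print(f"simulated {name}: {concs} (seed {seed})")
    pd.DataFrame(rows).to_csv(OUT / "manifest.csv", index=False)
    print(f"\nwrote FIDs, spectra and manifest to {OUT}")


if __name__ == "__main__":
    main()
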