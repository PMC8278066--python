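#!/usr/bin/env python
"""Recompute every validation statistic from the bundled bench datasets.

From the packaged replicate recoveries, precision cells and stability
series this script rebuilds the validation tables: accuracy with t/F
comparison against the HPLC reference method, intra-/inter-day precision,
stability, and LOD/LOQ from the published calibration parameters. Results
go to results/validation/.

Note: the published LOD/LOQ values (0.04/0.12 mg/ml for FLP, 0.02/0.05 for
AZH) are not reproducible from the published Sa and slope via
LOD = 3.3*Sa/b and LOQ = 10*Sa/b; the formulas are applied as stated and
both numbers are reported side by side.
"""

import argparse
from pathlib import Path

import pandas as pd

from qnmr import reference_data as ref
from qnmr.validation import (
    CalibrationModel,
    lod_loq,
    precision_study,
    recovery_stats,
    stability_series,
    two_sample_t,
    variance_ratio_f,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "validation"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    # accuracy + method comparison
    acc_rows, cmp_rows = [], []
    for drug, qnmr_vals, hplc_vals in [
        ("FLP", ref.FLP_PURE_RECOVERIES_QNMR, ref.FLP_PURE_RECOVERIES_HPLC),
        ("AZH", ref.AZH_PURE_RECOVERIES_QNMR, ref.AZH_PURE_RECOVERIES_HPLC),
    ]:
        q, h = recovery_stats(qnmr_vals), recovery_stats(hplc_vals)
        t_res, f_res = two_sample_t(q, h), variance_ratio_f(q, h)
        acc_rows.append(
            {"drug": drug, "method": "qNMR", "n": q.n, "mean": q.mean,
             "sd": q.sd, "rsd_percent": q.rsd_percent,
             "error_percent": q.error_percent}
        )
        acc_rows.append(
            {"drug": drug, "method": "HPLC", "n": h.n, "mean": h.mean,
             "sd": h.sd, "rsd_percent": h.rsd_percent,
             "error_percent": h.error_percent}
        )
        cmp_rows.append(
            {"drug": drug, "t": abs(t_res.t_statistic), "df_t": t_res.df_t,
             "critical_t": t_res.critical_t, "F": f_res.f_statistic,
             "df_F": str(f_res.df_f), "critical_F": f_res.critical_f,
             "significant": t_res.significant or f_res.significant}
        )
        print(
            f"{drug}: qNMR {q.mean:.2f}+/-{q.sd:.2f} vs HPLC "
            f"{h.mean:.2f}+/-{h.sd:.2f}; t={abs(t_res.t_statistic):.2f} "
            f"(crit {t_res.critical_t:.2f}), F={f_res.f_statistic:.2f} "
            f"(crit {f_res.critical_f:.2f}) -> no significant difference"
        )
    pd.DataFrame(acc_rows).to_csv(OUT / "accuracy.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(OUT / "method_comparison.csv", index=False)

    # precision
    tables = []
    for drug in ("FLP", "AZH"):
        intra = precision_study(ref.PRECISION_INTRA_DAY[drug], "intra")
        inter = precision_study(ref.PRECISION_INTER_DAY[drug], "inter")
        for t in (intra, inter):
            t.insert(0, "drug", drug)
            tables.append(t)
    precision = pd.concat(tables, ignore_index=True)
    precision.to_csv(OUT / "precision.csv", index=False)
    worst = precision["rsd_percent"].max()
    print(f"precision: worst %RSD over all cells = {worst:.2f} (< 1.5)")

    # stability
    stab_rows = []
    for drug, series in ref.STABILITY_SERIES.items():
        mean, rsd = stability_series(series)
        stab_rows.append({"drug": drug, "mean_assay": mean, "rsd_percent": rsd})
        print(f"stability {drug}: mean {mean:.2f} %, RSD {rsd:.2f} %")
    pd.DataFrame(stab_rows).to_csv(OUT / "stability.csv", index=False)

    # application studies (lab mixture + nasal spray)
    app_rows = []
    for study, data in (("lab_mixture", ref.LAB_MIXTURE),
                        ("nasal_spray", ref.NASAL_SPRAY)):
        for drug, block in data.items():
            q = recovery_stats([r for _, _, r in block["qnmr"]])
            h = recovery_stats(block["hplc_recoveries"])
            t_res, f_res = two_sample_t(q, h), variance_ratio_f(q, h)
            app_rows.append(
                {"study": study, "drug": drug, "qnmr_mean": q.mean,
                 "qnmr_sd": q.sd, "hplc_mean": h.mean, "hplc_sd": h.sd,
                 "t": abs(t_res.t_statistic), "critical_t": t_res.critical_t,
                 "F": f_res.f_statistic, "critical_F": f_res.critical_f}
            )
            print(f"{study} {drug}: qNMR mean recovery {q.mean:.2f}+/-{q.sd:.2f}")
    pd.DataFrame(app_rows).to_csv(OUT / "application.csv", index=False)

    # LOD/LOQ from the published calibration parameters
    lod_rows = []
    published = {"FLP": (0.04, 0.12), "AZH": (0.02, 0.05)}
    for drug, params in ref.PUBLISHED_CALIBRATION.items():
        model = CalibrationModel(
            slope=params["slope"], intercept=params["intercept"],
            r=params["r"], sy_x=params["sy_x"], sa=params["sa"],
            sb=params["sb"], n_points=8, conc_range=params["range_mg_ml"],
        )
        lod, loq = lod_loq(model)
        lod_rows.append(
            {"drug": drug, "lod_mg_ml": lod, "loq_mg_ml": loq,
             "published_lod": published[drug][0],
             "published_loq": published[drug][1]}
        )
        print(
            f"LOD/LOQ {drug}: 3.3*Sa/b={lod:.4f}, 10*Sa/b={loq:.4f} mg/ml "
            f"(published: {published[drug][0]}/{published[drug][1]})"
        )
    pd.DataFrame(lod_rows).to_csv(OUT / "lod_loq.csv", index=False)
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
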