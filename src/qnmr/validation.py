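"""ICH Q2(R1) method-validation statistics.

Implements the statistical toolkit used to validate a quantitative assay:
calibration linearity (ordinary least squares with the standard deviations
of slope, intercept and residuals), detection and quantification limits from
the calibration (LOD = 3.3*Sa/b, LOQ = 10*Sa/b), accuracy as percent
recovery, intra-/inter-day precision, sample stability over time, a
specificity check for cross-signal interference, and the two-sample pooled
t-test and variance-ratio F-test used to compare the method against an
independent reference method.

Conventions, chosen to match standard pharmaceutical-analysis practice:
standard deviations use the n-1 denominator; the percent error of a mean is
%RSD/sqrt(n); the F statistic puts the larger variance in the numerator so
F >= 1; critical values at alpha are taken from the t and F distribution
quantiles, never from hard-coded tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import Spectrum
from .quantification import IntegrationRegion, integrate_region

__all__ = [
    "CalibrationModel",
    "RecoveryStats",
    "ComparisonResult",
    "ValidationReport",
    "fit_calibration",
    "lod_loq",
    "recovery",
    "recovery_stats",
    "two_sample_t",
    "variance_ratio_f",
    "precision_study",
    "stability_series",
    "specificity_check",
]


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted calibration line ratio = intercept + slope * concentration.

    ``sy_x`` is the residual standard deviation (n-2 degrees of freedom),
    ``sa`` and ``sb`` the standard deviations of intercept and slope, and
    ``conc_range`` the validated concentration range in mg/ml.
    """

    slope: float
    intercept: float
    r: float
    sy_x: float
    sa: float
    sb: float
    n_points: int
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a calibration needs at least 3 points")
        if min(self.sy_x, self.sa, self.sb) < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class RecoveryStats:
    """Summary of a set of percent recoveries (mean, sd, %RSD, %error)."""

    values: tuple[float, ...]
    mean: float
    sd: float
    rsd_percent: float
    error_percent: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-method comparison (t and/or F test)."""

    alpha: float
    t_statistic: float | None = None
    df_t: int | None = None
    critical_t: float | None = None
    f_statistic: float | None = None
    df_f: tuple[int, int] | None = None
    critical_f: float | None = None
    significant: bool = False


def fit_calibration(
    points: Sequence[tuple[float, float]],
    conc_range: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Ordinary least squares of response on concentration.

    ``points`` are (concentration mg/ml, integral ratio) pairs; at least
    three distinct concentrations are required. Standard deviations follow
    the textbook OLS formulas with n-2 residual degrees of freedom.
    """
    if len(points) < 3:
        raise ValueError("at least 3 calibration points are required")
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("calibration concentrations are all identical")
    fit = sps.linregress(conc, resp)
    n = len(conc)
    residuals = resp - (fit.intercept + fit.slope * conc)
    sy_x = math.sqrt(float(residuals @ residuals) / (n - 2)) if n > 2 else 0.0
    if conc_range is None:
        conc_range = (float(conc.min()), float(conc.max()))
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        sy_x=sy_x,
        sa=float(fit.intercept_stderr),
        sb=float(fit.stderr),
        n_points=n,
        conc_range=conc_range,
    )


def lod_loq(model: CalibrationModel) -> tuple[float, float]:
    """Detection and quantification limits: (3.3*Sa/b, 10*Sa/b).

    Their ratio is exactly 10/3.3 whenever both come from the same model.
    """
    if model.slope == 0:
        raise ValueError("calibration slope is zero; LOD/LOQ undefined")
    b = abs(model.slope)
    return 3.3 * model.sa / b, 10.0 * model.sa / b


def recovery(found_mg_ml: float, taken_mg_ml: float) -> float:
    """Percent recovery, 100 * found / taken."""
    if taken_mg_ml <= 0:
        raise ValueError("taken_mg_ml must be positive")
    return 100.0 * found_mg_ml / taken_mg_ml


def recovery_stats(values: Sequence[float]) -> RecoveryStats:
    """Mean, sample sd (n-1), %RSD and %error = %RSD/sqrt(n) of recoveries."""
    if len(values) < 2:
        raise ValueError("at least 2 values are needed for a standard deviation")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("nan")
    return RecoveryStats(
        values=tuple(float(v) for v in arr),
        mean=mean,
        sd=sd,
        rsd_percent=rsd,
        error_percent=rsd / math.sqrt(len(arr)),
        n=len(arr),
    )


def two_sample_t(
    group1: RecoveryStats,
    group2: RecoveryStats,
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test of equal means (pooled variance by default).

    With the pooled form the degrees of freedom are n1 + n2 - 2; the Welch
    variant (Satterthwaite df) is available for unequal variances.
    Significance compares |t| to the two-sided critical value at ``alpha``.
    """
    n1, n2 = group1.n, group2.n
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = group1.sd**2, group2.sd**2
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance; t undefined")
    if welch:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df_float = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        df = int(round(df_float))
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    t_stat = (group1.mean - group2.mean) / se
    crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    return ComparisonResult(
        alpha=alpha,
        t_statistic=float(t_stat),
        df_t=df,
        critical_t=crit,
        significant=abs(t_stat) > crit,
    )


def variance_ratio_f(
    group1: RecoveryStats, group2: RecoveryStats, alpha: float = 0.05
) -> ComparisonResult:
    """Variance-ratio F-test with the larger variance in the numerator (F >= 1)."""
    v1, v2 = group1.sd**2, group2.sd**2
    if v1 == 0 or v2 == 0:
        raise ValueError("zero variance in a group; F undefined")
    if v1 >= v2:
        f_stat = v1 / v2
        df = (group1.n - 1, group2.n - 1)
    else:
        f_stat = v2 / v1
        df = (group2.n - 1, group1.n - 1)
    crit = float(sps.f.ppf(1.0 - alpha, df[0], df[1]))
    return ComparisonResult(
        alpha=alpha,
        f_statistic=float(f_stat),
        df_f=df,
        critical_f=crit,
        significant=f_stat > crit,
    )


def precision_study(
    cells: Mapping[float, Sequence[float]], scheme: str
) -> pd.DataFrame:
    """Per-concentration precision summary for an intra- or inter-day study.

    ``cells`` maps concentration (mg/ml) to its replicate percent-found
    values. Cells with fewer than 2 replicates are reported as absent (NaN
    statistics), never imputed.
    """
    if scheme not in ("intra", "inter"):
        raise ValueError("scheme must be 'intra' or 'inter'")
    rows = []
    for conc in sorted(cells):
        reps = list(cells[conc])
        if len(reps) < 2:
            rows.append(
                {
                    "scheme": scheme,
                    "concentration_mg_ml": conc,
                    "n": len(reps),
                    "mean": float("nan"),
                    "sd": float("nan"),
                    "rsd_percent": float("nan"),
                    "error_percent": float("nan"),
                }
            )
            continue
        st = recovery_stats(reps)
        rows.append(
            {
                "scheme": scheme,
                "concentration_mg_ml": conc,
                "n": st.n,
                "mean": st.mean,
                "sd": st.sd,
                "rsd_percent": st.rsd_percent,
                "error_percent": st.error_percent,
            }
        )
    return pd.DataFrame(rows)


def stability_series(
    assays: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Mean percent assay and %RSD across a (time, percent assay) series."""
    if len(assays) < 2:
        raise ValueError("at least 2 time points are required")
    values = np.asarray([a[1] for a in assays], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return mean, 100.0 * sd / mean


def specificity_check(
    blank: Spectrum,
    component_spectra: Mapping[str, Spectrum],
    mixture: Spectrum,
    regions: Sequence[IntegrationRegion],
    threshold_percent: float = 1.0,
) -> pd.DataFrame:
    """Quantify cross-interference in each quantitative region.

    For every region, the area in the blank and in each individually
    simulated/acquired non-owner component spectrum is expressed as a
    percent of the region's area in the full mixture. The region passes when
    no foreign contribution exceeds ``threshold_percent``.
    """
    rows = []
    for region in regions:
        mix_area = integrate_region(mixture, region).absolute_area
        ref = abs(mix_area) + 1e-300
        blank_pct = 100.0 * integrate_region(blank, region).absolute_area / ref
        contributions = {}
        for name, spec in component_spectra.items():
            if name == region.owner:
                continue
            contributions[name] = (
                100.0 * integrate_region(spec, region).absolute_area / ref
            )
        worst = max([abs(blank_pct)] + [abs(v) for v in contributions.values()])
        rows.append(
            {
                "region": region.label,
                "owner": region.owner,
                "mixture_area": mix_area,
                "blank_percent": blank_pct,
                **{f"from_{k}_percent": v for k, v in contributions.items()},
                "max_foreign_percent": worst,
                "passes": worst < threshold_percent,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Aggregated validation output mirroring a full assay validation.

    Tables are pandas DataFrames; ``to_csv``/``from_csv`` round-trip the
    report through a directory of CSV files at full float precision.
    """

    calibration: pd.DataFrame = field(default_factory=pd.DataFrame)
    accuracy: pd.DataFrame = field(default_factory=pd.DataFrame)
    precision: pd.DataFrame = field(default_factory=pd.DataFrame)
    stability: pd.DataFrame = field(default_factory=pd.DataFrame)
    specificity: pd.DataFrame = field(default_factory=pd.DataFrame)
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)

    _TABLES = (
        "calibration",
        "accuracy",
        "precision",
        "stability",
        "specificity",
        "comparisons",
    )

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            table: pd.DataFrame = getattr(self, name)
            table.to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "ValidationReport":
        directory = Path(directory)
        kwargs = {}
        for name in cls._TABLES:
            path = directory / f"{name}.csv"
            if path.exists():
                try:
                    kwargs[name] = pd.read_csv(path)
                except pd.errors.EmptyDataError:
                    kwargs[name] = pd.DataFrame()
        return cls(**kwargs)
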