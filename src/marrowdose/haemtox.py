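"""Blood-count nadir analysis and dose-toxicity correlation statistics.

The toxicity endpoint per analyte (Hb, WBC, PLT) is the decrease from the
pre-treatment baseline to the in-treatment nadir.  Its association with the
bone-marrow dose is tested by Pearson correlation and the ANOVA F statistic
of the ordinary least-squares regression (for simple linear regression
F = t^2 of the slope).  Two-sided p values, no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

ANALYTES = ("hb", "wbc", "plt")


@dataclass
class BloodSeries:
    """Baseline plus in-treatment values of one analyte."""

    analyte: str
    baseline: float
    values: list[float]
    units: str = ""
    times_h: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise DegenerateInputError("baseline must be positive")


def nadir_decrease(series: BloodSeries) -> float:
    """Baseline minus in-treatment nadir (analyte units).

    Negative when the series never drops below baseline (returned unclipped).
    """
    if not series.values:
        raise DegenerateInputError("series has no in-treatment values")
    return series.baseline - min(series.values)


@dataclass
class CorrelationResult:
    """Pearson/OLS summary of a dose-toxicity association."""

    r: float
    p: float
    slope: float
    intercept: float
    f_stat: float
    n: int
    perfect_fit: bool = False


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation plus the regression-ANOVA F statistic.

    ``x`` are doses (Gy), ``y`` the blood-count decreases.  A perfect linear
    relation gives |r| = 1 and an unbounded F; it is returned as ``inf`` and
    flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need matched x/y with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    if reg.stderr == 0 or 1.0 - r * r < 1e-12:
        f_stat, perfect = np.inf, True
    else:
        f_stat, perfect = (reg.slope / reg.stderr) ** 2, False
    return CorrelationResult(r=float(r), p=float(p), slope=float(reg.slope),
                             intercept=float(reg.intercept),
                             f_stat=float(f_stat), n=int(x.size),
                             perfect_fit=perfect)


def cohort_dataframe(records) -> pd.DataFrame:
    """Tabulate a cohort: doses and per-analyte nadir decreases."""
    rows = []
    for rec in records:
        row = {"patient": rec.patient_id,
               "dose_per_fraction_gy": rec.dose_per_fraction_gy,
               "total_dose_gy": rec.total_dose_gy}
        for analyte in rec.series:
            series = BloodSeries(analyte=analyte,
                                 baseline=rec.baselines[analyte],
                                 values=list(rec.series[analyte]))
            row[f"{analyte}_decrease"] = nadir_decrease(series)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_cohort(records, dose: str = "per_fraction") -> dict[str, CorrelationResult]:
    """Dose-toxicity correlations per analyte over a cohort.

    ``dose`` selects the per-fraction or total bone-marrow dose as the
    regressor.
    """
    table = cohort_dataframe(records)
    col = {"per_fraction": "dose_per_fraction_gy", "total": "total_dose_gy"}[dose]
    out = {}
    for analyte in ANALYTES:
        key = f"{analyte}_decrease"
        if key in table:
            out[analyte] = pearson_test(table[col].to_numpy(),
                                        table[key].to_numpy())
    return out
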