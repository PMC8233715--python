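"""Calibration and validation figures of merit.

The figures reported per analyte follow standard NIRS practice:

* SEC — standard error of calibration, ``sqrt(SSE / (n - F - 1))`` with F
  the number of PLS factors (degrees of freedom spent on the model).
* SEP — standard error of prediction, the bias-corrected standard deviation
  of validation residuals (``sqrt(sum((r - rbar)^2) / (n - 1))``); the plain
  RMSEP is computed alongside.
* R²c / R²p — squared Pearson correlation of reference and predicted values
  in the calibration / validation set.
* RPD — ratio of performance to deviation, validation-set SD divided by
  SEP; values below 2 indicate a model fit only for screening.
* Consistency — SEC·100/SEP (%); values near 100 mean calibration and
  validation errors are comparable, far from 100 flags over- or
  under-fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REPORT_COLUMNS = ["analyte", "n", "SEC", "R2c", "SEP", "R2p", "RPD", "Consistency"]


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean / min / max / sample SD / CV% of one analyte in one sample set."""

    n: int
    mean: float
    min: float
    max: float
    sd: float
    cv: float | None  # percent; None when the mean is zero


def descriptive(values) -> DescriptiveStats:
    """Descriptive statistics with sample (n-1) SD and CV% = SD/mean*100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = None if mean == 0 else sd / mean * 100.0
    return DescriptiveStats(n=v.size, mean=mean, min=float(v.min()),
                            max=float(v.max()), sd=sd, cv=cv)


def sec(y_true, y_pred, n_factors: int) -> float:
    """Standard error of calibration: sqrt(SSE / (n - F - 1))."""
    r = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    n = r.size
    if n <= n_factors + 1:
        raise ValueError(f"SEC undefined: n={n} <= F+1={n_factors + 1}")
    return float(math.sqrt(np.sum(r**2) / (n - n_factors - 1)))


def sep(y_true, y_pred) -> tuple[float, float]:
    """Bias-corrected standard error of prediction, and plain RMSEP.

    Returns ``(sep, rmsep)``.  A purely biased prediction (constant residual)
    has SEP 0 but nonzero RMSEP.
    """
    r = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 validation samples")
    sep_val = float(math.sqrt(np.sum((r - r.mean()) ** 2) / (r.size - 1)))
    rmsep = float(math.sqrt(np.mean(r**2)))
    return sep_val, rmsep


def r_squared(y_true, y_pred) -> float:
    """Squared Pearson correlation between reference and predicted values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.var(y_true) == 0:
        raise ValueError("R^2 undefined for constant reference values")
    if np.var(y_pred) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


def rpd(sd_validation: float, sep_value: float) -> float:
    """Ratio of performance to deviation: validation SD / SEP."""
    if sep_value <= 0:
        raise ZeroDivisionError("RPD undefined for SEP <= 0")
    return sd_validation / sep_value


def consistency(sec_value: float, sep_value: float) -> float:
    """Consistency percentage: SEC * 100 / SEP."""
    if sep_value <= 0:
        raise ZeroDivisionError("Consistency undefined for SEP <= 0")
    return sec_value * 100.0 / sep_value


def classify_rpd(rpd_value: float) -> str:
    """``"analytical"`` for RPD >= 2, else ``"screening"``.

    The boundary value 2.0 is classified as analytical.
    """
    if rpd_value < 0:
        raise ValueError("RPD cannot be negative")
    return "analytical" if rpd_value >= 2.0 else "screening"


def report_row(analyte: str, n: int, sec_value: float, r2c: float,
               sep_value: float, r2p: float, rpd_value: float,
               consistency_value: float) -> dict:
    return {
        "analyte": analyte, "n": n, "SEC": sec_value, "R2c": r2c,
        "SEP": sep_value, "R2p": r2p, "RPD": rpd_value,
        "Consistency": consistency_value,
    }


def write_report(path, rows: list[dict]) -> None:
    """Write a validation report as delimited text in the standard column order."""
    df = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df.loc[:, REPORT_COLUMNS].to_csv(path, index=False, float_format="%.6g")
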