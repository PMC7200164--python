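"""Power-law scaling of expression against contact frequency.

Across an allelic series, gene expression E relates to the contact
frequency f of the gene with its enhancer region as E = c * f^gamma; on
log-log axes this is a line whose slope (fitted by ordinary least squares)
is the scaling exponent.  The same machinery fits the exponent between the
contact frequencies of two regions across samples: an exponent above one
means the first region's contact escalates super-linearly — preferentially —
as insulation is released.  Spearman's rank correlation quantifies the
monotone association without the power-law assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, NumericError


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit on log10-log10 axes plus rank correlation."""

    exponent: float
    intercept: float  # log10 of the prefactor c
    spearman: float
    n: int

    def predict(self, f: np.ndarray) -> np.ndarray:
        return 10.0**self.intercept * np.asarray(f, dtype=float) ** self.exponent


def _validate_positive(values: np.ndarray, label: str, samples) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(values > 0))
    if bad.size:
        which = samples[bad[0]] if samples is not None else f"row {bad[0]}"
        raise DataValidationError(
            f"non-positive {label} value {values[bad[0]]!r} at {which}: "
            "log-log fitting requires positive values"
        )
    return values


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope/intercept of log10 y on log10 x."""
    lx, ly = np.log10(x), np.log10(y)
    xbar, ybar = lx.mean(), ly.mean()
    sxx = np.sum((lx - xbar) ** 2)
    if sxx == 0:
        raise NumericError("predictor is constant: slope undefined")
    slope = float(np.sum((lx - xbar) * (ly - ybar)) / sxx)
    return slope, float(ybar - slope * xbar)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise DataValidationError(f"need n >= 3, got {len(x)}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise NumericError("zero rank variance: a vector is constant")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def _rho_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho, degrading to NaN when a vector has no rank variance
    (a constant response still has a well-defined OLS slope of zero)."""
    try:
        return spearman_rho(x, y)
    except NumericError:
        return float("nan")


def fit_power_law(table: pd.DataFrame) -> ScalingFit:
    """Fit E = c * f^gamma by OLS of log10(expression) on log10(contact).

    ``table`` needs columns ``sample``, ``expression``, ``contact``; all
    expression and contact values must be positive (zeros are rejected, not
    pseudo-counted).
    """
    required = {"sample", "expression", "contact"}
    if not required.issubset(table.columns):
        raise DataValidationError(
            f"expected columns {sorted(required)}, got {list(table.columns)}"
        )
    n = len(table)
    if n < 3:
        raise DataValidationError(f"need n >= 3 rows, got {n}")
    samples = table["sample"].to_numpy()
    E = _validate_positive(table["expression"].to_numpy(), "expression", samples)
    f = _validate_positive(table["contact"].to_numpy(), "contact", samples)
    slope, intercept = _loglog_ols(f, E)
    return ScalingFit(slope, intercept, _rho_or_nan(f, E), n)


def contact_contact_scaling(fA: np.ndarray, fB: np.ndarray) -> ScalingFit:
    """Exponent of region-B contact against region-A contact across samples.

    OLS of log10(fB) on log10(fA); an exponent above 1 indicates that B's
    contact scales super-linearly (preferentially) with A's.
    """
    fA = _validate_positive(np.asarray(fA), "contact (A)", None)
    fB = _validate_positive(np.asarray(fB), "contact (B)", None)
    if fA.shape != fB.shape or fA.ndim != 1:
        raise DataValidationError("contact series must be 1-D and of equal length")
    if len(fA) < 3:
        raise DataValidationError(f"need n >= 3 samples, got {len(fA)}")
    slope, intercept = _loglog_ols(fA, fB)
    return ScalingFit(slope, intercept, _rho_or_nan(fA, fB), len(fA))
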