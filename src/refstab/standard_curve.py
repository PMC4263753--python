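"""Dilution-series standard curves and amplification-efficiency conversion.

A qPCR standard curve regresses Cq on log10 relative template amount over a
serial dilution of a pooled cDNA sample. The slope of that line determines
the per-cycle amplification factor E = 10^(−1/slope): a slope of −3.3219
corresponds to E = 2, i.e. perfect doubling each cycle. Percent efficiency
is (E − 1) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: log10 of a five-fold dilution step
FIVEFOLD_STEP = -np.log10(5.0)


@dataclass
class DilutionSeries:
    """Dilution points for one assay: (log10 relative amount, Cq)."""

    log10_amounts: np.ndarray
    cq: np.ndarray
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.log10_amounts = np.asarray(self.log10_amounts, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.log10_amounts.shape != self.cq.shape:
            raise ValueError("log10_amounts and cq must have equal length")
        if self.log10_amounts.size < 3:
            raise ValueError("a standard curve needs at least 3 dilution points")
        if not np.isfinite(self.cq).all() or not np.isfinite(self.log10_amounts).all():
            raise ValueError("non-finite values in dilution series")
        d = np.diff(self.log10_amounts)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("log10 amounts must be strictly monotone")


@dataclass
class StandardCurveFit:
    """OLS fit of Cq on log10 amount with derived efficiency.

    slope is in cycles per log10 dilution (negative for a real assay);
    E is the amplification factor per cycle; efficiency_percent = (E−1)·100.
    """

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    E: float
    efficiency_percent: float


def efficiency_from_slope(slope: float) -> float:
    """Amplification factor from a standard-curve slope: E = 10^(−1/slope)."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return float(10.0 ** (-1.0 / slope))


def slope_from_efficiency(e: float) -> float:
    """Standard-curve slope implied by an amplification factor:
    slope = −1/log10(E). Inverse of :func:`efficiency_from_slope`."""
    if e <= 1:
        raise ValueError("amplification factor must exceed 1")
    return float(-1.0 / np.log10(e))


def efficiency_percent(e: float) -> float:
    """Percent efficiency: (E − 1) × 100; 100% means perfect doubling."""
    if e <= 0:
        raise ValueError("amplification factor must be positive")
    return float((e - 1.0) * 100.0)


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Least-squares standard-curve fit.

    r² is the squared Pearson correlation between observed and fitted Cq,
    the convention instrument software reports.
    """
    x, y = series.log10_amounts, series.cq
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 amounts")
    res = stats.linregress(x, y)
    e = efficiency_from_slope(res.slope)
    return StandardCurveFit(
        gene_id=series.gene_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        E=e,
        efficiency_percent=efficiency_percent(e),
    )
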