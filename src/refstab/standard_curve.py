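"""Standard-curve fitting and efficiency-corrected relative quantities.

A qPCR standard curve regresses Cq on log10 relative input over a dilution
series. The raw regression slope is negative (more template, earlier
detection); by field convention the slope is reported as a positive
magnitude, and the per-cycle amplification efficiency follows as

    efficiency% = 100 * (10^(1/|slope|) - 1)

so |slope| = 1/log10(2) ~ 3.3219 corresponds to perfect doubling (100 %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurveFit",
    "fit_standard_curve",
    "efficiency_from_slope",
    "cq_to_relative_quantity",
]


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of one primer pair's dilution series."""

    gene: str
    slope: float  # magnitude, Cq per log10(input)
    intercept: float  # Cq at log10(input) = 0
    r_squared: float
    efficiency_percent: float
    n_points: int

    @property
    def amplification_factor(self) -> float:
        """Fold amplification per cycle, E = 1 + efficiency/100."""
        return 1.0 + self.efficiency_percent / 100.0

    def summary(self) -> str:
        # display rounding mirrors how such tables are printed (one decimal
        # for efficiency, 3-4 significant figures elsewhere); stored values
        # keep full precision
        return (
            f"Standard curve [{self.gene}]  slope={self.slope:.3f}  "
            f"intercept={self.intercept:.2f}  R^2={self.r_squared:.4f}  "
            f"efficiency={self.efficiency_percent:.1f}%  E={self.amplification_factor:.3f}"
        )


def efficiency_from_slope(slope: float) -> float:
    """Convert a standard-curve slope magnitude to amplification efficiency (%)."""
    if slope <= 0:
        raise ValueError(f"slope magnitude must be > 0, got {slope}")
    return 100.0 * (10.0 ** (1.0 / slope) - 1.0)


def fit_standard_curve(series: pd.DataFrame, gene: str | None = None) -> StandardCurveFit:
    """Fit Cq ~ log10(relative input) by ordinary least squares.

    ``series`` needs columns ``log10_input`` and ``cq`` (and optionally
    ``gene``, used for labelling when ``gene`` is not given). Replicate rows
    at the same dilution are used as-is.
    """
    if gene is None:
        gene = str(series["gene"].iloc[0]) if "gene" in series.columns else "?"
    x = np.asarray(series["log10_input"], dtype=float)
    y = np.asarray(series["cq"], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"{gene}: need >= 3 distinct dilution points, got {len(np.unique(x))}"
        )
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(
            f"{gene}: non-amplifying series (Cq does not decrease with input)"
        )
    slope_mag = -float(res.slope)
    return StandardCurveFit(
        gene=gene,
        slope=slope_mag,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_percent=efficiency_from_slope(slope_mag),
        n_points=len(np.unique(x)),
    )


def cq_to_relative_quantity(cq_values, E: float) -> np.ndarray:
    """Efficiency-corrected linear relative quantities, Q_i = E^(Cq_min - Cq_i).

    The sample with the lowest Cq (most template) is the reference and gets
    Q = 1; all other quantities fall in (0, 1]. Sample order is preserved.
    """
    if not (1.0 < E <= 2.2):
        raise ValueError(f"amplification factor E must be in (1, 2.2], got {E}")
    cq = np.asarray(cq_values, dtype=float)
    if cq.size == 0:
        raise ValueError("cq_values must be non-empty")
    if not np.all(np.isfinite(cq)):
        bad = np.flatnonzero(~np.isfinite(cq))
        raise ValueError(f"non-finite Cq at position(s) {bad.tolist()}")
    return E ** (cq.min() - cq)


def standard_curve_report(fits: list[StandardCurveFit]) -> pd.DataFrame:
    """Tabular report of standard-curve parameters, one row per primer pair."""
    return pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "intercept": [round(f.intercept, 2) for f in fits],
            "slope": [round(f.slope, 3) for f in fits],
            "efficiency_percent": [round(f.efficiency_percent, 1) for f in fits],
            "r_squared": [round(f.r_squared, 4) for f in fits],
        }
    )
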