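"""Measurement-level calculators for the physiological indicator panel.

Covers the thiobarbituric-acid MDA assay equation, inversion of linear
standard curves (HPLC peak area / absorbance -> concentration), derived
growth traits (root:shoot ratio, specific leaf area), percent-change effect
summaries between treatments, and the Pearson correlation matrix over
indicators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import IndicatorPanel, InsufficientDataError, StandardCurve

__all__ = [
    "AbsorbanceTriplet",
    "CorrelationMatrix",
    "mda_content",
    "curve_concentration",
    "derived_traits",
    "percent_change",
    "pearson_matrix",
]


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """Blank-corrected optical absorbances at 450, 532 and 600 nm."""

    A450: float
    A532: float
    A600: float

    def __post_init__(self) -> None:
        for name in ("A450", "A532", "A600"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite absorbance {name}")


def mda_content(a: AbsorbanceTriplet) -> float:
    """Malondialdehyde content from the three-wavelength TBA assay.

    MDA = 6.45 * (A532 - A600) - 0.56 * A450, in the assay's printed units
    (per gram fresh weight). A532-A600 removes turbidity background; the
    A450 term corrects for soluble-sugar interference.
    """
    return 6.45 * (a.A532 - a.A600) - 0.56 * a.A450


def curve_concentration(signal: float, curve: StandardCurve) -> float:
    """Invert a linear standard curve: concentration = (signal - b) / m.

    Emits a :class:`UserWarning` (not an error) when the recovered
    concentration falls outside the curve's validated range.
    """
    x = (signal - curve.intercept) / curve.slope
    if not curve.low <= x <= curve.high:
        warnings.warn(
            f"{curve.analyte}: concentration {x:g} outside validated range "
            f"[{curve.low:g}, {curve.high:g}] {curve.units}".strip(),
            stacklevel=2,
        )
    return x


def derived_traits(
    root_dw: float, shoot_dw: float, leaf_area: float, leaf_dw: float
) -> tuple[float, float]:
    """Root:shoot ratio and specific leaf area (cm^2 g^-1).

    root_shoot = root dry weight / shoot dry weight;
    SLA = leaf area / leaf dry weight.
    """
    if shoot_dw <= 0:
        raise ValueError(f"shoot dry weight must be positive, got {shoot_dw}")
    if leaf_dw <= 0:
        raise ValueError(f"leaf dry weight must be positive, got {leaf_dw}")
    return root_dw / shoot_dw, leaf_area / leaf_dw


def percent_change(reference: float, value: float, direction: str = "decrease") -> float:
    """Percent change of ``value`` relative to ``reference``.

    ``decrease`` -> 100*(reference-value)/reference (positive when the value
    dropped); ``increase`` -> 100*(value-reference)/reference.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    pct = 100.0 * (value - reference) / reference
    return -pct if direction == "decrease" else pct


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting style)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class CorrelationMatrix:
    """Square table of Pearson coefficients plus any constant-column flags."""

    table: pd.DataFrame
    constant_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.table.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation table must be square")
        finite = np.isfinite(arr)
        if not np.allclose(arr[finite & finite.T], arr.T[finite & finite.T], atol=1e-12):
            raise ValueError("correlation table must be symmetric")


def pearson_matrix(panel: IndicatorPanel) -> CorrelationMatrix:
    """Pairwise Pearson correlations over all replicates of all treatments.

    Uses sample (n-1) covariance. Constant columns yield undefined (NaN)
    coefficients and are reported in ``constant_columns``.
    """
    values = panel.values()
    if len(values) < 3:
        raise InsufficientDataError(
            f"need at least 3 rows for correlations, got {len(values)}"
        )
    constant = tuple(c for c in values.columns if values[c].nunique() <= 1)
    if constant:
        warnings.warn(f"constant columns (undefined correlations): {constant}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 on constant columns
        corr = values.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(corr, constant)
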