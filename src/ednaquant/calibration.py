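"""Standard-curve calibration and copy-number conversions.

A qPCR standard curve is the least-squares line of quantification cycle (Cq)
against log10 template copies fitted to a serial-dilution series:

    Cq = intercept + slope * log10(copies)

The slope determines the amplification efficiency
``E = (10**(-1/slope) - 1) * 100`` (percent); a perfect per-cycle doubling
gives slope -1/log10(2) ~ -3.32 and E = 100. Unknowns are back-calculated by
inverting the line: ``copies = 10**((cq - intercept) / slope)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .records import CalibrationError

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol.
DSDNA_BP_GRAMS_PER_MOL = 660.0

#: Efficiency window considered acceptable for a quantitative assay (percent).
EFFICIENCY_RANGE = (90.0, 110.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq-vs-log10(copies) calibration line."""

    slope: float  # cycles per log10(copies); negative
    intercept: float  # cycles at 1 copy
    r_squared: float
    efficiency_pct: float
    n_points: int
    copies_range: tuple[float, float] = (0.0, np.inf)  # span of the standards
    warnings: tuple[str, ...] = ()

    @property
    def efficiency_in_range(self) -> bool:
        lo, hi = EFFICIENCY_RANGE
        return lo <= self.efficiency_pct <= hi

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency_pct": self.efficiency_pct,
            "n_points": self.n_points,
            "copies_range": list(self.copies_range),
            "warnings": list(self.warnings),
        }


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from the calibration slope.

    Raises for a non-negative slope, which cannot arise from amplification.
    """
    if slope >= 0:
        raise CalibrationError(f"standard-curve slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def cq_to_copies(cq, curve: StandardCurve):
    """Back-calculate template copies per reaction from a Cq value.

    Accepts scalars or arrays; strictly decreasing in ``cq``. Extrapolation
    outside the standards' range is permitted (use
    :func:`is_extrapolated` to flag it).
    """
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def copies_to_cq(copies, curve: StandardCurve):
    """Predicted Cq for a known number of template copies (inverse of
    :func:`cq_to_copies`)."""
    return curve.intercept + curve.slope * np.log10(np.asarray(copies, dtype=float))


def is_extrapolated(copies, curve: StandardCurve):
    """True where a back-calculated copy number lies outside the standards."""
    q = np.asarray(copies, dtype=float)
    lo, hi = curve.copies_range
    return (q < lo) | (q > hi)


def ng_to_copies(mass_ng: float, construct_length_bp: float) -> float:
    """Convert a double-stranded DNA mass to molecule copies.

    ``copies = mass[g] * N_A / (length * 660 g/mol/bp)``. The construct
    length is the full plasmid-plus-insert length in base pairs.
    """
    if construct_length_bp <= 0:
        raise ValueError("construct length must be positive")
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng * 1e-9 * AVOGADRO / (construct_length_bp * DSDNA_BP_GRAMS_PER_MOL)


class StandardCurveRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares calibration of Cq on log10 copies.

    Parameters
    ----------
    efficiency_range : tuple of float
        Acceptance window for the amplification efficiency in percent;
        a fit outside it is flagged (warning, not error).
    min_levels : int
        Minimum number of distinct standard concentrations required.

    Attributes
    ----------
    slope_, intercept_ : float
        Calibration line coefficients (cycles per log10 copies; cycles).
    r_squared_ : float
    efficiency_pct_ : float
    n_points_ : int
        Number of detected standard wells used in the fit.
    copies_range_ : tuple of float
        (lowest, highest) standard concentration in the fit.
    warnings_ : list of str
    """

    def __init__(
        self,
        efficiency_range: tuple[float, float] = EFFICIENCY_RANGE,
        min_levels: int = 3,
    ):
        self.efficiency_range = efficiency_range
        self.min_levels = min_levels

    def fit(self, X, y):
        """Fit the line from standard concentrations and their Cq values.

        Parameters
        ----------
        X : array-like, shape (n_wells,) or (n_wells, 1)
            Known copies per reaction of each detected standard well.
        y : array-like, shape (n_wells,)
            Measured Cq of each well.
        """
        copies = np.asarray(X, dtype=float).reshape(-1)
        cq = np.asarray(y, dtype=float).reshape(-1)
        if copies.shape != cq.shape:
            raise ValueError("X and y must have the same length")
        mask = np.isfinite(cq) & np.isfinite(copies)
        copies, cq = copies[mask], cq[mask]
        if copies.size == 0:
            raise CalibrationError("no detected standard wells to fit")
        if np.any(copies <= 0):
            raise CalibrationError("standard copies must be positive")
        levels = np.unique(copies)
        if levels.size < self.min_levels:
            raise CalibrationError(
                f"need >= {self.min_levels} distinct standard concentrations, "
                f"got {levels.size}"
            )
        res = stats.linregress(np.log10(copies), cq)
        if res.slope >= 0:
            raise CalibrationError(
                f"fitted slope {res.slope:.4g} is non-negative; "
                "dilution series does not show amplification"
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.efficiency_pct_ = efficiency_from_slope(self.slope_)
        self.n_points_ = int(copies.size)
        self.copies_range_ = (float(levels.min()), float(levels.max()))
        self.warnings_: list[str] = []
        lo, hi = self.efficiency_range
        if not (lo <= self.efficiency_pct_ <= hi):
            msg = (
                f"amplification efficiency {self.efficiency_pct_:.2f}% outside "
                f"the accepted [{lo:g}, {hi:g}]% range"
            )
            self.warnings_.append(msg)
            warnings.warn(msg)
        return self

    def predict(self, X):
        """Predicted Cq for copy numbers ``X``."""
        return self.intercept_ + self.slope_ * np.log10(
            np.asarray(X, dtype=float).reshape(-1)
        )

    def predict_copies(self, cq):
        """Back-calculated copies per reaction for Cq values."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept_) / self.slope_)

    def to_curve(self) -> StandardCurve:
        """Freeze the fitted state into an immutable :class:`StandardCurve`."""
        return StandardCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            efficiency_pct=self.efficiency_pct_,
            n_points=self.n_points_,
            copies_range=self.copies_range_,
            warnings=tuple(self.warnings_),
        )


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Fit a standard curve from the ``standard`` rows of a plate table.

    Non-detect wells (missing Cq) are excluded from the fit; at least three
    distinct concentrations with at least one detected well each are
    required.
    """
    df = standards
    if "reaction_type" in df.columns:
        df = df[df["reaction_type"] == "standard"]
    if df.empty:
        raise CalibrationError("no standard wells in input")
    est = StandardCurveRegressor()
    est.fit(df["known_copies"].to_numpy(float), df["cq"].to_numpy(float))
    return est.to_curve()
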