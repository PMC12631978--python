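"""Concentration estimation for target and non-target compounds.

Target compounds are quantified by external calibration with
internal-standard (IS) corrected peak areas: the raw area is scaled by
the ratio of the IS reference area to the observed IS area, then mapped
through a linear calibration curve. Results above the highest standard
are right-censored (">top") because accuracy beyond the calibrated
range cannot be guaranteed; results below the lowest standard are
reported with a warning.

Annotated non-target compounds lack reference standards and are
*semiquantified*: a linear model in log space relates predicted
ionization efficiency (logIE) to response factor (logRF) across a set
of calibrant compounds; a candidate's predicted logIE then yields its
RF, and concentration = corrected area / RF. Semiquantified results
carry medium confidence; standard-based results carry high confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._errors import BelowRangeWarning, CalibrationError, HtedaError

__all__ = [
    "Location",
    "Quantification",
    "CalibrationCurve",
    "SemiquantModel",
    "SemiquantResults",
    "is_correct",
    "quantify_target",
    "fit_semiquant_model",
    "semiquantify",
]

# A measurement location: the unfractionated extract or one fraction.
Location = Union[Literal["unfractionated_extract"], int]


@dataclass(frozen=True)
class Quantification:
    """A concentration estimate with provenance and confidence."""

    compound: str
    concentration: float  # ug/L
    location: Location = "unfractionated_extract"
    confidence: Literal["high", "medium"] = "high"
    censor: Literal["none", "above_range"] = "none"
    below_range: bool = False

    def __str__(self) -> str:
        mark = ">" if self.censor == "above_range" else ""
        return f"{self.compound}@{self.location}: {mark}{self.concentration:g} ug/L"


def is_correct(area: float, is_area: float, is_area_ref: float) -> float:
    """Internal-standard correction of a raw peak area.

    Scales the area by ``is_area_ref / is_area`` so instrumental
    fluctuations tracked by the labelled internal standard cancel.
    """
    if is_area <= 0 or is_area_ref <= 0:
        raise HtedaError(
            f"internal-standard areas must be positive, got "
            f"({is_area}, {is_area_ref})"
        )
    return area * is_area_ref / is_area


@dataclass
class CalibrationCurve:
    """Linear external calibration for one compound.

    ``points`` holds (nominal concentration ug/L, IS-corrected area)
    pairs; the fit is unweighted OLS ``area = slope*conc + intercept``
    (1/x weighting available via ``weighting="1/x"``).
    """

    compound: str
    points: pd.DataFrame  # columns nominal_ug_per_L, area
    slope: float = field(init=False)
    intercept: float = field(init=False)
    weighting: str = "none"

    def __post_init__(self) -> None:
        need = {"nominal_ug_per_L", "area"}
        if not need <= set(self.points.columns):
            raise HtedaError(f"calibration points need columns {sorted(need)}")
        if len(self.points) < 2:
            raise CalibrationError(
                f"{self.compound}: >= 2 calibration points required"
            )
        x = self.points["nominal_ug_per_L"].to_numpy(float)
        y = self.points["area"].to_numpy(float)
        if self.weighting == "1/x":
            w = 1.0 / np.clip(x, x[x > 0].min(), None)
            res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        else:
            res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept, self.slope = (float(v) for v in res.params)
        self._ols = res
        if self.slope <= 0:
            raise CalibrationError(
                f"{self.compound}: non-positive calibration slope"
            )

    @property
    def valid_range(self) -> tuple[float, float]:
        x = self.points["nominal_ug_per_L"]
        return float(x.min()), float(x.max())

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def quantify_target(
    corrected_area: float,
    curve: CalibrationCurve,
    *,
    location: Location = "unfractionated_extract",
) -> Quantification:
    """Invert the calibration curve for an IS-corrected area.

    Above the highest standard the result is right-censored at the top
    of the calibrated range; below the lowest standard it is reported
    as-is with a :class:`BelowRangeWarning` (extrapolation).
    """
    conc = (corrected_area - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if conc > hi:
        return Quantification(
            compound=curve.compound,
            concentration=hi,
            location=location,
            confidence="high",
            censor="above_range",
        )
    below = conc < lo
    if below:
        warnings.warn(
            f"{curve.compound}: result {conc:.3g} ug/L below the lowest "
            f"standard ({lo:g} ug/L); extrapolated",
            BelowRangeWarning,
            stacklevel=2,
        )
    return Quantification(
        compound=curve.compound,
        concentration=float(max(conc, 0.0)),
        location=location,
        confidence="high",
        below_range=bool(below),
    )


class SemiquantModel:
    """Ionization-efficiency based response-factor model.

    Fits ``logRF = slope * logIE + intercept`` by OLS over calibrant
    compounds with known response factors and predicted ionization
    efficiencies. Accuracy is order-of-magnitude by design: the model
    transfers response behaviour across compounds without standards.
    """

    def __init__(self, calibrants: pd.DataFrame):
        need = {"logIE", "logRF"}
        if not need <= set(calibrants.columns):
            raise HtedaError(f"calibrant table needs columns {sorted(need)}")
        if len(calibrants) < 3:
            raise CalibrationError(">= 3 calibrants required")
        if np.ptp(calibrants["logIE"].to_numpy(float)) == 0:
            raise CalibrationError("degenerate calibrant set: all logIE equal")
        self.calibrants = calibrants.reset_index(drop=True)

    def fit(self) -> "SemiquantResults":
        x = self.calibrants["logIE"].to_numpy(float)
        y = self.calibrants["logRF"].to_numpy(float)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = (float(v) for v in res.params)
        return SemiquantResults(
            slope=slope, intercept=intercept, model=self, ols=res
        )


@dataclass
class SemiquantResults:
    slope: float
    intercept: float
    model: SemiquantModel
    ols: object = field(repr=False, default=None)

    def log_rf(self, logIE: float) -> float:
        return self.slope * logIE + self.intercept

    def response_factor(self, logIE: float) -> float:
        return float(10.0 ** self.log_rf(logIE))

    def summary(self) -> str:
        lines = [
            "Semiquantification model  logRF = slope*logIE + intercept",
            f"slope:     {self.slope:.4g}",
            f"intercept: {self.intercept:.4g}",
            f"n calibrants: {len(self.model.calibrants)}",
            f"R^2:       {self.ols.rsquared:.3f}" if self.ols is not None else "",
        ]
        return "\n".join(l for l in lines if l)


def fit_semiquant_model(calibrants: pd.DataFrame) -> SemiquantResults:
    """Convenience wrapper: ``SemiquantModel(calibrants).fit()``."""
    return SemiquantModel(calibrants).fit()


def semiquantify(
    corrected_area: float,
    logIE: float,
    model: SemiquantResults,
    *,
    compound: str = "",
    location: Location = "unfractionated_extract",
) -> Quantification:
    """Estimate a concentration from predicted ionization efficiency.

    ``RF = 10**(slope*logIE + intercept)``; concentration =
    corrected area / RF. Confidence is medium (no reference standard).
    """
    rf = model.response_factor(logIE)
    return Quantification(
        compound=compound,
        concentration=float(corrected_area / rf),
        location=location,
        confidence="medium",
    )
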