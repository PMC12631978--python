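"""Concentration-response modelling for microplate bioassays.

Raw luminescence is normalized to the maximal response of the reference
agonist (e.g. dihydrotestosterone in an androgen-receptor reporter
assay), fitted to a four-parameter log-logistic curve against dose
(reference concentration in ng/L, or unitless relative enrichment
factor REF for sample extracts), and effect concentrations (EC10, EC50)
are extracted by closed-form inversion. Bioanalytical equivalent
concentrations (BEQ) follow as the ratio of reference EC to sample EC
at the same effect level.

The fitting API follows the Model/Results convention: build a
:class:`DoseResponseModel` from dose/response arrays, call ``fit()``,
and read parameters, EC levels and a ``summary()`` off the returned
:class:`DoseResponseResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._errors import CalibrationError, FitFailureError, HtedaError

__all__ = [
    "normalize_to_reference",
    "DoseResponseModel",
    "DoseResponseResults",
    "EcEstimate",
    "BEQResult",
    "fit_sigmoid",
    "ec_at",
    "linear_range_ec10",
    "beq_from_ec",
]


def normalize_to_reference(
    raw: Sequence[Sequence[float]] | Sequence[float],
    reference_max: float,
    solvent_background: float,
) -> np.ndarray:
    """Normalize raw luminescence to percent of maximal reference response.

    ``raw`` is one replicate set per observation (a single flat sequence
    is treated as one replicate set). Replicates are averaged *before*
    normalization::

        response = 100 * (mean(raw) - background) / (ref_max - background)

    Raises
    ------
    CalibrationError
        If the reference maximum does not exceed the solvent background.
    """
    if reference_max <= solvent_background:
        raise CalibrationError(
            f"reference maximum ({reference_max}) must exceed solvent "
            f"background ({solvent_background})"
        )
    seq = list(raw)
    if seq and hasattr(seq[0], "__len__"):
        means = np.array([np.mean(np.asarray(r, dtype=float)) for r in seq])
    else:
        means = np.asarray(seq, dtype=float)
    return 100.0 * (means - solvent_background) / (reference_max - solvent_background)


def _loglogistic(dose, bottom, top, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, bottom, dtype=float)
    pos = dose > 0
    with np.errstate(over="ignore"):
        out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / dose[pos]) ** hill)
    return out


@dataclass(frozen=True)
class EcEstimate:
    """An effect concentration, possibly right-censored at the highest
    tested dose (the curve never reached the requested level)."""

    value: float
    level: float
    censored: bool = False

    def __str__(self) -> str:
        return f">{self.value:g}" if self.censored else f"{self.value:g}"


@dataclass(frozen=True)
class BEQResult:
    """Bioanalytical equivalent concentration of a sample.

    ``beq = ec_ref / ec_sample`` — the concentration of reference
    agonist (ng/L) producing the same effect as the sample at unit
    enrichment.
    """

    beq: float
    ec_level: float
    ec_ref: float
    ec_sample: float


def beq_from_ec(ec_ref: float, ec_sample: float, ec_level: float = 10.0) -> BEQResult:
    """BEQ from matched-level effect concentrations.

    ``ec_ref`` is the reference-agonist EC (ng/L); ``ec_sample`` the
    sample EC expressed as REF (unitless enrichment). The result is in
    ng reference-equivalents per litre of original sample.
    """
    if ec_ref <= 0 or ec_sample <= 0:
        raise HtedaError(
            f"EC values must be positive, got ec_ref={ec_ref}, "
            f"ec_sample={ec_sample}"
        )
    return BEQResult(
        beq=ec_ref / ec_sample, ec_level=ec_level, ec_ref=ec_ref, ec_sample=ec_sample
    )


class DoseResponseModel:
    """Four-parameter log-logistic dose-response model.

    Parameters
    ----------
    dose, response
        Dose (REF or ng/L, >= 0) and percent response arrays.
    bottom
        Fixed lower asymptote (default 0: responses are
        background-subtracted percentages). Pass ``None`` to free it.
    suppression_drop
        Points whose response falls more than this many percent below
        the running maximum observed at a *lower* dose are treated as
        high-dose suppression (cytotoxicity) and excluded from the fit.
    dose_unit
        Recorded on the results for reporting ("REF" or "ng_per_L").
    """

    def __init__(
        self,
        dose: Sequence[float],
        response: Sequence[float],
        *,
        bottom: Optional[float] = 0.0,
        suppression_drop: float = 20.0,
        dose_unit: str = "REF",
        min_signal: float = 5.0,
    ):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape or self.dose.ndim != 1:
            raise HtedaError("dose and response must be 1-D arrays of equal length")
        if np.any(self.dose < 0):
            raise HtedaError("doses must be non-negative")
        self.bottom = bottom
        self.suppression_drop = float(suppression_drop)
        self.dose_unit = dose_unit
        self.min_signal = float(min_signal)

    def _suppression_mask(self) -> np.ndarray:
        """True for points kept; high-dose suppressed points are False."""
        order = np.argsort(self.dose, kind="stable")
        keep = np.ones(self.dose.size, dtype=bool)
        run_max = -np.inf
        for i in order:
            if self.response[i] < run_max - self.suppression_drop:
                keep[i] = False
            else:
                run_max = max(run_max, self.response[i])
        return keep

    def fit(self) -> "DoseResponseResults":
        keep = self._suppression_mask()
        d, r = self.dose[keep], self.response[keep]
        nz = d[d > 0]
        if d.size < 4 or np.unique(nz).size < 2:
            raise FitFailureError(
                "need >= 4 points with >= 2 distinct nonzero doses",
                {"n_points": int(d.size), "n_nonzero_doses": int(np.unique(nz).size)},
            )
        if r.max() < self.min_signal:
            raise FitFailureError(
                f"maximal response {r.max():.2f}% below {self.min_signal}%: "
                "no information on the effect concentration",
                {"max_response": float(r.max())},
            )

        b_fixed = self.bottom
        lo_d, hi_d = np.log10(nz.min()), np.log10(nz.max())
        top0 = max(float(r.max()), 10.0)
        # dose nearest half-maximal response as EC50 start
        half = (top0 + (b_fixed if b_fixed is not None else float(r.min()))) / 2.0
        i0 = int(np.argmin(np.abs(r - half)))
        ec50_0 = float(d[i0]) if d[i0] > 0 else float(10 ** ((lo_d + hi_d) / 2))
        p0 = [top0, np.log10(ec50_0), 1.0]
        bounds_lo = [1e-6, lo_d - 4.0, 0.05]
        bounds_hi = [500.0, hi_d + 4.0, 20.0]

        if b_fixed is None:
            def f(dd, bottom, top, lec50, hill):
                return _loglogistic(dd, bottom, top, 10.0 ** lec50, hill)

            p0 = [float(r.min())] + p0
            bounds = ([-100.0] + bounds_lo, [100.0] + bounds_hi)
        else:
            def f(dd, top, lec50, hill):
                return _loglogistic(dd, b_fixed, top, 10.0 ** lec50, hill)

            bounds = (bounds_lo, bounds_hi)

        try:
            popt, pcov = curve_fit(
                f, d, r, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            raise FitFailureError(f"sigmoid fit did not converge: {exc}") from exc

        if b_fixed is None:
            bottom, top, lec50, hill = popt
        else:
            bottom = b_fixed
            top, lec50, hill = popt
        resid = r - _loglogistic(d, bottom, top, 10.0 ** lec50, hill)
        return DoseResponseResults(
            bottom=float(bottom),
            top=float(top),
            ec50=float(10.0 ** lec50),
            hill=float(hill),
            dose_unit=self.dose_unit,
            method="sigmoid_fit",
            model=self,
            used_mask=keep,
            residuals=resid,
            cov=pcov,
        )


@dataclass
class DoseResponseResults:
    """Fitted dose-response curve with EC extraction and reporting."""

    bottom: float
    top: float
    ec50: float
    hill: float
    dose_unit: str
    method: Literal["sigmoid_fit", "linear_range"]
    model: Optional[DoseResponseModel] = None
    used_mask: Optional[np.ndarray] = None
    residuals: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None
    # linear-range coefficients (response = slope*dose + intercept)
    slope: Optional[float] = None
    intercept: Optional[float] = None
    _extra: dict = field(default_factory=dict)

    @property
    def points_used(self) -> Optional[np.ndarray]:
        if self.model is None or self.used_mask is None:
            return None
        return np.column_stack(
            [self.model.dose[self.used_mask], self.model.response[self.used_mask]]
        )

    @property
    def excluded_points(self) -> Optional[np.ndarray]:
        if self.model is None or self.used_mask is None:
            return None
        m = ~self.used_mask
        return np.column_stack([self.model.dose[m], self.model.response[m]])

    def predict(self, dose) -> np.ndarray:
        if self.method == "linear_range":
            return self.slope * np.asarray(dose, dtype=float) + self.intercept
        return _loglogistic(dose, self.bottom, self.top, self.ec50, self.hill)

    def ec(self, level: float) -> float:
        """Closed-form effect concentration at ``level`` percent response.

        For the log-logistic curve::

            dose = ec50 * ((top - bottom)/(level - bottom) - 1) ** (-1/hill)

        Raises outside the open interval (bottom, top).
        """
        if self.method == "linear_range":
            return (level - self.intercept) / self.slope
        if not (self.bottom < level < self.top):
            raise HtedaError(
                f"effect level {level} outside the fitted response range "
                f"({self.bottom:.3g}, {self.top:.3g})"
            )
        return self.ec50 * ((self.top - self.bottom) / (level - self.bottom) - 1.0) ** (
            -1.0 / self.hill
        )

    def ec_estimate(self, level: float) -> EcEstimate:
        """EC at ``level``, right-censored at the highest tested dose when
        the response never reaches the level in the tested range."""
        max_dose = (
            float(np.max(self.model.dose)) if self.model is not None else np.inf
        )
        observed_max = (
            float(np.max(self.model.response)) if self.model is not None else self.top
        )
        attainable = max(observed_max, float(self.predict([max_dose])[0]))
        if level >= min(attainable, self.top):
            return EcEstimate(value=max_dose, level=level, censored=True)
        return EcEstimate(value=self.ec(level), level=level, censored=False)

    def summary(self) -> str:
        lines = [
            "Dose-response fit",
            "=================",
            f"method:      {self.method}",
            f"dose unit:   {self.dose_unit}",
        ]
        if self.method == "sigmoid_fit":
            lines += [
                f"bottom:      {self.bottom:.4g}",
                f"top:         {self.top:.4g}",
                f"ec50:        {self.ec50:.4g}",
                f"hill:        {self.hill:.4g}",
            ]
        else:
            lines += [
                f"slope:       {self.slope:.4g}",
                f"intercept:   {self.intercept:.4g}",
            ]
        if self.used_mask is not None:
            lines.append(
                f"points used: {int(self.used_mask.sum())}/{self.used_mask.size}"
                f" (suppression-excluded: {int((~self.used_mask).sum())})"
            )
        try:
            ec10 = self.ec_estimate(10.0)
            lines.append(f"EC10:        {ec10}")
        except HtedaError:
            pass
        return "\n".join(lines)


def fit_sigmoid(
    dose: Sequence[float],
    response: Sequence[float],
    **kwargs,
) -> DoseResponseResults:
    """Convenience wrapper: ``DoseResponseModel(dose, response).fit()``."""
    return DoseResponseModel(dose, response, **kwargs).fit()


def ec_at(fit: DoseResponseResults, level: float) -> float:
    """Effect concentration at ``level`` percent (closed-form inversion)."""
    return fit.ec(level)


def linear_range_ec10(
    dose: Sequence[float],
    response: Sequence[float],
    *,
    ceiling: float = 30.0,
    level: float = 10.0,
    dose_unit: str = "REF",
) -> DoseResponseResults:
    """EC10 from the linear low-dose range of the response curve.

    Ordinary least squares ``response = a*dose + b`` on points with
    response below ``ceiling`` percent; the EC at ``level`` is
    ``(level - b)/a``. Used when high-dose suppression makes the full
    sigmoid unreliable.
    """
    import statsmodels.api as sm

    d = np.asarray(dose, dtype=float)
    r = np.asarray(response, dtype=float)
    m = r < ceiling
    if m.sum() < 3:
        raise FitFailureError(
            f"need >= 3 points below the {ceiling}% ceiling, got {int(m.sum())}"
        )
    res = sm.OLS(r[m], sm.add_constant(d[m])).fit()
    b, a = res.params
    if a <= 0:
        raise FitFailureError(f"non-positive slope ({a:.3g}): no activity")
    mask = m.copy()
    return DoseResponseResults(
        bottom=0.0,
        top=float(ceiling),
        ec50=np.nan,
        hill=np.nan,
        dose_unit=dose_unit,
        method="linear_range",
        model=DoseResponseModel(d, r, dose_unit=dose_unit),
        used_mask=mask,
        residuals=np.asarray(res.resid),
        slope=float(a),
        intercept=float(b),
        _extra={"ols": res},
    )
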