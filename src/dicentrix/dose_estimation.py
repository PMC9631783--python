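"""Dose estimation by calibration-curve inversion with confidence limits.

The point dose for an observed yield y solves C + alpha*D + beta*D^2 = y:

    D = (-alpha + sqrt(alpha^2 + 4*beta*(y - C))) / (2*beta),

falling back to (y - C)/alpha when beta = 0. Yields at or below the fitted
background C give a dose of 0 Gy flagged as truncated, the convention also
applied to samples with no dicentrics at all.

Confidence limits combine two error sources: Poisson counting error on the
observed dicentric count, and uncertainty in the calibration curve itself.
The default construction (Merkle's method, the standard recipe in
cytogenetic dosimetry) takes 83% exact Poisson limits on the yield and
intersects them with the 83% delta-method confidence envelope of the curve;
the two 83% components combine to approximately 95% overall confidence. The
lower dose limit solves "upper curve envelope = lower yield limit" and the
upper dose limit solves "lower curve envelope = upper yield limit". A
``poisson-only`` alternative uses 95% Poisson limits on the yield inverted
through the point curve, ignoring curve uncertainty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import CalibrationCurve, DoseEstimate, SubjectSample, ValidationError

__all__ = [
    "YieldCI",
    "invert_curve",
    "poisson_yield_ci",
    "estimate_dose",
    "dose_correct",
    "mean_absolute_deviation",
]

#: Component confidence level whose two-sided combination gives ~95% overall.
MERKLE_COMPONENT_LEVEL = 0.83

#: Upper end of the dose bracket for root finding, Gy.
DOSE_SEARCH_MAX = 10.0

_ROOT_TOL = 1e-6


@dataclass(frozen=True)
class YieldCI:
    """Confidence limits on the expected dicentric yield (dicentrics/cell)."""

    y_low: float
    y_hat: float
    y_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.y_low <= self.y_hat <= self.y_high):
            raise ValidationError("require 0 <= y_low <= y_hat <= y_high")


def invert_curve(curve: CalibrationCurve, y: float) -> float:
    """Dose (Gy) whose expected yield equals ``y``; 0 when y <= background."""
    if not math.isfinite(y):
        raise ValidationError("yield must be finite")
    if y <= curve.c:
        return 0.0
    if curve.beta > 0:
        disc = curve.alpha**2 + 4.0 * curve.beta * (y - curve.c)
        return (-curve.alpha + math.sqrt(disc)) / (2.0 * curve.beta)
    if curve.alpha > 0:
        return (y - curve.c) / curve.alpha
    raise ValidationError("curve with alpha = beta = 0 cannot be inverted")


def poisson_yield_ci(dicentrics: int, cells: int, level: float = 0.95) -> YieldCI:
    """Exact (Garwood) Poisson limits on the expected count, per cell.

    For X observed events the two-sided limits on the Poisson mean are
    chi2(alpha/2, 2X)/2 and chi2(1 - alpha/2, 2X + 2)/2; the lower limit is
    0 when X = 0. Dividing by the number of cells gives yield limits.
    """
    if cells < 1:
        raise ValidationError("cells must be >= 1")
    if dicentrics < 0:
        raise ValidationError("dicentrics must be >= 0")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    alpha = 1.0 - level
    x = dicentrics
    low = 0.0 if x == 0 else stats.chi2.ppf(alpha / 2.0, 2 * x) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * x + 2) / 2.0
    return YieldCI(low / cells, x / cells, high / cells)


def _solve_dose(f, lo: float, hi: float) -> float:
    """Root of monotone f on [lo, hi] by Brent's method."""
    return float(optimize.brentq(f, lo, hi, xtol=_ROOT_TOL))


def estimate_dose(
    curve: CalibrationCurve,
    sample: SubjectSample,
    level: float = 0.95,
    ci_method: str = "merkle",
    dose_max: float = DOSE_SEARCH_MAX,
) -> DoseEstimate:
    """Estimate the absorbed dose for one scored sample.

    Parameters
    ----------
    curve : CalibrationCurve
        Calibration curve; needs uncertainty information for the Merkle
        construction (otherwise falls back to Poisson-only limits with a
        warning).
    sample : SubjectSample
        Cells scored and dicentrics observed.
    level : float
        Overall confidence level; 0.95 maps onto 83% components in the
        Merkle construction.
    ci_method : {"merkle", "poisson-only"}
    dose_max : float
        Upper end of the bracket used when solving for the dose limits.
    """
    if ci_method not in ("merkle", "poisson-only"):
        raise ValidationError("ci_method must be 'merkle' or 'poisson-only'")
    if ci_method == "merkle" and not curve.has_uncertainty:
        warnings.warn(
            f"curve {curve.label!r} has no uncertainty; using Poisson-only limits",
            stacklevel=2,
        )
        ci_method = "poisson-only"

    y_obs = sample.dicentric_yield
    dose = float(invert_curve(curve, y_obs))
    truncated = bool(sample.dicentrics == 0 or dose == 0.0)
    dose = 0.0 if truncated else dose

    if ci_method == "poisson-only":
        yci = poisson_yield_ci(sample.dicentrics, sample.cells, level=level)
        ci_low = float(invert_curve(curve, yci.y_low))
        ci_high = float(invert_curve(curve, yci.y_high))
        return DoseEstimate(dose, min(ci_low, dose), max(ci_high, dose), truncated, sample.sample_id)

    component = MERKLE_COMPONENT_LEVEL if abs(level - 0.95) < 1e-9 else level
    yci = poisson_yield_ci(sample.dicentrics, sample.cells, level=component)
    z = stats.norm.ppf(0.5 + component / 2.0)

    def upper_envelope(d):
        return curve.evaluate(d) + z * curve.yield_standard_error(d)

    def lower_envelope(d):
        return curve.evaluate(d) - z * curve.yield_standard_error(d)

    # lower dose limit: where the UPPER envelope reaches the LOWER yield limit
    if upper_envelope(0.0) >= yci.y_low:
        ci_low = 0.0
    else:
        ci_low = _solve_dose(lambda d: upper_envelope(d) - yci.y_low, 0.0, dose_max)

    # upper dose limit: where the LOWER envelope reaches the UPPER yield limit
    if lower_envelope(dose_max) < yci.y_high:
        raise ValidationError(
            f"upper dose limit exceeds the {dose_max} Gy search range; "
            "raise dose_max or recalibrate"
        )
    if lower_envelope(0.0) >= yci.y_high:
        ci_high = 0.0
    else:
        ci_high = _solve_dose(lambda d: lower_envelope(d) - yci.y_high, 0.0, dose_max)

    ci_low = min(ci_low, dose)
    ci_high = max(ci_high, dose)
    return DoseEstimate(dose, ci_low, ci_high, truncated, sample.sample_id)


def dose_correct(
    estimate: DoseEstimate, delivered: float, tolerance_gy: float = 0.5
) -> bool:
    """Triage correctness rule for a known delivered dose.

    An estimate is correct when the delivered dose falls inside its 95% CI,
    or the point estimate is within ``tolerance_gy`` (default 0.5 Gy) of the
    delivered dose.
    """
    in_ci = estimate.ci_low <= delivered <= estimate.ci_high
    close = abs(estimate.dose - delivered) <= tolerance_gy
    return bool(in_ci or close)


def mean_absolute_deviation(
    estimates: Sequence[DoseEstimate], delivered: Sequence[float]
) -> float:
    """Mean |estimated - delivered| dose over paired samples, Gy."""
    if len(estimates) != len(delivered):
        raise ValidationError("estimates and delivered doses must pair up")
    if len(estimates) == 0:
        raise ValidationError("need at least one pair")
    return float(
        np.mean([abs(e.dose - d) for e, d in zip(estimates, delivered)])
    )
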