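"""Core domain types for dicentric chromosome assay (DCA) biodosimetry.

The dicentric chromosome assay scores metaphase spreads from peripheral-blood
lymphocytes for dicentric chromosomes, a radiation-specific aberration. The
types here carry the three kinds of record the analysis works with: per-dose
multiplicity histograms from calibration irradiations, per-subject scoring
totals, and fitted linear-quadratic calibration curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DicentricDistribution",
    "CalibrationCurve",
    "SubjectSample",
    "DoseEstimate",
    "ConfusionTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class DicentricDistribution:
    """Multiplicity histogram of dicentrics per cell at one dose point.

    Parameters
    ----------
    dose : float
        Absorbed dose in Gy (non-negative).
    cells : int
        Number of metaphases scored, ``N``.
    multiplicity : tuple of int
        ``multiplicity[k]`` is the number of cells containing exactly *k*
        dicentrics; the counts must sum to ``cells``.
    """

    dose: float
    cells: int
    multiplicity: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "multiplicity", tuple(int(m) for m in self.multiplicity))
        if self.dose < 0 or not math.isfinite(self.dose):
            raise ValidationError(f"dose must be a non-negative real, got {self.dose}")
        if self.cells < 1:
            raise ValidationError(f"cells must be >= 1, got {self.cells}")
        if any(m < 0 for m in self.multiplicity):
            raise ValidationError("multiplicity counts must be non-negative")
        if sum(self.multiplicity) != self.cells:
            raise ValidationError(
                f"multiplicity counts sum to {sum(self.multiplicity)} "
                f"but cells = {self.cells} (dose {self.dose} Gy)"
            )

    @property
    def total_dicentrics(self) -> int:
        """Total dicentrics scored, ``X = sum_k k * D_k``."""
        return int(sum(k * m for k, m in enumerate(self.multiplicity)))

    @property
    def dicentric_yield(self) -> float:
        """Dicentrics per cell, ``Y = X / N``."""
        return self.total_dicentrics / self.cells

    def per_cell_counts(self) -> np.ndarray:
        """Expand the histogram into the length-``N`` vector of per-cell counts."""
        return np.repeat(np.arange(len(self.multiplicity)), self.multiplicity)


@dataclass
class CalibrationCurve:
    """Linear-quadratic dose-response curve ``Y = C + alpha*D + beta*D**2``.

    ``C`` is the background yield (dicentrics/cell), ``alpha`` the linear
    coefficient (per Gy) and ``beta`` the quadratic coefficient (per Gy^2).
    Standard errors and, optionally, the full 3x3 coefficient covariance are
    carried so that confidence envelopes on the curve can be propagated into
    dose uncertainties.
    """

    c: float
    alpha: float
    beta: float
    se_c: float | None = None
    se_alpha: float | None = None
    se_beta: float | None = None
    covariance: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.beta < 0 or self.c < 0:
            raise ValidationError("fitted coefficients C and beta must be non-negative")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise ValidationError("covariance must be 3x3")
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValidationError("covariance must be symmetric")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
                raise ValidationError("covariance must be positive semi-definite")
            self.covariance = cov

    @property
    def params(self) -> np.ndarray:
        return np.array([self.c, self.alpha, self.beta], dtype=float)

    @property
    def has_uncertainty(self) -> bool:
        return self.covariance is not None or None not in (
            self.se_c,
            self.se_alpha,
            self.se_beta,
        )

    def covariance_matrix(self) -> np.ndarray:
        """Coefficient covariance; falls back to a diagonal built from the SEs.

        Curves taken from the literature usually publish standard errors only;
        in that case the off-diagonal terms are assumed zero (with a warning),
        which is conservative for the low-dose region where C and alpha are
        negatively correlated in practice.
        """
        if self.covariance is not None:
            return self.covariance
        if not self.has_uncertainty:
            raise ValidationError(f"curve {self.label!r} carries no uncertainty")
        warnings.warn(
            f"curve {self.label!r} has standard errors but no covariance; "
            "assuming zero off-diagonal terms",
            stacklevel=2,
        )
        return np.diag(np.array([self.se_c, self.se_alpha, self.se_beta]) ** 2)

    def evaluate(self, dose) -> np.ndarray | float:
        """Expected dicentric yield at ``dose`` Gy."""
        dose = np.asarray(dose, dtype=float)
        out = self.c + self.alpha * dose + self.beta * dose**2
        return out if out.ndim else float(out)

    def yield_standard_error(self, dose) -> np.ndarray | float:
        """Delta-method SE of the fitted yield: sqrt(g' Sigma g), g = (1, D, D^2)."""
        cov = self.covariance_matrix()
        dose = np.asarray(dose, dtype=float)
        g = np.stack([np.ones_like(dose), dose, dose**2], axis=-1)
        var = np.einsum("...i,ij,...j->...", g, cov, g)
        if np.any(var < -1e-12):
            raise ValidationError("negative yield variance: covariance not PSD")
        out = np.sqrt(np.maximum(var, 0.0))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SubjectSample:
    """One scored individual or blind sample."""

    sample_id: str
    cells: int
    dicentrics: int
    delivered_dose: float | None = None
    method: str = "manual"

    _METHODS = ("manual", "semi_automated")

    def __post_init__(self) -> None:
        if self.cells < 1:
            raise ValidationError(f"sample {self.sample_id}: cells must be >= 1")
        if self.dicentrics < 0:
            raise ValidationError(f"sample {self.sample_id}: dicentrics must be >= 0")
        if self.method not in self._METHODS:
            raise ValidationError(
                f"sample {self.sample_id}: method must be one of {self._METHODS}"
            )

    @property
    def dicentric_yield(self) -> float:
        return self.dicentrics / self.cells


@dataclass(frozen=True)
class DoseEstimate:
    """Point dose estimate with 95% confidence limits.

    Samples with zero dicentrics, or whose yield falls below the calibration
    background, receive a dose of 0 Gy with ``truncated`` set.
    """

    dose: float
    ci_low: float
    ci_high: float
    truncated: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.dose + 1e-9 and self.dose <= self.ci_high + 1e-9):
            raise ValidationError(
                f"require 0 <= ci_low <= dose <= ci_high, got "
                f"({self.ci_low}, {self.dose}, {self.ci_high})"
            )
        if self.truncated and self.dose != 0:
            raise ValidationError("a truncated estimate must have dose == 0")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 contingency table.

    Laid out with agreement (or correct classification) on the diagonal:
    for triage classification ``a`` = true positive, ``b`` = false negative,
    ``c`` = false positive, ``d`` = true negative; for a two-method paired
    comparison ``a`` and ``d`` are the concordant cells and ``b``/``c`` the
    discordant ones.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.total < 1:
            raise ValidationError("contingency table must hold at least one pair")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def transpose(self) -> "ConfusionTable":
        """Swap the two raters/methods (rows and columns)."""
        return ConfusionTable(self.a, self.c, self.b, self.d)
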