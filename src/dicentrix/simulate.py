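"""Synthetic dicentric scoring: calibration datasets and subject cohorts.

The generator reproduces the count-level statistical structure of dicentric
scoring so that every stage of the pipeline can be exercised without real
slides. For a cell at dose D the true dicentric count is Poisson with mean
C + alpha*D + beta*D^2 from a generating curve. Scoring is then imperfect:

* each true dicentric is detected independently with probability
  ``detection_efficiency`` (binomial thinning; semi-automated scoring misses
  more dicentrics than a trained scorer);
* automated candidate detection adds false positives at
  ``fp_rate_per_cell`` per analyzed cell, of which a fraction
  ``fp_survival`` survives visual validation (0 after strict validation);
* a fraction ``rejection_rate`` of captured metaphases is rejected as
  unsuitable for automated analysis (about half in routine practice);
* scoring stops at ``stop_cells`` analyzed metaphases or ``stop_dicentrics``
  scored dicentrics, whichever comes first.

All randomness flows from an explicit seed through one numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datatypes import (
    CalibrationCurve,
    DicentricDistribution,
    SubjectSample,
    ValidationError,
)

__all__ = [
    "ScoringModel",
    "CohortSpec",
    "default_scoring_models",
    "simulate_distribution",
    "simulate_calibration_dataset",
    "simulate_paired_cohort",
]


@dataclass(frozen=True)
class ScoringModel:
    """Count-level model of one dicentric scoring method."""

    detection_efficiency: float = 1.0
    fp_rate_per_cell: float = 0.0
    fp_survival: float = 0.0
    rejection_rate: float = 0.0
    stop_cells: int = 1000
    stop_dicentrics: int = 100

    def __post_init__(self) -> None:
        for name in ("detection_efficiency", "fp_rate_per_cell", "fp_survival", "rejection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.stop_cells < 1 or self.stop_dicentrics < 1:
            raise ValidationError("stopping caps must be >= 1")

    @property
    def surviving_fp_rate(self) -> float:
        """Expected validated false positives per analyzed cell."""
        return self.fp_rate_per_cell * self.fp_survival


def default_scoring_models() -> tuple[ScoringModel, ScoringModel]:
    """Default (manual, semi_automated) scoring models.

    Manual scoring by trained scorers is treated as the reference: full
    detection, no false positives, no image rejection. Semi-automated
    scoring detects candidates automatically and keeps only those a scorer
    validates: detection efficiency 0.45 (chosen so binomial thinning of the
    manual linear coefficient approximates the semi-automated one in the
    1-2 Gy range; see the methods note for why one scalar cannot match both
    coefficients), 0.081 false positives per analyzed cell before validation
    none of which survive validation, and a 50% metaphase rejection rate.
    Both methods stop at 1,000 metaphases or 100 dicentrics.
    """
    manual = ScoringModel(
        detection_efficiency=1.0,
        fp_rate_per_cell=0.0,
        fp_survival=0.0,
        rejection_rate=0.0,
        stop_cells=1000,
        stop_dicentrics=100,
    )
    semi = ScoringModel(
        detection_efficiency=0.45,
        fp_rate_per_cell=0.081,
        fp_survival=0.0,
        rejection_rate=0.5,
        stop_cells=1000,
        stop_dicentrics=100,
    )
    return manual, semi


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a paired-scoring synthetic cohort.

    Each subject's true per-cell dicentric counts are shared between the two
    scoring methods, which then observe them through their own ScoringModel.
    ``captured_cells`` is the size of each subject's metaphase image pool
    before rejection and stopping.
    """

    true_doses: tuple[float, ...]
    curve: CalibrationCurve
    manual_scoring: ScoringModel = field(default_factory=lambda: default_scoring_models()[0])
    semi_scoring: ScoringModel = field(default_factory=lambda: default_scoring_models()[1])
    captured_cells: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_doses", tuple(float(d) for d in self.true_doses))
        if any(d < 0 for d in self.true_doses):
            raise ValidationError("true doses must be non-negative")
        if self.captured_cells < 1:
            raise ValidationError("captured_cells must be >= 1")


def _score_cells(
    true_counts: np.ndarray, scoring: ScoringModel, rng: np.random.Generator
) -> np.ndarray:
    """Observed counts for the analyzed cells after rejection, detection
    thinning, false positives and the stopping rule."""
    n = true_counts.size
    keep = rng.random(n) >= scoring.rejection_rate
    true_kept = true_counts[keep]
    if true_kept.size == 0:
        # degenerate pool: score the single least-rejectable cell anyway
        true_kept = true_counts[:1]
    observed = rng.binomial(true_kept, scoring.detection_efficiency)
    if scoring.surviving_fp_rate > 0:
        observed = observed + rng.poisson(scoring.surviving_fp_rate, size=observed.size)
    observed = observed[: scoring.stop_cells]
    cum = np.cumsum(observed)
    hit = np.nonzero(cum >= scoring.stop_dicentrics)[0]
    if hit.size:
        observed = observed[: hit[0] + 1]  # include the cell that crosses the cap
    return observed


def _histogram(observed: np.ndarray) -> tuple[int, ...]:
    return tuple(np.bincount(observed).tolist())


def simulate_distribution(
    dose: float,
    n_cells: int,
    curve: CalibrationCurve,
    scoring: ScoringModel | None = None,
    seed: int | np.random.Generator = 0,
) -> DicentricDistribution:
    """Simulate the multiplicity histogram of one dose point.

    ``n_cells`` is the captured metaphase pool; the returned distribution
    holds the analyzed cells left after rejection and the stopping rule.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    scoring = scoring if scoring is not None else ScoringModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y_true = float(curve.evaluate(dose))
    true_counts = rng.poisson(y_true, size=n_cells)
    observed = _score_cells(true_counts, scoring, rng)
    return DicentricDistribution(
        dose=dose, cells=observed.size, multiplicity=_histogram(observed)
    )


def simulate_calibration_dataset(
    doses: Sequence[float],
    cells_per_dose: Sequence[int],
    curve: CalibrationCurve,
    scoring: ScoringModel | None = None,
    seed: int = 0,
    apply_stopping: bool = False,
) -> list[DicentricDistribution]:
    """Simulate a full calibration design (one distribution per dose).

    Calibration scoring typically continues well past the triage stopping
    caps, so by default the caps are lifted and every non-rejected cell in
    the pool is scored.
    """
    if len(doses) != len(cells_per_dose):
        raise ValidationError("doses and cells_per_dose must pair up")
    scoring = scoring if scoring is not None else ScoringModel()
    if not apply_stopping:
        scoring = replace(
            scoring, stop_cells=int(max(cells_per_dose)), stop_dicentrics=10**9
        )
    rng = np.random.default_rng(seed)
    return [
        simulate_distribution(d, int(n), curve, scoring, seed=rng)
        for d, n in zip(doses, cells_per_dose)
    ]


def simulate_paired_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectSample], list[SubjectSample]]:
    """Simulate a cohort scored by both methods on shared true counts.

    For each subject a pool of true per-cell dicentric counts is drawn once
    from the generating curve, then scored independently under the manual
    and semi-automated ScoringModels (shared biology, independent scoring
    noise). Returns (manual_samples, semi_samples), paired by sample_id and
    carrying the true dose as ``delivered_dose``.
    """
    rng = np.random.default_rng(spec.seed)
    manual_out, semi_out = [], []
    for i, dose in enumerate(spec.true_doses):
        sid = f"S{i + 1:03d}"
        y_true = float(spec.curve.evaluate(dose))
        true_counts = rng.poisson(y_true, size=spec.captured_cells)
        for scoring, method, out in (
            (spec.manual_scoring, "manual", manual_out),
            (spec.semi_scoring, "semi_automated", semi_out),
        ):
            observed = _score_cells(true_counts, scoring, rng)
            out.append(
                SubjectSample(
                    sample_id=sid,
                    cells=observed.size,
                    dicentrics=int(observed.sum()),
                    delivered_dose=dose,
                    method=method,
                )
            )
    return manual_out, semi_out
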