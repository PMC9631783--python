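"""Poisson conformity testing for dicentric distributions.

Dose estimation from dicentric yields assumes the per-cell dicentric counts
after acute whole-body exposure are Poisson distributed. Conformity is
checked with the variance-to-mean (dispersion) index sigma^2/ybar and
Papworth's u statistic,

    u = (sigma^2/ybar - 1) * sqrt((N - 1) / (2 * (1 - 1/X))),

where N is the number of cells scored and X the total dicentrics. Under the
Poisson hypothesis u is approximately standard normal, so |u| < 1.96 at a
dose point is taken as conformity at the 5% level. The sample variance uses
the N-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import DicentricDistribution, ValidationError

__all__ = ["DispersionResult", "dispersion_index", "u_statistic", "poisson_conformity"]


@dataclass(frozen=True)
class DispersionResult:
    """Dispersion summary for one dicentric distribution.

    ``dispersion_index`` and ``u`` are NaN when undefined (no dicentrics
    scored, or fewer than two for u).
    """

    dose: float
    cells: int
    total_dicentrics: int
    mean_yield: float
    variance: float
    dispersion_index: float
    u: float

    @property
    def conforms(self) -> bool:
        """|u| < 1.96, i.e. no significant departure from Poisson at 5%."""
        return bool(abs(self.u) < 1.96) if math.isfinite(self.u) else True


def _moments(dist: DicentricDistribution) -> tuple[float, float]:
    """Mean and (N-1)-denominator variance of the per-cell dicentric counts."""
    counts = np.asarray(dist.multiplicity, dtype=float)
    k = np.arange(counts.size, dtype=float)
    n = dist.cells
    x = float(np.sum(k * counts))
    mean = x / n
    variance = (float(np.sum(k**2 * counts)) - x**2 / n) / (n - 1)
    return mean, variance


def dispersion_index(dist: DicentricDistribution) -> DispersionResult:
    """Variance-to-mean ratio and u statistic for one dose point.

    Requires at least two scored cells. A distribution with no dicentrics has
    an undefined index (0/0) and is reported with NaN rather than forced to a
    number.
    """
    if dist.cells < 2:
        raise ValidationError("dispersion index needs at least 2 cells")
    mean, variance = _moments(dist)
    x = dist.total_dicentrics
    di = variance / mean if mean > 0 else math.nan
    if x >= 2:
        u = (di - 1.0) * math.sqrt((dist.cells - 1) / (2.0 * (1.0 - 1.0 / x)))
    else:
        u = math.nan
    return DispersionResult(
        dose=dist.dose,
        cells=dist.cells,
        total_dicentrics=x,
        mean_yield=mean,
        variance=variance,
        dispersion_index=di,
        u=u,
    )


def u_statistic(dist: DicentricDistribution) -> float:
    """Papworth's u for one distribution (NaN when X < 2)."""
    return dispersion_index(dist).u


def poisson_conformity(
    dists: Sequence[DicentricDistribution], z_crit: float = 1.96
) -> pd.DataFrame:
    """Per-dose Poisson conformity table.

    Returns a DataFrame with one row per distribution (dose, cells, total
    dicentrics, yield, variance, dispersion index, u, conforms) and an
    ``overall_conforms`` entry in ``DataFrame.attrs`` that is True only when
    every defined |u| is below ``z_crit``.
    """
    if len(dists) == 0:
        raise ValidationError("poisson_conformity needs at least one distribution")
    rows = []
    for d in dists:
        r = dispersion_index(d)
        conforms = abs(r.u) < z_crit if math.isfinite(r.u) else True
        rows.append(
            {
                "dose": r.dose,
                "cells": r.cells,
                "dicentrics": r.total_dicentrics,
                "yield": r.mean_yield,
                "variance": r.variance,
                "dispersion_index": r.dispersion_index,
                "u": r.u,
                "conforms": conforms,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["z_crit"] = z_crit
    table.attrs["overall_conforms"] = bool(table["conforms"].all())
    return table
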