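"""Triage classification metrics and two-method agreement statistics.

Binary triage categories follow the clinical framework used in radiation
emergency response: "never vs. ever" exposed (threshold 0.1 Gy, to separate
the worried well from exposed individuals), <=0.1 vs. >0.1 Gy (detectable
deterministic/stochastic risk) and <=1.5 vs. >1.5 Gy (likely acute radiation
syndrome). Accuracy, sensitivity and specificity are reported in percent:

    accuracy    = (TP + TN) * 100 / total
    sensitivity = TP * 100 / (TP + FN)
    specificity = TN * 100 / (TN + FP)

Agreement between two scoring methods on paired samples is summarised with
Cohen's kappa, McNemar's test on the discordant cells (by default the
uncorrected chi-square (b-c)^2/(b+c)), and the Spearman rank correlation of
the paired dose estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import ConfusionTable, DoseEstimate, ValidationError

__all__ = [
    "TRIAGE_CATEGORIES",
    "TriageReport",
    "AgreementReport",
    "classify_binary",
    "confusion_table",
    "triage_metrics",
    "cohens_kappa",
    "mcnemar_test",
    "spearman_correlation",
    "compare_methods",
]

#: category name -> predicate marking the positive (exposed/high-dose) class.
TRIAGE_CATEGORIES = {
    "never_vs_ever": lambda dose: dose >= 0.1,
    "le0.1_vs_gt0.1": lambda dose: dose > 0.1,
    "le1.5_vs_gt1.5": lambda dose: dose > 1.5,
}


@dataclass(frozen=True)
class TriageReport:
    category: str
    table: ConfusionTable
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class AgreementReport:
    table: ConfusionTable
    kappa: float
    mcnemar_chi2: float
    mcnemar_p: float
    spearman_rho: float
    spearman_p: float
    threshold: float


def confusion_table(
    predicted_positive: Sequence[bool], true_positive: Sequence[bool]
) -> ConfusionTable:
    """Build the TP/FN/FP/TN table from paired binary labels."""
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(true_positive, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("label sequences must pair up")
    return ConfusionTable(
        a=int(np.sum(truth & pred)),
        b=int(np.sum(truth & ~pred)),
        c=int(np.sum(~truth & pred)),
        d=int(np.sum(~truth & ~pred)),
    )


def triage_metrics(table: ConfusionTable) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent; NaN on empty denominator."""
    tp, fn, fp, tn = table.a, table.b, table.c, table.d
    accuracy = (tp + tn) * 100.0 / table.total
    sensitivity = tp * 100.0 / (tp + fn) if tp + fn > 0 else math.nan
    specificity = tn * 100.0 / (tn + fp) if tn + fp > 0 else math.nan
    return accuracy, sensitivity, specificity


def classify_binary(
    estimates: Sequence[DoseEstimate],
    truth: Sequence[float],
    category: str,
) -> TriageReport:
    """Score point dose estimates against known doses for one triage category.

    Classification uses the point estimate only, not its confidence interval,
    matching how triage categories are assigned per sample in practice.
    """
    if category not in TRIAGE_CATEGORIES:
        raise ValidationError(
            f"category must be one of {sorted(TRIAGE_CATEGORIES)}, got {category!r}"
        )
    if len(estimates) != len(truth):
        raise ValidationError("estimates and truth must pair up")
    positive = TRIAGE_CATEGORIES[category]
    table = confusion_table(
        [positive(e.dose) for e in estimates], [positive(t) for t in truth]
    )
    acc, sens, spec = triage_metrics(table)
    return TriageReport(category, table, acc, sens, spec)


def cohens_kappa(table: ConfusionTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Observed agreement p_o is the diagonal fraction; expected agreement p_e
    comes from the marginal products. Returns NaN when p_e = 1 (both raters
    constant), where kappa is undefined.
    """
    n = table.total
    p_o = (table.a + table.d) / n
    row1, row2 = table.a + table.b, table.c + table.d
    col1, col2 = table.a + table.c, table.b + table.d
    p_e = (row1 * col1 + row2 * col2) / n**2
    if p_e == 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def mcnemar_test(table: ConfusionTable, variant: str = "chi2") -> tuple[float, float]:
    """McNemar's test of marginal homogeneity on the discordant cells.

    ``chi2`` (default): (b - c)^2 / (b + c), p from the chi-square(1) upper
    tail, no continuity correction. ``corrected``: (|b - c| - 1)^2 / (b + c).
    ``exact``: two-sided binomial test of b successes in b + c trials at 1/2
    (the chi2 value returned is then NaN). With no discordant pairs the test
    carries no information and p = 1 is returned.
    """
    b, c = table.b, table.c
    if b + c == 0:
        return 0.0, 1.0
    if variant == "chi2":
        chi2 = (b - c) ** 2 / (b + c)
    elif variant == "corrected":
        chi2 = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    elif variant == "exact":
        p = float(stats.binomtest(b, b + c, 0.5).pvalue)
        return math.nan, p
    else:
        raise ValidationError("variant must be 'chi2', 'corrected' or 'exact'")
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration (n <= 10).

    rho is an affine function of sum(rx * ry[perm]) for fixed mid-rank
    vectors, so only that inner product varies over permutations.
    """
    n = rx.size
    sx, sy = np.std(rx), np.std(ry)
    mx, my = np.mean(rx), np.mean(ry)
    count = 0
    total = 0
    obs = abs(rho_obs)
    for perm in itertools.permutations(range(n)):
        s = float(np.dot(rx, ry[list(perm)]))
        rho = (s / n - mx * my) / (sx * sy)
        if abs(rho) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with a two-sided p value.

    ``auto`` uses full permutation enumeration for n <= 10 and the
    t-approximation otherwise; ``exact`` and ``approx`` force one or the
    other. Constant input gives (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-d sequences")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method not in ("auto", "exact", "approx"):
        raise ValidationError("method must be 'auto', 'exact' or 'approx'")
    exact = method == "exact" or (method == "auto" and n <= 10)
    if exact:
        if n > 10:
            raise ValidationError("exact permutation p limited to n <= 10")
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def compare_methods(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    threshold: float = 0.1,
) -> AgreementReport:
    """Paired agreement of two scoring methods' dose estimates.

    Doses are dichotomised at ``threshold`` Gy (>= threshold counts as
    exposed) to form the paired contingency table for kappa and McNemar; the
    Spearman correlation uses the raw paired doses.
    """
    a = np.asarray(doses_a, dtype=float)
    b = np.asarray(doses_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("the two dose sequences must pair up")
    table = confusion_table(a >= threshold, b >= threshold)
    chi2, p_mcnemar = mcnemar_test(table)
    rho, p_rho = spearman_correlation(a, b, method="approx")
    return AgreementReport(
        table=table,
        kappa=cohens_kappa(table),
        mcnemar_chi2=chi2,
        mcnemar_p=p_mcnemar,
        spearman_rho=rho,
        spearman_p=p_rho,
        threshold=threshold,
    )
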