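"""Linear-quadratic calibration-curve fitting by Poisson maximum likelihood.

The standard acute low-LET dose-response model for dicentric yields is

    Y(D) = C + alpha * D + beta * D**2,

with C the background yield (dicentrics/cell), alpha the linear and beta the
quadratic coefficient. At dose point i with N_i cells scored, the total
dicentric count X_i is modelled as Poisson with mean N_i * Y(D_i): an
identity-link Poisson regression of aggregated counts with the cell numbers
as exposure. Aggregation per dose point is sufficient under the Poisson
assumption, so per-cell fitting would give the identical likelihood.

The model is fitted by Fisher scoring (Newton steps on the expected
information) with step-halving to keep every predicted mean positive and a
projection to the non-negative orthant, since negative yields and a negative
curvature are physically meaningless for this endpoint. Standard errors come
from the inverse information matrix, expected by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CalibrationCurve, DicentricDistribution, ValidationError

__all__ = [
    "DicentricCalibrationModel",
    "CalibrationResults",
    "GoodnessOfFit",
    "ConvergenceError",
    "fit_linear_quadratic",
    "coefficient_z_tests",
    "goodness_of_fit",
    "curve_confidence_band",
]

_PARAM_NAMES = ("C", "alpha", "beta")


class ConvergenceError(RuntimeError):
    """Fisher scoring failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: np.ndarray):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class GoodnessOfFit:
    statistic: float
    df: int
    pvalue: float
    kind: str


class DicentricCalibrationModel:
    """Identity-link Poisson model of aggregated dicentric counts.

    Parameters
    ----------
    dose : array-like of float
        Dose points in Gy.
    cells : array-like of int
        Metaphases scored at each dose (the Poisson exposure).
    dicentrics : array-like of int
        Total dicentrics at each dose.
    label : str
        Carried through to the fitted :class:`CalibrationCurve`.
    """

    def __init__(self, dose, cells, dicentrics, label: str = "fitted"):
        self.dose = np.asarray(dose, dtype=float)
        self.cells = np.asarray(cells, dtype=float)
        self.dicentrics = np.asarray(dicentrics, dtype=float)
        self.label = label
        if not (self.dose.shape == self.cells.shape == self.dicentrics.shape):
            raise ValidationError("dose, cells and dicentrics must have equal length")
        if self.dose.size < 4:
            raise ValidationError("need at least 4 dose points to fit C, alpha, beta")
        if np.unique(self.dose).size < 4:
            raise ValidationError("need at least 4 distinct dose points")
        if np.count_nonzero(self.dicentrics > 0) < 3:
            raise ValidationError("need positive dicentric counts at >= 3 doses")
        if np.any(self.cells < 1) or np.any(self.dicentrics < 0):
            raise ValidationError("cells must be >= 1 and dicentrics >= 0")
        # design gradient g_i = (1, D_i, D_i^2); mu_i = N_i * g_i . theta
        self._design = np.column_stack(
            [np.ones_like(self.dose), self.dose, self.dose**2]
        )

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_distributions(
        cls, dists: Sequence[DicentricDistribution], label: str = "fitted"
    ) -> "DicentricCalibrationModel":
        dists = sorted(dists, key=lambda d: d.dose)
        return cls(
            dose=[d.dose for d in dists],
            cells=[d.cells for d in dists],
            dicentrics=[d.total_dicentrics for d in dists],
            label=label,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose: str = "dose",
        cells: str = "cells",
        dicentrics: str = "dicentrics",
        label: str = "fitted",
    ) -> "DicentricCalibrationModel":
        return cls(df[dose].values, df[cells].values, df[dicentrics].values, label=label)

    # ---- likelihood ----------------------------------------------------
    def _mu(self, params: np.ndarray) -> np.ndarray:
        return self.cells * (self._design @ params)

    def loglike(self, params) -> float:
        """Poisson log-likelihood up to the data-only constant sum(log X_i!)."""
        mu = self._mu(np.asarray(params, dtype=float))
        if np.any(mu <= 0):
            return -np.inf
        return float(np.sum(self.dicentrics * np.log(mu) - mu))

    def score(self, params) -> np.ndarray:
        mu = self._mu(np.asarray(params, dtype=float))
        return (self._design * (self.cells * (self.dicentrics / mu - 1.0))[:, None]).sum(axis=0)

    def information(self, params, kind: str = "expected") -> np.ndarray:
        """Fisher information. ``expected`` uses E[X]=mu; ``observed`` uses -Hessian."""
        params = np.asarray(params, dtype=float)
        mu = self._mu(params)
        if kind == "expected":
            w = self.cells**2 / mu
        elif kind == "observed":
            w = self.cells**2 * self.dicentrics / mu**2
        else:
            raise ValueError("kind must be 'expected' or 'observed'")
        return (self._design * w[:, None]).T @ self._design

    def _start_params(self) -> np.ndarray:
        # weighted least squares on yields, clipped into the feasible orthant
        y = self.dicentrics / self.cells
        w = self.cells / np.maximum(y, 1.0 / self.cells)
        gw = self._design * np.sqrt(w)[:, None]
        theta, *_ = np.linalg.lstsq(gw, y * np.sqrt(w), rcond=None)
        theta = np.clip(theta, 0.0, None)
        floor = max(self.dicentrics.sum() / self.cells.sum(), 1e-8)
        if theta[0] <= 0:
            theta[0] = min(floor, 1e-4)
        if np.any(self._mu(theta) <= 0):
            theta = np.array([floor, 1e-3, 1e-3])
        return theta

    def fit(
        self,
        start_params=None,
        maxiter: int = 100,
        tol: float = 1e-10,
        information: str = "expected",
    ) -> "CalibrationResults":
        """Fisher scoring with step-halving and non-negativity projection.

        Convergence is declared when the relative change in log-likelihood
        falls below ``tol``. Raises :class:`ConvergenceError` (carrying the
        last iterate) if ``maxiter`` is exhausted.
        """
        theta = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self._start_params()
        )
        if np.any(self._mu(theta) <= 0):
            raise ValidationError("start_params give non-positive predicted means")
        ll = self.loglike(theta)
        niter = 0
        for niter in range(1, maxiter + 1):
            score = self.score(theta)
            # active-set: a coefficient pinned at 0 whose gradient points
            # outward stays fixed; Newton runs on the free coordinates only
            active = (theta <= 1e-12) & (score < 0)
            free = ~active
            if not free.any():
                break
            info = self.information(theta, kind="expected")
            step = np.zeros_like(theta)
            step[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
            # halve until the projected candidate is feasible and not worse
            t = 1.0
            for _ in range(60):
                cand = np.clip(theta + t * step, 0.0, None)
                ll_new = self.loglike(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-13:
                    break
                t /= 2.0
            else:
                raise ConvergenceError("step-halving failed to find an uphill step", theta)
            theta, ll_prev, ll = cand, ll, ll_new
            if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-300):
                break
        else:
            raise ConvergenceError(f"no convergence in {maxiter} iterations", theta)
        cov = np.linalg.inv(self.information(theta, kind=information))
        return CalibrationResults(self, theta, cov, niter=niter, information_kind=information)


class CalibrationResults:
    """Fitted linear-quadratic calibration curve.

    Attributes follow the conventions of regression results objects:
    ``params``, ``bse``, ``cov_params``, ``zvalues``, ``pvalues``,
    ``fittedvalues`` (expected dicentric counts per dose point), ``llf``.
    """

    def __init__(self, model, params, cov_params, niter=0, information_kind="expected"):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.niter = int(niter)
        self.information_kind = information_kind
        self.param_names = list(_PARAM_NAMES)

    # ---- estimates -----------------------------------------------------
    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        se = self.bse
        if np.any(se == 0):
            raise ValidationError("zero standard error; z statistic undefined")
        return self.params / se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def llf(self) -> float:
        return self.model.loglike(self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Expected dicentric counts N_i * Y(D_i)."""
        return self.model._mu(self.params)

    @property
    def curve(self) -> CalibrationCurve:
        se = self.bse
        return CalibrationCurve(
            c=self.params[0],
            alpha=self.params[1],
            beta=self.params[2],
            se_c=se[0],
            se_alpha=se[1],
            se_beta=se[2],
            covariance=self.cov_params,
            label=self.model.label,
        )

    def predict(self, dose) -> np.ndarray | float:
        """Fitted yield (dicentrics/cell) at ``dose`` Gy."""
        return self.curve.evaluate(dose)

    # ---- diagnostics ---------------------------------------------------
    def goodness_of_fit(self, kind: str = "pearson") -> GoodnessOfFit:
        """Chi-square goodness of fit on the dose points.

        ``pearson`` (default) is sum (X - mu)^2 / mu; ``deviance`` the
        residual Poisson deviance. df = dose points - 3 fitted coefficients.
        """
        obs = self.model.dicentrics
        mu = self.fittedvalues
        df = obs.size - 3
        if df < 1:
            raise ValidationError("goodness of fit needs more dose points than parameters")
        if kind == "pearson":
            chi2 = float(np.sum((obs - mu) ** 2 / mu))
        elif kind == "deviance":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(obs > 0, obs * np.log(obs / mu), 0.0)
            chi2 = float(2.0 * np.sum(term - (obs - mu)))
        else:
            raise ValueError("kind must be 'pearson' or 'deviance'")
        return GoodnessOfFit(chi2, df, float(stats.chi2.sf(chi2, df)), kind)

    def confidence_band(self, dose, level: float = 0.95):
        """Delta-method confidence band for the curve at ``dose`` Gy."""
        return curve_confidence_band(self.curve, dose, level)

    def estimate_dose(self, sample, level: float = 0.95, ci_method: str = "merkle"):
        """Invert the fitted curve for one scored sample (see dose_estimation)."""
        from .dose_estimation import estimate_dose

        return estimate_dose(self.curve, sample, level=level, ci_method=ci_method)

    # ---- presentation --------------------------------------------------
    def summary(self) -> str:
        gof = self.goodness_of_fit()
        lines = [
            "Linear-quadratic dicentric dose-response (Poisson ML, identity link)",
            f"label: {self.model.label}   dose points: {self.model.dose.size}   "
            f"iterations: {self.niter}   SEs: {self.information_kind} information",
            "",
            f"{'coef':>6} {'estimate':>12} {'std err':>12} {'z':>9} {'P>|z|':>10}",
        ]
        for name, est, se, z, p in zip(
            self.param_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(f"{name:>6} {est:>12.6g} {se:>12.3g} {z:>9.3f} {p:>10.3g}")
        lines += [
            "",
            f"goodness of fit ({gof.kind}): chi2 = {gof.statistic:.3f}, "
            f"df = {gof.df}, p = {gof.pvalue:.3f}",
            f"log-likelihood: {self.llf:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, dose_grid=None, level: float = 0.95, show_data: bool = True):
        """Plot the fitted curve, its confidence band and the observed yields."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if dose_grid is None:
            dose_grid = np.linspace(0, self.model.dose.max() * 1.05, 200)
        yhat = self.predict(dose_grid)
        lo, hi = self.confidence_band(dose_grid, level=level)
        ax.plot(dose_grid, yhat, label=f"{self.model.label} fit")
        ax.plot(dose_grid, lo, ":", color="grey")
        ax.plot(dose_grid, hi, ":", color="grey")
        if show_data:
            y = self.model.dicentrics / self.model.cells
            err = np.sqrt(np.maximum(self.model.dicentrics, 1)) / self.model.cells
            ax.errorbar(self.model.dose, y, yerr=err, fmt="o", color="k", ms=4)
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("dicentrics per cell")
        ax.legend()
        return ax


# ---- functional wrappers ----------------------------------------------


def fit_linear_quadratic(
    dists: Sequence[DicentricDistribution], label: str = "fitted", **fit_kwargs
) -> CalibrationResults:
    """Fit Y = C + alpha*D + beta*D^2 to per-dose dicentric distributions."""
    return DicentricCalibrationModel.from_distributions(dists, label=label).fit(**fit_kwargs)


def coefficient_z_tests(results: CalibrationResults) -> pd.DataFrame:
    """Wald z test per coefficient (z = estimate / SE, two-sided normal p)."""
    return pd.DataFrame(
        {
            "coef": results.param_names,
            "estimate": results.params,
            "se": results.bse,
            "z": results.zvalues,
            "pvalue": results.pvalues,
        }
    )


def goodness_of_fit(results: CalibrationResults, kind: str = "pearson") -> GoodnessOfFit:
    return results.goodness_of_fit(kind=kind)


def curve_confidence_band(curve: CalibrationCurve, dose, level: float = 0.95):
    """Pointwise delta-method band: Yhat +/- z * sqrt(g' Sigma g), g = (1, D, D^2)."""
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    yhat = curve.evaluate(dose)
    se = curve.yield_standard_error(dose)
    return yhat - z * se, yhat + z * se
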