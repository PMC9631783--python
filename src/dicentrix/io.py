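"""Delimited-text readers and writers for assay tables.

All files are comma-separated UTF-8 with a header row and "." decimals.
Thousands separators inside quoted numeric fields (as printed in many
cytogenetics reports) are stripped on read. Distribution tables use the
columns ``dose,cells,d0,d1,d2,...`` with an open-ended number of
multiplicity columns.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CalibrationCurve,
    DicentricDistribution,
    DoseEstimate,
    SubjectSample,
    ValidationError,
)

__all__ = [
    "read_distribution_table",
    "write_distribution_table",
    "read_sample_table",
    "write_sample_table",
    "read_curve_table",
    "write_curve_table",
    "read_dose_estimates",
    "write_dose_estimates",
]

_MULT_RE = re.compile(r"^d(\d+)$")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, comment="#", thousands=",", skip_blank_lines=True,
        float_precision="round_trip",
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_distribution_table(path) -> list[DicentricDistribution]:
    """Read per-dose dicentric multiplicity histograms.

    Returns the distributions sorted by dose. A row whose multiplicity counts
    do not sum to its cell count raises :class:`ValidationError` naming the
    offending row.
    """
    df = _read_csv(path)
    for col in ("dose", "cells"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    mult_cols = sorted(
        (c for c in df.columns if _MULT_RE.match(c)),
        key=lambda c: int(_MULT_RE.match(c).group(1)),
    )
    if not mult_cols:
        raise ValidationError(f"{path}: no multiplicity columns d0,d1,... found")
    ks = [int(_MULT_RE.match(c).group(1)) for c in mult_cols]
    if ks != list(range(len(ks))):
        raise ValidationError(f"{path}: multiplicity columns must be contiguous from d0")
    out = []
    for idx, row in df.iterrows():
        mult = tuple(int(row[c]) if pd.notna(row[c]) else 0 for c in mult_cols)
        try:
            out.append(
                DicentricDistribution(
                    dose=float(row["dose"]), cells=int(row["cells"]), multiplicity=mult
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}, row {idx + 1}: {err}") from err
    return sorted(out, key=lambda d: d.dose)


def write_distribution_table(dists: Sequence[DicentricDistribution], path) -> None:
    kmax = max(len(d.multiplicity) for d in dists) if dists else 1
    rows = []
    for d in dists:
        mult = list(d.multiplicity) + [0] * (kmax - len(d.multiplicity))
        rows.append({"dose": d.dose, "cells": d.cells, **{f"d{k}": m for k, m in enumerate(mult)}})
    cols = ["dose", "cells"] + [f"d{k}" for k in range(kmax)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_sample_table(path) -> list[SubjectSample]:
    """Read per-subject scoring totals.

    Columns: ``sample_id,cells,dicentrics[,delivered_dose][,method]``. The
    delivered dose is optional (unknown for field samples); duplicate sample
    ids are retained so the same subject may appear once per scoring method.
    """
    try:
        df = _read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty sample table", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty sample table", stacklevel=2)
        return []
    for col in ("sample_id", "cells", "dicentrics"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = []
    for idx, row in df.iterrows():
        delivered = row.get("delivered_dose")
        delivered = None if pd.isna(delivered) else float(delivered)
        method = row.get("method")
        method = "manual" if pd.isna(method) else str(method).strip()
        try:
            out.append(
                SubjectSample(
                    sample_id=str(row["sample_id"]),
                    cells=int(row["cells"]),
                    dicentrics=int(row["dicentrics"]),
                    delivered_dose=delivered,
                    method=method,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}, row {idx + 1}: {err}") from err
    return out


def write_sample_table(samples: Sequence[SubjectSample], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cells": s.cells,
            "dicentrics": s.dicentrics,
            "delivered_dose": s.delivered_dose,
            "method": s.method,
        }
        for s in samples
    ]
    cols = ["sample_id", "cells", "dicentrics", "delivered_dose", "method"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


_CURVE_COLS = [
    "label", "c", "se_c", "alpha", "se_alpha", "beta", "se_beta",
    "cov_c_alpha", "cov_c_beta", "cov_alpha_beta",
]


def read_curve_table(path) -> list[CalibrationCurve]:
    """Read calibration-curve coefficient files.

    Off-diagonal covariance columns are optional; when absent the covariance
    is left unset and downstream code assumes independent coefficients.
    """
    df = _read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            c=float(row["c"]),
            alpha=float(row["alpha"]),
            beta=float(row["beta"]),
            label=str(row.get("label", "")),
        )
        for k in ("se_c", "se_alpha", "se_beta"):
            v = row.get(k)
            kwargs[k] = None if pd.isna(v) else float(v)
        offs = [row.get(k) for k in ("cov_c_alpha", "cov_c_beta", "cov_alpha_beta")]
        if all(pd.notna(v) for v in offs) and None not in (
            kwargs["se_c"], kwargs["se_alpha"], kwargs["se_beta"]
        ):
            ca, cb, ab = (float(v) for v in offs)
            v0, v1, v2 = (kwargs["se_c"] ** 2, kwargs["se_alpha"] ** 2, kwargs["se_beta"] ** 2)
            kwargs["covariance"] = np.array(
                [[v0, ca, cb], [ca, v1, ab], [cb, ab, v2]]
            )
        out.append(CalibrationCurve(**kwargs))
    return out


def write_curve_table(curves: Iterable[CalibrationCurve], path) -> None:
    rows = []
    for cv in curves:
        row = {
            "label": cv.label, "c": cv.c, "se_c": cv.se_c, "alpha": cv.alpha,
            "se_alpha": cv.se_alpha, "beta": cv.beta, "se_beta": cv.se_beta,
            "cov_c_alpha": None, "cov_c_beta": None, "cov_alpha_beta": None,
        }
        if cv.covariance is not None:
            row["cov_c_alpha"] = cv.covariance[0, 1]
            row["cov_c_beta"] = cv.covariance[0, 2]
            row["cov_alpha_beta"] = cv.covariance[1, 2]
        rows.append(row)
    pd.DataFrame(rows, columns=_CURVE_COLS).to_csv(path, index=False, float_format="%.17g")


def write_dose_estimates(estimates: Sequence[DoseEstimate], path, precision: int = 6) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "dose": round(e.dose, precision),
            "ci_low": round(e.ci_low, precision),
            "ci_high": round(e.ci_high, precision),
            "truncated": e.truncated,
        }
        for e in estimates
    ]
    cols = ["sample_id", "dose", "ci_low", "ci_high", "truncated"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_dose_estimates(path) -> list[DoseEstimate]:
    df = _read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            DoseEstimate(
                dose=float(row["dose"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                truncated=bool(row["truncated"]),
                sample_id=str(row.get("sample_id", "")),
            )
        )
    return out
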