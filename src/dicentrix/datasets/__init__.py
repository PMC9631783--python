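"""Packaged reference datasets.

Small delimited-text fixtures shipped with the package: the semi-automated
calibration scoring table (nine Co-60 dose points, 0-4 Gy), the two
published calibration curves, and the paired worker triage contingency
table. They drive the worked examples, the test suite and the reproduction
command.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..datatypes import CalibrationCurve, ConfusionTable, DicentricDistribution
from ..io import read_curve_table, read_distribution_table

__all__ = [
    "calibration_distributions",
    "published_curves",
    "worker_agreement_table",
    "dataset_path",
]


def dataset_path(name: str):
    """Filesystem path of a packaged dataset file."""
    path = resources.files(__package__).joinpath(name)
    if not path.is_file():
        raise FileNotFoundError(f"no packaged dataset {name!r}")
    return path


def calibration_distributions() -> list[DicentricDistribution]:
    """Nine-dose semi-automated calibration scoring table (0-4 Gy)."""
    with resources.as_file(dataset_path("semi_automated_calibration.csv")) as p:
        return read_distribution_table(p)


def published_curves() -> dict[str, CalibrationCurve]:
    """Published manual and semi-automated curves, keyed by label."""
    with resources.as_file(dataset_path("published_curves.csv")) as p:
        return {cv.label: cv for cv in read_curve_table(p)}


def worker_agreement_table() -> ConfusionTable:
    """Paired 0.1 Gy classification of 35 workers by the two methods."""
    with resources.as_file(dataset_path("worker_agreement.csv")) as p:
        df = pd.read_csv(p, comment="#")
    row = df.iloc[0]
    return ConfusionTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
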