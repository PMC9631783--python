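import pytest
from hypothesis import settings

from dicentrix.datasets import (
    calibration_distributions,
    published_curves,
    worker_agreement_table,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib_dists():
    """The packaged nine-dose semi-automated calibration scoring table."""
    return calibration_distributions()


@pytest.fixture(scope="session")
def curves():
    """Published manual and semi-automated curves, keyed by label."""
    return published_curves()


@pytest.fixture(scope="session")
def worker_table():
    """Paired 0.1 Gy worker classification table (a=18, b=4, c=1, d=12)."""
    return worker_agreement_table()


@pytest.fixture(scope="session")
def fitted(calib_dists):
    """Poisson-ML linear-quadratic fit of the calibration table."""
    from dicentrix import fit_linear_quadratic

    return fit_linear_quadratic(calib_dists, label="semi_automated")
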