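import numpy as np
import pytest

from funfanova import (
    FunctionalSample,
    PairedFunctionalSample,
    make_bspline_basis,
)


@pytest.fixture(scope="session")
def cubic20():
    return make_bspline_basis((0.0, 1.0), 20, 4)


@pytest.fixture(scope="session")
def cubic7():
    return make_bspline_basis((0.0, 1.0), 7, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_paired_sample(basis, n, rng, scale=1.0):
    """Random Gaussian paired coefficient sample on a given basis."""
    A1 = scale * rng.standard_normal((n, basis.n_basis))
    A2 = 0.5 * A1 + scale * rng.standard_normal((n, basis.n_basis))
    return PairedFunctionalSample(
        basis=basis,
        coeff_cond1=A1,
        coeff_cond2=A2,
        unit_ids=[f"u{j}" for j in range(n)],
    )


def random_functional_sample(basis, n, rng, name="X"):
    return FunctionalSample(
        basis=basis,
        coefficients=rng.standard_normal((n, basis.n_basis)),
        unit_ids=[f"u{j}" for j in range(n)],
        variable_name=name,
    )
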