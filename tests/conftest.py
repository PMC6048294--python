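import numpy as np
import pytest

from sc4a import ExplanatoryMatrix, Orientation, validate_expression


@pytest.fixture
def toy_diag():
    """2x2 diagonal table: one unit of total inertia, perfectly associated."""
    return validate_expression([[10, 0], [0, 10]], ["g1", "g2"], ["s1", "s2"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_expression(rng, p, m, low=0.1, high=10.0, orientation=Orientation.GENES_BY_SAMPLES):
    vals = rng.uniform(low, high, (p, m))
    return validate_expression(
        vals, [f"g{i}" for i in range(p)], [f"s{j}" for j in range(m)], orientation
    )


def fullrank_Z(rng, p):
    """Random covariates spanning (with the implicit intercept) the full space."""
    return ExplanatoryMatrix(
        rng.normal(size=(p, p)), [f"z{i}" for i in range(p)]
    ).standardize()
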