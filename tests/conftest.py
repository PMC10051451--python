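import numpy as np
import pytest

from shiftbench import (
    ConformerShieldings,
    MethodLabel,
    ShieldingSet,
    load_delta50,
    load_probe_summary,
)


@pytest.fixture(scope="session")
def delta50():
    return load_delta50()


@pytest.fixture(scope="session")
def probe_records():
    return load_probe_summary()


@pytest.fixture
def two_compound_set():
    """Small multi-conformer shielding set for round-trip tests."""
    label = MethodLabel(functional="wB97X-D", basis="def2-SVP")
    conformers = {
        "a": [
            ConformerShieldings("a", "c1", 0.0, {1: 100.5, 2: 25.123456789012}),
            ConformerShieldings("a", "c2", 1.25, {1: 99.875, 2: 25.5}),
        ],
        "b": [
            ConformerShieldings("b", "c1", 0.0, {1: -12.75, 3: 180.0}),
        ],
    }
    return ShieldingSet(method_label=label, conformers=conformers)


def ols_normal_equations(delta, sigma):
    """Independent OLS oracle: solve the 2x2 normal equations directly."""
    delta = np.asarray(delta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = delta.size
    A = np.array([[n, delta.sum()], [delta.sum(), (delta**2).sum()]])
    y = np.array([sigma.sum(), (delta * sigma).sum()])
    b, m = np.linalg.solve(A, y)
    return m, b
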