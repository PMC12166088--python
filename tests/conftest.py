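import numpy as np
import pytest

from pdcrec import ResponseMatrix, get_scheme


def make_matrix(values, scheme="gdsc_pIC50", cells=None, drugs=None, missing=None):
    """Build a small ResponseMatrix from a nested list; NaN entries (or an
    explicit mask) mark missing values."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cells = cells or [f"c{i}" for i in range(n)]
    drugs = drugs or [f"d{j}" for j in range(m)]
    if missing is None:
        missing = np.isnan(values)
    return ResponseMatrix(cells, drugs, values, np.asarray(missing, bool), get_scheme(scheme))


def random_matrix(rng, n_cells, n_drugs, missing_fraction=0.0, scheme="gdsc_pIC50"):
    values = rng.normal(size=(n_cells, n_drugs))
    missing = rng.random((n_cells, n_drugs)) < missing_fraction
    values[missing] = np.nan
    return make_matrix(values, scheme=scheme)


@pytest.fixture
def mk():
    return make_matrix


@pytest.fixture
def rmk():
    return random_matrix
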