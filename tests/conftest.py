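import numpy as np
import pandas as pd
import pytest

import refstab as rs


@pytest.fixture(scope="session")
def asc() -> rs.CtTable:
    """The packaged 15-sample x 5-gene ASC housekeeping-gene table."""
    return rs.load_asc_table()


@pytest.fixture(scope="session")
def asc_f(asc) -> rs.CtTable:
    return asc.select_conditions("F")


@pytest.fixture(scope="session")
def asc_s(asc) -> rs.CtTable:
    return asc.select_conditions("S")


def make_table(matrix, genes=None, conditions=None, donors=None) -> rs.CtTable:
    """Small helper to build a CtTable from a plain array."""
    X = np.asarray(matrix, dtype=float)
    n, g = X.shape
    genes = genes or [f"G{j + 1}" for j in range(g)]
    samples = [f"S{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "donor": donors or [f"D{i + 1}" for i in range(n)],
            "condition": conditions or ["F"] * n,
        },
        index=pd.Index(samples, name="sample"),
    )
    return rs.CtTable(pd.DataFrame(X, index=meta.index, columns=genes), meta)


@pytest.fixture
def toy_table():
    return make_table(
        [[20.0, 21.0, 25.0], [20.5, 21.6, 24.0], [19.8, 20.7, 26.0], [20.2, 21.2, 25.5]]
    )
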