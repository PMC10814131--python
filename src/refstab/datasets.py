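"""Packaged example dataset.

``load_asc_table`` returns the published Ct matrix of five candidate
housekeeping genes (ACTB, B2M, GAPDH, HPRT1, RPLP0) measured in
adipose-derived mesenchymal stromal cells from three donors under five
culture conditions (serum, serum + IL-1beta, starvation, starvation +
IL-1beta, and starvation after IL-1beta priming) — 15 samples in total.
Values are final Ct values after technical normalization, printed to two
decimals.
"""

from __future__ import annotations

from importlib import resources

from .datamodel import CtTable
from .io import read_ct_table


def load_asc_table() -> CtTable:
    """The 15-sample x 5-gene ASC housekeeping-gene Ct table."""
    with resources.as_file(
        resources.files("refstab").joinpath("data", "asc_hkg_ct.csv")
    ) as path:
        return read_ct_table(path, format="wide")
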