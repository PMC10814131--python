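"""Geometric-mean consensus ranking across the four stability methods.

Each method contributes a per-gene rank (1 = most stable); the comprehensive
score of a gene is the geometric mean of its four ranks, i.e. the fourth root
of the rank product. geNorm contributes its pair rule — both final-pair genes
at rank 1, the next gene at rank 3 — so a gene ranked worst (g) by all four
methods scores exactly g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import ValidationError
from .stability import StabilityResult

METHODS = ("delta_ct", "bestkeeper", "normfinder", "genorm")


@dataclass(frozen=True)
class ConsensusRanking:
    """Per-gene method ranks and geometric-mean score, sorted best-first
    (ties in geomean broken alphabetically by gene symbol)."""

    table: pd.DataFrame  # columns rank_<method>..., geomean
    subset: tuple[str, ...]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def best(self) -> str:
        return self.table.index[0]

    @property
    def worst(self) -> str:
        return self.table.index[-1]

    @property
    def geomean(self) -> pd.Series:
        return self.table["geomean"]


def consensus_rank(
    results: Mapping[str, StabilityResult] | Iterable[StabilityResult],
) -> ConsensusRanking:
    """Aggregate four :class:`StabilityResult` objects (one per method, same
    genes, same sample subset) into a :class:`ConsensusRanking`."""
    if isinstance(results, Mapping):
        by_method = dict(results)
    else:
        by_method = {r.method: r for r in results}
    missing = [m for m in METHODS if m not in by_method]
    if missing:
        raise ValidationError(f"consensus requires all four methods; missing {missing}")

    ref = by_method[METHODS[0]]
    gene_set = set(ref.genes)
    for m in METHODS[1:]:
        other = set(by_method[m].genes)
        if other != gene_set:
            raise ValidationError(
                f"gene sets differ between {METHODS[0]} and {m}: "
                f"only in {METHODS[0]}: {sorted(gene_set - other)}, "
                f"only in {m}: {sorted(other - gene_set)}"
            )
        if set(by_method[m].subset) != set(ref.subset):
            raise ValidationError(
                f"sample subsets differ between {METHODS[0]} and {m}"
            )

    genes = sorted(gene_set)
    frame = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for m in METHODS:
        frame[f"rank_{m}"] = by_method[m].ranks.loc[genes]
    rank_cols = [f"rank_{m}" for m in METHODS]
    frame["geomean"] = np.prod(frame[rank_cols].to_numpy(), axis=1) ** 0.25
    frame = frame.sort_values(["geomean", "gene"], kind="stable")
    return ConsensusRanking(table=frame, subset=tuple(ref.subset))
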