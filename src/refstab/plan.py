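"""Condition-combinatorial orchestration of stability + consensus analyses.

The study design asks how reference-gene stability changes with the sample
subset: each culture condition alone, biologically meaningful pairs of
conditions, and all samples together. An :class:`AnalysisPlan` is a list of
(label, condition set) pairs; :func:`run_plan` analyses each subset
independently with the four stability methods and the consensus ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .consensus import METHODS, ConsensusRanking, consensus_rank
from .datamodel import CtTable, ValidationError
from .stability import StabilityResult, all_methods

#: the default plan: 5 single conditions, 6 coupled sets, and everything
DEFAULT_SUBSETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("F", ("F",)),
    ("F+IL1", ("F+IL1",)),
    ("S", ("S",)),
    ("S+IL1", ("S+IL1",)),
    ("F+IL1/S", ("F+IL1/S",)),
    ("F and F+IL1", ("F", "F+IL1")),
    ("S and S+IL1", ("S", "S+IL1")),
    ("S and F+IL1/S", ("S", "F+IL1/S")),
    ("F+IL1 and S+IL1", ("F+IL1", "S+IL1")),
    ("F and S", ("F", "S")),
    ("F+IL1 and F+IL1/S", ("F+IL1", "F+IL1/S")),
    ("ALL", ("F", "F+IL1", "S", "S+IL1", "F+IL1/S")),
)


@dataclass(frozen=True)
class AnalysisPlan:
    """Named condition subsets to analyse. The default is the study's 12
    analyses (5 single, 6 coupled, plus ALL)."""

    subsets: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_SUBSETS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        """Load a plan from YAML: a mapping of label -> list of conditions."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or not raw:
            raise ValidationError(f"{path}: plan must be a non-empty mapping")
        subsets = tuple(
            (str(label), tuple(str(c) for c in conds)) for label, conds in raw.items()
        )
        return cls(subsets=subsets)

    def labels(self) -> list[str]:
        return [label for label, _ in self.subsets]


@dataclass(frozen=True)
class SubsetAnalysis:
    """Results of one plan entry: the four stability results plus the
    consensus ranking."""

    label: str
    conditions: tuple[str, ...]
    stability: dict[str, StabilityResult]
    consensus: ConsensusRanking


def run_plan(
    table: CtTable, plan: AnalysisPlan | None = None
) -> list[SubsetAnalysis]:
    """Run stability + consensus on every subset of ``plan`` (default: the
    study's 12 analyses), in plan order. Each subset must resolve to at least
    3 samples."""
    plan = plan or AnalysisPlan()
    data_conditions = set(table.conditions)
    out: list[SubsetAnalysis] = []
    for label, conds in plan.subsets:
        unknown = sorted(set(conds) - data_conditions)
        if unknown:
            raise ValidationError(
                f"plan subset {label!r} names conditions absent from the data: {unknown}"
            )
        sub = table.select_conditions(conds)
        if sub.n_samples < 3:
            raise ValidationError(
                f"plan subset {label!r} resolves to {sub.n_samples} samples (< 3)"
            )
        results = all_methods(sub)
        out.append(
            SubsetAnalysis(
                label=label,
                conditions=tuple(conds),
                stability=results,
                consensus=consensus_rank(results),
            )
        )
    return out


def results_to_frame(analyses: Sequence[SubsetAnalysis]) -> pd.DataFrame:
    """Serialize plan results as one tidy long-format table: one row per
    (subset, method, gene) with the stability value and rank, plus the
    consensus geomean rows under method ``"consensus"``."""
    rows = []
    for a in analyses:
        for method in METHODS:
            res = a.stability[method]
            for gene in res.genes:
                rows.append(
                    {
                        "subset": a.label,
                        "method": method,
                        "gene": gene,
                        "value": res.values[gene],
                        "rank": res.ranks[gene],
                    }
                )
        for gene, row in a.consensus.table.iterrows():
            rows.append(
                {
                    "subset": a.label,
                    "method": "consensus",
                    "gene": gene,
                    "value": row["geomean"],
                    "rank": float(
                        a.consensus.table.index.get_loc(gene) + 1
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["subset", "method", "gene", "value", "rank"])
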