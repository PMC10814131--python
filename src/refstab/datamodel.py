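"""Core data containers for Ct (cycle-threshold) tables.

A :class:`CtTable` is the single currency of the pipeline: a samples x genes
matrix of Ct values together with per-sample metadata (donor, culture
condition). Ct values live on a log2 scale — one cycle difference is roughly
a two-fold difference in template amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five culture conditions of the study design:
#: F        — 48 h in complete medium (FBS)
#: F+IL1    — FBS plus IL-1beta (inflammatory priming)
#: S        — serum starvation after FBS expansion
#: S+IL1    — starvation plus IL-1beta
#: F+IL1/S  — starvation after an IL-1beta-primed FBS phase
CONDITIONS: tuple[str, ...] = ("F", "F+IL1", "S", "S+IL1", "F+IL1/S")

#: condition -> (serum present, IL-1beta present, primed during FBS phase)
CONDITION_FLAGS: Mapping[str, tuple[bool, bool, bool]] = {
    "F": (True, False, False),
    "F+IL1": (True, True, False),
    "S": (False, False, False),
    "S+IL1": (False, True, False),
    "F+IL1/S": (False, False, True),
}

#: Ct values must lie strictly inside this range to be considered measurements.
CT_BOUNDS = (0.0, 45.0)


class ValidationError(ValueError):
    """Raised when a table violates a data-model invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation. ``serum``/``il1b``/``primed`` derive from the
    condition label and are exposed for convenience in condition algebra."""

    donor: str
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_FLAGS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def serum(self) -> bool:
        return CONDITION_FLAGS[self.condition][0]

    @property
    def il1b(self) -> bool:
        return CONDITION_FLAGS[self.condition][1]

    @property
    def primed(self) -> bool:
        return CONDITION_FLAGS[self.condition][2]


@dataclass(frozen=True)
class ControlReadings:
    """Per-sample Ct of the positive PCR control (PPC) and the reverse
    transcription control (RTC), used for technical normalization."""

    ppc: pd.Series
    rtc: pd.Series

    def __post_init__(self) -> None:
        if not self.ppc.index.equals(self.rtc.index):
            raise ValidationError("PPC and RTC cover different sample sets")
        for name, s in (("ppc", self.ppc), ("rtc", self.rtc)):
            if not np.isfinite(s.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite {name.upper()} control readings")

    @property
    def samples(self) -> list[str]:
        return list(self.ppc.index)


class CtTable:
    """A validated samples x genes Ct matrix with per-sample metadata.

    Parameters
    ----------
    ct
        DataFrame indexed by sample identifier with one float column per gene.
        ``NaN`` marks an explicitly missing measurement.
    meta
        DataFrame indexed by the same samples with columns ``donor`` and
        ``condition``.
    provenance
        Free-form strings recording how the table was produced (file read,
        duplicate collapsing rule, normalization, ...).
    """

    def __init__(
        self,
        ct: pd.DataFrame,
        meta: pd.DataFrame,
        provenance: Sequence[str] = (),
    ) -> None:
        ct = ct.astype(float).copy()
        meta = meta.copy()
        if ct.index.has_duplicates:
            dupes = ct.index[ct.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        if ct.columns.has_duplicates:
            dupes = ct.columns[ct.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        missing_meta = [c for c in ("donor", "condition") if c not in meta.columns]
        if missing_meta:
            raise ValidationError(f"metadata lacks columns {missing_meta}")
        if not ct.index.equals(meta.index):
            try:
                meta = meta.loc[ct.index]
            except KeyError as exc:
                raise ValidationError(
                    "metadata does not cover every sample in the Ct matrix"
                ) from exc
        bad_cond = sorted(set(meta["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(
                f"unknown condition labels {bad_cond}; expected one of {CONDITIONS}"
            )
        vals = ct.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        lo, hi = CT_BOUNDS
        if np.any((vals[present] <= lo) | (vals[present] >= hi)):
            raise ValidationError(f"Ct values must lie strictly in {CT_BOUNDS}")
        self.ct = ct
        self.meta = meta
        self.provenance: tuple[str, ...] = tuple(provenance)

    # -- basic views ----------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_samples(self) -> int:
        return self.ct.shape[0]

    @property
    def n_genes(self) -> int:
        return self.ct.shape[1]

    @property
    def conditions(self) -> pd.Series:
        return self.meta["condition"]

    @property
    def donors(self) -> pd.Series:
        return self.meta["donor"]

    def matrix(self) -> np.ndarray:
        """Samples x genes float matrix."""
        return self.ct.to_numpy(dtype=float)

    def sample_meta(self, sample: str) -> SampleMeta:
        row = self.meta.loc[sample]
        return SampleMeta(donor=str(row["donor"]), condition=str(row["condition"]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CtTable({self.n_samples} samples x {self.n_genes} genes, "
            f"conditions={sorted(set(self.conditions))})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtTable):
            return NotImplemented
        return self.ct.equals(other.ct) and self.meta[["donor", "condition"]].equals(
            other.meta[["donor", "condition"]]
        )

    # -- manipulation ---------------------------------------------------

    def with_provenance(self, *notes: str) -> "CtTable":
        return CtTable(self.ct, self.meta, self.provenance + tuple(notes))

    def select_conditions(self, conditions: Iterable[str] | str) -> "CtTable":
        """Restrict to samples whose condition is in ``conditions``."""
        if isinstance(conditions, str):
            conditions = [conditions]
        wanted = list(conditions)
        unknown = sorted(set(wanted) - set(CONDITIONS))
        if unknown:
            raise ValidationError(f"unknown condition labels {unknown}")
        mask = self.meta["condition"].isin(wanted)
        if not mask.any():
            raise ValidationError(f"no samples in conditions {wanted}")
        return CtTable(
            self.ct.loc[mask],
            self.meta.loc[mask],
            self.provenance + (f"subset conditions={wanted}",),
        )

    def select_genes(self, genes: Sequence[str]) -> "CtTable":
        missing = [g for g in genes if g not in self.ct.columns]
        if missing:
            raise ValidationError(f"genes not in table: {missing}")
        return CtTable(self.ct[list(genes)], self.meta, self.provenance)

    def require_complete(self, context: str = "this operation") -> None:
        """Raise if any cell is missing; stability statistics refuse to
        impute and instead fail loudly."""
        if np.isnan(self.matrix()).any():
            bad = self.ct.isna()
            cells = [
                (s, g) for s in self.ct.index for g in self.ct.columns if bad.loc[s, g]
            ]
            raise ValidationError(
                f"{context} requires a complete Ct matrix; missing cells: {cells[:5]}"
                + ("..." if len(cells) > 5 else "")
            )
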