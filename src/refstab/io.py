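"""Reading and writing Ct tables, controls files, and duplicate collapsing.

Two tabular dialects are supported, both plain CSV/TSV:

* wide  — ``sample,donor,condition,<gene1>,<gene2>,...`` one row per sample;
* long  — ``sample,donor,condition,gene,ct`` one row per measurement.

The delimiter is inferred from the file extension (``.tsv``/``.txt`` -> tab,
otherwise comma) and can be overridden. Instrument-native exports
(QuantStudio EDS/XLSX) are out of scope; export to CSV first.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import ControlReadings, CtTable, ValidationError

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample", "donor", "condition")

#: technical duplicates further apart than this (cycles) trigger a warning
DUPLICATE_SPREAD_WARN = 1.0


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _read_frame(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=_delimiter(path, delimiter))
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def read_ct_table(
    path: str | Path,
    format: Literal["wide", "long"] = "wide",
    delimiter: str | None = None,
) -> CtTable:
    """Read a Ct table from a wide- or long-format CSV/TSV file.

    Duplicate (sample, gene) records are rejected; collapse technical
    replicates first with :func:`collapse_duplicates`.
    """
    frame = _read_frame(path, delimiter)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if format == "wide":
        genes = [c for c in frame.columns if c not in META_COLUMNS]
        if not genes:
            raise ParseError(f"{path}: wide format has no gene columns")
        if frame["sample"].duplicated().any():
            dupes = frame.loc[frame["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(
                f"{path}: duplicate (sample, gene) records for samples {dupes}"
            )
        ct = frame.set_index("sample")[genes]
        meta = frame.set_index("sample")[["donor", "condition"]]
    elif format == "long":
        for col in ("gene", "ct"):
            if col not in frame.columns:
                raise ParseError(f"{path}: long format requires a {col!r} column")
        if frame.duplicated(subset=["sample", "gene"]).any():
            raise ValidationError(
                f"{path}: repeated (sample, gene) records; use collapse_duplicates()"
            )
        ct = frame.pivot(index="sample", columns="gene", values="ct")
        # preserve first-appearance order rather than pivot's alphabetical order
        sample_order = list(dict.fromkeys(frame["sample"]))
        gene_order = list(dict.fromkeys(frame["gene"]))
        ct = ct.loc[sample_order, gene_order]
        ct.columns.name = None
        meta = (
            frame.drop_duplicates("sample")
            .set_index("sample")[["donor", "condition"]]
            .loc[sample_order]
        )
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown format {format!r}")
    try:
        ct = ct.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric Ct value ({exc})") from exc
    return CtTable(ct, meta, provenance=(f"read {format} {Path(path).name}",))


def write_ct_table(
    table: CtTable,
    path: str | Path,
    format: Literal["wide", "long"] = "wide",
    delimiter: str | None = None,
) -> None:
    """Write a table in the same dialects :func:`read_ct_table` accepts."""
    path = Path(path)
    sep = _delimiter(path, delimiter)
    if format == "wide":
        out = table.meta[["donor", "condition"]].join(table.ct)
        out.rename_axis("sample").to_csv(path, sep=sep)
    elif format == "long":
        long = table.ct.stack(future_stack=True).rename("ct").reset_index()
        long.columns = ["sample", "gene", "ct"]
        long = long.merge(
            table.meta[["donor", "condition"]], left_on="sample", right_index=True
        )[["sample", "donor", "condition", "gene", "ct"]]
        long.to_csv(path, sep=sep, index=False)
    else:  # pragma: no cover
        raise ValueError(f"unknown format {format!r}")


def read_controls(path: str | Path, delimiter: str | None = None) -> ControlReadings:
    """Read a ``sample,ppc,rtc`` CSV of technical-control Ct values."""
    frame = _read_frame(path, delimiter)
    for col in ("sample", "ppc", "rtc"):
        if col not in frame.columns:
            raise ParseError(f"{path}: controls file requires a {col!r} column")
    frame = frame.set_index("sample")
    return ControlReadings(
        ppc=frame["ppc"].astype(float), rtc=frame["rtc"].astype(float)
    )


def collapse_duplicates(
    records: pd.DataFrame,
    rule: Literal["mean", "median"] = "mean",
) -> CtTable:
    """Collapse technical replicates into one Ct per (sample, gene) cell.

    ``records`` is a long-format frame with columns
    ``sample, donor, condition, gene, ct`` in which (sample, gene) may repeat.
    Replicates whose spread exceeds 1.0 cycles are collapsed anyway but logged
    as a warning. The collapsing rule is recorded in the table's provenance.
    """
    required = [*META_COLUMNS, "gene", "ct"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ParseError(f"records frame missing columns {missing}")
    if rule not in ("mean", "median"):
        raise ValueError(f"unknown collapsing rule {rule!r}")
    records = records.copy()
    records["ct"] = pd.to_numeric(records["ct"])

    for (sample, gene), grp in records.groupby(["sample", "gene"], sort=False):
        spread = grp["ct"].max() - grp["ct"].min()
        if spread > DUPLICATE_SPREAD_WARN:
            logger.warning(
                "technical replicates for (%s, %s) differ by %.2f cycles",
                sample,
                gene,
                spread,
            )

    agg = getattr(records.groupby(["sample", "gene"], sort=False)["ct"], rule)()
    collapsed = agg.reset_index()
    ct = collapsed.pivot(index="sample", columns="gene", values="ct")
    sample_order = list(dict.fromkeys(records["sample"]))
    gene_order = list(dict.fromkeys(records["gene"]))
    ct = ct.loc[sample_order, gene_order]
    ct.columns.name = None
    meta = (
        records.drop_duplicates("sample")
        .set_index("sample")[["donor", "condition"]]
        .loc[sample_order]
    )
    return CtTable(ct, meta, provenance=(f"collapsed technical replicates rule={rule}",))


def call_amplification(ct: float) -> bool:
    """Amplification call: ``True`` iff the Ct is finite and strictly below 35
    cycles; a missing (NaN) Ct is called negative."""
    if ct is None:
        return False
    ct = float(ct)
    if math.isnan(ct):
        return False
    return ct < 35.0
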