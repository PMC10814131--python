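"""Relative quantification of target genes against a housekeeping gene.

Implements the 2^-ddCt method: dCt = Ct_target - Ct_hkg per sample, ddCt per
donor between two conditions (donors matched across conditions), fold change
= 2^-ddCt. Significance follows the study conventions: Shapiro-Wilk at alpha
0.01 gates a parametric test; two conditions -> unpaired Student's t-test;
all conditions -> one-way ANOVA with Tukey post hoc; significance at
p <= 0.05, a "tendency" band at 0.05 < p <= 0.1; a call of up/down
additionally requires mean fold >= 2 / <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CtTable, ValidationError

SIGNIFICANCE_ALPHA = 0.05
TENDENCY_UPPER = 0.1
NORMALITY_ALPHA = 0.01
FOLD_UP = 2.0
FOLD_DOWN = 0.5


class NormalityError(ValueError):
    """Raised when Shapiro-Wilk rejects normality: the study design defines
    no non-parametric fallback, so the user must decide how to proceed."""


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    test: str
    call: Literal["significant", "tendency", "ns"]
    tukey: pd.DataFrame | None = None  # pairwise p-values, ANOVA design only


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-donor 2^-ddCt fold changes of ``target`` in ``condition`` relative
    to ``reference``, normalized to ``hkg``."""

    target: str
    hkg: str
    condition: str
    reference: str
    per_donor: pd.Series  # fold change per donor
    mean: float
    sd: float  # SD of the per-donor fold values (linear scale, n-1)
    p_value: float
    test: str
    call: Literal["up", "down", "unchanged", "tendency"]


def _shapiro_gate(values: np.ndarray, label: str) -> None:
    if len(values) < 3:
        raise ValidationError(f"group {label!r} has fewer than 3 values")
    if np.ptp(values) == 0:
        return  # identical values: normality test undefined, treat as pass
    p = stats.shapiro(values).pvalue
    if p < NORMALITY_ALPHA:
        raise NormalityError(
            f"Shapiro-Wilk rejects normality for group {label!r} "
            f"(p = {p:.4g} < {NORMALITY_ALPHA}); no non-parametric fallback is "
            "defined — inspect the data or choose a different test"
        )


def _call_from_p(p: float) -> Literal["significant", "tendency", "ns"]:
    if p <= SIGNIFICANCE_ALPHA:
        return "significant"
    if p <= TENDENCY_UPPER:
        return "tendency"
    return "ns"


def significance(
    *groups: Sequence[float],
    design: Literal["two_conditions", "all_conditions"] | None = None,
) -> SignificanceResult:
    """Study-convention significance testing.

    Two groups (``two_conditions``): Shapiro-Wilk gate then unpaired
    Student's t-test. Three or more (``all_conditions``): gate then one-way
    ANOVA with Tukey's post hoc (pairwise table in ``tukey``).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if design is None:
        design = "two_conditions" if len(arrays) == 2 else "all_conditions"
    if design == "two_conditions" and len(arrays) != 2:
        raise ValidationError("two_conditions design requires exactly 2 groups")
    if design == "all_conditions" and len(arrays) < 3:
        raise ValidationError("all_conditions design requires >= 3 groups")
    for i, arr in enumerate(arrays):
        _shapiro_gate(arr, f"group{i + 1}")

    if design == "two_conditions":
        a, b = arrays
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all values identical in both groups
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return SignificanceResult(p_value=p, test="t_test", call=_call_from_p(p))

    p = float(stats.f_oneway(*arrays).pvalue)
    hsd = stats.tukey_hsd(*arrays)
    k = len(arrays)
    rows = [
        {"group_a": i + 1, "group_b": j + 1, "p_value": float(hsd.pvalue[i, j])}
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return SignificanceResult(
        p_value=p,
        test="anova_tukey",
        call=_call_from_p(p),
        tukey=pd.DataFrame(rows),
    )


def relative_expression(table: CtTable, target: str, hkg: str) -> pd.Series:
    """Per-sample relative expression 2^-dCt of ``target`` versus ``hkg``."""
    for gene in (target, hkg):
        if gene not in table.genes:
            raise ValidationError(f"gene {gene!r} not in table")
    dct = table.ct[target] - table.ct[hkg]
    return np.power(2.0, -dct).rename(f"2^-dCt({target}/{hkg})")


def ddct_fold_change(
    table: CtTable,
    target: str,
    hkg: str,
    condition: str,
    reference: str,
    test_scale: Literal["dct", "fold"] = "dct",
) -> FoldChangeResult:
    """2^-ddCt fold change of ``target`` in ``condition`` vs ``reference``,
    normalized to ``hkg``, with per-donor matching.

    Donors must appear in both conditions; ddCt per donor is the donor's dCt
    in ``condition`` minus the same donor's dCt in ``reference``. The t-test
    runs unpaired on dCt values by default (``test_scale="dct"``); pass
    ``"fold"`` to test the linear-scale per-donor fold values against 1.
    """
    for gene in (target, hkg):
        if gene not in table.genes:
            raise ValidationError(f"gene {gene!r} not in table")
    dct = (table.ct[target] - table.ct[hkg]).rename("dct")
    frames = {}
    for cond in (condition, reference):
        sub = table.meta["condition"] == cond
        if not sub.any():
            raise ValidationError(f"no samples in condition {cond!r}")
        frames[cond] = pd.Series(
            dct[sub].to_numpy(), index=table.meta.loc[sub, "donor"]
        )
    a, b = frames[condition], frames[reference]
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValidationError(
            f"donors not matched across conditions: only in {condition!r}: {only_a}, "
            f"only in {reference!r}: {only_b}"
        )
    donors = list(a.index)
    ddct = a.loc[donors] - b.loc[donors]
    fold = np.power(2.0, -ddct)

    if test_scale == "dct":
        sig = significance(a.to_numpy(), b.to_numpy(), design="two_conditions")
    elif test_scale == "fold":
        sig_p = float(stats.ttest_1samp(fold.to_numpy(), 1.0).pvalue)
        sig = SignificanceResult(
            p_value=sig_p, test="t_test_fold_vs_1", call=_call_from_p(sig_p)
        )
    else:
        raise ValueError(f"unknown test_scale {test_scale!r}")

    mean_fold = float(fold.mean())
    if mean_fold >= FOLD_UP and sig.p_value <= SIGNIFICANCE_ALPHA:
        call: Literal["up", "down", "unchanged", "tendency"] = "up"
    elif mean_fold <= FOLD_DOWN and sig.p_value <= SIGNIFICANCE_ALPHA:
        call = "down"
    elif SIGNIFICANCE_ALPHA < sig.p_value <= TENDENCY_UPPER:
        call = "tendency"
    else:
        call = "unchanged"
    return FoldChangeResult(
        target=target,
        hkg=hkg,
        condition=condition,
        reference=reference,
        per_donor=fold,
        mean=mean_fold,
        sd=float(fold.std(ddof=1)),
        p_value=sig.p_value,
        test=sig.test,
        call=call,
    )
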