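"""The four reference-gene stability statistics and descriptive statistics.

All four methods operate on Ct values, which are log2-scale quantities
(assuming amplification efficiency 2, one cycle = one log2 unit), and return
a per-gene stability score where **lower means more stable**:

* **comparative dCt** — for each gene, the mean over all partner genes of the
  sample SD (n-1 denominator) of the per-sample pairwise Ct difference.
* **BestKeeper** — a descriptive approach: the reported "SD" of a gene is the
  mean absolute deviation (MAD) of its Ct values from their arithmetic mean.
  The BestKeeper index (per-sample mean across candidates) and each gene's
  Pearson correlation with it are reported as extras but do not drive the
  ranking.
* **NormFinder** — a variance-decomposition model: after removing gene and
  sample main effects, each gene's residual variance is estimated with a
  small-panel bias correction; stability is the square root of the estimate,
  floored at zero. An optional grouped variant combines intra- and
  inter-group variation.
* **geNorm** — the average pairwise variation M: the mean over partners of
  the SD of the pairwise log-ratio (Ct difference). The worst gene is
  excluded stepwise until a final best pair remains, which shares the SD of
  its mutual Ct difference as M.

Ranks are ascending in the stability value at full precision; exact ties get
average ranks, except the geNorm final pair which shares rank 1 (the next
gene gets rank 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .datamodel import CtTable, ValidationError

Method = Literal["delta_ct", "bestkeeper", "normfinder", "genorm"]


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene stability values and ranks for one method on one sample
    subset. ``genorm_pair`` is set only by :func:`genorm`."""

    method: str
    values: pd.Series  # per-gene score, lower = more stable
    ranks: pd.Series  # 1 = best; average ranks on ties (geNorm: pair rule)
    subset: tuple[str, ...]  # sample identifiers used
    genorm_pair: tuple[str, str] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def ordered(self) -> pd.Series:
        """Values sorted best-first (ties broken alphabetically)."""
        return self.values.sort_values(kind="stable")


def _check(table: CtTable, min_genes: int, min_samples: int, method: str) -> np.ndarray:
    table.require_complete(method)
    if table.n_genes < min_genes:
        raise ValidationError(f"{method} requires >= {min_genes} genes")
    if table.n_samples < min_samples:
        raise ValidationError(f"{method} requires >= {min_samples} samples")
    return table.matrix()


def _average_ranks(values: pd.Series) -> pd.Series:
    return pd.Series(rankdata(values.to_numpy()), index=values.index)


def descriptives(table: CtTable) -> pd.DataFrame:
    """Per-gene mean, population SD (n denominator), min, max and range of Ct
    over all samples in the table."""
    _check(table, 1, 2, "descriptives")
    ct = table.ct
    out = pd.DataFrame(
        {
            "mean": ct.mean(),
            "sd": ct.std(ddof=0),
            "min": ct.min(),
            "max": ct.max(),
        }
    )
    out["range"] = out["max"] - out["min"]
    return out.rename_axis("gene")  # rename_axis copies; never mutate ct's index


def _pairwise_sd_matrix(X: np.ndarray, ddof: int) -> np.ndarray:
    """S[i, j] = SD over samples of (Ct_i - Ct_j); diagonal NaN."""
    g = X.shape[1]
    diff = X[:, :, None] - X[:, None, :]  # samples x genes x genes
    S = diff.std(axis=0, ddof=ddof)
    np.fill_diagonal(S, np.nan)
    return S


def delta_ct_stability(table: CtTable) -> StabilityResult:
    """Comparative dCt stability: mean over partner genes of the sample SD
    (n-1) of the per-sample pairwise Ct difference."""
    X = _check(table, 2, 3, "comparative dCt")
    S = _pairwise_sd_matrix(X, ddof=1)
    values = pd.Series(np.nanmean(S, axis=1), index=table.genes)
    return StabilityResult(
        method="delta_ct",
        values=values,
        ranks=_average_ranks(values),
        subset=tuple(table.samples),
    )


def bestkeeper(table: CtTable, center: Literal["arithmetic", "geometric"] = "arithmetic") -> StabilityResult:
    """BestKeeper descriptive stability: mean absolute deviation of each
    gene's Ct from its mean over the subset.

    The original tool centres on the geometric mean of Ct; at typical Ct
    magnitudes the difference is negligible and the arithmetic mean (default)
    reproduces published tables. Extras carry the BestKeeper index (per-sample
    arithmetic mean across candidates) and each gene's Pearson r with it
    (NaN for a constant gene).
    """
    X = _check(table, 1, 3, "BestKeeper")
    if center == "arithmetic":
        centers = X.mean(axis=0)
    elif center == "geometric":
        centers = np.exp(np.log(X).mean(axis=0))
    else:
        raise ValueError(f"unknown center {center!r}")
    values = pd.Series(np.abs(X - centers).mean(axis=0), index=table.genes)

    index = pd.Series(X.mean(axis=1), index=table.samples, name="bestkeeper_index")
    corr = {}
    for j, gene in enumerate(table.genes):
        col = X[:, j]
        if np.ptp(col) == 0 or np.ptp(index.to_numpy()) == 0:
            corr[gene] = np.nan
        else:
            corr[gene] = float(pearsonr(col, index.to_numpy()).statistic)
    return StabilityResult(
        method="bestkeeper",
        values=values,
        ranks=_average_ranks(values),
        subset=tuple(table.samples),
        extras={"index": index, "index_correlation": pd.Series(corr)},
    )


def _normfinder_single(X: np.ndarray) -> np.ndarray:
    """Ungrouped NormFinder variance estimates (may be negative before
    flooring). X is samples x genes with g >= 3."""
    n, g = X.shape
    Z = X - X.mean(axis=0) - X.mean(axis=1, keepdims=True) + X.mean()
    u = (Z**2).sum(axis=0) / (n - 1)
    total = g / (g - 1) * u.sum()  # unbiased estimate of the summed variances
    return g / (g - 2) * (u - total / g**2)  # small-panel bias correction


def _normfinder_grouped(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Grouped NormFinder stability: shrunken absolute inter-group difference
    plus its posterior SD, averaged over groups."""
    n, g = X.shape
    groups = list(dict.fromkeys(labels))
    D = len(groups)
    # sample effects removed globally
    R = X - X.mean(axis=1, keepdims=True)
    sigma2 = np.empty((g, D))
    z = np.empty((g, D))
    for d, grp in enumerate(groups):
        sel = labels == grp
        n_d = int(sel.sum())
        if n_d < 2:
            raise ValidationError(f"group {grp!r} has fewer than 2 samples")
        sigma2[:, d] = np.maximum(_normfinder_single(X[sel]), 0.0)
        z[:, d] = R[sel].mean(axis=0)
    d_mat = z - z.mean(axis=1, keepdims=True)  # gene x group interaction
    n_per = np.array([int((labels == grp).sum()) for grp in groups])
    noise = sigma2 / n_per  # sampling variance of each d estimate
    gamma2 = max(0.0, (d_mat**2).sum() / ((g - 1) * (D - 1)) - noise.mean())
    shrink = gamma2 / (gamma2 + noise) if gamma2 > 0 else np.zeros_like(noise)
    d_tilde = d_mat * shrink
    post_sd = np.sqrt(noise * shrink) if gamma2 > 0 else np.sqrt(noise)
    return (np.abs(d_tilde) + post_sd).mean(axis=1)


def normfinder(
    table: CtTable, groups: Sequence[str] | pd.Series | None = None
) -> StabilityResult:
    """NormFinder model-based stability on Ct (log2-scale) values.

    Without ``groups``: double-centre the sample x gene matrix and estimate
    each gene's residual variance with the small-panel bias correction;
    stability is sqrt of the estimate floored at 0. With ``groups`` (e.g. the
    condition labels): intra- and inter-group variation are combined.
    """
    X = _check(table, 3, 2, "NormFinder")
    if groups is None:
        var = _normfinder_single(X)
        values = pd.Series(np.sqrt(np.maximum(var, 0.0)), index=table.genes)
        extras = {"variance_estimate": pd.Series(var, index=table.genes)}
    else:
        labels = np.asarray(
            groups.loc[table.samples] if isinstance(groups, pd.Series) else groups
        )
        if labels.shape[0] != table.n_samples:
            raise ValidationError("group labels do not match the sample set")
        values = pd.Series(_normfinder_grouped(X, labels), index=table.genes)
        extras = {"grouped": True}
    return StabilityResult(
        method="normfinder",
        values=values,
        ranks=_average_ranks(values),
        subset=tuple(table.samples),
        extras=extras,
    )


def genorm(
    table: CtTable, sd_denominator: Literal["sample", "population"] = "sample"
) -> StabilityResult:
    """geNorm M-value with stepwise exclusion down to the final best pair.

    At each step the expression stability M of gene *i* is the mean over the
    remaining partners *j* of the SD of the per-sample Ct difference (log2
    ratio at efficiency 2) between *i* and *j*. The gene with the highest M is
    excluded and its M at that step recorded; when two genes remain they form
    ``genorm_pair`` and share the SD of their mutual difference as M.

    ``sd_denominator`` selects n-1 (``sample``, default) or n
    (``population``). Ties on exclusion are broken by excluding the
    alphabetically later gene.
    """
    X = _check(table, 2, 3, "geNorm")  # 2 genes degenerate to the final pair
    ddof = 1 if sd_denominator == "sample" else 0
    if sd_denominator not in ("sample", "population"):
        raise ValueError(f"unknown sd_denominator {sd_denominator!r}")

    genes = list(table.genes)
    remaining = list(range(len(genes)))
    values: dict[str, float] = {}
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        S = _pairwise_sd_matrix(X[:, remaining], ddof)
        M = np.nanmean(S, axis=1)
        # worst gene out; ties -> alphabetically later gene excluded
        worst_val = M.max()
        tied = [k for k in range(len(remaining)) if M[k] == worst_val]
        worst = max(tied, key=lambda k: genes[remaining[k]])
        values[genes[remaining[worst]]] = float(M[worst])
        exclusion_order.append(genes[remaining[worst]])
        remaining.pop(worst)

    pair = tuple(sorted(genes[k] for k in remaining))
    final_m = float(np.std(X[:, remaining[0]] - X[:, remaining[1]], ddof=ddof))
    for name in pair:
        values[name] = final_m

    value_series = pd.Series({g: values[g] for g in genes})
    # pair rule: both final genes rank 1, then 3, 4, ... by reverse exclusion
    ranks = {name: 1.0 for name in pair}
    for k, name in enumerate(reversed(exclusion_order)):
        ranks[name] = 3.0 + k
    rank_series = pd.Series({g: ranks[g] for g in genes})
    return StabilityResult(
        method="genorm",
        values=value_series,
        ranks=rank_series,
        subset=tuple(table.samples),
        genorm_pair=pair,  # type: ignore[arg-type]
        extras={"exclusion_order": tuple(exclusion_order)},
    )


def all_methods(
    table: CtTable, normfinder_groups: Sequence[str] | pd.Series | None = None
) -> dict[str, StabilityResult]:
    """Run the four stability methods on one table; keys are method names."""
    return {
        "delta_ct": delta_ct_stability(table),
        "bestkeeper": bestkeeper(table),
        "normfinder": normfinder(table, groups=normfinder_groups),
        "genorm": genorm(table),
    }
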