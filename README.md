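# refstab

Reference-gene (housekeeping-gene, HKG) stability analysis for RT-qPCR.

Relative quantification by qPCR divides every target-gene measurement by a
reference gene assumed constant across conditions. That assumption routinely
fails: common treatments — serum starvation for secretome/EV collection,
inflammatory priming with IL-1β — shift the expression of classic
normalizers such as *ACTB* or *GAPDH* by more than the effects being
measured. `refstab` implements the standard computational toolkit used to
vet candidate reference genes from a panel of Ct values, for bench
scientists and bioinformaticians who need a defensible normalizer choice
per experimental condition.

## What it computes

Given a samples × genes table of Ct values (log2-scale; one cycle ≈ 2-fold),
`refstab` provides:

- **Comparative ΔCt** — stability of gene *i* = mean over partners *j* of
  SD<sub>s</sub>(Ct<sub>i,s</sub> − Ct<sub>j,s</sub>), sample (n−1) SD.
- **BestKeeper** — descriptive stability: the mean absolute deviation of a
  gene's Ct from its mean, plus the BestKeeper index (per-sample mean of all
  candidates) and each gene's Pearson r with it.
- **NormFinder** — a variance-decomposition model: after removing gene and
  sample main effects, each gene's residual variance is estimated with a
  small-panel bias correction; stability = √(max(σ̂², 0)). An optional
  grouped variant combines intra- and inter-group variation.
- **geNorm** — average pairwise variation M(i) = mean<sub>j</sub>
  SD(ΔCt<sub>i−j</sub>), with stepwise exclusion of the worst gene down to a
  final best pair.
- **Consensus ranking** — the geometric mean of a gene's four method ranks,
  (r<sub>ΔCt</sub> · r<sub>BK</sub> · r<sub>NF</sub> · r<sub>geNorm</sub>)<sup>1/4</sup>,
  with the geNorm final pair sharing rank 1.
- **Technical normalization** — subtraction of per-sample deviations of the
  positive-PCR-control (PPC) and reverse-transcription-control (RTC) wells.
- **Condition plans** — the four methods + consensus run over single,
  coupled, and pooled condition subsets in one call.
- **2^−ΔΔCt fold changes** — donor-paired relative quantification with
  Shapiro–Wilk-gated t-test / ANOVA + Tukey significance calls.
- **Multivariate overview** — PCA (samples as observations) and UPGMA
  clustering under correlation distance, with tighter-cluster-first leaf
  ordering.
- **Synthetic data** — a generator for donor × condition Ct panels with
  known ground-truth stability order, for pipeline validation.

The package ships the published 15-sample × 5-gene Ct table of
adipose-derived mesenchymal stromal cells (3 donors × 5 culture conditions:
serum `F`, serum+IL-1β `F+IL1`, starvation `S`, starvation+IL-1β `S+IL1`,
and starvation after priming `F+IL1/S`) as `refstab.load_asc_table()`.

## Worked example

```python
import refstab as rs

table = rs.load_asc_table()
serum = table.select_conditions("F")
results = rs.all_methods(serum)
consensus = rs.consensus_rank(results)
print(consensus.table.round(2))
```

prints

```
       rank_delta_ct  rank_bestkeeper  rank_normfinder  rank_genorm  geomean
gene
HPRT1            1.0              2.0              1.5          1.0     1.32
B2M              2.0              3.0              1.5          1.0     1.73
ACTB             3.0              4.0              3.0          3.0     3.22
RPLP0            5.0              1.0              5.0          5.0     3.34
GAPDH            4.0              5.0              4.0          4.0     4.23
```

Each row is one candidate reference gene; the four rank columns come from
the four stability methods (1 = most stable; B2M|HPRT1 share geNorm rank 1
as its final pair), and `geomean` is the fourth root of their product —
so in serum culture *HPRT1* is the best normalizer and *GAPDH* the worst.
Running the full default plan (`rs.run_plan(table)`) shows the winner
changing with condition — *GAPDH* under inflammation, *B2M* under
starvation, *RPLP0* under starvation+IL-1β, and *HPRT1* overall — while
*ACTB* is unanimously last (geomean 5.00) whenever starvation is involved.

The `examples/` directory contains one short script per capability
(ranking, condition plans, fold-change normalizer effects, PCA/clustering,
simulation with ground-truth recovery). A thin CLI mirrors the library:
`refstab normalize | stability | consensus | run | compare | pca | cluster |
simulate` (see `refstab --help`).

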