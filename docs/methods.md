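# Methods

This note records the statistical conventions `refstab` implements, the
choices made where the field's tool descriptions are ambiguous, and what the
synthetic-data generator does and does not emulate.

## Data model

A `CtTable` is a samples × genes matrix of cycle-threshold values with
per-sample metadata (donor, condition). Ct is treated throughout as a
log2-scale abundance (amplification efficiency assumed 2; assays are
expected to be pre-validated at >90% efficiency — no efficiency correction
is applied). Values must lie strictly in (0, 45) cycles; an amplification
call is positive iff Ct < 35 (strict). Technical replicates are collapsed by
arithmetic mean by default (median available); replicates differing by more
than 1.0 cycle are collapsed anyway but logged. Missing cells are
representable but rejected by every stability operation: with complete
published matrices as the reference use case, failing loudly beats silent
imputation.

## Technical normalization

qPCR arrays carry a positive PCR control (PPC) and a reverse-transcription
control (RTC) per sample. When these are tight across samples, their
per-sample deviation from the cross-sample mean is a plate/technical offset
shared by all assays of that sample, and is subtracted:

    adjusted = raw − (ppc_s − mean(ppc)) − (rtc_s − mean(rtc))

applied sequentially (PPC first, then RTC). Mean-centring makes the
procedure scale-preserving (flat controls → identity), invariant to adding a
constant to all control readings, and idempotent once the controls are
re-centred. The report's control SDs use the population (n) denominator,
matching the descriptive convention below. Other normalization schemes
(e.g. scaling) are conceivable; the chosen subtraction is the natural
reading of "technical normalization" for log-scale Ct data and is recorded
in the output report.

## Stability statistics

All four methods score lower = more stable, and are invariant to per-gene
constant offsets; comparative ΔCt, geNorm and NormFinder are additionally
invariant to per-sample offsets (pairwise differencing / double-centring
cancels them), while BestKeeper deliberately is not — per-sample shifts are
exactly the signal its dispersion measure reacts to.

**Comparative ΔCt.** Stability of gene *i* = mean over partners *j* of the
sample SD (n−1) of the per-sample difference Ct_i − Ct_j. The n−1
denominator is required to reproduce the published per-condition values at
n = 3.

**BestKeeper.** The reported "SD" of the original tool is the mean absolute
deviation (MAD) of a gene's Ct from its arithmetic mean — this, not a
root-mean-square SD, reproduces published BestKeeper tables. The original
centres on the geometric mean of Ct; at Ct ≈ 19–28 the two differ by < 0.01
cycles, and the geometric variant is available via `center="geometric"`.
The BestKeeper index (per-sample arithmetic mean over candidates) and each
gene's Pearson correlation with it are reported as extras but never drive
the ranking; the correlation is undefined (NaN) for a constant gene.

**NormFinder.** Ct values enter as log2-scale quantities. Ungrouped model
(default): write x_gs = α_g + β_s + ε_gs and double-centre the matrix
(subtract gene means and sample means, add the grand mean). With
u_g = Σ_s z_gs²/(n−1), the heteroscedastic residual variances satisfy
E[u_g] = (1 − 2/G)σ_g² + (Σ_h σ_h²)/G², giving the bias-corrected estimator

    σ̂_g² = G/(G−2) · (u_g − T̂/G²),  T̂ = G/(G−1) · Σ_g u_g

and stability = √max(σ̂_g², 0). The correction matters at small panel sizes
(G = 5 here). The grouped variant (groups = conditions) applies the same
estimator within each group, adds the shrunken absolute gene × group
interaction d̃_gd = d_gd · γ²/(γ² + σ̂²_gd/n_d) plus its posterior SD, and
averages over groups — the source method's variance-decomposition algebra
rendered directly; it is not exercised by the published tables (the
consensus tooling the reference study used takes no group labels) and is
provided for completeness.

Flooring at zero means genes whose variance estimate goes negative tie at
stability 0 and receive average ranks. On 3-sample subsets this happens for
the top genes, so consensus scores that hinge on NormFinder's 1-vs-2
ordering can differ from published values (e.g. 1.32 vs a printed 1.19)
even though every published *ordering* and every best/worst call is
reproduced. Published NormFinder magnitudes vary across reimplementations;
they are therefore validated as orderings, not magnitudes.

**geNorm.** M(i) = mean over remaining partners of SD(ΔCt_i−j). The worst
gene is excluded stepwise (ties excluded alphabetically-last for
determinism), recording its M at exclusion; the final two genes form the
best pair and share M = SD of their mutual ΔCt. The SD denominator is
selectable; the default n−1 reproduces published final-pair values, while
some published intermediate-step values are more consistent with a
population (n) denominator — both are implemented, and only final-pair
values are treated as exactly reproducible.

## Consensus ranking

Each method contributes ranks at full precision (never at printed
precision — rounding changes rankings); exact ties get average ranks. geNorm
contributes (1, 1, 3, 4, …, G): both final-pair genes at rank 1, the next at
rank 3 — the convention of the comprehensive web tools, recoverable from
published geomeans. The consensus score is the geometric mean of the four
ranks; output is sorted ascending with alphabetical tie-break. A gene ranked
last by all four methods scores exactly G.

## Condition plans

The default `AnalysisPlan` runs 12 analyses: each of the five conditions
alone, six coupled sets ({F, F+IL1}, {S, S+IL1}, {S, F+IL1/S},
{F+IL1, S+IL1}, {F, S}, {F+IL1, F+IL1/S}), and all samples pooled. Each
subset is analysed independently (results depend only on the selected
rows); subsets resolving to fewer than 3 samples are rejected. Custom plans
load from YAML.

## Relative quantification and significance

ΔCt = Ct_target − Ct_HKG per sample; ΔΔCt is donor-paired (the same donor's
reference-condition ΔCt is subtracted — donors are the replicate unit);
fold = 2^−ΔΔCt. The fold-change mean ± SD is computed on the linear-scale
per-donor folds. Significance follows the study conventions: Shapiro–Wilk
at α = 0.01 gates parametric testing (rejection raises an error rather than
silently switching tests); two conditions → unpaired Student's t-test on
ΔCt values by default (`test_scale="fold"` tests per-donor folds against 1);
≥3 conditions → one-way ANOVA with Tukey's post hoc. Calls: significant at
p ≤ 0.05; a "tendency" band at 0.05 < p ≤ 0.1 (stated inconsistently as
"0.1 ≤ p < 0.05" in some sources; the coherent reading is used); "up"/"down"
additionally require mean fold ≥ 2 / ≤ 0.5.

## Multivariate overview

PCA treats samples as observations and genes as variables, mean-centred.
Unit-variance scaling is off by default: the published variance shares for
the packaged dataset (87.2% / 8.6%) are produced by centring alone, and the
source figure states no scaling was applied (its methods text says
otherwise; the numbers settle it). `scale=True` and the transposed
orientation are available. Clustering uses 1 − Pearson r as distance with
average linkage (UPGMA) on both axes; leaf ordering puts the subtree merged
at the lower height first at every node (ties toward the alphabetically
smallest leaf). The exported heatmap matrix is the per-gene row-centred Ct
matrix.

## Synthetic data generator

`generate(spec, seed)` draws Ct[g, s] = baseline_g + shift_{g, cond(s)} +
donor_offset + ε, with ε ~ N(0, σ_g), gene-shared Normal donor offsets
(default SD 0.3 cycles, the order of inter-donor spread typical of expanded
primary cells), and control readings ~ N(18.65, 0.36²) / N(22.62, 0.31²)
(PPC/RTC). The raw table embeds the per-sample control deviations so that
technical normalization exactly recovers the clean table. Generated Cts
outside (5, 40) raise. The designed stability order ranks genes by
(population SD of the shift profile + σ_g).

The built-in `paper_like_spec()` is a 3-donor × 5-condition × 5-gene panel:
baselines 18.5–26.3; starvation shifting the two responsive genes by ~1–2
cycles with distinct per-condition profiles (one further gene drops
slightly under starvation, one responds mildly to IL-1β); σ 0.10–0.30.
Distinct profiles are deliberate: two genes with an *identical* response
profile form a co-regulated pair whose mutual ΔCt is quiet, so pairwise
statistics (comparative ΔCt, geNorm) cannot distinguish them from stable
genes — the classic co-regulation blind spot of these methods. With this
spec the designed best/worst genes win/lose the all-sample consensus in
≳95% of replicate experiments.

What the generator does **not** emulate: amplification curves or raw
fluorescence, heavy-tailed or outlier noise, donor × condition interaction
(donor offsets are gene- and condition-shared), missingness, or co-regulated
gene modules. Passing recovery tests therefore demonstrates the pipeline's
correctness under the additive-Normal model, not robustness to those
real-data features.

## Numerical choices and degenerate inputs

Problem sizes throughout are desk-scale (the packaged study is 15 × 5;
simulation batteries use 200 replicates of the same size), so all
computations are exact linear algebra with no iterative fitting. SDs: n−1
for stability statistics unless noted; population (n) for descriptive
statistics and control summaries — the denominators published tables imply.
Constant genes: stability 0 (ΔCt/geNorm/BestKeeper), NaN correlation with
the BestKeeper index, error under PCA scaling and correlation-distance
clustering. Two-gene tables: geNorm degenerates to the final pair, equal to
the comparative ΔCt value. Identical groups in the t-test return p = 1.

## Limitations

- Published NormFinder magnitudes are not reproduced (see above); orderings
  are.
- BestKeeper output is limited to MAD, index and index correlations — no
  regression/CV table.
- geNorm's V(n/n+1) "how many reference genes" statistic is not computed.
- No instrument-native file parsing; CSV/TSV only.
- Fold-change analysis assumes complete donor matching across the two
  conditions; unbalanced designs are rejected, not modelled.
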