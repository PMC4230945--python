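# Methods

## Screening model

A reference-gene candidate should be moderately and flatly expressed.
Screening works on a gene × sample abundance matrix (RPKM-like units) bound
to a factorial design (organ × growth stage). Sample groups are the margins
of that design: one organ across all stages, one stage across all organs
(3 + 5 = 8 groups under the default 3 × 5 layout). Per (gene, group) the
package computes the mean, sample SD (n − 1 denominator; a config switch
allows n), CV% = 100·SD/mean and MFC = max/min.

Decision rule: a (gene, group) passes when `round(CV, 2) ≤ cv_max` (default
20%) and `round(MFC, 2) ≤ mfc_max` (default 1.50). Comparison happens at
two-decimal precision with ≤ semantics because published screening tables
print two decimals and list borderline passers at exactly the threshold;
strict `<` at full precision would reclassify printed passers. The candidate
set is the union of genes passing in at least `min_groups` groups (default
1); a stricter intersection-style screen is available by raising it. An
abundance window (default 50–500) on the per-group means excludes weak genes
and rRNA-like genes with means in the thousands; whether the window applies
to per-group means or per-sample values is a genuinely open convention — we
use group means (configurable via the grouping argument). Genes on a
user-supplied housekeeping list are exempt from the screen and carried into
the downstream panel regardless; benchmarking novel candidates against the
traditional panel requires keeping the panel.

The packaged fixture `load_ginseng_screening()` holds the printed per-group mean/CV/MFC
values for the 20-gene ginseng panel (10 housekeeping, 10 novel genes). The
originating study deposited no raw RPKM or Ct data, so its downstream
stability values (geNorm M values, NormFinder scores, BestKeeper CV±SD) are
not recomputable from public material; only the screening table itself is
reproduced, and all other validation runs on synthetic data with planted
truth.

## geNorm

Input: relative quantities Q = E^(minCt − Ct) per gene, E the per-amplicon
amplification factor in (1, 2.2], default 2.0 (perfect doubling) when no
efficiency file is given. Each gene's maximum Q is 1 by construction.

* Pairwise variation V[j,k] = SD over samples (n − 1) of log2(Q_j/Q_k).
* M_j = mean of V[j,k] over the other active genes; with two genes both M
  equal their V.
* Stepwise exclusion: remove the highest-M gene, recompute, until two
  remain; those two share rank 1 (the method cannot order them — their
  2-gene M values are identical), the next gene is rank 3.
* Normalization factor NF_n = per-sample geometric mean of the n most
  stable genes' Q; V(n/n+1) = SD over samples of log2(NF_n/NF_{n+1}) for
  n = 2 … G−1. The recommended panel size is the smallest n with
  V(n/n+1) < cutoff (default 0.15); when never reached, the result is
  `None` rather than a forced choice.

Numerical choices: ties on M exclude the gene occurring later in input
order (deterministic, logged in the exclusion order); genes with any
missing Q are dropped with a logged warning before analysis because the
pairwise matrix requires completeness; an all-missing gene is an error.
Adding a constant to one gene's Ct (equivalently rescaling its Q) changes
no M and no V — this shift invariance is asserted by property tests.

## NormFinder

Input scale: y = −Ct, which is log2 expression up to a per-gene additive
constant; an efficiency-corrected y = log2(Q) path is equally valid and all
statistics are invariant to per-gene constants, so both give identical
results at E = 2. Model: y[i,s] = gene effect + sample effect + group bias
d_ig + noise with gene-specific variance γ²_i.

Sample centering z[i,s] = y[i,s] − meanᵢ y[i,s] removes the sample effect
but mixes 1/n of every gene's noise into each row. Writing v_ig for the
within-group sample variance of z[i,·], expectation algebra on the model
gives E[v_ig] = γ²_ig(1 − 2/n) + Σ_k γ²_kg/n², hence the mean-unbiased
estimator

    γ̂²_ig = max(0, (v_ig − Σ_k v_kg/(n(n−1))) / (1 − 2/n)),

undefined at n = 2 (the package requires ≥3 genes) and floored at zero with
flooring logged. Unbiasedness is enforced by a Monte-Carlo oracle rather
than by fidelity to the original closed-source spreadsheet, whose exact
arithmetic is unverifiable; the estimator is test-pinned.

Grouped mode (≥2 groups, each with K_g ≥ 2 samples): d̂_ig is the deviation
of gene i's group mean of z from its across-group average (zero-sum per
gene); its sampling noise is γ̂²_ig/K_g, so it is shrunk by the signal
fraction d̃ = d̂·τ̂²/(τ̂² + γ̂²/K) with τ̂² the floored moment estimate of
the true inter-group variance (0/0 defined as no shrinkage). Stability
ρ_i = meanᵍ(|d̃_ig| + √(γ̂²_ig/K_g)); ungrouped ρ_i = √γ̂²_i. Lower is more
stable; ties rank by input order.

## BestKeeper

Descriptive dispersion of raw Ct per gene: arithmetic and geometric mean,
range, SD and CV% = 100·SD/mean. The default SD is the mean absolute
deviation around the arithmetic mean — the original tool's convention —
with the classic n − 1 SD behind `sd_method="classic"`; which convention a
given published table used is usually unstated, so both are first-class.
The index is the per-sample geometric mean Ct of the candidates (≤ 10 genes
by default, mirroring the original limit; the cap is configuration, not
statistics), and each gene is correlated against it (Pearson r, two-sided p
from the t distribution with n − 2 df; zero-variance genes report missing
with a logged reason). Ranking is by (CV, SD) ascending.

Known limitation: raw-Ct dispersion confounds a gene's own instability with
shared sample-loading variation and with its baseline Ct (through the CV
denominator). With a large shared sample effect, BestKeeper's ranking
converges toward uninformative; the planted-recovery scenarios below take
this into account.

## Consensus

Per sample set the three rankings are tabulated side by side (genes outside
BestKeeper's capped input show a missing rank, and the pipeline feeds
BestKeeper the 10 most stable genes by geNorm order when more are present).
The aggregate is the geometric mean of the available ranks — the common
"comprehensive ranking" convention — with ties broken by geNorm rank and
then input order; the arithmetic mean is available as an option.
Aggregation is monotone: improving one method's rank can only improve the
aggregate.

The pipeline derives its sample sets from the design table rather than
hard-coding them: the total set, one per organ level, one per stage level —
nine sets under the default 3 × 5 design. NormFinder group labels are
chosen per set (`auto`): the first margin with ≥2 levels of ≥2 samples each
(organ for the total set); single-organ or single-stage sets fall back to
ungrouped mode since their other margin has one sample per level. All
pipeline outputs are written with fixed float formatting; two runs of the
same configuration are byte-identical.

## Synthetic data generator

Per gene the truth plants a baseline abundance and baseline Ct, a residual
log2 SD γ, and organ/stage offsets (log2, centered). Per sample a shared
loading/RT effect (SD `sample_effect_sd`, Ct cycles) is added to the Ct
table only — RPKM values are treated as library-normalized. Technical
replicates add Gaussian well noise (`replicate_sd`). All noise is Gaussian
on the log2/Ct scale, the standard qPCR error model; a `heavy_tail_frac`
option substitutes t(3) draws for robustness checks. Expected stability
order = ascending γ² + between-cell variance of the offsets.

Defaults mirror the motivating study design: 20 genes (10 housekeeping-like
with residual SD 0.25–0.6 log2 and organ/stage offsets of SD 0.35, one
rRNA-like gene with ~2500 RPKM and SD 0.9, 10 novel genes with SD 0.08–0.2
and near-zero offsets), 3 organs × 5 stages × 3 replicates, baselines
Ct 19–24 (rRNA-like 15.1, one late amplicon 26.4), RPKM 80–500, sample
effect SD 0.3 cycles, replicate SD 0.15 cycles, E = 2.0.

What the generator does not emulate: count-based sampling noise at low
abundance, amplification-efficiency drift across runs, plate/batch effects,
inhibitor-induced non-linearity, or correlated co-regulation between genes.
Passing recovery tests therefore demonstrates that the algorithms rank
planted log-scale variance structure correctly, not that any particular
real panel is stable.

## Validation scenarios and problem sizes

* geNorm oracle: 200 random matrices (3–6 genes × 3–8 samples) checked
  against an independent loop-based brute force to 1e-10 (observed
  agreement ~1e-15).
* NormFinder estimator: 400 Monte-Carlo draws per planted γ² ∈
  {0.01, 0.1, 0.5} at n = 10 genes, K = 50 samples; median |relative bias|
  of the per-gene mean estimate must stay below 5%.
* Planted outlier: 8 genes on the 15-sample study design, stable residual
  SD 0.10 vs outlier 0.80 log2 (an 8× margin). The margin is wide by
  design: BestKeeper's per-gene Ct SD carries the shared sample-effect
  variance (0.3² cycles²) on top of the planted residual, so at 15 samples
  a narrower gradient would test sampling noise rather than the
  implementation. Each method must rank the outlier last in ≥95% of 200
  seeded runs.
* Consensus top-1 recovery uses a separate gradient scenario (equal
  baselines, sample effect SD 0.05) — the regime in which all three
  methods, including BestKeeper, measure the same planted gradient.
* Full pipeline: 20 genes × 15 samples × 3 replicates, two runs compared
  byte for byte across all 48 report files.

## Degenerate inputs

Empty matrices, header-only files, duplicate genes or wells, Ct outside
(0, 50), efficiencies outside (1, 2.2], groups with fewer than two samples,
singleton active sets, single-gene indices and all-missing genes raise
`ValueError` with coordinates; partial missingness is dropped (geNorm,
BestKeeper descriptives) or propagated (replicate collapse) with logged
counts, never imputed — substituting 0 or 40 for a failed well biases every
variance statistic downstream.
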