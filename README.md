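# refstab

Selection and validation of reference genes for qRT-PCR normalization.

Quantitative RT-PCR measures a transcript relative to one or more reference
genes, so the result is only as reliable as the references are stable. This
package implements the full workflow used to establish a reference-gene
panel for a new organism or tissue series (the motivating case: a medicinal
plant sampled over three organs and five growth stages):

1. **Screening** candidates from a transcriptome abundance matrix
   (RPKM-like): an abundance window (default 50–500) plus per-group
   coefficient of variation (CV = 100·SD/mean < 20%) and maximum fold change
   (MFC = max/min ≤ 1.5) thresholds.
2. **Stability ranking** of the candidates from qPCR Ct data with the three
   classic algorithms, implemented here as scikit-learn-style estimators:
   - **geNorm** (`GeNorm`): M value = mean SD over samples of pairwise
     log2 expression ratios; stepwise exclusion of the least stable gene;
     V(n/n+1) pairwise variation of normalization factors with the 0.15
     cutoff to choose how many references to use. Quantities are computed
     as Q = E^(minCt − Ct) with per-amplicon efficiency E (default 2.0).
   - **NormFinder** (`NormFinder`): model-based decomposition into
     intra-group variance γ² (estimated with a centering-bias–corrected,
     mean-unbiased estimator) and shrunk inter-group bias d̃; stability
     ρ = meanᵍ(|d̃| + √(γ²/K)), or √γ² ungrouped.
   - **BestKeeper** (`BestKeeper`): per-gene Ct dispersion (mean absolute
     deviation and CV), the geometric-mean Ct index, and each gene's
     Pearson correlation with it; 10-gene cap as in the original tool.
3. **Consensus**: a side-by-side rank table per sample set and a
   geometric-mean rank aggregate producing one final order.
4. **Synthetic data** with planted per-gene variances, group offsets,
   sample effects and replicate noise, so every stage can be validated
   against known ground truth.

The published per-group CV/MFC screening table of the ginseng reference-gene
study (10 housekeeping + 10 novel genes over 8 sample groups) ships as a
package fixture (`refstab.load_ginseng_screening()`); the study's raw RPKM/Ct data were
never deposited, so analyses beyond that table run on synthetic data.

## Worked example

```python
import refstab as r

truth = r.default_truth(seed=7)              # 20 genes, 3 organs x 5 stages x 3 reps
ct = r.collapse_replicates(r.simulate_ct(truth))
q = r.ct_to_quantity(ct)                     # Q = E^(minCt - Ct)

model = r.GeNorm().fit(q.T)                  # samples x genes
print(model.most_stable_pair_)               # ('ARF', 'QCR')
print(model.recommended_n_)                  # 2
print(model.m_final_.sort_values().head(3).round(3))
# QCR         0.121
# ARF         0.121
# 60SRPL13    0.164

nf = r.stability_values(-ct.sample_matrix(), groups=ct.design.table["organ"])
bk = r.BestKeeper().fit(ct.sample_matrix().loc[model.stability_order_[:10]].T)
agg = r.aggregate_ranks(r.method_rank_table(model, nf, bk))
print(agg.head(3).round(2)[["genorm", "normfinder", "bestkeeper", "aggregate"]])
#           genorm  normfinder  bestkeeper  aggregate
# QCR          1.0         1.0         1.0       1.00
# ARF          1.0         4.0         2.0       2.00
# 60SRPL13     3.0         2.0         7.0       3.48
```

The most stable pair (`ARF`, `QCR`) shares geNorm rank 1 with M = 0.121
(genes with M below ~0.5 are conventionally considered stable), and
V(2/3) = 0.051 < 0.15 means two reference genes suffice for this dataset.
All three methods and the aggregate put `QCR` first — consistent with the
planted truth, where it is among the flattest genes.

The same workflow is available from the shell:

```sh
refstab simulate --seed 7 --out-dir sim/
refstab screen sim/expression.tsv sim/design.tsv
refstab genorm sim/ct.tsv sim/design.tsv --efficiency sim/efficiency.tsv
refstab run-all config.yaml --out-dir reports/   # all nine sample sets
```

`run-all` analyses nine sample sets (total, each organ, each stage), writing
per-set TSVs, a combined `summary.json` and a plain-text rank table.

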