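# creglink

Integrated scATAC-seq + scRNA-seq analysis of cancer gene regulation:
quality control and metacell aggregation, distance-penalized graphical-lasso
co-accessibility, peak–gene links calibrated against a trans-chromosomal
null, differential and cell-type-conserved regulatory regions, chromVAR-style
motif deviations with Tn5 footprinting, a tumor-specific transcription-factor
filter, and consensus-NMF intratumor meta-programs. A synthetic-cohort
generator with planted ground truth makes every stage testable end to end.

`creglink` is aimed at computational biologists who want a compact, fully
tested re-implementation of this multi-omic regulatory workflow — either to
analyze desk-scale data or to study the statistical behavior of the methods
themselves under known ground truth.

## The statistics at the core

**Peak–gene links.** Cells are aggregated into metacells (k = 50 nearest
neighbors in LSI space). For every peak *p* within ±500 kb of a gene *g*'s
TSS, the Pearson correlation r(p, g) of log-normalized metacell accessibility
and expression is standardized against an empirical null built from 1000
peaks on *other* chromosomes:

    z = (r − μ₀) / σ₀,   p = 2·Φ(−|z|),   FDR by Benjamini–Hochberg.

A link is *reliable* when FDR < 0.1 (0.2 for the OC cohort) **and** the
peak's graphical-lasso co-accessibility with a promoter peak of the gene
exceeds 0.2. Co-accessibility is the regularized partial correlation
−Ω₍ᵢⱼ₎/√(Ω₍ᵢᵢ₎Ω₍ⱼⱼ₎) from a graphical lasso whose elementwise penalty grows
linearly with genomic distance (cap 500 kb).

**Motif deviations.** For motif *m* and cell *c*, the deviation
d = (obs − exp)/exp compares reads in motif-matched peaks with the
depth-weighted expectation; z-scores standardize d against GC- and
accessibility-matched background peak sets. Tumor-specific TFs must show
higher deviation z, increased footprint binding, and elevated expression in
tumor versus normal epithelial cells.

**Meta-programs.** Per tumor sample, consensus NMF (KL-divergence
multiplicative updates, k = 2..6, 30 restarts) factorizes the centered,
zero-clipped relative expression of tumor cells; the rank precedes the
largest drop of the cophenetic coefficient. Top-100 gene signatures are
module-scored in every sample, and Ward clustering of the cross-sample
average program-score correlations yields meta-programs (clusters covering
under half of the samples are dropped).

## Worked example

```python
import numpy as np
from creglink import SimulationConfig, simulate_cohort
from creglink import preprocess, linking, coaccess

cohort = simulate_cohort(SimulationConfig(seed=11))
keep = np.asarray(cohort.atac.counts.sum(axis=0)).ravel() > 500
atac, rna = cohort.atac.subset_cells(keep), cohort.rna.subset_cells(keep)

emb = preprocess.lsi_embedding(atac, n_components=150)
mc = preprocess.make_metacells(emb, k=50, seed=3, n_groups=200)
agg_a = np.asarray(preprocess.log_normalize(mc.aggregate(atac.counts)).todense())
agg_r = np.asarray(preprocess.log_normalize(mc.aggregate(rna.counts)).todense())

pairs = coaccess.coaccess_scores(agg_a, atac.peaks)
cand = linking.candidate_pairs(atac.peaks, rna.genes)
corr = linking.grouped_correlation(cand, agg_a, agg_r, rna.genes.index)
null = linking.build_null(atac.peaks, rna.genes, agg_a, agg_r, seed=5)
mu0, sd0 = null.lookup(corr["gene"])
corr["z"], corr["p"] = linking.null_significance(corr["r"].to_numpy(), mu0, sd0)
net = linking.build_link_network(corr, pairs, atac.peaks, rna.genes)

truth = {(r.gene, r.peak) for r in cohort.truth.true_links.itertuples()}
pred = {(r.gene, atac.peak_ids[r.peak_index])
        for r in net[net.reliable].itertuples()}
tp = len(truth & pred)
print(f"candidate pairs: {len(cand)}")
print(f"reliable links:  {len(pred)}")
print(f"recall {tp/len(truth):.2f}  precision {tp/len(pred):.2f}")
```

Output on this seed:

```
candidate pairs: 38219
reliable links:  90
recall 0.90  precision 1.00
```

The cohort plants 50 enhancer–gene links (each also couples the gene's
promoter peak, so the truth table holds 100 peak–gene pairs) with a grouped
correlation of 0.6; at the default cutoffs the network recovers 90% of them
with no false links.

The same analysis runs from the shell:

```bash
creglink simulate --out cohort/ --seed 11
creglink run --config pipeline.yaml       # simulate → qc → … → nmf
```

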