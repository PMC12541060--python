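# Methods

This note documents the models and procedures implemented in `creglink`, the
assumptions behind them, the parameters that matter, and what the synthetic
cohort does and does not emulate.

## Quality control

Per-cell metrics follow the conventions of the single-cell ATAC/RNA QC
literature:

* **TSS enrichment** — both fragment ends count as Tn5 insertions; the score
  is the mean insertion density over TSS ± 1000 bp divided by the mean
  density in the outer 100 bp flanks, with a pseudocount of 0.5 in the
  denominator. Cells without fragments score 0. The precise formula is this
  package's choice (the metric is usually named but not defined); it is
  Signac-like in spirit.
* **Nucleosome signal** — mononucleosome (147–294 bp) over subnucleosome
  (< 147 bp) fragment counts; +inf when a cell has no subnucleosome
  fragments.
* **Filters** — strict inequalities exactly as printed: scATAC cells need
  2000 < counts < 30,000, nucleosome signal < 4 and TSS enrichment > 2;
  scRNA cells 500 < counts < 50,000, 500 < features < 6,000 and
  mitochondrial fraction < 25%; multiome cells 1,000 < ATAC counts < 20,000
  and 500 < RNA counts < 25,000 (the multiome preset carries no nucleosome
  bound). A cell sitting exactly on a bound is removed. On desk-scale
  synthetic cohorts the pipeline config substitutes bounds matched to the
  simulated depths; the presets above are the defaults for real-scale data.

## Metacells and LSI

Accessibility is TF-IDF transformed (term frequency × ln(1 + n_cells/df))
and reduced by truncated SVD; the first component is dropped when its
absolute correlation with sequencing depth exceeds 0.9. Metacells are formed
by sampling seed cells without replacement and taking each seed's k = 50
nearest neighbors; a group whose Jaccard overlap with an accepted group
exceeds 0.8 is discarded. The overlap cap and the seed-sampling order are
this package's (cicero-like) choices and are configurable. The pipeline uses
150 LSI components by default so that the latent cell-state manifold of the
synthetic cohort — and comparably complex real data — is fully represented
in the space that the metacell neighborhoods are built in.

Grouped data for linking are metacell-summed counts, log-normalized
(ln(1 + count/total × 10⁴)). Metacell groups are computed on the ATAC
embedding and applied to both modalities of the same (paired) cells; for
unpaired data the module refuses rather than guessing an alignment.

## Co-accessibility

Each chromosome is tiled with overlapping windows. The spec-level constraint
is a 500 kb interaction cap with half-window steps; windows of length
750 kb (cap + step) stepping by 250 kb guarantee that every peak pair within
500 kb shares at least one window, and the pair relation additionally
requires center distance ≤ 500 kb, so no more distant pair is ever scored.

Within a window, a graphical lasso runs on the empirical correlation matrix
of log-normalized aggregated accessibility with elementwise penalty
ρ_ij = scale × d_ij / 500 kb (diagonal ridge 10⁻³). cicero calibrates its
distance penalty by subsampling; here the scale is a fixed, configurable
constant (default 1.0). The solver is a block coordinate-descent graphical
lasso with a per-element penalty matrix (numba-compiled); sklearn's
implementation only supports scalar penalties. The co-accessibility score is
the partial correlation −Ω_ij/√(Ω_ii Ω_jj), averaged over windows containing
the pair. For a 2×2 problem the solution is analytic —
soft(s, ρ)/(1 + ridge) — and the implementation is tested against it.

## Peak–gene links

Candidate pairs are peaks whose center lies within ±500 kb of the
strand-aware TSS, on the same chromosome. Pearson correlations across
metacell groups are standardized per gene against the trans-chromosomal
null: 1000 peaks sampled once per chromosome from *other* chromosomes
(with replacement if fewer exist, logged), correlated with every gene of
that chromosome; z = (r − μ₀)/σ₀ with two-sided normal p-values, pooled BH
across all candidate pairs of a cohort. Two-sided p-values are a deliberate
choice (repressive distal elements exist); the promoter definition is
TSS ± 1 kb. A peak that is itself a promoter peak of the gene is assigned
promoter co-accessibility 1 (self co-accessibility), so promoter-proximal
pairs pass the co-accessibility gate on the strength of their correlation
alone. Reliability: FDR < 0.1 (0.2 for cohort label "OC") and promoter
co-accessibility > 0.2.

The trans null is what makes the calibration work on structured data: any
correlation that cell-state or composition structure induces between random
peak–gene pairs is present identically in the trans pairs, so μ₀ and σ₀
absorb it. On a synthetic cohort with no planted links the resulting
p-values are uniform (KS α = 0.01) and essentially no reliable links are
called.

## Differential and conserved regions

DARs are one-vs-rest positive markers per cell type: Wilcoxon rank-sum on
log-normalized accessibility with Signac-like gates (detection fraction
≥ 0.05 in the target type, log2 fold change ≥ 0.25 on expm1-means with
pseudocount 1, BH FDR < 0.05). For total sample sizes ≤ 16 the p-value is
computed by exact enumeration of label assignments (midranks, so ties are
handled); otherwise by the tie-corrected normal approximation. A DAR is
cancer-exclusive when it has no ≥1 bp overlap with a same-cell-type DAR of
another cancer type.

Iterative overlap merging keeps the highest-scoring remaining region and
discards everything overlapping it (≥ 1 bp) until no regions remain — ties
break on a secondary score, then coordinate order. Conserved regulatory
regions per cell type: reliable-link peaks intersected with the cell type's
DARs per cancer, merged across cancers, and retained only when supported by
≥ 2 cancer types. Merging happens before the ≥2-cancer filter; the opposite
order is a documented alternative.

## Motif deviations and footprints

Motif scanning converts PFMs to log-odds against a uniform background
(pseudocount 0.8); a peak matches when any position on either strand reaches
80% of the motif's maximum score; N bases score 0.

Deviations follow the chromVAR recipe: expectation = cell total × the read
fraction of the matched peak set, raw deviation (obs − exp)/exp, and
bias-corrected z against 50 background motif-sets in which each matched peak
is replaced by an accessibility/GC-matched background peak. Two refinements
matter at desk scale: (1) background peaks are drawn from an equal-occupancy
50×50 grid of GC × log mean accessibility with ring-expansion to a pool of
at least 60 candidates and Gaussian kernel weighting, and (2) each
background set's deviations are rescaled by √(share_b/share_m) — the ratio
of the background set's expected read share to the motif set's — which
removes the residual 1/E mismatch that heavy-tailed peak accessibility
otherwise leaves in the z denominator. With these, per-motif z on a cohort
with no biological structure has |mean| < 0.05 and sd ≈ 1.0–1.1.

Footprint profiles aggregate Tn5 insertions over motif sites and cells of a
type, ±250 bp around the center, normalized by the mean count in the
200–250 bp flanks. No hexamer insertion-bias correction is applied (the
generator has no sequence bias); the API leaves room for a bias table. The
*binding statistic* used by the TF filter is the mean of the 11-bp-smoothed,
flank-normalized profile over the 10–60 bp shoulders around the center.
Occupied motifs concentrate accessibility immediately around the protected
core; a pointwise maximum is dominated by single-base sampling spikes in
small pseudo-bulks, whereas the shoulder mean measures the same occupancy
signal robustly.

The tumor-specific-TF triple criterion: (a) higher deviation z in tumor
cells (Wilcoxon BH FDR < 0.05, positive direction), (b) higher binding
statistic in tumor pseudo-bulk, (c) expression log2FC > 0.25 with Wilcoxon
FDR < 0.05. The quantitative gates are declared defaults — the criterion is
qualitative in its original statement.

## Intratumor programs

Per sample with > 500 tumor cells (strict), the relative expression matrix
is log-normalized expression centered per gene across that sample's tumor
cells with negatives set to zero. Consensus NMF uses KL-divergence
multiplicative updates (Brunet variant, authored here so the per-iteration
monotonicity contract is testable; reconstruction is cross-checked against
sklearn's MU solver), nrun = 30 restarts (10 in the benchmark harness), and
the consensus matrix of argmax-H co-clustering. The cophenetic coefficient
is the correlation between (1 − consensus) and the cophenetic distances of
its average-linkage dendrogram. The selected rank is the k immediately
preceding the largest drop (ties to the smallest k; a never-decreasing curve
selects the largest k with a warning). Benchmark-level rank recovery is a
recovery simulation: the cohort is regenerated per trial and the recovered
rank is the majority k* over its samples — per-sample ranks legitimately
vary by one in this kind of analysis. The benchmark's meta-program assembly
factorizes at the rank pooled across trials (``discover_programs`` accepts a
fixed rank for this).

Module scores are Seurat-style: genes binned into 24 equal-occupancy bins by
average expression, 100 control genes per set gene from the same bin, score
= mean(set) − mean(controls) per cell. Meta-programs: every program's
top-100 signature is scored in every sample; within-sample Pearson
correlations of program scores are averaged across samples; Ward clustering
on 1 − average correlation is cut at the number of clusters (2 to
n_programs − 1) maximizing the silhouette; clusters whose members span
fewer than half of the samples are dropped; the meta-program signature is
the 100 genes with the highest average W score over member programs.

## The synthetic cohort

The generator emulates a paired multi-sample carcinoma cohort: ~10 cell
types (tumor, normal epithelium, immune and stromal), 4 chromosomes, one
promoter peak per gene plus distal peaks kept ≥ 4 kb from TSSs, Poisson
counts with library-size variation, and a fragment file with TSS-enriched,
nucleosome-banded fragments. Key generative choices:

* **Cell states.** Cells occupy ~120 discrete micro-states in a 128-dim
  latent space (cluster centers plus within-state noise 0.25); every peak
  and gene responds along its own random loading direction (amplitudes
  0.5–1.0 for peaks, scaled by 0.25 for genes). Metacell kNN tracks the
  micro-states, so feature co-variation survives aggregation, and the
  trans-chromosomal null sees the same state-driven correlation structure
  as candidate pairs — which is exactly what makes the calibration testable.
* **Planted links.** Each link couples an enhancer peak (5–150 kb from the
  TSS), the gene's promoter peak and the gene's expression through aligned
  state loadings. Metacell aggregation, counting noise, expression
  overdispersion and the log transform attenuate the realized correlation by
  a measured factor of ~0.78 under the default conditions, so the planted
  alignment is divided by that factor — the grouped Pearson correlation then
  has expectation ≈ `link_effect_size` (measured 0.61 at a planted 0.6).
  Planted peaks and genes get an accessibility/expression floor so counting
  noise does not drown the covariation; both the enhancer and promoter pairs
  enter the truth table.
* **Tumor TFs.** Peaks matched to the chosen motifs are amplified by
  `tf_activity_shift` in tumor cells; the TF genes (which share the motif
  names) are overexpressed by `tf_expr_fold`; tumor fragments carry a
  protected ±10 bp core (insertion probability × (1 − dip)) and elevated
  10–60 bp shoulders at the motif sites. TF genes are given a sensible
  expression baseline and cell-type-uniform background so the filter tests
  fold change, not detectability.
* **Programs.** Tumor cells are assigned balanced primary programs with mild
  cross-program mixing; sibling programs share a weak flat "parent" module
  with graded strengths (a two-level hierarchy), and ~10% of tumor cells
  carry private extreme gene signatures ("stressed" cells). These features
  reproduce the qualitative behavior of consensus NMF on real tumor data:
  coarse factorizations merge programs the same way in every restart, while
  ranks above the planted one chase individual outlier cells with
  init-dependent membership, so the cophenetic coefficient is high through
  the true rank and declines beyond it. RNA rates carry lognormal
  overdispersion (sd 0.7). Even so, the cophenetic curve on clean low-rank
  data is nearly flat (all values > 0.97), so single-sample rank selection
  by the maximum-drop rule retains a ~10% error rate; the cohort-level
  majority over samples is the robust statistic and is what the benchmark
  reports.
* **Degraded cells.** A configurable fraction of cells has low depth,
  diffuse fragments, mononucleosome-heavy length distributions and elevated
  mitochondrial expression, giving the QC stage something real to remove.

What the generator does **not** emulate: sequence-level reads, GC effects on
counts (peak GC is an independent label), doublets, batch effects, CNV
profiles, or trans-chromosomal co-accessibility. Passing tests therefore
demonstrate the statistical machinery under a faithful but idealized noise
model, not robustness to those artifacts.

Benchmark problem sizes (the package's own choices): the linking cohorts use
4 samples × 1200 cells, 2000 peaks, 610 genes and 200 metacells; the
TF-activity cohorts 2 × 1000 cells; the NMF cohort 3 samples with ≈ 540
tumor cells each. Determinism: a single integer seed drives every scenario;
identical configs and seeds produce byte-identical cohorts.

## Numerical notes

* The glasso declares convergence when the working covariance changes by
  < 10⁻⁵ between sweeps; non-convergence raises with the window id.
* Pearson correlations are clipped to [−1, 1]; zero-variance vectors drop
  the pair (logged) rather than propagating NaNs.
* BH adjustment delegates to statsmodels and is verified against a hand
  step-up implementation.
* `select_k` treats drops equal within 10⁻⁹ as ties (smallest k wins).
* The degenerate noise-free link check asserts rank correlation ≈ 1; the
  log1p transform attenuates the Pearson correlation of the planted
  monotone relationship slightly even without noise.
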