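# Methods

## Problem and overall procedure

`scdiscrim` identifies transcripts whose expression discriminates tumor
from normal epithelial single cells. The input is a transcripts × cells
matrix of processed FPKM values with a binary per-cell label (tumor =
positive). The pipeline has five stages:

1. **Expression filter.** Keep transcripts whose maximum FPKM across all
   cells is strictly greater than a threshold (default 5). This removes
   transcripts never expressed at a usable level in any cell.
2. **mRMR ranking.** Rank transcripts by minimal-redundancy
   maximal-relevance on discretized expression (details below), keeping the
   top `top_n` (default 500).
3. **Incremental feature selection (IFS).** Evaluate the nested prefixes of
   the ranking (top 1, top 2, …, top `k_max`) with a support-vector
   classifier under leave-one-out cross-validation (LOOCV); summarize each
   prefix by Sn, Sp, ACC and MCC; select the smallest prefix size attaining
   the maximal MCC (the peak of the IFS curve). MCC is the peak criterion
   because the class sizes are unbalanced and MCC is robust to that.
4. **Direction assignment.** Split the optimal transcript set into
   tumor-upregulated and tumor-downregulated groups by two-way hierarchical
   clustering of the row-standardized matrix; a per-transcript
   mean-difference labeling is computed as an independent cross-check.
5. **Enrichment.** Hypergeometric (upper tail) enrichment of the up and
   down gene lists against user-supplied GMT collections with
   Benjamini–Hochberg FDR, plus a two-list overlap test against external
   signatures.

## Mutual information and discretization

Relevance and redundancy both use the plug-in mutual information estimate
on observed frequencies,

    I(X;Y) = Σ_{a,b} p(a,b) log2 [ p(a,b) / (p(a) p(b)) ],

in bits (zero-count cells contribute 0). The base-2 convention only
rescales the per-step criterion monotonically, but recorded scores need a
fixed unit.

MI requires categorical inputs, so continuous expression is discretized
per transcript into three states relative to its own distribution: high
(+1) above mean + σ·sd, low (−1) below mean − σ·sd, mid (0) otherwise,
with the population (divide-by-n) standard deviation and σ = 1 by default.
This is the convention of the classical mRMR implementation. A
zero-variance transcript discretizes to all-mid and therefore carries no
relevance. σ is exposed (`discretize.sigma`) for sensitivity checks.

Both discretization and every continuous consumer of expression (the SVM,
the clustering) operate on log2(FPKM+1) by default (`transform: log2p1`,
configurable to `identity`). FPKM is heavy-tailed; mean ± sd bins on the
raw scale collapse to near-degenerate states dominated by the largest
values. The transform choice is recorded in the run manifest so runs are
comparable.

## mRMR ranking

With Ω the transcript universe, S the already-selected list and c the cell
label, the greedy step selects the candidate t maximizing the difference
form of the criterion

    D(t) − R(t) = I(x_t; c) − (1/|S|) Σ_{s∈S} I(x_t; x_s),

with R defined as 0 while S is empty (so the first pick maximizes plain
relevance). The quotient variant is not implemented. Ties are broken by
lower original row index, with candidates within 1e-12 of the step
maximum treated as tied so that exact mathematical ties cannot be flipped
by floating-point summation order; the ranking is fully deterministic.

The loop is incremental: when a transcript is selected, its pairwise MI
with all remaining candidates is computed once, vectorized over
candidates, and accumulated into a running redundancy sum — O(p·n_cells)
per step rather than O(p·m) separate MI calls. Per-step criterion values
("scores") and plain relevance are both recorded, since either could be
reported as a transcript's headline score.

## Classifier and LOOCV

The default classifier mirrors the documented defaults of the classical
libsvm interface: RBF kernel, cost C = 1, kernel width γ = 1/n_features,
with per-feature standardization. Scaling statistics are computed on the
training fold only and applied to the held-out cell, which prevents
leakage while matching implementations that scale inside each fit.
Constant features in a fold are centered only. No class weighting or
hyperparameter search is done. The classifier consumes the continuous
log2(FPKM+1) values; the three-state discretization exists only for MI.

Metric conventions: Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/n,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A zero denominator
yields NaN for Sn/Sp (undefined is distinguished from poor and propagates
as missing, never as 0) and MCC = 0 by convention. Note that an
all-wrong classifier (TP = TN = 0 with FP, FN > 0) has a non-zero
denominator and MCC = −1; the zero-denominator convention applies only
when a full row or column of the confusion table is empty.

### LOOCV behavior on null data

On label-permuted data the LOOCV MCC is not centered exactly at zero:
removing one cell leaves a training fold whose majority is the opposite
class, and any classifier that leans toward the training majority is
thereby biased toward negative MCC. At 30+30 cells with 10 noise features
the null MCC over 20 permutation seeds has mean ≈ −0.1 and sd ≈ 0.2, so
individual seeds can reach |MCC| ≈ 0.5 while the seed-averaged MCC stays
well within ±0.35 of zero. The calibration test therefore bounds the
mean across seeds, which is the quantity the permutation null actually
pins down at this sample size.

## Two-way clustering and direction labels

Rows (transcripts) are z-scored (population sd) on the log2 scale;
zero-variance rows become all-zero. Both dimensions are clustered
agglomeratively with distance 1 − Pearson correlation and complete
linkage (configurable to euclidean/ward). Correlation distance matches
the "scaled expression" semantics of the heatmap; the distance between a
constant vector and anything is undefined and is replaced by 1
(uncorrelated). The transcript dendrogram is cut into exactly two
clusters; the cluster with the higher mean z over tumor cells is labeled
up-in-tumor. Zero-variance transcripts are excluded from the linkage,
appended after the dendrogram leaf order, and assigned by the sign of
their raw tumor − normal mean difference (tie → down, logged). If the
two-cut is trivial (a singleton cluster), labeling falls back to the
mean-difference rule with a warning. Both the cluster-based and the
mean-based labelings are available, since on real data the two can
disagree for transcripts with weak or non-monotone signal.

## Enrichment and overlap statistics

Enrichment is one-sided (upper tail): enrichment, not depletion, is the
hypothesis. Set members are restricted to the background before counting;
query genes outside the background are dropped with a warning. The
default background is all gene symbols surviving the expression filter
(each symbol once); a fixed integer background is available for
reproducing literature comparisons. FDR is Benjamini–Hochberg step-up,
the field default. Significance thresholds are configuration, not
constants. Symbol matching is uppercase-exact with no alias resolution.

The two-list overlap test builds the 2×2 table on a fixed-size background
and reports the sample odds ratio ad/bc, the hypergeometric upper-tail
p-value and the expected overlap |A||B|/N. The Haldane 0.5 correction is
applied only when a denominator cell (b or c) is zero — a zero overlap
between non-empty lists is an honest odds ratio of 0, not a degenerate
one. For reference list sizes (342 and 55 genes sharing 22 on a
32,610-gene background) the sample odds ratio is ≈ 67.2 and the tail
p ≈ 10^−29; published analyses of the same sizes have printed larger
odds ratios, which is expected if a different background size or a
conditional-MLE estimator was used — neither is recoverable from printed
set sizes alone, so this package reports the sample statistic it defines.

## Synthetic data generator

The generator emulates exactly the features the pipeline's claims rest
on, with defaults chosen as the study-shape conditions:

| parameter | default | meaning |
|---|---|---|
| n_pos / n_neg | 272 / 160 | tumor / normal cell counts |
| n_transcripts | 2,000 | transcript universe |
| n_de | 30 | planted differential transcripts (half up, half down) |
| lfc | 2.0 | planted log2 fold-change in the tumor class |
| base_mu / base_sigma | 2.0 / 1.5 | log2-scale mean / sd of baseline expression |
| dropout_p | 0.3 | probability an entry is zeroed |
| n_redundant_blocks × block_size | 3 × 5 | correlated copies of planted transcripts |
| redundant_noise_sd | 0.5 | log2-scale sd of copy noise (pairwise r ≈ 0.9) |

Each entry is 2^Normal(base_mu, base_sigma) — log-normal, heavy-tailed,
continuous like FPKM (a negative-binomial count model would suit UMI data,
not FPKM). Dropout is independent Bernoulli zeroing, class-independent by
default so that planted signal is a pure mean shift (a class-dependent
dropout option exists, off by default). Redundant blocks copy a planted
transcript's latent log2 values plus Gaussian noise, giving strongly
correlated feature groups that exercise the redundancy penalty. A toy GMT
is emitted whose first two sets are ~80% planted-up and ~80% planted-down
genes, with random sets alongside.

What the generator does **not** model: per-transcript baseline
heterogeneity, mean–variance coupling, batch effects, doublets, cell-type
mixtures, or the empirical FPKM distribution of any particular data set.
Passing the recovery tests therefore shows the pipeline is correct and
sensitive under its own assumptions — not that it will attain the same
recovery on real single-cell data.

## Problem sizes used in tests

The end-to-end recovery check runs the generator defaults (2,000
transcripts × 432 cells), ranks the top 200 and scans the IFS curve to
k = 60 — large enough that the planted structure, the redundancy penalty
and the MCC peak are all non-trivial, and small enough to run in a few
minutes on one core. Unit tests use desk-scale fixtures (≤ a few hundred
transcripts); oracle-equivalence checks use ≤ 8 transcripts × ≤ 40 cells
where brute-force evaluation is exact and instant.

## Known limitations

* The plug-in MI estimator is biased upward at small cell counts; ranks
  are comparable within a run, not across cohort sizes.
* LOOCV with 432 cells refits the classifier per held-out cell; quadratic
  growth makes cohorts beyond a few thousand cells impractical without a
  k-fold option (deliberately not offered — the design fixes LOOCV).
* The 2-cut direction assignment assumes the optimal set actually splits
  into two expression programs; mixed or non-monotone transcripts are
  forced into one of the two groups (compare with the mean-based labels).
* Enrichment results depend entirely on the user-supplied annotation
  collections; no annotation content ships with the package.
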