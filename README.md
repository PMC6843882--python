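# scdiscrim

Discriminative-transcript discovery for tumor versus normal single cells.

Single-cell RNA-seq of a tumor and its adjacent normal tissue yields an
FPKM matrix over hundreds of epithelial cells. `scdiscrim` answers the
question *which transcripts, jointly, separate the tumor cells from the
normal cells* — and in which direction each moves — using a feature-
selection pipeline built for unbalanced two-class cell cohorts:

1. **Filter**: keep transcripts with max FPKM > 5 across all cells.
2. **mRMR ranking**: greedily rank transcripts by mutual information with
   the cell class minus mean mutual information with transcripts already
   chosen, so the top of the list is discriminative *and* non-redundant:

       max_t [ I(x_t; c) − (1/|S|) Σ_{s∈S} I(x_t; x_s) ]

   MI is the plug-in estimate in bits on three-state (low/mid/high)
   discretized expression.
3. **Incremental feature selection**: evaluate the top-1, top-2, …, top-k
   prefixes with an RBF support-vector classifier under leave-one-out
   cross-validation; pick the prefix with the highest Matthews correlation
   coefficient (MCC), the peak of the IFS curve.
4. **Direction assignment**: two-way hierarchical clustering (1 − Pearson,
   complete linkage) splits the optimal set into tumor-up and tumor-down
   groups, heatmap-ready.
5. **Enrichment**: hypergeometric tests of the up/down gene lists against
   GMT gene-set collections with Benjamini–Hochberg FDR, plus a two-list
   overlap test against published signatures.

A seeded synthetic-data generator (log-normal FPKM, dropout, planted
differential transcripts, correlated redundant blocks) makes the whole
pipeline testable end-to-end without any external download. See
`docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np
from scdiscrim import (SyntheticSpec, generate, filter_by_max_expression,
                       discretize, mrmr_rank, run_ifs, two_way_cluster)

matrix, truth = generate(SyntheticSpec(n_transcripts=500, n_de=12, seed=1))
filtered = filter_by_max_expression(matrix, threshold=5.0)

ranking = mrmr_rank(discretize(filtered), filtered.labels, top_n=50)
curve = run_ifs(filtered, ranking, k_max=20)
peak = curve.peak_metrics
print(f"IFS peak at k={curve.peak_k}: Sn={peak.sn:.3f} Sp={peak.sp:.3f} "
      f"ACC={peak.acc:.3f} MCC={peak.mcc:.3f}")

part = two_way_cluster(filtered.subset_transcripts(ranking.order[:curve.peak_k]))
print(f"{len(part.up_in_tumor)} transcripts up in tumor, "
      f"{len(part.down_in_tumor)} down in tumor")

planted = set(truth.planted_ids)
optimal = {filtered.transcript_ids[i] for i in ranking.order[:curve.peak_k]}
print(f"recovered {len(planted & optimal)}/{len(planted)} planted transcripts")
```

prints (≈1 minute; 432 cells, 500 transcripts, 12 planted):

```
IFS peak at k=17: Sn=0.956 Sp=0.875 ACC=0.926 MCC=0.840
11 transcripts up in tumor, 6 down in tumor
recovered 11/12 planted transcripts
```

The peak says 17 transcripts classify the 272 tumor / 160 normal cells
with MCC 0.84 under LOOCV; 11 of the 12 planted differential transcripts
sit inside that optimal set, and the clustering splits it into the
expected up- and down-in-tumor groups.

The same pipeline is available from the shell:

```sh
scdiscrim simulate --seed 1 --out sim/
scdiscrim ifs --matrix sim/matrix.tsv --labels sim/labels.tsv \
              --top-n 200 --k-max 60 --out run/
scdiscrim run --config run.yaml     # full pipeline from a YAML config
```

Stage outputs (`ranks.tsv`, `curve.tsv`, `peak.txt`, `signature_up.txt`,
`signature_down.txt`, `heatmap.tsv`, enrichment tables and
`manifest.json`) are plain TSV/JSON; the manifest records every parameter
and seed needed to re-run a result bit-identically.

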