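"""Direction assignment for the optimal transcript set via two-way clustering.

The classifier-selected transcripts discriminate tumor from normal cells but
carry no sign. Two-way agglomerative clustering of the row-standardized
log2(FPKM+1) matrix — transcripts one way, cells the other, with
1 - Pearson correlation distance and complete linkage — splits the
transcripts into two groups; the group with the higher mean z-score over
tumor cells is labeled up-in-tumor, the other down-in-tumor. A per-transcript
mean-difference labeling is provided as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .expression_io import ExpressionMatrix
from .preprocessing import apply_transform

logger = logging.getLogger(__name__)


@dataclass
class SignaturePartition:
    """Up/down split of the optimal set plus heatmap-ready ordering.

    ``zmatrix`` is the row-standardized matrix aligned to
    ``transcript_order`` x ``cell_order``. ``method`` records which labeling
    produced the split ("cluster" or "mean").
    """

    up_in_tumor: list[str]
    down_in_tumor: list[str]
    transcript_order: list[str]
    cell_order: list[str]
    zmatrix: np.ndarray
    method: str = "cluster"

    def __post_init__(self) -> None:
        if set(self.up_in_tumor) & set(self.down_in_tumor):
            raise ValueError("up and down sets must be disjoint")
        if set(self.up_in_tumor) | set(self.down_in_tumor) != set(self.transcript_order):
            raise ValueError("up + down must cover the transcript set")


def zscore_rows(values: np.ndarray) -> np.ndarray:
    """Row-standardize with population sd; zero-variance rows become all-0."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    np.divide(values - mu, sd, out=out, where=sd > 0)
    return out


def _linkage(z: np.ndarray, metric: str, linkage: str) -> np.ndarray:
    d = pdist(z, metric=metric)
    # correlation distance is undefined against constant vectors; treat the
    # pair as uncorrelated rather than poisoning the whole linkage
    d = np.nan_to_num(d, nan=1.0)
    return sch.linkage(d, method=linkage)


def direction_by_mean(
    x: ExpressionMatrix, transform: str = "log2p1"
) -> SignaturePartition:
    """Label each transcript by the sign of its tumor - normal mean difference.

    A tie (exact zero difference) goes to down-in-tumor with a warning.
    Input orders are kept as-is; no clustering is performed.
    """
    x.require_both_classes()
    logv = apply_transform(x, transform).values
    diff = logv[:, x.labels == 1].mean(axis=1) - logv[:, x.labels == 0].mean(axis=1)
    n_ties = int(np.sum(diff == 0))
    if n_ties:
        logger.warning("%d transcripts tie at zero mean difference; assigned down", n_ties)
    up = [t for t, d in zip(x.transcript_ids, diff) if d > 0]
    down = [t for t, d in zip(x.transcript_ids, diff) if d <= 0]
    return SignaturePartition(
        up_in_tumor=up,
        down_in_tumor=down,
        transcript_order=list(x.transcript_ids),
        cell_order=list(x.cell_ids),
        zmatrix=zscore_rows(logv),
        method="mean",
    )


def two_way_cluster(
    x: ExpressionMatrix,
    transform: str = "log2p1",
    metric: str = "correlation",
    linkage: str = "complete",
) -> SignaturePartition:
    """Cluster transcripts and cells; split transcripts into up/down groups.

    Rows are z-scored on the transformed scale; both dimensions are
    agglomeratively clustered (default 1 - Pearson distance, complete
    linkage); the transcript dendrogram is cut into exactly two clusters and
    the cluster with higher mean z over tumor cells becomes up-in-tumor.
    Zero-variance transcripts cannot be clustered on correlation distance:
    they keep an all-zero z-row, are assigned by the sign of their raw
    tumor - normal mean difference (tie -> down, logged), and are appended
    after the dendrogram leaf order. If the two-cut is trivial (a singleton
    cluster), labeling falls back to the mean-difference rule with a warning.
    """
    if x.n_transcripts < 2 or x.n_cells < 2:
        raise ValueError("two-way clustering needs >= 2 transcripts and >= 2 cells")
    x.require_both_classes()
    logv = apply_transform(x, transform).values
    z = zscore_rows(logv)

    constant = z.std(axis=1) == 0
    active = np.flatnonzero(~constant)
    if active.size < 2:
        logger.warning("fewer than 2 non-constant transcripts; using mean-based labels")
        return direction_by_mean(x, transform)

    zt = z[active]
    row_link = _linkage(zt, metric, linkage)
    row_leaves = sch.leaves_list(row_link)
    col_link = _linkage(z.T, metric, linkage)
    col_leaves = sch.leaves_list(col_link)

    assign = sch.fcluster(row_link, t=2, criterion="maxclust")
    sizes = np.bincount(assign)[1:]
    tumor = x.labels == 1
    if sizes.min() == 1 and active.size > 2:
        logger.warning("trivial 2-cut (singleton cluster); using mean-based labels")
        mean_part = direction_by_mean(x, transform)
        up_ids, down_ids = set(mean_part.up_in_tumor), set(mean_part.down_in_tumor)
        method = "mean"
    else:
        mean_z_tumor = np.array([
            zt[assign == c][:, tumor].mean() for c in (1, 2)
        ])
        up_cluster = 1 + int(np.argmax(mean_z_tumor))
        up_ids = {x.transcript_ids[active[i]] for i in np.flatnonzero(assign == up_cluster)}
        down_ids = {x.transcript_ids[active[i]] for i in np.flatnonzero(assign != up_cluster)}
        method = "cluster"
        # constant transcripts: direction from raw mean difference
        for i in np.flatnonzero(constant):
            d = (x.values[i, tumor].mean() - x.values[i, ~tumor].mean())
            if d > 0:
                up_ids.add(x.transcript_ids[i])
            else:
                if d == 0:
                    logger.warning(
                        "constant transcript %s ties at zero difference; assigned down",
                        x.transcript_ids[i],
                    )
                down_ids.add(x.transcript_ids[i])

    transcript_order = [x.transcript_ids[active[i]] for i in row_leaves]
    transcript_order += [x.transcript_ids[i] for i in np.flatnonzero(constant)]
    cell_order = [x.cell_ids[i] for i in col_leaves]

    row_index = {t: i for i, t in enumerate(x.transcript_ids)}
    cell_index = {c: i for i, c in enumerate(x.cell_ids)}
    zmat = z[np.ix_(
        [row_index[t] for t in transcript_order],
        [cell_index[c] for c in cell_order],
    )]
    return SignaturePartition(
        up_in_tumor=sorted(up_ids, key=row_index.get),
        down_in_tumor=sorted(down_ids, key=row_index.get),
        transcript_order=transcript_order,
        cell_order=cell_order,
        zmatrix=zmat,
        method=method,
    )


def plot_heatmap(partition: SignaturePartition, labels_by_cell: dict[str, int],
                 path: str) -> None:
    """Render the clustered heatmap with tumor/normal column colors.

    Tumor columns are annotated red and normal columns green. Requires
    matplotlib (optional extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(8, 6), height_ratios=[1, 24], sharex=True
    )
    colors = ["red" if labels_by_cell[c] == 1 else "green" for c in partition.cell_order]
    ax_bar.bar(range(len(colors)), np.ones(len(colors)), color=colors, width=1.0)
    ax_bar.axis("off")
    im = ax.imshow(partition.zmatrix, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xlabel("cells (dendrogram order)")
    ax.set_ylabel("transcripts (dendrogram order)")
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.savefig(path, dpi=120)
    plt.close(fig)
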