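"""Minimal-redundancy maximal-relevance (mRMR) transcript ranking.

Given discretized expression states and a binary cell-type target, each
transcript's *relevance* is its mutual information with the target and its
*redundancy* is the mean mutual information with the transcripts already
selected. The greedy ranking repeatedly picks the candidate maximizing

    relevance(t) - redundancy(t)        (the difference form)

so the top of the list is both discriminative and non-duplicative. Mutual
information is the plug-in (empirical frequency) estimate in bits.

The greedy loop is incremental: after a transcript is selected, only its
pairwise mutual information with the remaining candidates is computed
(vectorized over candidates), giving O(p * n_cells) work per step for p
candidates. Ties are broken by lower original row index, which makes the
ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import DiscretizedMatrix

__all__ = [
    "mutual_information",
    "MrmrState",
    "RankedTranscripts",
    "relevance",
    "redundancy",
    "mrmr_rank",
]


def _encode(v) -> tuple[np.ndarray, int]:
    """Map an arbitrary categorical vector to codes 0..k-1."""
    v = np.asarray(v)
    _, codes = np.unique(v, return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1 if codes.size else 0


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two categorical vectors, in bits.

    I(X;Y) = sum_{a,b} p(a,b) log2( p(a,b) / (p(a) p(b)) ), with zero-count
    cells contributing 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    xc, kx = _encode(x)
    yc, ky = _encode(y)
    joint = np.bincount(xc * ky + yc, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_joint(joint[None, :, :])[0]


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits from a stack of joint count tables (m, kx, ky)."""
    n = joint.sum(axis=(1, 2), keepdims=True).astype(float)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return np.nansum(terms, axis=(1, 2))


def entropy(x) -> float:
    """Shannon entropy of a categorical vector, in bits."""
    return mutual_information(x, x)


def _mi_rows_vs_vector(rows: np.ndarray, y: np.ndarray, ky: int) -> np.ndarray:
    """MI in bits between every row of a state matrix and one code vector.

    ``rows`` holds three-state entries in {-1,0,1}; ``y`` holds codes
    0..ky-1. Vectorized via one bincount over all rows.
    """
    m, n = rows.shape
    codes = (rows.astype(np.int64) + 1) * ky + y[None, :]
    offsets = (np.arange(m, dtype=np.int64) * (3 * ky))[:, None]
    joint = np.bincount((codes + offsets).ravel(), minlength=m * 3 * ky)
    return _mi_from_joint(joint.reshape(m, 3, ky))


@dataclass
class MrmrState:
    """Bookkeeping for the greedy selection loop.

    ``selected`` is the rank order so far; ``candidates`` the still-eligible
    transcript indices; ``target`` the per-cell class vector.
    """

    selected: list[int]
    candidates: set[int]
    all_indices: range
    target: np.ndarray

    def __post_init__(self) -> None:
        if set(self.selected) & self.candidates:
            raise ValueError("selected and candidates must be disjoint")


@dataclass
class RankedTranscripts:
    """mRMR ranking: transcript indices with per-step criterion values.

    ``scores`` holds the relevance-minus-redundancy criterion at the step a
    transcript was selected; ``relevance`` its mutual information with the
    target. The first entry always maximizes relevance over the universe.
    """

    order: list[int]
    scores: list[float]
    relevance: list[float]
    transcript_ids: list[str] | None = None
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        if not (len(self.order) == len(self.scores) == len(self.relevance)):
            raise ValueError("order, scores and relevance must be parallel")
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranked indices must be unique")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> list[int]:
        return self.order[:k]


def relevance(t: int, state: MrmrState, disc: DiscretizedMatrix) -> float:
    """Mutual information of transcript t's states with the target."""
    if t in state.selected:
        raise ValueError(f"transcript {t} is already selected")
    return mutual_information(disc.states[t], state.target)


def redundancy(t: int, state: MrmrState, disc: DiscretizedMatrix) -> float:
    """Mean MI of transcript t with the selected set; 0 when none selected."""
    if t in state.selected:
        raise ValueError(f"transcript {t} is already selected")
    if not state.selected:
        return 0.0
    return float(
        np.mean([mutual_information(disc.states[t], disc.states[s])
                 for s in state.selected])
    )


def mrmr_rank(
    disc: DiscretizedMatrix, target, top_n: int = 500
) -> RankedTranscripts:
    """Greedy mRMR ranking of all transcripts, truncated to ``top_n``.

    At each step the candidate maximizing relevance minus mean redundancy
    with the already-selected transcripts is appended; ties go to the lower
    original row index.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    y, ky = _encode(target)
    if ky < 2:
        raise ValueError("target must contain both classes")
    if len(y) != disc.n_cells:
        raise ValueError("target length must equal the number of cells")
    p = disc.n_transcripts
    n_select = min(top_n, p)

    states = disc.states
    rel = _mi_rows_vs_vector(states, y, ky)
    red_sum = np.zeros(p)
    selected_mask = np.zeros(p, dtype=bool)

    order: list[int] = []
    scores: list[float] = []
    relevances: list[float] = []
    for step in range(n_select):
        crit = rel - (red_sum / step if step else 0.0)
        crit[selected_mask] = -np.inf
        # lowest row index wins among candidates within numerical tolerance
        # of the maximum, so exact mathematical ties cannot be flipped by
        # floating-point summation order
        best = int(np.argmax(crit >= crit.max() - 1e-12))
        order.append(best)
        scores.append(float(crit[best]))
        relevances.append(float(rel[best]))
        selected_mask[best] = True
        if step + 1 < n_select:
            red_sum += _mi_rows_vs_vector(states, states[best] + 1, 3)
    return RankedTranscripts(order=order, scores=scores, relevance=relevances)


def annotate_ranking(
    ranking: RankedTranscripts, transcript_ids, gene_symbols
) -> RankedTranscripts:
    """Attach identifiers (in ranking order) for table output."""
    ranking.transcript_ids = [transcript_ids[i] for i in ranking.order]
    ranking.gene_symbols = [gene_symbols[i] for i in ranking.order]
    return ranking
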