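"""Hypergeometric gene-set enrichment and two-gene-list overlap testing.

Enrichment of a query gene list against a collection of sets uses the
one-sided (upper tail) hypergeometric test: with a background of N genes of
which K belong to a set, the probability of seeing at least k set members
among n query genes is P(X >= k), X ~ Hypergeometric(N, K, n). P-values are
adjusted across sets with the Benjamini-Hochberg step-up FDR.

The overlap test compares two gene lists (e.g. a derived signature against
a published one) on a fixed-size background: it builds the 2x2 table,
reports the sample odds ratio (with a Haldane 0.5 correction only when a
zero cell occurs), the hypergeometric upper-tail p-value of the overlap,
and the overlap expected under independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]

from .expression_io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the annotated genes in the background, n
    the query size, k the observed hits. Evaluated with the survival
    function (log-space internally), clipped to [0, 1].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters: K={K}, n={n}, N={N}")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1.0
    return float(min(1.0, max(0.0, hypergeom.sf(k - 1, N, K, n))))


@dataclass
class EnrichmentRow:
    set_name: str
    k_hits: int
    set_size_in_background: int
    query_size: int
    background_size: int
    p: float
    fdr: float = float("nan")
    hit_genes: list[str] = field(default_factory=list)


def enrich(
    query: Sequence[str],
    sets: GeneSetCollection,
    background: Sequence[str],
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of a query list against every set.

    Query genes outside the background are dropped with a warning; set
    members are restricted to the background before counting. Rows are
    BH-adjusted and sorted by p ascending, ties by set name.
    """
    bg = list(dict.fromkeys(g.upper() for g in background))
    if not bg:
        raise ValueError("empty background")
    bg_set = set(bg)
    q = list(dict.fromkeys(g.upper() for g in query))
    dropped = [g for g in q if g not in bg_set]
    if dropped:
        logger.warning("%d query genes absent from background were dropped", len(dropped))
    q = [g for g in q if g in bg_set]
    q_set = set(q)

    rows: list[EnrichmentRow] = []
    for gs in sets:
        members = [g for g in gs.genes if g in bg_set]
        hits = [g for g in q if g in set(members)]
        p = hypergeom_upper_tail(len(hits), len(members), len(q), len(bg))
        rows.append(
            EnrichmentRow(
                set_name=gs.name,
                k_hits=len(hits),
                set_size_in_background=len(members),
                query_size=len(q),
                background_size=len(bg),
                p=p,
                hit_genes=hits,
            )
        )
    if rows:
        fdrs = bh_fdr([r.p for r in rows])
        for r, f in zip(rows, fdrs):
            r.fdr = float(f)
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame([
        {
            "set_name": r.set_name,
            "k_hits": r.k_hits,
            "set_size_in_background": r.set_size_in_background,
            "query_size": r.query_size,
            "background_size": r.background_size,
            "p": r.p,
            "fdr": r.fdr,
            "hit_genes": ",".join(r.hit_genes),
        }
        for r in rows
    ])
    return df


@dataclass
class OverlapResult:
    """2x2 overlap of two gene lists on a background of known size.

    ``a`` = overlap, ``b`` = in A only, ``c`` = in B only, ``d`` = neither.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_upper: float
    expected_overlap: float
    haldane_corrected: bool = False

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def overlap_test(
    list_a: Sequence[str], list_b: Sequence[str], background_size: int
) -> OverlapResult:
    """Hypergeometric overlap test between two gene lists.

    Both lists are uppercased and de-duplicated. The upper-tail p-value is
    P(overlap >= a) drawing |B| genes from the background with |A| marked.
    """
    if background_size < 1:
        raise ValueError("background_size must be positive")
    A = set(g.upper() for g in list_a)
    B = set(g.upper() for g in list_b)
    if len(A | B) > background_size:
        raise ValueError(
            f"background ({background_size}) smaller than the union ({len(A | B)})"
        )
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = background_size - a - b - c
    # Haldane 0.5 correction only when the denominator vanishes; a zero
    # overlap with non-empty lists is an honest odds ratio of 0
    corrected = b == 0 or c == 0
    if corrected:
        orx = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orx = (a * d) / (b * c)
    return OverlapResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=orx,
        p_upper=hypergeom_upper_tail(a, len(A), len(B), background_size),
        expected_overlap=len(A) * len(B) / background_size,
        haldane_corrected=corrected,
    )
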