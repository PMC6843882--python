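"""Two-class synthetic single-cell FPKM generator with known ground truth.

Emulates the statistical features of processed single-cell FPKM data that
the discriminative-transcript pipeline relies on:

* heavy-tailed non-negative expression — each entry is log-normal on the
  log2 scale, value = 2 ** Normal(base_mu, base_sigma);
* dropout — each entry is independently zeroed with probability
  ``dropout_p`` (class-independent by default, so planted signal is a pure
  mean shift);
* planted differential transcripts — ``n_de`` transcripts whose tumor-class
  log2-mean is shifted by +lfc (half, "up") or -lfc (half, "down");
* redundant blocks — groups of transcripts that copy one planted
  transcript's latent log2 values plus small Gaussian noise, exercising the
  mRMR redundancy penalty with strongly correlated features.

Default cell counts (272 tumor / 160 normal) mirror the colorectal
epithelial cohort the pipeline was designed around. Generation is a pure
function of the spec: the same spec yields a byte-identical matrix.

A toy gene-set collection is emitted alongside the truth: one set is 80%
planted-up genes, one is 80% planted-down genes, and the rest are random —
enough structure for the enrichment stage to find at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix, GeneSetCollection


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic data set; generation is seeded and pure."""

    n_pos: int = 272
    n_neg: int = 160
    n_transcripts: int = 2000
    n_de: int = 30
    lfc: float = 2.0
    base_mu: float = 2.0
    base_sigma: float = 1.5
    dropout_p: float = 0.3
    n_redundant_blocks: int = 3
    block_size: int = 5
    redundant_noise_sd: float = 0.5
    dropout_p_pos: float | None = None  # class-dependent dropout, off by default
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg) < 2:
            raise ValueError("need at least 2 cells per class")
        if self.n_de > self.n_transcripts:
            raise ValueError("n_de cannot exceed n_transcripts")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.dropout_p_pos is not None and not (0 <= self.dropout_p_pos < 1):
            raise ValueError("dropout_p_pos must be in [0, 1)")
        if self.base_sigma <= 0 or self.redundant_noise_sd < 0:
            raise ValueError("base_sigma must be > 0 and redundant_noise_sd >= 0")
        if self.n_redundant_blocks > self.n_de:
            raise ValueError("each redundant block copies a distinct planted transcript")
        if self.n_redundant_blocks * self.block_size > self.n_transcripts - self.n_de:
            raise ValueError("redundant copies exceed the non-planted transcript budget")


@dataclass
class GroundTruth:
    """What was planted: ids, directions, redundancy structure, toy sets."""

    planted_ids: list[str]
    directions: dict[str, str]              # transcript id -> "up" | "down"
    block_members: dict[str, list[str]]     # planted parent id -> copy ids
    gene_symbol_of: dict[str, str]
    gene_sets: GeneSetCollection = field(default_factory=GeneSetCollection)

    @property
    def planted_symbols(self) -> list[str]:
        return [self.gene_symbol_of[t] for t in self.planted_ids]


def _toy_gene_sets(
    truth_dirs: dict[str, str],
    symbol_of: dict[str, str],
    all_symbols: list[str],
    rng: np.random.Generator,
    n_random_sets: int = 10,
    set_size: int = 15,
) -> GeneSetCollection:
    planted_up = [symbol_of[t] for t, d in truth_dirs.items() if d == "up"]
    planted_down = [symbol_of[t] for t, d in truth_dirs.items() if d == "down"]
    planted = set(planted_up) | set(planted_down)
    others = [s for s in all_symbols if s not in planted]
    set_size = min(set_size, len(all_symbols))

    collection = GeneSetCollection()
    for name, members in (("PLANTED_UP_SET", planted_up), ("PLANTED_DOWN_SET", planted_down)):
        if not members:
            continue
        # all planted genes plus random fillers, keeping the planted
        # fraction at ~80% of the set
        n_fill = max(1, round(0.25 * len(members)))
        filler = list(rng.choice(others, size=n_fill, replace=False))
        collection.add(name, "synthetic truth-enriched set", members + filler)
    for j in range(n_random_sets):
        members = rng.choice(all_symbols, size=set_size, replace=False)
        collection.add(f"RANDOM_SET_{j:02d}", "synthetic random set", list(members))
    return collection


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic expression matrix plus its ground truth.

    Planted transcripts and block copies are scattered over random row
    positions so rank order carries no information about the truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_pos + spec.n_neg
    labels = np.r_[np.ones(spec.n_pos, dtype=np.int8), np.zeros(spec.n_neg, dtype=np.int8)]
    tumor = labels == 1

    p = spec.n_transcripts
    n_up = spec.n_de - spec.n_de // 2
    # latent log2 expression, iid baseline
    latent = rng.normal(spec.base_mu, spec.base_sigma, size=(p, n_cells))

    # choose row positions: planted first from a random permutation, then copies
    perm = rng.permutation(p)
    planted_rows = perm[: spec.n_de]
    n_copies = spec.n_redundant_blocks * spec.block_size
    copy_rows = perm[spec.n_de : spec.n_de + n_copies]

    directions_by_row = {}
    for j, row in enumerate(planted_rows):
        direction = "up" if j < n_up else "down"
        directions_by_row[row] = direction
        shift = spec.lfc if direction == "up" else -spec.lfc
        latent[row, tumor] += shift

    block_by_row: dict[int, list[int]] = {}
    for b in range(spec.n_redundant_blocks):
        parent = planted_rows[b]
        rows = copy_rows[b * spec.block_size : (b + 1) * spec.block_size]
        block_by_row[parent] = list(rows)
        for r in rows:
            latent[r] = latent[parent] + rng.normal(0, spec.redundant_noise_sd, size=n_cells)

    values = np.exp2(latent)
    drop_p = np.full(n_cells, spec.dropout_p)
    if spec.dropout_p_pos is not None:
        drop_p[tumor] = spec.dropout_p_pos
    values[rng.random(size=(p, n_cells)) < drop_p[None, :]] = 0.0

    transcript_ids = [f"SYNT{i:07d}.1" for i in range(p)]
    gene_symbols = [f"SYNG{i:05d}" for i in range(p)]
    cell_ids = [f"cell_{'T' if labels[i] else 'N'}{i:04d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(
        values=values,
        transcript_ids=transcript_ids,
        gene_symbols=gene_symbols,
        cell_ids=cell_ids,
        labels=labels,
    )

    symbol_of = dict(zip(transcript_ids, gene_symbols))
    planted_ids = [transcript_ids[r] for r in planted_rows]
    directions = {transcript_ids[r]: d for r, d in directions_by_row.items()}
    block_members = {
        transcript_ids[parent]: [transcript_ids[r] for r in rows]
        for parent, rows in block_by_row.items()
    }
    truth = GroundTruth(
        planted_ids=planted_ids,
        directions=directions,
        block_members=block_members,
        gene_symbol_of=symbol_of,
        gene_sets=_toy_gene_sets(directions, symbol_of, gene_symbols, rng),
    )
    return matrix, truth
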