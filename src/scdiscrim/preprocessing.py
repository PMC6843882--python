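"""Expression filtering, log transform, and three-state discretization.

Transcripts are kept when their maximum FPKM across all cells exceeds a
threshold (default 5, strict inequality). Mutual-information estimation
downstream needs categorical variables, so continuous expression is
discretized per transcript into three states relative to its own mean:

* ``+1`` (high)  when value > mean + sigma * sd
* ``-1`` (low)   when value < mean - sigma * sd
* ``0``  (mid)   otherwise

with the population (divide-by-n) standard deviation and sigma = 1 by
default. A zero-variance transcript discretizes to all-mid. By default the
transform applied before discretization (and before the classifier and the
clustering) is log2(FPKM + 1), since raw FPKM is heavy-tailed enough that
mean +- sd bins on the raw scale are nearly degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionMatrix

TRANSFORMS = ("log2p1", "identity")


@dataclass
class DiscretizedMatrix:
    """Three-state (low/mid/high) integer matrix with its thresholds.

    ``states`` is int8 with entries in {-1, 0, +1}; ``low_cut``/``high_cut``
    are per-transcript thresholds in transformed-expression units.
    """

    states: np.ndarray
    low_cut: np.ndarray
    high_cut: np.ndarray
    transform: str
    sigma: float

    def __post_init__(self) -> None:
        if not np.all(np.isin(self.states, (-1, 0, 1))):
            raise ValueError("states must be in {-1, 0, +1}")
        if np.any(self.low_cut > self.high_cut):
            raise ValueError("low_cut must not exceed high_cut")

    @property
    def n_transcripts(self) -> int:
        return self.states.shape[0]

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]


def filter_by_max_expression(
    x: ExpressionMatrix, threshold: float = 5.0
) -> ExpressionMatrix:
    """Keep transcripts whose maximum value across cells is > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = np.flatnonzero(x.values.max(axis=1) > threshold)
    if keep.size == 0:
        raise ValueError("empty matrix after filtering")
    return x.subset_transcripts(keep)


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with values mapped v -> log2(v + 1)."""
    return x.with_values(np.log2(x.values + 1.0))


def apply_transform(x: ExpressionMatrix, transform: str = "log2p1") -> ExpressionMatrix:
    if transform == "log2p1":
        return log_transform(x)
    if transform == "identity":
        return x
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def discretize(
    x: ExpressionMatrix, sigma: float = 1.0, transform: str = "log2p1"
) -> DiscretizedMatrix:
    """Discretize each transcript into low/mid/high around its own mean.

    The transform is applied first; thresholds are mean -+ sigma * sd with
    the population standard deviation, recorded per transcript.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = apply_transform(x, transform).values
    mu = v.mean(axis=1)
    sd = v.std(axis=1)  # population sd: zero-variance rows get sd 0
    low = mu - sigma * sd
    high = mu + sigma * sd
    states = np.zeros(v.shape, dtype=np.int8)
    states[v > high[:, None]] = 1
    states[v < low[:, None]] = -1
    return DiscretizedMatrix(
        states=states, low_cut=low, high_cut=high, transform=transform, sigma=sigma
    )
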