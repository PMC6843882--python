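import numpy as np
import pytest

from scdiscrim import ExpressionMatrix, SyntheticSpec, generate


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 transcripts x 4 cells, 2 tumor + 2 normal, hand-written values."""
    return ExpressionMatrix(
        values=np.array([
            [10.0, 8.0, 0.5, 0.2],
            [0.1, 0.0, 6.0, 7.5],
            [3.0, 3.0, 3.0, 3.0],
        ]),
        transcript_ids=["ENST000A.1", "ENST000B.2", "ENST000C.1"],
        gene_symbols=["GENEA", "GENEB", "GENEC"],
        cell_ids=["c1", "c2", "c3", "c4"],
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_synth():
    """100 transcripts, 10 planted, default 272/160 cohort; shared read-only."""
    return generate(SyntheticSpec(n_transcripts=100, n_de=10, seed=7))


def planted_rows(matrix, truth) -> set[int]:
    index = {t: i for i, t in enumerate(matrix.transcript_ids)}
    return {index[t] for t in truth.planted_ids if t in index}
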