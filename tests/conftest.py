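import numpy as np
import pytest

from circust.data_io import ExpressionMatrix


def make_matrix(rows, gene_ids=None, sample_ids=None, state="raw", **kw):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n_g, n_s = rows.shape
    return ExpressionMatrix(
        values=rows,
        gene_ids=gene_ids or [f"G{i + 1}" for i in range(n_g)],
        sample_ids=sample_ids or [f"S{j + 1}" for j in range(n_s)],
        state=state,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)


def circular_arc(a, b):
    """Shorter-arc distance between two angles (scalar helper for tests)."""
    d = abs((a - b) % (2 * np.pi))
    return min(d, 2 * np.pi - d)
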