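import numpy as np
import pandas as pd
import pytest

from pcgrn import ExpressionMatrix


def matrix_from_array(arr, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Wrap a plain 2-D array as an ExpressionMatrix with trivial metadata."""
    arr = np.asarray(arr, dtype=float)
    genes = gene_ids or [f"G{i + 1:03d}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"S{j + 1:03d}" for j in range(arr.shape[1])]
    meta = pd.DataFrame(
        {
            "time_point": [str(j + 1) for j in range(len(samples))],
            "replicate": ["1"] * len(samples),
            "condition": [""] * len(samples),
        },
        index=samples,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), sample_meta=meta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
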